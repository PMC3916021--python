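"""Reliable gene expression: combine per-edge reliability ``mu`` and merged
expression ``sigma`` into the score ``theta``, and select significant
interactions within each training set.

An edge is kept only when its reliability and its expression deviate from
their stratum means in the same direction (``delta = +1``); for those edges
``theta = beta1*mu + beta2*sigma`` with published per-stratum coefficients,
and the high-theta tail (upper-tail z-test, alpha = 0.05) is flagged
significant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ThetaCoefficients:
    """Coefficients of ``theta = beta0 + beta1*mu + beta2*sigma``."""

    beta0: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "beta2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite theta coefficient {name}")


#: Published per-stratum coefficients (intercepts are numerically zero and
#: fixed at 0). Keys are (er_status, grade).
DEFAULT_THETA_COEFFICIENTS: dict[tuple[str, int], ThetaCoefficients] = {
    ("pos", 1): ThetaCoefficients(0.0, 0.4601, 0.7066),
    ("pos", 2): ThetaCoefficients(0.0, 0.4878, 0.6846),
    ("pos", 3): ThetaCoefficients(0.0, 0.4650, 0.7094),
    ("neg", 1): ThetaCoefficients(0.0, 0.4273, 0.7274),
    ("neg", 2): ThetaCoefficients(0.0, 0.4484, 0.7199),
    ("neg", 3): ThetaCoefficients(0.0, 0.4673, 0.7078),
}

DEFAULT_ALPHA = 0.05


def compute_delta(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Direction-of-deviation indicator for each edge.

    ``delta = sign((mu - mean(mu)) * (sigma - mean(sigma)))`` in
    {-1, 0, +1}: +1 when reliability and expression deviate from their
    stratum means in the same direction, -1 when they oppose, 0 when either
    sits exactly on its mean. With fewer than two edges both deviations are
    zero and all deltas are 0 (warned).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape != sigma.shape:
        raise ValueError("mu and sigma must have equal length")
    if mu.size < 2:
        warnings.warn("fewer than 2 edges: all delta set to 0", stacklevel=2)
        return np.zeros_like(mu, dtype=int)
    product = (mu - mu.mean()) * (sigma - sigma.mean())
    return np.sign(product).astype(int)


def filter_positive(edges: pd.DataFrame, delta: np.ndarray | None = None) -> pd.DataFrame:
    """Retain exactly the positively correlated (``delta = +1``) edges."""
    d = edges["delta"].to_numpy() if delta is None else np.asarray(delta)
    kept = edges.loc[d == 1]
    if kept.empty:
        warnings.warn("no positively correlated edges in this stratum", stacklevel=2)
    return kept


def compute_theta(
    mu: np.ndarray, sigma: np.ndarray, coefficients: ThetaCoefficients
) -> np.ndarray:
    """Reliable gene expression ``theta`` for positively correlated edges."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    return coefficients.beta0 + coefficients.beta1 * mu + coefficients.beta2 * sigma


def select_significant(
    theta: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-tail z-test of each theta against the stratum's distribution.

    ``z = (theta - mean) / sd`` with the population (n) standard deviation
    over the stratum's positively correlated edges; ``p`` is the standard
    normal upper-tail probability and an edge is significant when
    ``p < alpha``. A zero-spread stratum yields no significant edges.

    Returns ``(p_values, significant_mask)``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    sd = theta.std(ddof=0)
    # spread below float round-off of the values themselves is no spread
    if theta.size < 2 or sd <= 1e-12 * max(1.0, float(np.abs(theta).max())):
        warnings.warn("degenerate theta spread: no significant edges", stacklevel=2)
        return np.ones_like(theta), np.zeros(theta.shape, dtype=bool)
    z = (theta - theta.mean()) / sd
    p = stats.norm.sf(z)
    return p, p < alpha


def score_stratum(
    edges: pd.DataFrame,
    stratum: tuple[str, int],
    coefficients: dict[tuple[str, int], ThetaCoefficients] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Full per-stratum edge scoring: delta -> positive filter -> theta ->
    significance.

    ``edges`` must carry columns ``gene_a gene_b mu sigma`` (unmeasured
    edges already excluded). Returns the table extended with ``delta``,
    ``theta`` (NaN off the positive set), ``p`` and ``significant``.
    """
    coefficients = DEFAULT_THETA_COEFFICIENTS if coefficients is None else coefficients
    if stratum not in coefficients:
        raise KeyError(f"no theta coefficients for stratum {stratum!r}")
    out = edges.copy()
    if out.empty:
        out["delta"] = pd.Series(dtype=int)
        out["theta"] = pd.Series(dtype=float)
        out["p"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["delta"] = compute_delta(out["mu"].to_numpy(), out["sigma"].to_numpy())
    out["theta"] = np.nan
    out["p"] = np.nan
    out["significant"] = False
    pos = out["delta"] == 1
    if pos.any():
        theta = compute_theta(
            out.loc[pos, "mu"].to_numpy(),
            out.loc[pos, "sigma"].to_numpy(),
            coefficients[stratum],
        )
        p, sig = select_significant(theta, alpha=alpha)
        out.loc[pos, "theta"] = theta
        out.loc[pos, "p"] = p
        out.loc[pos, "significant"] = sig
    return out
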