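"""Expression preprocessing: rescaling, probe collapse, cohort integration,
ER-status x histologic-grade stratification, and the per-gene / per-edge
expression summaries used downstream.

The per-gene summary ``G`` is the quadratic mean (RMS) of a gene's values
over a stratum's samples; the per-edge summary ``sigma`` is the harmonic
mean of the two endpoint ``G`` values, so an edge only scores high when
both of its genes are expressed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ER_LEVELS = ("pos", "neg")
GRADE_LEVELS = (1, 2, 3)

#: The six (ER status, grade) strata, in a fixed order.
STRATA: tuple[tuple[str, int], ...] = tuple(
    (er, g) for er in ER_LEVELS for g in GRADE_LEVELS
)


@dataclass
class TrainingSet:
    """One ER-status x grade stratum of the integrated cohort."""

    er_status: str
    grade: int
    values: pd.DataFrame  # genes x samples, restricted to the stratum

    @property
    def stratum(self) -> tuple[str, int]:
        return (self.er_status, self.grade)

    @property
    def n(self) -> int:
        return self.values.shape[1]


def normalize_dataset(values: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale each gene (row) to [0, 1] within one dataset.

    ``(g - min_i) / (max_i - min_i)`` per feature i across the dataset's
    samples. A constant feature maps to all zeros (warned).
    """
    if not np.issubdtype(values.to_numpy().dtype, np.number):
        raise ValueError("expression matrix contains non-numeric values")
    lo = values.min(axis=1)
    hi = values.max(axis=1)
    span = hi - lo
    flat = span == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant feature(s) rescaled to all-zero",
            stacklevel=2,
        )
    safe = span.where(~flat, 1.0)
    out = values.sub(lo, axis=0).div(safe, axis=0)
    out.loc[flat] = 0.0
    return out


def collapse_probes(
    probe_values: pd.DataFrame,
    probe_map: pd.Series | dict,
    method: str = "max_variance",
) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene level.

    Control probes (ids beginning with ``AFFX``) are removed, probes with no
    gene mapping are dropped (logged), and each gene keeps either its
    highest-variance probe (default) or the mean over its probes.
    """
    if isinstance(probe_map, dict):
        probe_map = pd.Series(probe_map)
    if probe_map.empty:
        raise ValueError("empty probe->gene map")
    if probe_values.index.has_duplicates:
        raise ValueError("duplicate probe ids")
    keep = ~probe_values.index.str.startswith("AFFX")
    values = probe_values.loc[keep]
    mapped = values.index.intersection(probe_map.index)
    n_dropped = values.shape[0] - len(mapped)
    if n_dropped:
        logger.info("dropped %d unmapped probe(s)", n_dropped)
    values = values.loc[mapped]
    genes = probe_map.loc[mapped]
    if method == "mean":
        out = values.groupby(genes.to_numpy()).mean()
    elif method == "max_variance":
        # deterministic tie-break: highest variance, then smallest probe id
        order = pd.DataFrame(
            {
                "gene": genes.to_numpy(),
                "var": values.var(axis=1, ddof=0).to_numpy(),
                "probe": values.index,
            }
        ).sort_values(["gene", "var", "probe"], ascending=[True, False, True])
        chosen = order.groupby("gene", sort=True).head(1)
        out = values.loc[chosen["probe"]]
        out.index = chosen["gene"].to_numpy()
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    out.index.name = probe_values.index.name or "gene"
    return out


def integrate_datasets(datasets: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate already-normalised datasets over the common gene set.

    Genes are intersected (no imputation); samples are concatenated in input
    order. Raises if the gene intersection is empty.
    """
    if not datasets:
        raise ValueError("no datasets to integrate")
    common = datasets[0].index
    for d in datasets[1:]:
        common = common.intersection(d.index)
    if len(common) == 0:
        raise ValueError("empty gene intersection across datasets")
    return pd.concat([d.loc[common] for d in datasets], axis=1)


def stratify_training_sets(
    values: pd.DataFrame, metadata: pd.DataFrame
) -> dict[tuple[str, int], TrainingSet]:
    """Partition the integrated cohort into the six ER x grade training sets.

    Samples with missing ER status or grade are excluded. Returns a dict
    keyed by ``(er_status, grade)`` covering all six strata; empty strata are
    kept (with a warning) and yield empty downstream outputs.

    ``metadata`` must be indexed by sample id with columns ``er_status``
    (``pos``/``neg``/``missing``) and ``grade`` (1/2/3/``missing``).
    """
    meta = metadata.loc[values.columns]
    er = meta["er_status"].astype(str)
    grade = pd.to_numeric(meta["grade"], errors="coerce")
    ok = er.isin(ER_LEVELS) & grade.isin(GRADE_LEVELS)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("excluded %d sample(s) with missing ER status or grade", n_dropped)
    out: dict[tuple[str, int], TrainingSet] = {}
    for er_level, grade_level in STRATA:
        mask = ok & (er == er_level) & (grade == grade_level)
        cols = values.columns[mask.to_numpy()]
        if len(cols) == 0:
            warnings.warn(f"empty stratum ({er_level}, grade {grade_level})",
                          stacklevel=2)
        out[(er_level, grade_level)] = TrainingSet(
            er_status=er_level, grade=grade_level, values=values[cols]
        )
    return out


def summarize_gene(stratum: TrainingSet | pd.DataFrame) -> pd.Series:
    """Quadratic-mean (RMS) expression of each gene over a stratum's samples.

    ``G(a) = sqrt(mean_i g_i(a)^2)``. Lies between the min and max sample
    value and equals the value of a constant profile; on non-negative data
    it never falls below the arithmetic mean.
    """
    values = stratum.values if isinstance(stratum, TrainingSet) else stratum
    if values.shape[1] == 0:
        raise ValueError("cannot summarise a stratum with no samples")
    return np.sqrt((values**2).mean(axis=1))


def merge_edge_expression(
    gene_summary: pd.Series, edges: list[tuple[str, str]]
) -> pd.DataFrame:
    """Harmonic-mean merged expression ``sigma`` for each edge.

    ``sigma = 2 G(a) G(b) / (G(a) + G(b))``; defined as 0 when both
    summaries are 0. Edges with an endpoint absent from the expression data
    are flagged ``measured=False`` and should be excluded downstream.
    """
    rows = []
    n_degenerate = 0
    for a, b in edges:
        measured = a in gene_summary.index and b in gene_summary.index
        if measured:
            ga, gb = float(gene_summary[a]), float(gene_summary[b])
            total = ga + gb
            if total == 0.0:
                sigma = 0.0
                n_degenerate += 1
            else:
                sigma = 2.0 * ga * gb / total
        else:
            sigma = np.nan
        rows.append((a, b, sigma, measured))
    if n_degenerate:
        logger.info("%d edge(s) with both endpoint summaries zero: sigma=0", n_degenerate)
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "sigma", "measured"])


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata_tsv(path) -> pd.DataFrame:
    """Read a sample metadata TSV (``sample_id dataset_id er_status grade``)."""
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return meta
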