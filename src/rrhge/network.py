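"""Gene-interaction network construction and interaction-reliability scoring.

Multi-source protein-interaction compendia are noisy: a large fraction of
reported interactions are experimental false positives. Before expression
information is brought in, every interaction is scored with three reliability
measures —

* ``R1`` — number of distinct data sources (databases) reporting the edge,
* ``R2`` — number of distinct experimental methods that identified it,
* ``R3`` — combined number of level-2 neighbours of its two endpoints
  (partners-of-partners; an edge whose endpoints sit in a well-connected
  neighbourhood is less likely to be spurious),

each min-max normalised to [0, 1] across the network, and combined into a
single weighted reliability ``mu`` by an affine model with fixed published
coefficients (see :data:`DEFAULT_RELIABILITY_WEIGHTS`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved method label for interaction records lacking one.
UNKNOWN_METHOD = "unknown"


class InteractionRecord(NamedTuple):
    """One reported gene-gene interaction from one source/method."""

    gene_a: str
    gene_b: str
    source: str
    method: str


@dataclass(frozen=True)
class ReliabilityWeights:
    """Coefficients of the affine reliability model
    ``mu = beta0 + beta1*r1 + beta2*r2 + beta3*r3``."""

    beta0: float = 0.0
    beta1: float = 0.7138
    beta2: float = 0.2912
    beta3: float = 0.3072

    def __post_init__(self) -> None:
        for name in ("beta0", "beta1", "beta2", "beta3"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite reliability weight {name}")


#: Published operating point of the reliability model (intercept fixed at 0).
DEFAULT_RELIABILITY_WEIGHTS = ReliabilityWeights()


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Order-free representation of an undirected gene pair."""
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


def build_network(records: Iterable[InteractionRecord]) -> nx.Graph:
    """Assemble the deduplicated, undirected gene-interaction network.

    Self-interactions are dropped and duplicate reports of the same pair are
    merged; each edge accumulates the union of the sources and methods that
    reported it (``sources`` / ``methods`` edge attributes). The result is
    invariant under permutation of the input records.

    Parameters
    ----------
    records
        Interaction reports. Records with an empty method label are pooled
        under the reserved :data:`UNKNOWN_METHOD` bucket.

    Raises
    ------
    ValueError
        If no records are given or a record has an empty gene identifier.
    """
    graph = nx.Graph()
    n_records = 0
    n_self = 0
    n_unknown_method = 0
    for rec in records:
        n_records += 1
        if not rec.gene_a or not rec.gene_b:
            raise ValueError(f"record {n_records}: empty gene identifier in {rec!r}")
        if rec.gene_a == rec.gene_b:
            n_self += 1
            continue
        method = rec.method if rec.method else UNKNOWN_METHOD
        if method is UNKNOWN_METHOD:
            n_unknown_method += 1
        a, b = canonical_pair(rec.gene_a, rec.gene_b)
        if graph.has_edge(a, b):
            data = graph.edges[a, b]
            data["sources"].add(rec.source)
            data["methods"].add(method)
        else:
            graph.add_edge(a, b, sources={rec.source}, methods={method})
    if n_records == 0:
        raise ValueError("empty interaction record list")
    if n_self:
        logger.info("dropped %d self-interaction record(s)", n_self)
    if n_unknown_method:
        logger.info("%d record(s) without method label pooled as %r",
                    n_unknown_method, UNKNOWN_METHOD)
    return graph


def read_edge_list(path) -> list[InteractionRecord]:
    """Read a 4-column TSV edge list (``gene_a gene_b source method``).

    A header row is required; lines starting with ``#`` are comments.
    """
    records: list[InteractionRecord] = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns, got {len(fields)}")
            gene_a, gene_b, source = fields[0], fields[1], fields[2]
            method = fields[3] if len(fields) > 3 and fields[3] else UNKNOWN_METHOD
            if not gene_a or not gene_b:
                raise ValueError(f"{path}: line {lineno}: empty gene identifier")
            records.append(InteractionRecord(gene_a, gene_b, source, method))
    if header is None:
        raise ValueError(f"{path}: missing header row")
    return records


def write_sif(graph: nx.Graph, path, relation: str = "pp") -> None:
    """Export edges in Cytoscape SIF format (``gene_a pp gene_b``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(graph.edges()):
            fh.write(f"{a}\t{relation}\t{b}\n")


def compute_r1(graph: nx.Graph) -> dict[tuple[str, str], int]:
    """Per-edge count of distinct reporting data sources."""
    return {canonical_pair(a, b): len(d["sources"]) for a, b, d in graph.edges(data=True)}


def compute_r2(graph: nx.Graph) -> dict[tuple[str, str], int]:
    """Per-edge count of distinct identifying experimental methods."""
    return {canonical_pair(a, b): len(d["methods"]) for a, b, d in graph.edges(data=True)}


def _level2_neighbours(graph: nx.Graph, node: str) -> set[str]:
    # partners of partners; only the focal node itself is excluded, so
    # level-1 neighbours reached through triangles do count
    second: set[str] = set()
    for nbr in graph.neighbors(node):
        second.update(graph.neighbors(nbr))
    second.discard(node)
    return second


def compute_r3(graph: nx.Graph) -> dict[tuple[str, str], int]:
    """Per-edge combined level-2 neighbour count.

    For an edge (a, b), ``R3 = |N2(a)| + |N2(b)|`` where ``N2(x)`` is the set
    of interaction partners of x's partners, excluding x itself. Endpoints of
    edges embedded in richly connected neighbourhoods score high; an isolated
    edge scores 0.
    """
    cache: dict[str, int] = {}
    out: dict[tuple[str, str], int] = {}
    for a, b in graph.edges():
        for node in (a, b):
            if node not in cache:
                cache[node] = len(_level2_neighbours(graph, node))
        out[canonical_pair(a, b)] = cache[a] + cache[b]
    return out


def normalize_reliability(raw: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Min-max rescale one raw reliability measure to [0, 1] across edges.

    A degenerate range (all edges equal) maps every edge to 0: an
    uninformative measure confers no reliability credit.
    """
    if not raw:
        raise ValueError("no edges to normalize")
    lo = min(raw.values())
    hi = max(raw.values())
    if hi == lo:
        return {edge: 0.0 for edge in raw}
    span = hi - lo
    return {edge: (value - lo) / span for edge, value in raw.items()}


def compute_mu(
    r1: dict[tuple[str, str], float],
    r2: dict[tuple[str, str], float],
    r3: dict[tuple[str, str], float],
    weights: ReliabilityWeights = DEFAULT_RELIABILITY_WEIGHTS,
) -> dict[tuple[str, str], float]:
    """Weighted reliability ``mu`` from the three normalised measures."""
    return {
        edge: weights.beta0
        + weights.beta1 * r1[edge]
        + weights.beta2 * r2[edge]
        + weights.beta3 * r3[edge]
        for edge in r1
    }


def score_reliability(
    graph: nx.Graph,
    weights: ReliabilityWeights = DEFAULT_RELIABILITY_WEIGHTS,
) -> pd.DataFrame:
    """Compute raw and normalised R1/R2/R3 and mu for every edge.

    Returns a DataFrame with one row per edge, columns
    ``gene_a gene_b R1 R2 R3 r1 r2 r3 mu``, sorted by gene pair.
    """
    raw1 = compute_r1(graph)
    raw2 = compute_r2(graph)
    raw3 = compute_r3(graph)
    n1 = normalize_reliability(raw1)
    n2 = normalize_reliability(raw2)
    n3 = normalize_reliability(raw3)
    mu = compute_mu(n1, n2, n3, weights)
    edges = sorted(raw1)
    return pd.DataFrame(
        {
            "gene_a": [e[0] for e in edges],
            "gene_b": [e[1] for e in edges],
            "R1": [raw1[e] for e in edges],
            "R2": [raw2[e] for e in edges],
            "R3": [raw3[e] for e in edges],
            "r1": [n1[e] for e in edges],
            "r2": [n2[e] for e in edges],
            "r3": [n3[e] for e in edges],
            "mu": [mu[e] for e in edges],
        }
    )
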