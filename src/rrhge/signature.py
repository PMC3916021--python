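"""Hub-centred subnetwork extraction and gene-signature assembly.

Within each training set the significant, positively correlated, reliable
interactions form a graph whose connected components are the candidate
subnetworks. Each subnetwork is summarised by

* ``lambda`` — the sum of theta over its edges (subnetwork score), and
* ``chi`` — the hub score: for each maximum-degree (hub) gene, the mean
  theta of its incident edges; ties give several hubs and the subnetwork's
  chi is the maximum over them.

The subnetwork with maximal lambda is retained whole; any other subnetwork
whose chi strictly exceeds the chosen one's contributes its hub gene(s)
plus their direct interactors. Intersecting the three grade lists within
each ER status and removing genes shared between the two sides yields the
final disjoint ER+/ER- signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class Subnetwork:
    """One connected component of a stratum's significant-edge graph."""

    genes: frozenset[str]
    edges: tuple[tuple[str, str, float], ...]  # (gene_a, gene_b, theta)
    hub_genes: frozenset[str]
    lam: float
    chi: float
    hub_chi: dict[str, float]


@dataclass
class SubnetworkList:
    """Genes retained for one stratum, with the rule that admitted each."""

    stratum: tuple[str, int]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.provenance)

    def add(self, gene: str, rule: str) -> None:
        self.provenance.setdefault(gene, set()).add(rule)


@dataclass
class GeneSignature:
    """Final disjoint ER+ / ER- gene sets."""

    er_pos_genes: frozenset[str]
    er_neg_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.er_pos_genes & self.er_neg_genes:
            raise ValueError("signature sides must be disjoint")


def find_hub_genes(graph: nx.Graph) -> set[str]:
    """All genes attaining the maximal degree within one subnetwork.

    Ties are kept: a subnetwork may have several hubs.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("hub genes undefined for an edgeless subnetwork")
    degrees = dict(graph.degree())
    top = max(degrees.values())
    return {g for g, d in degrees.items() if d == top}


def subnetwork_score(edge_thetas: list[float]) -> float:
    """Subnetwork score lambda: exact sum of theta over the edges."""
    return float(sum(edge_thetas))


def hub_score(graph: nx.Graph, hub: str) -> float:
    """Mean theta over the edges incident to one hub gene."""
    incident = [graph.edges[hub, nbr]["theta"] for nbr in graph.neighbors(hub)]
    return float(sum(incident) / len(incident))


def extract_subnetworks(edges: pd.DataFrame) -> list[Subnetwork]:
    """Connected components of the significant-edge graph, fully scored.

    ``edges`` needs columns ``gene_a gene_b theta``. Genes touching no
    significant edge produce no subnetwork; an empty table yields [].
    """
    graph = nx.Graph()
    for a, b, theta in edges[["gene_a", "gene_b", "theta"]].itertuples(index=False):
        graph.add_edge(a, b, theta=float(theta))
    out: list[Subnetwork] = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        hubs = find_hub_genes(sub)
        hub_chi = {h: hub_score(sub, h) for h in hubs}
        out.append(
            Subnetwork(
                genes=frozenset(component),
                edges=tuple(
                    (*sorted((a, b)), d["theta"]) for a, b, d in sub.edges(data=True)
                ),
                hub_genes=frozenset(hubs),
                lam=subnetwork_score([d["theta"] for _, _, d in sub.edges(data=True)]),
                chi=max(hub_chi.values()),
                hub_chi=hub_chi,
            )
        )
    # deterministic order: best lambda first; ties broken by size then
    # lexicographically smallest gene id
    out.sort(key=lambda s: (-s.lam, -len(s.genes), min(s.genes)))
    return out


def build_subnetwork_list(
    subnetworks: list[Subnetwork], stratum: tuple[str, int]
) -> SubnetworkList:
    """Apply the selection rule to one stratum's subnetworks.

    The maximum-lambda subnetwork is admitted whole (tie-break: larger gene
    count, then smallest gene id). Every other subnetwork whose chi strictly
    exceeds the chosen subnetwork's chi contributes its hub gene(s) and
    their direct interactors. Provenance records which rule admitted each
    gene (``top_subnetwork`` / ``hub_neighbourhood``).
    """
    result = SubnetworkList(stratum=stratum)
    if not subnetworks:
        warnings.warn(f"stratum {stratum}: no subnetworks", stacklevel=2)
        return result
    ordered = sorted(subnetworks, key=lambda s: (-s.lam, -len(s.genes), min(s.genes)))
    chosen = ordered[0]
    for gene in chosen.genes:
        result.add(gene, "top_subnetwork")
    for other in ordered[1:]:
        if other.chi > chosen.chi:
            adjacency: dict[str, set[str]] = {}
            for a, b, _ in other.edges:
                adjacency.setdefault(a, set()).add(b)
                adjacency.setdefault(b, set()).add(a)
            for hub in other.hub_genes:
                result.add(hub, "hub_neighbourhood")
                for nbr in adjacency[hub]:
                    result.add(nbr, "hub_neighbourhood")
    return result


def _common_genes(lists: list[SubnetworkList], threshold: int) -> set[str]:
    counts: dict[str, int] = {}
    for lst in lists:
        for gene in lst.genes:
            counts[gene] = counts.get(gene, 0) + 1
    return {g for g, c in counts.items() if c >= threshold}


def assemble_signature(
    lists: dict[tuple[str, int], SubnetworkList], common_threshold: int = 3
) -> GeneSignature:
    """Build the final disjoint ER+/ER- signature from the six stratum lists.

    Per ER status, the genes appearing in at least ``common_threshold`` of
    the three grade lists are the side's common genes (default 3 = strict
    intersection). Genes common to both sides are removed from both,
    guaranteeing disjoint signatures.

    Raises ``ValueError`` if both resulting sets are empty.
    """
    if not 1 <= common_threshold <= 3:
        raise ValueError("common_threshold must be in {1, 2, 3}")
    pos_lists = [lst for (er, _), lst in lists.items() if er == "pos"]
    neg_lists = [lst for (er, _), lst in lists.items() if er == "neg"]
    pos_common = _common_genes(pos_lists, common_threshold)
    neg_common = _common_genes(neg_lists, common_threshold)
    shared = pos_common & neg_common
    pos_final = pos_common - shared
    neg_final = neg_common - shared
    if not pos_final and not neg_final:
        raise ValueError("no signature derivable: both gene sets empty")
    return GeneSignature(frozenset(pos_final), frozenset(neg_final))


def compare_signatures(sig1: set[str], sig2: set[str]) -> tuple[int, float]:
    """Overlap between two gene signatures.

    Returns ``(|intersection|, 100 * |intersection| / |sig1|)``.
    """
    if not sig1:
        raise ValueError("reference signature is empty")
    overlap = len(set(sig1) & set(sig2))
    return overlap, 100.0 * overlap / len(sig1)


def write_signature(signature: GeneSignature, out_dir) -> None:
    """Write ``er_pos.txt`` / ``er_neg.txt`` plain gene lists."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "er_pos.txt").write_text("".join(f"{g}\n" for g in sorted(signature.er_pos_genes)))
    (out / "er_neg.txt").write_text("".join(f"{g}\n" for g in sorted(signature.er_neg_genes)))
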