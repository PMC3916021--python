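"""Seeded synthetic studies: multi-source interaction edge lists and
ER-status x grade expression cohorts with planted differential modules.

The generator emulates the shape of the real inputs — several interaction
databases reporting overlapping edge sets with varying experimental-method
evidence, plus a false-positive fraction carrying minimal evidence, and a
stratified breast-cancer-style expression cohort in which the genes of a
planted module are shifted upward in the samples of one ER side across all
three histologic grades. Ground-truth module membership is returned so that
end-to-end signature recovery and held-out classification can be scored.

Everything is driven by one master seed: each stage draws from its own
stream spawned from it, so repeated runs are byte-identical and stages can
be regenerated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import GRADE_LEVELS, STRATA
from .network import InteractionRecord


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class PlantedModule:
    """A densely wired, differentially expressed gene module."""

    genes: tuple[str, ...]
    side: str  # "pos" or "neg": which ER class over-expresses the module
    expression_shift: float = 0.5
    density: float = 0.6


def _default_modules() -> tuple[PlantedModule, ...]:
    names = _gene_names(20)
    return (
        PlantedModule(genes=tuple(names[:10]), side="pos"),
        PlantedModule(genes=tuple(names[10:20]), side="neg"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but fully structured study: a 200-gene
    network over six sources and five methods at background edge density
    0.02 with a 10% minimal-evidence (false-positive-like) edge fraction,
    two planted 10-gene modules (one per ER side, expression shift 0.5,
    within-module wiring density 0.6), 20 training samples per stratum,
    30 held-out test samples per ER class, and Gaussian sample noise with
    sd 0.05 on [0, 1]-scale expression.
    """

    seed: int = 0
    n_genes: int = 200
    n_sources: int = 6
    n_methods: int = 5
    edge_prob: float = 0.02
    fp_edge_fraction: float = 0.1
    n_samples_per_stratum: int = 20
    n_test_per_class: int = 30
    noise_sd: float = 0.05
    planted_modules: tuple[PlantedModule, ...] = field(default_factory=_default_modules)
    n_train_datasets: int = 2
    raw_scale: bool = False

    def __post_init__(self) -> None:
        for name in ("edge_prob", "fp_edge_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        universe = set(_gene_names(self.n_genes))
        seen: set[str] = set()
        for module in self.planted_modules:
            if len(module.genes) > self.n_genes:
                raise ValueError("planted module larger than gene universe")
            if not set(module.genes) <= universe:
                raise ValueError("planted module genes outside gene universe")
            if seen & set(module.genes):
                raise ValueError("planted module gene sets must be disjoint")
            seen.update(module.genes)

    @property
    def gene_names(self) -> list[str]:
        return _gene_names(self.n_genes)

    @property
    def source_labels(self) -> list[str]:
        return [f"SRC{i}" for i in range(1, self.n_sources + 1)]

    @property
    def method_labels(self) -> list[str]:
        return [f"METH{i}" for i in range(1, self.n_methods + 1)]


@dataclass
class StudyFixture:
    """Bundled inputs for a full pipeline run plus the planted truth."""

    config: SimulationConfig
    records: list[InteractionRecord]
    train_values: pd.DataFrame
    train_metadata: pd.DataFrame
    test_values: pd.DataFrame
    test_metadata: pd.DataFrame
    truth: dict[str, list[str]]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "network": np.random.default_rng(children[0]),
        "expression": np.random.default_rng(children[1]),
        "test": np.random.default_rng(children[2]),
    }


def _edge_records(
    rng: np.random.Generator,
    pair: tuple[str, str],
    sources: list[str],
    methods: list[str],
    n_src: int,
    n_meth: int,
) -> list[InteractionRecord]:
    src = list(rng.choice(sources, size=n_src, replace=False))
    meth = list(rng.choice(methods, size=n_meth, replace=False))
    return [
        InteractionRecord(pair[0], pair[1], src[j % n_src], meth[j % n_meth])
        for j in range(max(n_src, n_meth))
    ]


def generate_network(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> list[InteractionRecord]:
    """Draw the multi-source interaction record list.

    Planted-module edges (a connectivity-guaranteeing ring plus random
    within-module pairs at the module's density) carry rich evidence: 4-6
    sources and 3-5 methods. Background edges appear with ``edge_prob`` and
    carry light evidence (1-3 sources / methods); a ``fp_edge_fraction`` of
    them get exactly one source and one method, mimicking false-positive
    reports.
    """
    if rng is None:
        rng = _streams(config.seed)["network"]
    genes = config.gene_names
    sources = config.source_labels
    methods = config.method_labels
    hi_src = (min(max(4, config.n_sources - 2), config.n_sources), config.n_sources)
    hi_meth = (min(max(1, config.n_methods - 2), config.n_methods), config.n_methods)
    records: list[InteractionRecord] = []
    module_pairs: set[tuple[str, str]] = set()
    for module in config.planted_modules:
        ordered = sorted(module.genes)
        pairs: set[tuple[str, str]] = set()
        if len(ordered) > 1:
            for i, gene in enumerate(ordered):  # ring keeps the module connected
                j = (i + 1) % len(ordered)
                pairs.add(tuple(sorted((gene, ordered[j]))))
        for i in range(len(ordered)):
            for j in range(i + 1, len(ordered)):
                if rng.random() < module.density:
                    pairs.add((ordered[i], ordered[j]))
        for pair in sorted(pairs):
            n_src = int(rng.integers(hi_src[0], hi_src[1] + 1))
            n_meth = int(rng.integers(hi_meth[0], hi_meth[1] + 1))
            records.extend(_edge_records(rng, pair, sources, methods, n_src, n_meth))
        module_pairs.update(pairs)
    module_sets = [set(m.genes) for m in config.planted_modules]
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            pair = (genes[i], genes[j])
            if any(genes[i] in s and genes[j] in s for s in module_sets):
                continue  # within-module pairs handled above
            if rng.random() >= config.edge_prob:
                continue
            if rng.random() < config.fp_edge_fraction:
                n_src, n_meth = 1, 1
            else:
                n_src = 1 + int(rng.binomial(min(2, config.n_sources - 1), 0.5))
                n_meth = 1 + int(rng.binomial(min(2, config.n_methods - 1), 0.5))
            records.extend(_edge_records(rng, pair, sources, methods, n_src, n_meth))
    return records


def _cohort(
    rng: np.random.Generator,
    config: SimulationConfig,
    baselines: np.ndarray,
    samples: list[tuple[str, str, str, int]],  # (sample_id, dataset_id, er, grade)
) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = config.gene_names
    gene_index = {g: i for i, g in enumerate(genes)}
    shift = np.zeros((len(genes), 2))  # column 0: pos samples, column 1: neg
    for module in config.planted_modules:
        col = 0 if module.side == "pos" else 1
        for gene in module.genes:
            shift[gene_index[gene], col] = module.expression_shift
    values = np.empty((len(genes), len(samples)))
    for s, (_, _, er, _) in enumerate(samples):
        col = 0 if er == "pos" else 1
        noise = rng.normal(0.0, config.noise_sd, size=len(genes))
        values[:, s] = np.clip(baselines + shift[:, col] + noise, 0.0, 1.0)
    frame = pd.DataFrame(values, index=genes,
                         columns=[s[0] for s in samples])
    meta = pd.DataFrame(
        {
            "dataset_id": [s[1] for s in samples],
            "er_status": [s[2] for s in samples],
            "grade": [s[3] for s in samples],
        },
        index=pd.Index([s[0] for s in samples], name="sample_id"),
    )
    if config.raw_scale:
        # per-dataset affine distortion so the min-max rescaling step is
        # exercised nontrivially
        for dataset in meta["dataset_id"].unique():
            gain = rng.uniform(50.0, 150.0)
            offset = rng.uniform(10.0, 50.0)
            cols = meta.index[meta["dataset_id"] == dataset]
            frame[cols] = frame[cols] * gain + offset
    return frame, meta


def generate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the stratified training cohort (values, metadata).

    Each gene has a fixed baseline drawn uniformly on [0, 1]; planted-module
    genes gain their module's shift in samples of the matching ER side (all
    grades); Gaussian noise with ``noise_sd`` is added per sample and values
    are clipped to [0, 1]. Training samples are assigned round-robin to
    ``n_train_datasets`` dataset ids.
    """
    if config.n_samples_per_stratum < 1:
        raise ValueError("n_samples_per_stratum must be >= 1")
    if rng is None:
        rng = _streams(config.seed)["expression"]
    baselines = rng.uniform(0.0, 1.0, size=config.n_genes)
    samples = []
    counter = 0
    for er, grade in STRATA:
        for i in range(config.n_samples_per_stratum):
            dataset = f"D{counter % config.n_train_datasets + 1}"
            samples.append((f"TR_{er}_g{grade}_{i:03d}", dataset, er, grade))
            counter += 1
    values, meta = _cohort(rng, config, baselines, samples)
    return values, meta


def generate_study(config: SimulationConfig) -> StudyFixture:
    """Generate the full fixture: network, training cohort, held-out test
    cohort and ground-truth planted gene lists."""
    streams = _streams(config.seed)
    records = generate_network(config, streams["network"])
    expr_rng = streams["expression"]
    baselines = expr_rng.uniform(0.0, 1.0, size=config.n_genes)
    train_samples = []
    counter = 0
    for er, grade in STRATA:
        for i in range(config.n_samples_per_stratum):
            dataset = f"D{counter % config.n_train_datasets + 1}"
            train_samples.append((f"TR_{er}_g{grade}_{i:03d}", dataset, er, grade))
            counter += 1
    train_values, train_meta = _cohort(expr_rng, config, baselines, train_samples)
    test_samples = []
    for er in ("pos", "neg"):
        for i in range(config.n_test_per_class):
            grade = GRADE_LEVELS[i % len(GRADE_LEVELS)]
            test_samples.append((f"TE_{er}_{i:03d}", "TEST", er, grade))
    test_values, test_meta = _cohort(streams["test"], config, baselines, test_samples)
    truth = {
        "er_pos": sorted(g for m in config.planted_modules if m.side == "pos"
                         for g in m.genes),
        "er_neg": sorted(g for m in config.planted_modules if m.side == "neg"
                         for g in m.genes),
    }
    return StudyFixture(
        config=config,
        records=records,
        train_values=train_values,
        train_metadata=train_meta,
        test_values=test_values,
        test_metadata=test_meta,
        truth=truth,
    )


def write_study(fixture: StudyFixture, out_dir) -> None:
    """Write the fixture as plain-text files (TSV + JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tsource\tmethod\n")
        for rec in fixture.records:
            fh.write(f"{rec.gene_a}\t{rec.gene_b}\t{rec.source}\t{rec.method}\n")
    fixture.train_values.to_csv(out / "train_expression.tsv", sep="\t")
    fixture.train_metadata.to_csv(out / "train_metadata.tsv", sep="\t")
    fixture.test_values.to_csv(out / "test_expression.tsv", sep="\t")
    fixture.test_metadata.to_csv(out / "test_metadata.tsv", sep="\t")
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(fixture.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
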