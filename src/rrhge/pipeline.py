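"""End-to-end orchestration: from interaction records and a stratified
expression cohort to the disjoint ER+/ER- gene signature and held-out
classification metrics.

The stages are the library modules run in order: network construction and
reliability scoring (``mu``), per-dataset rescaling and integration,
ER x grade stratification, per-stratum gene and edge expression summaries
(``G``, ``sigma``), reliable-expression scoring and significance selection
(``delta``, ``theta``, p), hub-centred subnetwork selection, signature
assembly, and 3NN classification on the (S+, S-) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import classify, expression, network, scoring, signature
from .signature import GeneSignature
from .simulate import SimulationConfig, StudyFixture, generate_study


def prepare_expression(
    values: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Min-max rescale each dataset separately, then integrate.

    Columns are grouped by the metadata ``dataset_id``; each dataset is
    rescaled per gene and the datasets are concatenated over their common
    genes (original column order restored).
    """
    meta = metadata.loc[values.columns]
    datasets = [
        expression.normalize_dataset(values[meta.index[meta["dataset_id"] == d]])
        for d in meta["dataset_id"].unique()
    ]
    integrated = expression.integrate_datasets(datasets)
    return integrated[values.columns]


@dataclass
class SignatureResult:
    """Signature plus per-stratum intermediates for inspection."""

    signature: GeneSignature
    stratum_edges: dict[tuple[str, int], pd.DataFrame]
    subnetworks: dict[tuple[str, int], list[signature.Subnetwork]]
    subnetwork_lists: dict[tuple[str, int], signature.SubnetworkList]
    reliability: pd.DataFrame


def derive_signature(
    records: list[network.InteractionRecord],
    train_values: pd.DataFrame,
    train_metadata: pd.DataFrame,
    *,
    weights: network.ReliabilityWeights = network.DEFAULT_RELIABILITY_WEIGHTS,
    theta_coefficients: dict[tuple[str, int], scoring.ThetaCoefficients] | None = None,
    alpha: float = scoring.DEFAULT_ALPHA,
    common_threshold: int = 3,
) -> SignatureResult:
    """Run the training half of the pipeline.

    Expression values are rescaled per dataset and integrated; the network
    is reliability-scored once and its ``mu`` values are shared by all six
    strata, while ``sigma``/``theta`` and the significance filter are
    per stratum. Strata with no samples or no significant edges simply
    contribute empty subnetwork lists.
    """
    graph = network.build_network(records)
    reliability = network.score_reliability(graph, weights)
    mu = dict(zip(zip(reliability["gene_a"], reliability["gene_b"]),
                  reliability["mu"]))
    edge_pairs = list(mu)

    integrated = prepare_expression(train_values, train_metadata)
    strata = expression.stratify_training_sets(integrated, train_metadata)

    stratum_edges: dict[tuple[str, int], pd.DataFrame] = {}
    subnetworks: dict[tuple[str, int], list[signature.Subnetwork]] = {}
    lists: dict[tuple[str, int], signature.SubnetworkList] = {}
    for stratum, training_set in strata.items():
        if training_set.n == 0:
            scored = pd.DataFrame(
                columns=["gene_a", "gene_b", "sigma", "measured", "mu",
                         "delta", "theta", "p", "significant"])
        else:
            summary = expression.summarize_gene(training_set)
            edges = expression.merge_edge_expression(summary, edge_pairs)
            edges = edges.loc[edges["measured"]].copy()
            edges["mu"] = [
                mu[(a, b)] for a, b in zip(edges["gene_a"], edges["gene_b"])
            ]
            scored = scoring.score_stratum(
                edges, stratum, coefficients=theta_coefficients, alpha=alpha
            )
        stratum_edges[stratum] = scored
        significant = (
            scored.loc[scored["significant"]]
            if not scored.empty
            else scored
        )
        subs = signature.extract_subnetworks(significant)
        subnetworks[stratum] = subs
        lists[stratum] = signature.build_subnetwork_list(subs, stratum)

    final = signature.assemble_signature(lists, common_threshold=common_threshold)
    return SignatureResult(
        signature=final,
        stratum_edges=stratum_edges,
        subnetworks=subnetworks,
        subnetwork_lists=lists,
        reliability=reliability,
    )


@dataclass
class EvaluationResult:
    counts: classify.ConfusionCounts
    metrics: classify.ClassificationMetrics
    sample_points: pd.DataFrame  # per test sample: s_plus, s_minus, predicted, truth


def evaluate_holdout(
    sig: GeneSignature,
    train_values: pd.DataFrame,
    train_metadata: pd.DataFrame,
    test_values: pd.DataFrame,
    test_metadata: pd.DataFrame,
    k: int = 3,
) -> EvaluationResult:
    """Classify held-out samples with the signature and score the result.

    Reference points are all labelled training samples (the six strata
    pooled) projected onto the (S+, S-) plane; test samples are rescaled
    within their own dataset, projected the same way and classified by
    majority vote of their ``k`` nearest references under L1 distance.
    """
    train_points = classify.score_samples(
        prepare_expression(train_values, train_metadata), sig
    )
    labels = train_metadata.loc[train_points.index, "er_status"].to_numpy()
    test_points = classify.score_samples(
        prepare_expression(test_values, test_metadata), sig
    )
    predicted = classify.knn_classify(
        test_points.to_numpy(), train_points.to_numpy(), labels, k=k
    )
    truth = test_metadata.loc[test_points.index, "er_status"].to_numpy()
    counts = classify.confusion(predicted, truth)
    result = test_points.copy()
    result["predicted"] = predicted
    result["truth"] = truth
    return EvaluationResult(
        counts=counts, metrics=classify.metrics(counts), sample_points=result
    )


@dataclass
class StudyResult:
    """Outcome of a full synthetic-study run."""

    fixture: StudyFixture
    signature_result: SignatureResult
    evaluation: EvaluationResult
    recovery_pos: float
    recovery_neg: float
    recovery: float


def run_study(config: SimulationConfig, **derive_kwargs) -> StudyResult:
    """Generate a synthetic study, derive the signature and evaluate it.

    ``recovery`` is the fraction of planted module genes present in the
    matching side of the derived signature.
    """
    fixture = generate_study(config)
    sig_result = derive_signature(
        fixture.records,
        fixture.train_values,
        fixture.train_metadata,
        **derive_kwargs,
    )
    evaluation = evaluate_holdout(
        sig_result.signature,
        fixture.train_values,
        fixture.train_metadata,
        fixture.test_values,
        fixture.test_metadata,
    )
    truth_pos = set(fixture.truth["er_pos"])
    truth_neg = set(fixture.truth["er_neg"])
    hit_pos = len(truth_pos & sig_result.signature.er_pos_genes)
    hit_neg = len(truth_neg & sig_result.signature.er_neg_genes)
    recovery_pos = hit_pos / len(truth_pos) if truth_pos else float("nan")
    recovery_neg = hit_neg / len(truth_neg) if truth_neg else float("nan")
    total = len(truth_pos) + len(truth_neg)
    recovery = (hit_pos + hit_neg) / total if total else float("nan")
    return StudyResult(
        fixture=fixture,
        signature_result=sig_result,
        evaluation=evaluation,
        recovery_pos=recovery_pos,
        recovery_neg=recovery_neg,
        recovery=recovery,
    )
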