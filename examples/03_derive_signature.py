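"""Derive the ER+/ER- gene signature from a synthetic training study.

Runs the training half of the pipeline — reliability scoring, per-dataset
rescaling, ER x grade stratification, reliable-expression significance
filtering and hub-centred subnetwork selection — then compares the derived
signature with the planted truth.
"""

import warnings

from rrhge import SimulationConfig, compare_signatures, derive_signature, generate_study

warnings.filterwarnings("ignore")

fixture = generate_study(SimulationConfig(seed=42))
result = derive_signature(
    fixture.records, fixture.train_values, fixture.train_metadata
)

sig = result.signature
print(f"ER+ signature ({len(sig.er_pos_genes)} genes): "
      f"{', '.join(sorted(sig.er_pos_genes))}")
print(f"ER- signature ({len(sig.er_neg_genes)} genes): "
      f"{', '.join(sorted(sig.er_neg_genes))}")

for stratum, subs in result.subnetworks.items():
    if subs:
        top = subs[0]
        print(f"stratum {stratum}: {len(subs)} subnetwork(s); top lambda="
              f"{top.lam:.2f}, chi={top.chi:.2f}, hubs={sorted(top.hub_genes)}")

count, pct = compare_signatures(set(fixture.truth["er_pos"]), sig.er_pos_genes)
print(f"\nplanted ER+ genes recovered: {count} ({pct:.1f}%)")
count, pct = compare_signatures(set(fixture.truth["er_neg"]), sig.er_neg_genes)
print(f"planted ER- genes recovered: {count} ({pct:.1f}%)")
print("lambda sums theta over a subnetwork's edges; chi is the hub's mean")
print("incident theta — together they decide which genes enter the signature.")
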