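"""Score the reliability of every interaction in a small multi-source network.

Builds a toy edge list the way interaction databases report it — the same
gene pair showing up in several databases, identified by several
experimental methods — plus one weakly supported edge, then prints the
three reliability measures and the weighted reliability mu for each
deduplicated interaction.
"""

from rrhge import InteractionRecord, build_network, score_reliability

records = [
    # BRCA1-BARD1: reported by three databases, two methods, and embedded
    # in a connected neighbourhood -> high reliability
    InteractionRecord("BRCA1", "BARD1", "HPRD", "Y2H"),
    InteractionRecord("BARD1", "BRCA1", "BIOGRID", "affinity-chromatography"),
    InteractionRecord("BRCA1", "BARD1", "INTACT", "Y2H"),
    InteractionRecord("BRCA1", "TP53", "HPRD", "in-vivo"),
    InteractionRecord("TP53", "MDM2", "BIOGRID", "in-vitro"),
    InteractionRecord("BARD1", "CSTF1", "MINT", "Y2H"),
    # a singleton report with no second-level support -> likely false positive
    InteractionRecord("GENEX", "GENEY", "DIP", "Y2H"),
]

network = build_network(records)
table = score_reliability(network)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
best = table.loc[table["mu"].idxmax()]
print(f"Most reliable interaction: {best.gene_a}-{best.gene_b} (mu={best.mu:.3f})")
print("R1/R2/R3 count supporting databases, methods and level-2 neighbours;")
print("r1/r2/r3 are their [0,1] rescalings and mu their weighted combination —")
print("the isolated GENEX-GENEY edge scores 0 on every measure.")
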