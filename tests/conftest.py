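import numpy as np
import pytest

from rrhge import InteractionRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture
def toy_records():
    """Three sources reporting a small network with a duplicate and a self-loop."""
    return [
        InteractionRecord("a", "b", "HPRD", "Y2H"),
        InteractionRecord("b", "a", "DIP", "Y2H"),
        InteractionRecord("c", "c", "DIP", "Y2H"),
        InteractionRecord("b", "c", "MINT", "affinity-chromatography"),
        InteractionRecord("c", "d", "HPRD", "in-vivo"),
    ]


def random_records(rng, n_records=50, n_genes=12, n_sources=4, n_methods=3):
    genes = [f"g{i}" for i in range(n_genes)]
    records = []
    while len(records) < n_records:
        a, b = rng.choice(genes, size=2, replace=False)
        records.append(
            InteractionRecord(
                a,
                b,
                f"S{rng.integers(n_sources)}",
                f"M{rng.integers(n_methods)}",
            )
        )
    return records
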