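import io

import numpy as np
import pytest

from sidefactor import (
    TrainConfig,
    binarize,
    build_count_matrix,
    split_dataset,
)
from sidefactor.synthetic import generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 60x80 synthetic world shared by read-only tests."""
    return generate_world(m=60, n=80, k_true=4, n_severe=15, seed=42)


@pytest.fixture(scope="session")
def small_split(small_world):
    A = binarize(small_world.counts, 3)
    return A, split_dataset(A, seed=5)


@pytest.fixture()
def quick_cfg():
    return TrainConfig(k=4, lambda_l2=5e-3, max_epochs=60, patience=10,
                       decay_patience=5, lr_init=0.05, seed=0)


@pytest.fixture()
def toy_counts():
    triples = [
        ("ASPIRIN", "NAUSEA", 3),
        ("ASPIRIN", "RASH", 1),
        ("IBUPROFEN", "NAUSEA", 5),
        ("WARFARIN", "BLEEDING", 12),
    ]
    return build_count_matrix(triples)


def drug_table_text(sep="$"):
    rows = [
        ["primaryid", "drugname", "role_cod"],
        ["100", "Aspirin ", "PS"],
        ["100", "warfarin", "SS"],
        ["101", "ASPIRIN", "PS"],
        ["102", "ibuprofen", "PS"],
        ["102", "ibuprofen", "PS"],  # duplicate row within the case
        ["103", "warfarin", "C"],
    ]
    return "\n".join(sep.join(r) for r in rows) + "\n"


def reac_table_text(sep="$"):
    rows = [
        ["primaryid", "pt"],
        ["100", "Nausea"],
        ["100", "rash"],
        ["101", "NAUSEA"],
        ["102", "headache"],
        ["103", "bleeding"],
    ]
    return "\n".join(sep.join(r) for r in rows) + "\n"


@pytest.fixture()
def faers_streams():
    return io.StringIO(drug_table_text()), io.StringIO(reac_table_text())
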