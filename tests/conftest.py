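"""Shared fixtures: small seeded synthetic datasets for every engine."""

from __future__ import annotations

import numpy as np
import pytest

from allerkit import ElicitParams, FixtureSpec, Label, ProteinRecord, SequenceDataset, generate
from allerkit.alphabet import decode

#: Width grid / restart counts trimmed for unit-test speed; the full defaults
#: are exercised in the acceptance tests.
FAST_ELICIT = dict(width_min=6, width_max=12, em_restarts=6)


@pytest.fixture(scope="session")
def planted_fixture() -> SequenceDataset:
    """Two 15-member allergen families sharing planted 10-mers + 30 random negatives."""
    return generate(
        FixtureSpec(
            n_families=2,
            family_size=15,
            seq_length=100,
            planted_word_length=10,
            n_negatives=30,
            negative_mode="random",
            seed=8,
        )
    )


@pytest.fixture(scope="session")
def single_family_motif_ds() -> SequenceDataset:
    """20 sequences each carrying one exact copy of WWHHWWHHWW."""
    spec = FixtureSpec(
        n_families=1, family_size=20, seq_length=100, motif_consensi=["WWHHWWHHWW"], n_negatives=0, seed=3
    )
    return generate(spec).filter_label(Label.ALLERGEN)


@pytest.fixture(scope="session")
def two_family_motif_ds() -> SequenceDataset:
    """Two disjoint planted-motif families, 15 members each."""
    spec = FixtureSpec(
        n_families=2,
        family_size=15,
        seq_length=100,
        motif_consensi=["WWHHWWHHWW", "CCYYCCYYCC"],
        n_negatives=0,
        seed=5,
    )
    return generate(spec).filter_label(Label.ALLERGEN)


@pytest.fixture(scope="session")
def fast_params() -> ElicitParams:
    return ElicitParams(seed=11, **FAST_ELICIT)


def random_protein_dataset(
    n: int, length: int, seed: int, label: Label = Label.ALLERGEN, prefix: str = "r"
) -> SequenceDataset:
    """I.i.d. uniform-composition sequences (the null model for every engine)."""
    rng = np.random.default_rng(seed)
    return SequenceDataset(
        [ProteinRecord(f"{prefix}{i}", decode(rng.integers(0, 20, length)), label=label) for i in range(n)]
    )
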