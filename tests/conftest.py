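"""Shared fixtures: small synthetic clade databases with planted primer sites."""

from __future__ import annotations

import numpy as np
import pytest

from cladeqpcr import FixtureSpec, PlantedSite, generate_clade_db

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int, alphabet: str = BASES) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


@pytest.fixture(scope="session")
def planted_spec() -> FixtureSpec:
    """Two clades, one discriminative primer pair planted into clade C01:
    non-targets carry >= 4 mismatches in each site."""
    return FixtureSpec(
        n_clades=2,
        seqs_per_clade=5,
        seq_length_bp=260,
        intra_clade_substitution_rate=0.08,
        inter_clade_divergence=65,
        planted_sites=[
            PlantedSite(
                clade="C01",
                forward_coord=60,
                forward_seq="TGCAGGTCAACGTTCAG",
                reverse_coord=180,
                reverse_seq="ACGTTCAGGCATCTGAC",
                min_nontarget_mismatches=4,
            )
        ],
        seed=7,
    )


@pytest.fixture(scope="session")
def planted_db(planted_spec):
    return generate_clade_db(planted_spec)


@pytest.fixture(scope="session")
def fourteen_clade_db():
    """A 14-clade x 10-sequence database without planted sites."""
    spec = FixtureSpec(
        n_clades=14,
        seqs_per_clade=10,
        seq_length_bp=300,
        intra_clade_substitution_rate=0.03,
        inter_clade_divergence=50,
        seed=11,
    )
    return generate_clade_db(spec)
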