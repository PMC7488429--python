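"""Shared fixtures: small synthetic corpora and random-structure helpers."""

from __future__ import annotations

import numpy as np
import pytest

from magqc import DbConfig, MarkerDatabase, synthesize_reference_fixture
from magqc.tree import ReferenceTree


def random_tree(n_leaves: int, rng: np.random.Generator) -> ReferenceTree:
    """Random rooted binary tree over leaves L0..L{n-1}."""
    labels = [f"L{i}" for i in range(n_leaves)]

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return items[0]
        cut = int(rng.integers(1, len(items)))
        return f"({build(items[:cut])},{build(items[cut:])})"

    return ReferenceTree.from_newick(build(labels) + ";")


@pytest.fixture(scope="session")
def small_fixture():
    """Eight species, 30 profiles, mild dropout/duplication."""
    return synthesize_reference_fixture(
        n_species=8, n_profiles=30, per_profile_dropout=0.05,
        duplication_rate=0.2, seed=11, genome_length=1_000_000, n_contigs=2,
    )


@pytest.fixture(scope="session")
def small_db(small_fixture):
    return MarkerDatabase.build(
        small_fixture.hits,
        small_fixture.tree,
        DbConfig(prevalence_cutoff=0.7, min_species=3, min_profiles=5),
    )


@pytest.fixture(scope="session")
def clean_fixture():
    """No dropout, no duplication: every profile single-copy everywhere."""
    return synthesize_reference_fixture(
        n_species=8, n_profiles=40, per_profile_dropout=0.0,
        duplication_rate=0.0, seed=7, genome_length=2_000_000, n_contigs=2,
    )


@pytest.fixture(scope="session")
def clean_db(clean_fixture):
    return MarkerDatabase.build(
        clean_fixture.hits,
        clean_fixture.tree,
        DbConfig(prevalence_cutoff=0.98, min_species=3, min_profiles=20),
    )
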