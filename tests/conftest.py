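"""Shared fixtures and helpers for the hugseq test suite."""

from __future__ import annotations

import pytest

from hugseq.model import Pattern
from hugseq.synth import SynthConfig, generate_sequential_dataset, toy_fixture


@pytest.fixture(scope="session")
def toy():
    """The three-patient worked-example dataset and its importance table."""
    return toy_fixture()


@pytest.fixture(scope="session")
def toy_dataset(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_imp(toy):
    return toy[1]


def small_random_dataset(seed: int):
    """A noise-only small study: 4 patients, 3 genes (6 regulation items),
    5 time samples.  Dense enough to exercise the search, small enough
    for exhaustive enumeration."""
    cfg = SynthConfig(
        n_patients=4, n_genes=3, n_time_samples=5, noise_sd=0.6, seed=seed
    )
    dataset, _ = generate_sequential_dataset(cfg)
    return dataset


def is_tree_ancestor(alpha: Pattern, beta: Pattern) -> bool:
    """True when ``beta`` lies in the lexicographic-tree subtree rooted at
    ``alpha`` (including ``beta == alpha``).

    In the tree, a child appends one item to the last element (I) or a
    new singleton element (S); hence an ancestor of ``beta`` at length L
    consists of ``beta``'s first L-1 elements plus a prefix of its L-th.
    """
    la = alpha.length
    if la > beta.length:
        return False
    if alpha.elements[: la - 1] != beta.elements[: la - 1]:
        return False
    last = alpha.elements[-1]
    return beta.elements[la - 1][: len(last)] == last
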