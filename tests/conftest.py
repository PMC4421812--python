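"""Shared fixtures and tree/variant builders for the test suite."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from hypothesis import settings

from kelpscan.core_io import VariantTable

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_table(genotypes, samples=None, chrom="chr1", positions=None) -> VariantTable:
    """Build a VariantTable from a (samples x sites) genotype-code array."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n_samp, n_sites = gt.shape
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samp)]
    if positions is None:
        positions = np.arange(n_sites) * 10
    return VariantTable(
        samples=list(samples),
        chrom=np.array([chrom] * n_sites, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        genotypes=gt,
    )


def random_unrooted_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random unrooted binary tree with branch lengths in [0.1, 1]."""
    from kelpscan.synthetic_data import random_tree

    return random_tree(n_leaves, rng, rooted=False, length_range=(0.1, 1.0))


def random_rooted_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted binary tree with branch lengths in [0.05, 0.3]."""
    from kelpscan.synthetic_data import random_tree

    return random_tree(n_leaves, rng, rooted=True, length_range=(0.05, 0.3))


from kelpscan.phylo_dollo import unrooted_splits  # noqa: E402,F401  (re-export)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
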