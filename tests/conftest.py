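"""Shared fixtures and independent oracles for the test suite.

Oracles here deliberately avoid the library's own code paths: the
hypergeometric tail is enumerated exactly with Fractions and binomial
coefficients, and overlaps are counted with plain set arithmetic.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from sigoverlap import DifferentialResult, GeneSignature, UniverseSpec
from sigoverlap.signatures import rank_entries


def hypergeom_tail_oracle(k: int, n1: int, n2: int, N: int) -> Fraction:
    """Exact P(X >= k) by direct summation of the hypergeometric pmf."""
    total = comb(N, n2)
    lo = max(0, n1 + n2 - N)
    acc = Fraction(0)
    for j in range(max(k, lo), min(n1, n2) + 1):
        acc += Fraction(comb(n1, j) * comb(N - n1, n2 - j), total)
    return acc


def make_signature(
    directed_genes, name: str = "sig", fc: float = 2.0, p_start: float = 1e-4
) -> GeneSignature:
    """Signature from an ordered (gene, direction) sequence.

    The listed order becomes the rank order: each gene is assigned an
    increasing p-value so the standard ranking rule reproduces it.
    """
    items = list(directed_genes.items()) if isinstance(directed_genes, dict) else list(directed_genes)
    results = [
        DifferentialResult(
            feature_id=g,
            mean_log2_numerator=float("nan"),
            mean_log2_denominator=float("nan"),
            signed_fold_change=fc if d == "up" else -fc,
            p_value=p_start * (i + 1),
        )
        for i, (g, d) in enumerate(items)
    ]
    return GeneSignature(name, "", tuple(rank_entries(results)), 1.0, 1.0)


def random_signature(
    rng: np.random.Generator, universe_genes, size: int, name: str = "sig"
) -> GeneSignature:
    genes = rng.choice(np.asarray(list(universe_genes)), size=size, replace=False)
    dirs = rng.choice(["up", "down"], size=size)
    return make_signature([(str(g), str(d)) for g, d in zip(genes, dirs)], name=name)


@pytest.fixture
def universe200():
    genes = [f"U{i:03d}" for i in range(200)]
    return genes, UniverseSpec(genes)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
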