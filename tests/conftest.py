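"""Shared fixtures and independent oracles.

The oracles here are deliberately written from first principles, separate
from the package implementation they check: the per-site Weir & Cockerham
(1984) variance components computed scalar-by-scalar from genotype lists,
and the deterministic one-locus selection recursion.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def wc_theta_oracle(genotypes_a: list[int], genotypes_b: list[int]) -> float:
    """Weir & Cockerham (1984) per-site theta for two samples of diploid
    genotypes given as alt-allele dosages (0/1/2; missing entries omitted
    by the caller).  Returns NaN when the estimator is undefined.
    """
    r = 2
    samples = [list(genotypes_a), list(genotypes_b)]
    n = [len(g) for g in samples]
    if min(n) < 1:
        return float("nan")
    p = [sum(g) / (2 * len(g)) for g in samples]
    het = [sum(1 for x in g if x == 1) / len(g) for g in samples]
    n_bar = sum(n) / r
    if n_bar <= 1:
        return float("nan")
    n_c = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, het)) / sum(n)
    a = (n_bar / n_c) * (
        s2
        - (1 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    denom = a + b + c
    if denom == 0:
        return float("nan")
    return a / denom


def selection_recursion(p0: float, s: float, h: float, n_gen: int) -> float:
    """Deterministic one-locus recursion with fitnesses 1, 1+hs, 1+s."""
    p = p0
    for _ in range(n_gen):
        q = 1.0 - p
        w_a = p * (1 + s) + q * (1 + h * s)
        w_bar = p * p * (1 + s) + 2 * p * q * (1 + h * s) + q * q
        p = p * w_a / w_bar
    return p


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Deterministic toy dataset written once per session."""
    from sweepset.pipeline import make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    paths = make_fixtures(str(out), seed=7)
    return paths
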