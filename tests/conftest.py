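"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom, nbinom

from parcel import CountMatrix, SampleDesign


# ---------------------------------------------------------------------------
# brute-force segment oracles (independent of the Ruzzo-Tompa code path)


def brute_best_subarray(scores) -> tuple[int, int, float] | None:
    """Exhaustive maximum subarray: (start, end, score), 0-based inclusive.

    Score ties prefer the shortest subarray, then the leftmost (the
    minimal representative of the maximal segment); returns None when no
    subarray has positive score.
    """
    scores = list(scores)
    best = None
    eps = 1e-12
    for i in range(len(scores)):
        total = 0.0
        for j in range(i, len(scores)):
            total += scores[j]
            if total <= 0:
                continue
            if (
                best is None
                or total > best[2] + eps
                or (abs(total - best[2]) <= eps and (j - i) < (best[1] - best[0]))
            ):
                best = (i, j, total)
    return best


def brute_all_maximal(scores) -> list[tuple[int, int, float]]:
    """All disjoint maximal segments by recursive best-subarray removal."""
    scores = list(scores)

    def rec(lo: int, hi: int) -> list[tuple[int, int, float]]:
        if lo > hi:
            return []
        sub = brute_best_subarray(scores[lo : hi + 1])
        if sub is None:
            return []
        i, j, s = sub
        i, j = i + lo, j + lo
        return rec(lo, i - 1) + [(i, j, s)] + rec(j + 1, hi)

    return sorted(rec(0, len(scores) - 1))


# ---------------------------------------------------------------------------
# exact-test oracle: direct enumeration of the conditional distribution


def oracle_exact_pval(sa: int, sb: int, n_a: int, n_b: int, phi: float) -> float:
    """Doubled-tail conditional p-value by direct enumeration.

    Uses scipy's nbinom/binom pmfs (independent of the package's
    log-gamma composition): group sums of n iid NB(mu, phi) replicates
    are NB with mean n*mu and size n/phi; condition on the total and
    double the smaller inclusive tail.
    """
    t = sa + sb
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if phi == 0:
        pmf = binom.pmf(y, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        ra, rb = n_a / phi, n_b / phi
        fa = nbinom.pmf(y, ra, ra / (ra + n_a * mu))
        fb = nbinom.pmf(y[::-1], rb, rb / (rb + n_b * mu))
        pmf = fa * fb
        pmf = pmf / pmf.sum()
    lower = pmf[: sa + 1].sum()
    upper = pmf[sa:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


# ---------------------------------------------------------------------------
# small fixtures


@pytest.fixture
def small_matrix() -> CountMatrix:
    rng = np.random.default_rng(42)
    return CountMatrix(
        counts={
            "txA": rng.poisson(5.0, size=(40, 3)),
            "txB": rng.poisson(2.0, size=(25, 3)),
        },
        samples=["s1", "s2", "s3"],
    )


@pytest.fixture
def paired_design() -> SampleDesign:
    return SampleDesign.from_conditions(
        {"s1": "TPP", "s2": "control", "s3": "control"}
    )
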