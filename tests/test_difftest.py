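"""Differential testing: dispersion estimation, NB exact test, scoring."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from parcel import (
    CountMatrix,
    SampleDesign,
    SimulationConfig,
    Window,
    estimate_common_dispersion,
    nb_exact_test,
    score_positions,
    simulate_counts,
)
from parcel.difftest import LN_PVAL_REF
from parcel.difftest import test_all_positions as compute_position_stats

from conftest import oracle_exact_pval


class TestCommonDispersion:
    def test_identical_replicates_give_zero(self):
        arr = np.tile(np.arange(1, 101)[:, None], (1, 4))
        cm = CountMatrix({"t": arr}, ["a", "b", "c", "d"])
        design = SampleDesign.from_conditions({s: "c" for s in "abcd"})
        assert estimate_common_dispersion(cm, design) <= 1e-6

    def test_poisson_counts_near_zero(self):
        cfg = SimulationConfig(
            n_transcripts=4, lengths=500, conditions=("c",), replicates=4,
            dispersion=0.0, seed=3,
        )
        cm, design, _ = simulate_counts(cfg)
        assert estimate_common_dispersion(cm, design) <= 0.01

    def test_recovers_true_dispersion(self):
        """phi = 0.1 from 2000 positions x 4 replicates within +-0.03."""
        cfg = SimulationConfig(
            n_transcripts=4, lengths=500, conditions=("c",), replicates=4,
            dispersion=0.1, seed=11,
        )
        cm, design, _ = simulate_counts(cfg)
        assert abs(estimate_common_dispersion(cm, design) - 0.1) <= 0.03

    def test_requires_replicates(self, small_matrix):
        design = SampleDesign.from_conditions(
            {"s1": "a", "s2": "b", "s3": "c"}
        )
        with pytest.raises(ValueError, match="dispersion"):
            estimate_common_dispersion(small_matrix, design)


class TestExactTest:
    def test_perfectly_balanced_is_one(self):
        assert nb_exact_test([5, 5], [5, 5], 0.1) == 1.0

    def test_zero_total_is_one(self):
        assert nb_exact_test([0, 0], [0, 0], 0.2) == 1.0

    def test_binomial_limit(self):
        """phi = 0, equal libraries: two-sided binomial exact test."""
        got = nb_exact_test([0], [20], 0.0)
        assert got == pytest.approx(binomtest(0, 20, 0.5).pvalue, abs=1e-12)
        got = nb_exact_test([3], [11], 0.0)
        assert got == pytest.approx(binomtest(3, 14, 0.5).pvalue, rel=1e-10)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 2), (2, 3)])
    def test_matches_enumeration_oracle(self, phi, n_a, n_b):
        """Random small cases agree with direct conditional enumeration."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            t = int(rng.integers(1, 31))
            sa = int(rng.integers(0, t + 1))
            a = np.zeros(n_a, dtype=int)
            a[0] = sa
            b = np.zeros(n_b, dtype=int)
            b[0] = t - sa
            got = nb_exact_test(a, b, phi)
            want = oracle_exact_pval(sa, t - sa, n_a, n_b, phi)
            assert got == pytest.approx(want, abs=1e-10)

    def test_symmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            a = rng.poisson(8, size=2)
            b = rng.poisson(8, size=3)
            assert nb_exact_test(a, b, 0.15) == pytest.approx(
                nb_exact_test(b, a, 0.15), abs=1e-12
            )

    def test_rejects_invalid_input(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1], [2], 0.1)
        with pytest.raises(ValueError):
            nb_exact_test([1], [2], -0.1)


class TestPositionTesting:
    def test_low_abundance_positions_not_tested(self):
        arr = np.zeros((10, 4), dtype=int)
        arr[4] = [20, 20, 20, 20]
        arr[7] = [1, 0, 1, 0]  # a_mean = 0.5 <= 1
        cm = CountMatrix({"t": arr}, list("abcd"))
        design = SampleDesign.from_conditions(
            {"a": "TPP", "b": "TPP", "c": "ctl", "d": "ctl"}
        )
        stats = compute_position_stats(cm, design, "TPP", dispersion=0.1,
                                   normalization="library")
        row = stats.set_index("position")
        assert not row.loc[8, "abundance_pass"]
        assert np.isnan(row.loc[8, "pval"])
        assert row.loc[5, "abundance_pass"]
        assert 0 < row.loc[5, "pval"] <= 1

    def test_null_pvalues_are_tail_calibrated(self):
        """P(p <= a) tracks a closely: the E-value null assumption."""
        cfg = SimulationConfig(
            n_transcripts=10, lengths=1000, conditions=("TPP", "ctl"),
            replicates=2, seed=5, baseline_log_mean=math.log(20),
            baseline_log_sigma=0.5, transcript_log_sigma=0.0,
        )
        cm, design, _ = simulate_counts(cfg)
        stats = compute_position_stats(cm, design, "TPP", dispersion=0.1)
        pv = stats.loc[stats["abundance_pass"], "pval"].dropna().to_numpy()
        assert len(pv) > 9000
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = (pv <= alpha).mean()
            assert 0.6 * alpha <= frac <= 1.25 * alpha

    def test_implanted_window_yields_small_pvalues(self):
        """4-fold window at ~30x position coverage: median p < 1e-3."""
        cfg = SimulationConfig(
            n_transcripts=2, lengths=300, seed=9, transcript_log_sigma=0.0,
            windows=[Window("tx1", 101, 140, 4.0, "TPP", baseline_mean=30.0)],
        )
        cm, design, _ = simulate_counts(cfg)
        stats = compute_position_stats(cm, design, "TPP", dispersion=0.1)
        window = stats[
            (stats["transcript"] == "tx1")
            & stats["position"].between(101, 140)
        ]
        assert window["pval"].median() < 1e-3


class TestScoring:
    def make_stats(self, pvals, passed=None):
        n = len(pvals)
        passed = [True] * n if passed is None else passed
        return pd.DataFrame(
            {
                "transcript": "t",
                "position": np.arange(1, n + 1),
                "a_mean": np.where(passed, 5.0, 0.5),
                "abundance_pass": passed,
                "pval": [p if ok else np.nan for p, ok in zip(pvals, passed)],
                "log2fc": 0.0,
            }
        )

    def test_score_examples(self):
        tracks = score_positions(self.make_stats([0.1, 0.01, 1.0]))
        s = tracks["t"].scores
        assert s[0] == pytest.approx(0.0, abs=1e-12)
        assert s[1] == pytest.approx(math.log(10), abs=1e-9)  # 2.302585...
        assert s[2] == pytest.approx(LN_PVAL_REF)

    def test_penalty_for_abundance_failures_and_gaps(self):
        tracks = score_positions(
            self.make_stats([0.5, 0.5], passed=[True, False]),
            transcript_lengths={"t": 4},
        )
        s, tested = tracks["t"].scores, tracks["t"].tested
        assert s[1] == -10.0 and s[2] == -10.0 and s[3] == -10.0
        assert tested.tolist() == [True, False, False, False]

    def test_score_strictly_decreasing_in_pvalue(self):
        pv = np.sort(np.random.default_rng(1).uniform(1e-8, 1, size=50))
        tracks = score_positions(self.make_stats(pv))
        s = tracks["t"].scores
        assert np.all(np.diff(s) < 0)
        assert np.all((s > 0) == (pv < 0.1))

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            tracks = score_positions(self.make_stats([0.0]))
        assert np.isfinite(tracks["t"].scores[0])
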