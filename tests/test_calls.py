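"""Call filters, region assignment and the scaled position histogram."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from parcel import (
    FilterThresholds,
    Segment,
    TranscriptAnnotation,
    apply_filters,
    assign_region,
    default_params,
    scaled_position_histogram,
)


def make_stats(n=100, a_mean=5.0, pval=0.5, log2fc=0.0, transcript="t"):
    return pd.DataFrame(
        {
            "transcript": transcript,
            "position": np.arange(1, n + 1),
            "a_mean": np.full(n, a_mean, dtype=float),
            "abundance_pass": np.full(n, a_mean > 1.0),
            "pval": np.full(n, pval, dtype=float),
            "log2fc": np.full(n, log2fc, dtype=float),
        }
    )


class TestFilters:
    def test_high_evalue_segment_not_called(self):
        """E_v above the threshold of 10 blocks the call (length-scaled
        E-values; the plain formula is bounded by K and cannot reach 10)."""
        stats = make_stats(pval=1e-4, log2fc=2.0)
        stats.loc[stats["position"] == 10, "a_mean"] = 100.0
        seg = Segment("t", 10, 10, score=2.0)
        res = apply_filters([seg], stats, n_positions=10_000_000)
        assert res.loc[0, "e_value"] > 10
        assert not res.loc[0, "pass_evalue"]
        assert not res.loc[0, "called"]

    def test_weak_fold_change_not_called(self):
        """|log2FC| = 0.8 < 1 fails the f > 2 filter."""
        stats = make_stats(pval=1e-8, log2fc=0.8)
        stats.loc[stats["position"] == 10, "a_mean"] = 100.0
        seg = Segment("t", 10, 10, score=16.0)
        res = apply_filters([seg], stats)
        assert not res.loc[0, "pass_fold_change"]
        assert not res.loc[0, "called"]
        assert res.loc[0, "pass_evalue"] and res.loc[0, "pass_bonferroni"]

    def test_all_filters_pass(self):
        stats = make_stats(pval=0.5)
        idx = stats["position"] == 10
        stats.loc[idx, ["pval", "log2fc", "a_mean"]] = [1e-8, 2.5, 100.0]
        seg = Segment("t", 10, 10, score=16.0)
        res = apply_filters([seg], stats)
        assert bool(res.loc[0, "called"])
        # Bonferroni denominator is the number of tested positions
        assert res.loc[0, "min_p_bonferroni"] == pytest.approx(1e-8 * 100)

    def test_untested_only_segment_fails_evidence_filters(self):
        stats = make_stats(a_mean=0.5)  # nothing passes abundance
        stats["pval"] = np.nan
        stats["abundance_pass"] = False
        seg = Segment("t", 5, 8, score=1.0)
        res = apply_filters([seg], stats)
        assert not res.loc[0, "pass_abundance"]
        assert not res.loc[0, "pass_bonferroni"]
        assert not res.loc[0, "called"]

    def test_filters_are_monotone_in_thresholds(self):
        """Raising the E cutoff or lowering the fold-change cutoff never
        removes a call."""
        rng = np.random.default_rng(2)
        stats = make_stats(n=200, pval=0.5)
        hot = rng.choice(200, size=12, replace=False)
        stats.loc[hot, "pval"] = rng.uniform(1e-9, 1e-2, size=12)
        stats.loc[hot, "log2fc"] = rng.uniform(-3, 3, size=12)
        stats.loc[hot, "a_mean"] = rng.uniform(5, 80, size=12)
        segs = [Segment("t", int(p) + 1, int(p) + 1, score=5.0) for p in hot]
        loose = apply_filters(
            segs, stats, thresholds=FilterThresholds(e_value=100.0, fold_change=1.5)
        )
        tight = apply_filters(
            segs, stats, thresholds=FilterThresholds(e_value=10.0, fold_change=2.0)
        )
        called_tight = set(tight.loc[tight["called"], "start"])
        called_loose = set(loose.loc[loose["called"], "start"])
        assert called_tight <= called_loose


class TestRegions:
    @pytest.fixture
    def annotation(self):
        ann = TranscriptAnnotation()
        ann.add("t", 1, 50, "5'UTR")
        ann.add("t", 40, 200, "CDS")  # overlaps the 5'UTR on 40-50
        ann.add("t", 201, 260, "3'UTR")
        return ann

    def test_precedence_five_prime_over_cds(self, annotation):
        assert annotation.position_class("t", 45) == "5'UTR"
        assert assign_region(Segment("t", 42, 48, 1.0), annotation) == "5'UTR"

    def test_fully_inside_cds(self, annotation):
        assert assign_region(Segment("t", 100, 120, 1.0), annotation) == "CDS"

    def test_majority_rule_on_straddling_call(self, annotation):
        # 6 positions in CDS (195-200), 4 in 3'UTR (201-204)
        assert assign_region(Segment("t", 195, 204, 1.0), annotation) == "CDS"

    def test_unannotated(self, annotation):
        assert assign_region(Segment("t", 300, 310, 1.0), annotation) == "unannotated"
        assert assign_region(Segment("other", 5, 6, 1.0), annotation) == "unannotated"

    def test_gff3_and_bed_loaders(self, tmp_path):
        gff = tmp_path / "a.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "t\tsrc\tfive_prime_UTR\t1\t50\t.\t+\t.\tID=u5\n"
            "t\tsrc\tCDS\t51\t200\t.\t+\t.\tID=c\n"
            "t\tsrc\tthree_prime_UTR\t201\t260\t.\t+\t.\tID=u3\n"
        )
        ann = TranscriptAnnotation.from_gff3(gff)
        assert ann.position_class("t", 25) == "5'UTR"
        assert ann.feature_span("t", "CDS") == (51, 200)
        bed = tmp_path / "a.bed"
        bed.write_text("t\t0\t50\tfive_prime_UTR\nt\t50\t200\tCDS\n")
        ann2 = TranscriptAnnotation.from_bed(bed)
        assert ann2.position_class("t", 50) == "5'UTR"
        assert ann2.position_class("t", 51) == "CDS"


class TestScaledHistogram:
    def make_calls(self, positions, transcript="t"):
        return pd.DataFrame(
            {
                "transcript": transcript,
                "start": positions,
                "end": positions,
            }
        )

    def test_midpoint_maps_to_500(self):
        ann = TranscriptAnnotation()
        ann.add("t", 1, 333, "CDS")
        counts, edges = scaled_position_histogram(
            self.make_calls([167]), ann, n_bins=10
        )
        assert counts.sum() == 1
        assert counts[np.digitize(500.0, edges) - 1] == 1

    def test_empty_calls_all_zero(self):
        ann = TranscriptAnnotation()
        ann.add("t", 1, 100, "CDS")
        counts, _ = scaled_position_histogram(self.make_calls([]), ann)
        assert counts.sum() == 0

    def test_uniform_calls_give_flat_histogram(self):
        """1e4 uniform positions over a CDS: chi-square p > 0.01."""
        ann = TranscriptAnnotation()
        ann.add("t", 1, 5000, "CDS")
        rng = np.random.default_rng(8)
        pos = rng.integers(1, 5001, size=10_000)
        counts, _ = scaled_position_histogram(self.make_calls(pos), ann, n_bins=20)
        assert chisquare(counts).pvalue > 0.01

    def test_flank_mode_covers_500bp_windows(self):
        ann = TranscriptAnnotation()
        ann.add("t", 501, 1500, "CDS")
        counts, edges = scaled_position_histogram(
            self.make_calls([300, 1000, 1700]), ann, n_bins=20, flank=500
        )
        assert counts.sum() == 3
        assert edges[0] == -500 and edges[-1] == 1500
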