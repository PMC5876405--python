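"""Scikit-learn-style estimator wrapping the whole detection pipeline."""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .calls import FilterThresholds, TranscriptAnnotation, apply_filters
from .counts import CountMatrix, SampleDesign
from .difftest import estimate_common_dispersion, score_positions, test_all_positions
from .segments import Segment, max_scoring_segments
from .significance import compute_K

__all__ = ["ParcelDetector"]


class ParcelDetector(BaseEstimator):
    """Detect ligand-responsive RNA structural elements from V1 counts.

    ``fit`` runs the full pipeline on a :class:`~parcel.counts.CountMatrix`
    and a :class:`~parcel.counts.SampleDesign`: per-position NB exact
    tests of the contrast condition against all others, the
    ``ln(0.1) - ln(p)`` score transform with abundance penalties,
    Ruzzo-Tompa maximal-segment search, Karlin-Altschul E-values, and
    the final call filters.

    Parameters
    ----------
    contrast
        Condition tested against the pool of all other conditions.
    a_threshold
        Minimum average normalized counts per sample for a position to
        be tested (``a > a_threshold``; penalized otherwise).
    penalty
        Flat score of penalized positions.
    e_threshold, fc_threshold, bonferroni_threshold
        Call filters: E-value cutoff, linear fold-change cutoff, and
        Bonferroni-corrected p-value cutoff.
    e_inclusive
        Whether the E-value filter is ``<=`` (default) or strict ``<``.
    dispersion
        Common NB dispersion; estimated from replicates when None.
    normalization
        'tmm' (default) or 'library'.
    scale_evalues_by_length
        Scale E-values by the number of tested positions
        (``K * n * exp(-lambda*S)``) instead of the plain formula.
    best_only
        Report only the single best segment per transcript (Kadane
        answer) instead of all disjoint maximal segments.

    Attributes
    ----------
    dispersion_ : float
        Common dispersion used.
    stats_ : pandas.DataFrame
        Per-position differential statistics.
    score_tracks_ : dict[str, ScoreTrack]
        Per-transcript score tracks.
    segments_ : list[Segment]
        All maximal segments found.
    calls_ : pandas.DataFrame
        All segments with E-values, filter flags and the ``called`` flag.
    ka_params_ : KAParams
        Karlin-Altschul lambda and K computed from first principles.
    n_tested_ : int
        Number of abundance-passing tested positions (Bonferroni factor).
    """

    def __init__(
        self,
        contrast: str = "TPP",
        *,
        a_threshold: float = 1.0,
        penalty: float = -10.0,
        e_threshold: float = 10.0,
        fc_threshold: float = 2.0,
        bonferroni_threshold: float = 10.0,
        e_inclusive: bool = True,
        dispersion: float | None = None,
        normalization: str = "tmm",
        scale_evalues_by_length: bool = False,
        best_only: bool = False,
    ):
        self.contrast = contrast
        self.a_threshold = a_threshold
        self.penalty = penalty
        self.e_threshold = e_threshold
        self.fc_threshold = fc_threshold
        self.bonferroni_threshold = bonferroni_threshold
        self.e_inclusive = e_inclusive
        self.dispersion = dispersion
        self.normalization = normalization
        self.scale_evalues_by_length = scale_evalues_by_length
        self.best_only = best_only

    def fit(
        self,
        X: CountMatrix,
        y: SampleDesign | None = None,
        *,
        annotation: TranscriptAnnotation | None = None,
    ) -> "ParcelDetector":
        """Run the pipeline; ``X`` is the count matrix, ``y`` the design."""
        if y is None:
            raise ValueError("a SampleDesign is required (pass as y)")
        design = y
        design.validate_against(X)

        if self.dispersion is not None:
            self.dispersion_ = float(self.dispersion)
        else:
            self.dispersion_ = estimate_common_dispersion(
                X, design, normalization=self.normalization
            )
        self.stats_ = test_all_positions(
            X,
            design,
            self.contrast,
            a_threshold=self.a_threshold,
            dispersion=self.dispersion_,
            normalization=self.normalization,
        )
        self.score_tracks_ = score_positions(
            self.stats_, penalty=self.penalty, transcript_lengths=X.transcripts
        )
        segments: list[Segment] = []
        for track in self.score_tracks_.values():
            segs = max_scoring_segments(track)
            if self.best_only and segs:
                segs = [max(segs, key=lambda g: (g.score, -g.start, -g.length))]
            segments.extend(segs)
        self.segments_ = segments
        self.ka_params_ = compute_K()
        self.n_tested_ = int(
            (self.stats_["abundance_pass"] & self.stats_["pval"].notna()).sum()
        )
        thresholds = FilterThresholds(
            e_value=self.e_threshold,
            fold_change=self.fc_threshold,
            bonferroni=self.bonferroni_threshold,
            e_inclusive=self.e_inclusive,
        )
        self.calls_ = apply_filters(
            segments,
            self.stats_,
            self.ka_params_,
            thresholds,
            annotation=annotation,
            n_positions=self.n_tested_ if self.scale_evalues_by_length else None,
        )
        return self

    def predict(self, X: CountMatrix | None = None) -> pd.DataFrame:
        """Return the called aptamer candidates (rows of ``calls_``)."""
        if not hasattr(self, "calls_"):
            raise AttributeError("ParcelDetector is not fitted yet; call fit first")
        return self.calls_[self.calls_["called"]].reset_index(drop=True)

    def fit_predict(
        self,
        X: CountMatrix,
        y: SampleDesign | None = None,
        **fit_kwargs,
    ) -> pd.DataFrame:
        return self.fit(X, y, **fit_kwargs).predict()
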