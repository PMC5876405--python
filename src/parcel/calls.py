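"""Final filtering and annotation of candidate aptamer segments.

A maximal segment becomes a candidate RNA aptamer when it passes all of

* E-value at most a threshold (default 10),
* at least one position with absolute fold-change above 2
  (|log2 fold-change| > 1),
* at least one position whose relative abundance exceeds the transcript
  median plus one standard deviation (avoids low-accessibility regions),
* minimum Bonferroni-corrected p-value in the segment below a threshold
  (default 10, with the number of abundance-passing tested positions as
  the correction factor; avoids segments without any strongly changing
  position).

Every segment is retained in the output with per-filter flags so the
decisions are auditable; ``called`` marks the all-pass rows.  Calls are
optionally classified by transcript region with the precedence
5'UTR > CDS/operon > 3'UTR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .segments import Segment
from .significance import KAParams, default_params, evalue

__all__ = [
    "FilterThresholds",
    "TranscriptAnnotation",
    "apply_filters",
    "assign_region",
    "scaled_position_histogram",
    "REGION_PRECEDENCE",
]

REGION_PRECEDENCE = ("5'UTR", "CDS", "3'UTR")

_GFF_CLASSES = {
    "five_prime_utr": "5'UTR",
    "cds": "CDS",
    "operon": "CDS",
    "three_prime_utr": "3'UTR",
}


@dataclass(frozen=True)
class FilterThresholds:
    """Call thresholds; defaults follow the published pipeline."""

    e_value: float = 10.0
    fold_change: float = 2.0  # linear scale; |log2fc| > log2(fold_change)
    bonferroni: float = 10.0
    e_inclusive: bool = True  # E_v <= threshold (vs strict <)


@dataclass
class TranscriptAnnotation:
    """1-based inclusive feature intervals per transcript.

    Intervals may overlap; per-position class conflicts resolve by the
    precedence 5'UTR > CDS > 3'UTR.
    """

    intervals: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def add(self, transcript: str, start: int, end: int, cls: str) -> None:
        if cls not in REGION_PRECEDENCE:
            raise ValueError(f"unknown region class {cls!r}")
        if start < 1 or end < start:
            raise ValueError(f"bad interval [{start}, {end}]")
        self.intervals.setdefault(transcript, []).append((start, end, cls))

    def position_class(self, transcript: str, position: int) -> str | None:
        """Region class of one position after precedence, None if unannotated."""
        hits = {
            cls
            for start, end, cls in self.intervals.get(transcript, [])
            if start <= position <= end
        }
        for cls in REGION_PRECEDENCE:
            if cls in hits:
                return cls
        return None

    def feature_span(self, transcript: str, cls: str) -> tuple[int, int] | None:
        spans = [
            (s, e) for s, e, c in self.intervals.get(transcript, []) if c == cls
        ]
        if not spans:
            return None
        return min(s for s, _ in spans), max(e for _, e in spans)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "TranscriptAnnotation":
        """Load five_prime_UTR / CDS (or operon) / three_prime_UTR features.

        Coordinates in GFF3 are already 1-based inclusive; the seqid
        column must name the transcript used by the count matrix.
        """
        ann = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 8:
                    raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
                seqid, _, ftype, start, end = fields[:5]
                key = ftype.lower()
                if key in _GFF_CLASSES:
                    ann.add(seqid, int(start), int(end), _GFF_CLASSES[key])
        return ann

    @classmethod
    def from_bed(cls, path: str | Path) -> "TranscriptAnnotation":
        """BED with the class in column 4 (0-based half-open -> 1-based)."""
        ann = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end, name = line.split()[:4]
                key = name.lower()
                cls_name = _GFF_CLASSES.get(key, name)
                ann.add(chrom, int(start) + 1, int(end), cls_name)
        return ann


def assign_region(
    segment: Segment, annotation: TranscriptAnnotation
) -> str:
    """Majority region class of a segment's positions ('unannotated' if none).

    Each position first resolves overlaps by precedence; the segment
    takes the majority class over annotated positions, ties breaking by
    precedence order.
    """
    votes: dict[str, int] = {}
    for pos in segment.positions():
        c = annotation.position_class(segment.transcript, pos)
        if c is not None:
            votes[c] = votes.get(c, 0) + 1
    if not votes:
        return "unannotated"
    best = max(votes.values())
    for cls in REGION_PRECEDENCE:
        if votes.get(cls) == best:
            return cls
    return "unannotated"


def apply_filters(
    segments: Sequence[Segment],
    stats: pd.DataFrame,
    params: KAParams | None = None,
    thresholds: FilterThresholds | None = None,
    *,
    annotation: TranscriptAnnotation | None = None,
    n_positions: int | None = None,
) -> pd.DataFrame:
    """Annotate segments with E-values and the four call filters.

    Parameters
    ----------
    segments
        Maximal segments from the segment finder.
    stats
        Per-position table from :func:`parcel.difftest.test_all_positions`
        (same coordinates as the segments).
    params
        Karlin-Altschul parameters; computed from first principles when
        omitted.
    thresholds
        Call thresholds (defaults: E_v <= 10, |fold-change| > 2,
        Bonferroni-corrected p < 10).
    annotation
        Optional region annotation; adds a ``region`` column.
    n_positions
        When given, E-values are scaled by this search-space size
        (``K * n * exp(-lambda*S)``) instead of the plain
        ``K * exp(-lambda*S)``.

    The Bonferroni correction factor is the number of abundance-passing
    tested positions in the whole analysis.  Relative abundance compares
    each position's mean normalized count against the median + SD of its
    transcript's nonzero-coverage positions.
    """
    if params is None:
        params = default_params()
    if thresholds is None:
        thresholds = FilterThresholds()

    tested = stats[stats["abundance_pass"] & stats["pval"].notna()]
    n_tests = max(len(tested), 1)
    log2_thr = float(np.log2(thresholds.fold_change))

    # per-transcript abundance cutoff over nonzero-coverage positions
    cutoff: dict[str, float] = {}
    for t, grp in stats.groupby("transcript", sort=False):
        nonzero = grp.loc[grp["a_mean"] > 0, "a_mean"]
        if len(nonzero):
            cutoff[t] = float(nonzero.median() + nonzero.std(ddof=1))
        else:
            cutoff[t] = np.inf

    by_tx = {t: grp.set_index("position") for t, grp in stats.groupby("transcript", sort=False)}

    rows = []
    for seg in segments:
        grp = by_tx.get(seg.transcript)
        window = (
            grp.loc[seg.start : seg.end]
            if grp is not None
            else pd.DataFrame(columns=stats.columns)
        )
        seg_tested = window[window["abundance_pass"] & window["pval"].notna()]
        e_v = float(evalue(seg.score, params, n_positions=n_positions))
        if len(seg_tested):
            max_fc = float(seg_tested["log2fc"].abs().max())
            min_p_bonf = float(seg_tested["pval"].min() * n_tests)
            max_abund = float(seg_tested["a_mean"].max())
        else:
            # a segment referencing only untested positions carries no
            # evidence; it fails the evidence filters by definition
            max_fc, min_p_bonf, max_abund = 0.0, np.inf, 0.0
        pass_e = e_v <= thresholds.e_value if thresholds.e_inclusive else e_v < thresholds.e_value
        pass_fc = max_fc > log2_thr
        pass_ab = max_abund > cutoff.get(seg.transcript, np.inf)
        pass_bonf = min_p_bonf < thresholds.bonferroni
        row = {
            "transcript": seg.transcript,
            "start": seg.start,
            "end": seg.end,
            "length": seg.length,
            "score": seg.score,
            "e_value": e_v,
            "max_abs_log2fc": max_fc,
            "min_p_bonferroni": min_p_bonf,
            "max_rel_abundance": max_abund,
            "pass_evalue": pass_e,
            "pass_fold_change": pass_fc,
            "pass_abundance": pass_ab,
            "pass_bonferroni": pass_bonf,
            "called": bool(pass_e and pass_fc and pass_ab and pass_bonf),
        }
        if annotation is not None:
            row["region"] = assign_region(seg, annotation)
        rows.append(row)
    cols = [
        "transcript", "start", "end", "length", "score", "e_value",
        "max_abs_log2fc", "min_p_bonferroni", "max_rel_abundance",
        "pass_evalue", "pass_fold_change", "pass_abundance",
        "pass_bonferroni", "called",
    ]
    if annotation is not None:
        cols.append("region")
    return pd.DataFrame(rows, columns=cols)


def scaled_position_histogram(
    calls: pd.DataFrame,
    annotation: TranscriptAnnotation,
    n_bins: int = 50,
    *,
    feature_class: str = "CDS",
    flank: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of call positions with the feature scaled to 1 kbp.

    Every position of every call row in ``calls`` maps into [0, 1000]
    along its transcript's ``feature_class`` span; with ``flank > 0``
    positions up to ``flank`` bp outside the feature map linearly into
    [-flank, 0] and [1000, 1000 + flank] (for genomes without UTR
    annotation).  Returns ``(counts, bin_edges)``.
    """
    lo = -float(flank)
    hi = 1000.0 + float(flank)
    edges = np.linspace(lo, hi, n_bins + 1)
    scaled: list[float] = []
    for row in calls.itertuples(index=False):
        span = annotation.feature_span(row.transcript, feature_class)
        if span is None:
            continue
        fs, fe = span
        width = fe - fs + 1
        for pos in range(int(row.start), int(row.end) + 1):
            if fs <= pos <= fe:
                scaled.append((pos - fs + 0.5) / width * 1000.0)
            elif flank and fs - flank <= pos < fs:
                scaled.append(float(pos - fs) + 0.5)
            elif flank and fe < pos <= fe + flank:
                scaled.append(1000.0 + float(pos - fe) - 0.5)
    counts, _ = np.histogram(scaled, bins=edges)
    return counts, edges
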