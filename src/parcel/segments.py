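"""Maximal-scoring contiguous segments of a per-position score track.

The single best segment is the classic maximal-subarray (Kadane) answer;
candidate region discovery needs *all* disjoint maximal segments, found
with the Ruzzo-Tompa linear-time algorithm.  A segment is maximal when no
extension or trimming at either end increases its aggregate score; every
reported segment has positive score and starts/ends on a positive-score
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .difftest import ScoreTrack

__all__ = ["Segment", "max_scoring_segments", "best_segment", "segments_frame"]


@dataclass(frozen=True)
class Segment:
    """Contiguous run [start, end] (1-based, inclusive) with score sum S > 0."""

    transcript: str
    start: int
    end: int
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)


def _ruzzo_tompa(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal scoring subsequences as 0-based (start, end, score)."""
    # list entries: [L, R, start, end] with L/R cumulative sums bracketing
    # the candidate subsequence
    out: list[list[float]] = []
    cum = 0.0
    for i, s in enumerate(scores):
        prev = cum
        cum += s
        if s <= 0:
            continue
        L, R, start, end = prev, cum, i, i
        while True:
            # rightmost existing candidate whose left anchor is below L
            j = len(out) - 1
            while j >= 0 and out[j][0] >= L:
                j -= 1
            if j < 0 or out[j][1] >= R:
                out.append([L, R, start, end])
                break
            # merge candidate j with the current one and retry
            L, start = out[j][0], int(out[j][2])
            del out[j:]
    return [(int(a[2]), int(a[3]), float(a[1] - a[0])) for a in out]


def max_scoring_segments(track: ScoreTrack | Sequence[float]) -> list[Segment]:
    """All disjoint maximal-scoring positive segments, sorted by start.

    Accepts a :class:`~parcel.difftest.ScoreTrack` or a bare score
    sequence (transcript name ``""``).  Returns an empty list when no
    positive subarray exists.
    """
    if isinstance(track, ScoreTrack):
        name, scores = track.transcript, track.scores
    else:
        name, scores = "", np.asarray(track, dtype=float)
    if scores.size == 0:
        return []
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return [
        Segment(transcript=name, start=s + 1, end=e + 1, score=sc)
        for s, e, sc in _ruzzo_tompa(scores)
    ]


def best_segment(track: ScoreTrack | Sequence[float]) -> Segment | None:
    """The single maximal subarray (Kadane answer); ties break to the
    leftmost start, then the shortest segment."""
    segs = max_scoring_segments(track)
    if not segs:
        return None
    return max(segs, key=lambda g: (g.score, -g.start, -g.length))


def segments_frame(segments: Iterable[Segment]) -> pd.DataFrame:
    """Tabular view of segments (one row each)."""
    rows = [
        (g.transcript, g.start, g.end, g.length, g.score) for g in segments
    ]
    return pd.DataFrame(
        rows, columns=["transcript", "start", "end", "length", "score"]
    )
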