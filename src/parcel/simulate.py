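"""Synthetic V1 structure-probing data with known ground truth.

Counts are negative binomial around a per-position baseline mean that is
shared by every library; a ligand-responsive window multiplies the mean
in the affected condition only, emulating a local change in
double-strandedness upon ligand binding.  Baselines combine a
transcript-level expression factor with position-level cleavage
preference, both log-normal, mirroring the strong coverage
heterogeneity of nuclease probing libraries.

Randomness comes from the counter-based Philox generator keyed by
``(seed, transcript index)``, so any transcript can be regenerated in
isolation and results are independent of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .counts import CountMatrix, SampleDesign

__all__ = ["Window", "SimulationConfig", "simulate_counts", "write_fixture_sam"]


@dataclass(frozen=True)
class Window:
    """Implanted ligand-responsive region.

    ``fold_change`` multiplies the NB mean of the affected ``condition``
    inside [start, end] (1-based, inclusive); values below 1 model loss
    of structure.  ``baseline_mean`` optionally pins the per-position
    baseline inside the window (otherwise the drawn baseline is kept).
    """

    transcript: str
    start: int
    end: int
    fold_change: float
    condition: str
    baseline_mean: float | None = None


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults emulate a small multi-ligand probing experiment: four
    conditions (three metabolites and a water control) in duplicate,
    NB dispersion 0.1, and log-normal baselines giving a few counts per
    sample at a typical position with heavy tails.
    """

    n_transcripts: int = 6
    lengths: int | Sequence[int] = 400
    conditions: Sequence[str] = ("TPP", "FMN", "SAM", "control")
    replicates: int = 2
    dispersion: float = 0.1
    baseline_log_mean: float = math.log(5.0)
    baseline_log_sigma: float = 1.0
    transcript_log_sigma: float = 0.75
    windows: Sequence[Window] = field(default_factory=tuple)
    seed: int = 0

    def transcript_lengths(self) -> dict[str, int]:
        if isinstance(self.lengths, int):
            lens = [self.lengths] * self.n_transcripts
        else:
            lens = list(self.lengths)
            if len(lens) != self.n_transcripts:
                raise ValueError("lengths must match n_transcripts")
        return {f"tx{i + 1}": int(l) for i, l in enumerate(lens)}

    def sample_names(self) -> list[str]:
        return [
            f"{c}_rep{r + 1}" for c in self.conditions for r in range(self.replicates)
        ]

    def validate(self) -> None:
        lengths = self.transcript_lengths()
        if self.replicates < 1 or self.n_transcripts < 1:
            raise ValueError("need >= 1 transcript and >= 1 replicate")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for w in self.windows:
            if w.transcript not in lengths:
                raise ValueError(f"window references unknown transcript {w.transcript!r}")
            if not (1 <= w.start <= w.end <= lengths[w.transcript]):
                raise ValueError(
                    f"window [{w.start}, {w.end}] outside {w.transcript!r} "
                    f"(length {lengths[w.transcript]})"
                )
            if w.fold_change <= 0:
                raise ValueError("fold_change must be > 0")
            if w.condition not in self.conditions:
                raise ValueError(f"window condition {w.condition!r} not simulated")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, dispersion phi) via gamma-Poisson mixture; Poisson at phi=0."""
    if phi <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, SampleDesign, list[Window]]:
    """Draw a count matrix, its design, and the implanted truth windows."""
    cfg.validate()
    lengths = cfg.transcript_lengths()
    samples = cfg.sample_names()
    condition_of = {
        s: c for c in cfg.conditions for s in samples if s.startswith(f"{c}_rep")
    }
    design = SampleDesign.from_conditions({s: condition_of[s] for s in samples})

    counts: dict[str, np.ndarray] = {}
    for t_idx, (name, length) in enumerate(lengths.items()):
        rng = np.random.Generator(np.random.Philox(key=[cfg.seed, t_idx]))
        tx_factor = float(
            np.exp(rng.normal(0.0, cfg.transcript_log_sigma))
        )
        baseline = tx_factor * np.exp(
            rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sigma, size=length)
        )
        for w in cfg.windows:
            if w.transcript == name and w.baseline_mean is not None:
                baseline[w.start - 1 : w.end] = w.baseline_mean
        mean = np.tile(baseline[:, None], (1, len(samples)))
        for w in cfg.windows:
            if w.transcript != name:
                continue
            cols = [j for j, s in enumerate(samples) if condition_of[s] == w.condition]
            mean[w.start - 1 : w.end, cols] *= w.fold_change
        counts[name] = _nb_draw(rng, mean, cfg.dispersion).astype(np.int64)

    return CountMatrix(counts=counts, samples=samples), design, list(cfg.windows)


def write_fixture_sam(cm: CountMatrix, path: str | Path, read_length: int = 20) -> None:
    """Write a SAM file whose cleavage counts reproduce ``cm`` exactly.

    Inverse of the counting rule: a count at position p becomes a
    forward read starting at p + 1 (so a count at the final transcript
    position is unrepresentable - the read would start past the end -
    and raises).  Samples are encoded as read groups.  An empty matrix
    yields a header-only SAM.
    """
    lengths = cm.transcripts
    for name, arr in cm.counts.items():
        if arr.shape[0] and arr[-1].any():
            raise ValueError(
                f"count at final position of {name!r} cannot be represented: "
                "a read would have to start beyond the transcript end"
            )
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for s in cm.samples:
            fh.write(f"@RG\tID:{s}\tSM:{s}\n")
        n = 0
        for name, arr in cm.counts.items():
            length = arr.shape[0]
            for row, col in zip(*np.nonzero(arr)):
                start = int(row) + 2  # 1-based read start = position + 1
                span = min(read_length, length - start + 1)
                seq = "A" * span
                for _ in range(int(arr[row, col])):
                    n += 1
                    fh.write(
                        f"r{n}\t0\t{name}\t{start}\t42\t{span}M\t*\t0\t0\t"
                        f"{seq}\t*\tRG:Z:{cm.samples[col]}\n"
                    )
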