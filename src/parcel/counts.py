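"""Per-position RNase V1 cleavage count matrices.

A V1 structure-probing read marks a double-stranded cleavage site: the
enzyme cuts one base *upstream* of the read's first mapped base, so a read
whose 5' end maps to 1-based position ``p`` contributes one count to
position ``p - 1`` of its reference.  This module turns aligned reads
(SAM/BAM, single-end, uniquely mapped) or plain TSV tables into
:class:`CountMatrix` objects and persists them.

Coordinates are 1-based, fully closed, transcript-relative throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "count_cleavages",
    "count_libraries",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_transcript_table",
]


@dataclass
class CountMatrix:
    """Per-(transcript, position, sample) V1 cleavage counts.

    Parameters
    ----------
    counts
        Mapping ``transcript id -> (length, n_samples)`` integer array.
        Row ``i`` holds 1-based position ``i + 1``.
    samples
        Sample identifiers, one per array column.
    """

    counts: dict[str, np.ndarray]
    samples: list[str]

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        for name, arr in list(self.counts.items()):
            arr = np.asarray(arr)
            if arr.ndim != 2 or arr.shape[1] != len(self.samples):
                raise ValueError(
                    f"counts for {name!r} must be (length, {len(self.samples)}), "
                    f"got {arr.shape}"
                )
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.mod(arr, 1) == 0):
                    raise ValueError(f"non-integer counts for transcript {name!r}")
                arr = arr.astype(np.int64)
            if np.any(arr < 0):
                raise ValueError(f"negative counts for transcript {name!r}")
            self.counts[name] = np.ascontiguousarray(arr, dtype=np.int64)

    @property
    def transcripts(self) -> dict[str, int]:
        """Transcript id -> length (nt)."""
        return {name: arr.shape[0] for name, arr in self.counts.items()}

    @property
    def library_size(self) -> pd.Series:
        """Total counted reads per sample (sum over all positions)."""
        total = np.zeros(len(self.samples), dtype=np.int64)
        for arr in self.counts.values():
            total += arr.sum(axis=0)
        return pd.Series(total, index=self.samples, name="library_size")

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def to_frame(self, sparse: bool = True) -> pd.DataFrame:
        """Long/wide table: transcript, position, one column per sample."""
        blocks = []
        for name, arr in self.counts.items():
            if sparse:
                rows = np.flatnonzero(arr.any(axis=1))
            else:
                rows = np.arange(arr.shape[0])
            df = pd.DataFrame(arr[rows], columns=self.samples)
            df.insert(0, "position", rows + 1)
            df.insert(0, "transcript", name)
            blocks.append(df)
        if not blocks:
            return pd.DataFrame(columns=["transcript", "position", *self.samples])
        return pd.concat(blocks, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and set(self.counts) == set(other.counts)
            and all(
                np.array_equal(self.counts[t], other.counts[t]) for t in self.counts
            )
        )


@dataclass
class SampleDesign:
    """Assignment of libraries to ligand conditions and replicates.

    The tested contrast is always one condition versus the pool of all
    other conditions.
    """

    table: pd.DataFrame  # columns: sample, condition, replicate

    REQUIRED = ("sample", "condition", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].tolist()
            raise ValueError(f"duplicate samples in design: {dup}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_conditions(cls, mapping: Mapping[str, str]) -> "SampleDesign":
        rows = []
        seen: dict[str, int] = {}
        for sample, cond in mapping.items():
            seen[cond] = seen.get(cond, 0) + 1
            rows.append((sample, cond, seen[cond]))
        return cls(pd.DataFrame(rows, columns=["sample", "condition", "replicate"]))

    @property
    def samples(self) -> list[str]:
        return self.table["sample"].tolist()

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    def condition_of(self, sample: str) -> str:
        row = self.table.loc[self.table["sample"] == sample, "condition"]
        if row.empty:
            raise KeyError(f"sample {sample!r} not in design")
        return row.iloc[0]

    def samples_for(self, condition: str) -> list[str]:
        return self.table.loc[self.table["condition"] == condition, "sample"].tolist()

    def contrast_groups(self, contrast: str) -> tuple[list[str], list[str]]:
        """Samples for (contrast condition, pool of all other conditions)."""
        if contrast not in self.conditions:
            raise KeyError(f"contrast condition {contrast!r} not in design")
        a = self.samples_for(contrast)
        b = [s for s in self.samples if s not in a]
        return a, b

    def validate_against(self, cm: CountMatrix) -> None:
        design = set(self.samples)
        matrix = set(cm.samples)
        if design != matrix:
            raise ValueError(
                f"design/count-matrix sample mismatch: only in design "
                f"{sorted(design - matrix)}, only in matrix {sorted(matrix - design)}"
            )

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


def read_transcript_table(path: str | Path) -> dict[str, int]:
    """Transcript lengths from FASTA (sequence lengths) or 2-column TSV."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        lengths: dict[str, int] = {}
        name = None
        n = 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        lengths[name] = n
                    name = line[1:].split()[0]
                    n = 0
                elif line:
                    n += len(line)
        if name is not None:
            lengths[name] = n
        return lengths
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: transcript table needs 2 columns (id, length)")
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


def count_cleavages(
    alignments: str | Path | pysam.AlignmentFile,
    transcript_lengths: Mapping[str, int],
    *,
    sample: str | None = None,
    min_mapq: int = 1,
    drop_reverse: bool = True,
) -> CountMatrix:
    """Count V1 cleavage sites from single-end alignments.

    A read whose first mapped base is 1-based position ``p`` increments
    position ``p - 1``; reads starting at position 1 are dropped (the
    inspected upstream position does not exist).  Unmapped, secondary and
    supplementary records, and records below the mapping-quality floor,
    are skipped ("uniquely mapped reads only").  Samples are taken from
    read groups when the file defines them, otherwise all reads go to a
    single sample.

    Parameters
    ----------
    alignments
        SAM/BAM path or an open :class:`pysam.AlignmentFile`.
    transcript_lengths
        Mapping reference id -> length; references seen in the input but
        absent here are a hard error.
    sample
        Sample name used when the file defines no read groups; defaults
        to the file stem.
    min_mapq
        Keep records with ``MAPQ >= min_mapq`` (default 1, i.e. quality
        above 0); bowtie2 ``-k 1`` emits a single alignment per read, so
        any positive MAPQ denotes a unique placement.
    drop_reverse
        Drop reverse-strand alignments (transcriptome BAMs are expected
        forward; the V1 cut maps to the read 5' end).  Set False to count
        the read 5' end in reference coordinates on either strand.
    """
    own = False
    if not isinstance(alignments, pysam.AlignmentFile):
        path = Path(alignments)
        mode = "rb" if path.suffix == ".bam" else "r"
        alignments = pysam.AlignmentFile(str(path), mode, check_sq=False)
        own = True
        if sample is None:
            sample = path.stem
    elif sample is None:
        sample = "sample"

    header = alignments.header.to_dict()
    rg_ids = [rg["ID"] for rg in header.get("RG", [])]
    samples = rg_ids if rg_ids else [sample]
    sidx = {s: i for i, s in enumerate(samples)}

    counts = {
        str(name): np.zeros((int(length), len(samples)), dtype=np.int64)
        for name, length in transcript_lengths.items()
    }
    n_accepted = n_skipped = n_at_one = n_reverse = 0
    try:
        for read in alignments:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                n_skipped += 1
                continue
            if read.mapping_quality < min_mapq:
                n_skipped += 1
                continue
            if read.is_reverse:
                if drop_reverse:
                    n_reverse += 1
                    continue
                p = read.reference_end  # 5' end of a reverse read, 1-based
            else:
                p = read.reference_start + 1
            ref = read.reference_name
            if ref not in counts:
                raise KeyError(
                    f"alignment reference {ref!r} not in transcript table"
                )
            if p <= 1:
                n_at_one += 1
                continue
            if p - 1 > counts[ref].shape[0]:
                raise ValueError(
                    f"read start {p} beyond transcript {ref!r} "
                    f"length {counts[ref].shape[0]}"
                )
            col = sidx[read.get_tag("RG")] if rg_ids else 0
            counts[ref][p - 2, col] += 1
            n_accepted += 1
    finally:
        if own:
            alignments.close()

    if n_accepted == 0:
        warnings.warn("no reads counted; returning all-zero count matrix")
    return CountMatrix(counts=counts, samples=samples)


def count_libraries(
    library_paths: Mapping[str, str | Path],
    transcript_lengths: Mapping[str, int],
    **kwargs,
) -> CountMatrix:
    """Count several single-sample libraries into one matrix (one file each)."""
    samples = list(library_paths)
    counts = {
        str(name): np.zeros((int(length), len(samples)), dtype=np.int64)
        for name, length in transcript_lengths.items()
    }
    for j, (name, path) in enumerate(library_paths.items()):
        cm = count_cleavages(path, transcript_lengths, sample=name, **kwargs)
        if len(cm.samples) != 1:
            raise ValueError(
                f"{path}: expected a single-sample library, found read groups "
                f"{cm.samples}; use count_cleavages directly"
            )
        for t, arr in cm.counts.items():
            counts[t][:, j] += arr[:, 0]
    return CountMatrix(counts=counts, samples=samples)


def write_counts_tsv(cm: CountMatrix, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write a sparse TSV count matrix (transcript lengths in # headers)."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for name, length in cm.transcripts.items():
            fh.write(f"## length\t{name}\t{length}\n")
        fh.write("transcript\tposition\t" + "\t".join(cm.samples) + "\n")
        for name, arr in cm.counts.items():
            for row in np.flatnonzero(arr.any(axis=1)):
                vals = "\t".join(str(v) for v in arr[row])
                fh.write(f"{name}\t{row + 1}\t{vals}\n")


def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Read a count matrix written by :func:`write_counts_tsv`.

    Malformed rows, negative or non-integer counts, and out-of-range
    positions are rejected with the offending line number.
    """
    lengths: dict[str, int] = {}
    samples: list[str] | None = None
    rows: list[tuple[str, int, list[int]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("## length\t"):
                _, name, length = line.split("\t")
                lengths[name] = int(length)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if samples is None:
                if fields[:2] != ["transcript", "position"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header starting with "
                        "'transcript\\tposition'"
                    )
                samples = fields[2:]
                continue
            if len(fields) != 2 + len(samples):
                raise ValueError(f"{path}:{lineno}: expected {2 + len(samples)} fields")
            name = fields[0]
            try:
                pos = int(fields[1])
                vals = [int(v) for v in fields[2:]]
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer position or count"
                ) from None
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: position {pos} < 1 (1-based)")
            if any(v < 0 for v in vals):
                raise ValueError(f"{path}:{lineno}: negative count")
            rows.append((name, pos, vals))
    if samples is None:
        raise ValueError(f"{path}: no header line found")
    for name, pos, _ in rows:
        if name not in lengths:
            lengths[name] = 0
        lengths[name] = max(lengths[name], pos)
    counts = {
        name: np.zeros((length, len(samples)), dtype=np.int64)
        for name, length in lengths.items()
    }
    for name, pos, vals in rows:
        if pos > lengths[name]:
            raise ValueError(f"{path}: position {pos} beyond length of {name!r}")
        counts[name][pos - 1] = vals
    return CountMatrix(counts=counts, samples=list(samples))
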