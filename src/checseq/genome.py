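"""Coordinate-safe data model and file I/O shared by the whole pipeline.

All coordinates are 0-based half-open (BED convention), everywhere.  A
fragment ``[start, end)`` occupies bases ``start .. end-1``; its two cleavage
ends are the terminal bases ``start`` and ``end - 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Size of the budding yeast genome used for genome-scale normalization.
YEAST_GENOME_SIZE = 12_495_000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIndex:
    """Ordered chromosome names with lengths in bp.

    Parameters
    ----------
    lengths
        Mapping of chromosome name to length in bp; insertion order is the
        genome order.
    """

    def __init__(self, lengths: Mapping[str, int]):
        if not lengths:
            raise ValueError("no chromosomes")
        self._lengths: dict[str, int] = {}
        for name, length in lengths.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in self._lengths:
                raise ValueError(f"duplicate chromosome {name!r}")
            self._lengths[name] = length

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def total(self) -> int:
        """Total genome length in bp (sum of chromosome lengths)."""
        return sum(self._lengths.values())

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __len__(self) -> int:
        return len(self._lengths)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeIndex({len(self)} chromosomes, {self.total} bp)"


def read_chrom_sizes(path: str | Path) -> GenomeIndex:
    """Read a two-column ``name<TAB>length`` chrom.sizes file."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'name<TAB>length', got {line!r}")
            name, raw = fields[0], fields[1]
            try:
                length = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric length {raw!r} for chromosome {name!r}"
                ) from None
            if name in lengths:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            lengths[name] = length
    if not lengths:
        raise ValueError(f"{path}: no chromosomes")
    return GenomeIndex(lengths)


def write_chrom_sizes(genome: GenomeIndex, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in genome.names:
            fh.write(f"{name}\t{genome[name]}\n")


@dataclass
class FragmentSet:
    """Paired-end fragment intervals for one sample / time point.

    ``frame`` has columns ``chrom`` (str), ``start``, ``end`` (int, 0-based
    half-open).  Each fragment carries two cleavage ends, so
    ``n_ends == 2 * n_fragments`` by construction.
    """

    frame: pd.DataFrame
    genome: GenomeIndex
    sample: str = ""
    time: float | None = None  # seconds after calcium addition

    def __post_init__(self):
        df = self.frame
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"fragment frame needs columns {sorted(required)}")
        if len(df):
            if (df["start"] >= df["end"]).any():
                i = int(np.argmax((df["start"] >= df["end"]).to_numpy()))
                raise ValueError(f"fragment record {i}: start >= end")
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.genome:
                    raise ValueError(f"fragment on unknown chromosome {chrom!r}")
                if (sub["start"] < 0).any() or (sub["end"] > self.genome[chrom]).any():
                    bad = sub.index[(sub["start"] < 0) | (sub["end"] > self.genome[chrom])][0]
                    raise ValueError(f"fragment record {bad}: outside {chrom} bounds")

    @property
    def n_fragments(self) -> int:
        return len(self.frame)

    @property
    def n_ends(self) -> int:
        return 2 * len(self.frame)

    @property
    def mapped_bases(self) -> int:
        """Total mapped bases = sum of fragment lengths."""
        if not len(self.frame):
            return 0
        return int((self.frame["end"] - self.frame["start"]).sum())


def read_fragments(
    path: str | Path,
    genome: GenomeIndex,
    sample: str = "",
    time: float | None = None,
) -> FragmentSet:
    """Read a BED3+ file of paired-end fragment intervals.

    Only the first three columns are used; extra columns are ignored.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({"chrom": pd.Series(dtype=str),
                           "start": pd.Series(dtype=np.int64),
                           "end": pd.Series(dtype=np.int64)})
    return FragmentSet(df, genome, sample=sample, time=time)


def write_fragments(fragments: FragmentSet, path: str | Path) -> None:
    fragments.frame[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


@dataclass
class SignalTrack:
    """Per-base-pair numeric values for every chromosome of a genome.

    ``units`` declares what the values mean: ``raw`` end counts,
    ``depth_normalized``, or ``genome_scaled``.
    """

    genome: GenomeIndex
    data: dict[str, np.ndarray]
    units: str = "raw"

    def __post_init__(self):
        for name in self.genome.names:
            if name not in self.data:
                raise ValueError(f"track missing chromosome {name!r}")
            v = np.asarray(self.data[name], dtype=float)
            if v.shape != (self.genome[name],):
                raise ValueError(
                    f"track length {v.shape} != chromosome {name!r} length {self.genome[name]}"
                )
            self.data[name] = v

    @classmethod
    def zeros(cls, genome: GenomeIndex, units: str = "raw") -> "SignalTrack":
        return cls(genome, {n: np.zeros(genome[n]) for n in genome.names}, units=units)

    def sum(self) -> float:
        return float(np.sum([v.sum() for v in self.data.values()]))

    def mean(self) -> float:
        """Genome-wide mean over every base of every chromosome, zeros included."""
        return self.sum() / self.genome.total

    def copy(self, units: str | None = None) -> "SignalTrack":
        return SignalTrack(
            self.genome,
            {n: v.copy() for n, v in self.data.items()},
            units=self.units if units is None else units,
        )

    def allclose(self, other: "SignalTrack", atol: float = 0.0) -> bool:
        return self.genome == other.genome and all(
            np.allclose(self.data[n], other.data[n], atol=atol, rtol=0)
            for n in self.genome.names
        )


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    score: float | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class PeakSet:
    """Called peaks: intervals with midpoints and optional occupancy sums.

    ``frame`` columns: ``chrom``, ``start``, ``end``, ``midpoint`` and
    optionally ``occupancy``.  ``threshold`` records the genome-wide value
    threshold that produced the set.
    """

    frame: pd.DataFrame
    threshold: float | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        req = {"chrom", "start", "end"}
        if not req.issubset(self.frame.columns):
            raise ValueError(f"peak frame needs columns {sorted(req)}")
        if "midpoint" not in self.frame.columns:
            self.frame = self.frame.assign(
                midpoint=(self.frame["start"] + self.frame["end"]) // 2
            )

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval], **kw) -> "PeakSet":
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return cls(df, **kw)

    def to_bed(self, path: str | Path, name_prefix: str = "peak") -> None:
        df = self.frame
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": [f"{name_prefix}_{i}" for i in range(len(df))],
                "score": df["occupancy"] if "occupancy" in df else 0.0,
                "strand": ".",
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ peak file (external peak sets for overlap comparisons)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64}, comment="#",
    )
    return PeakSet(df)


# ---------------------------------------------------------------------------
# bedgraph

def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a 4-column bedgraph; runs of equal value merge, zero runs omitted.

    Values are written with ``repr`` so the round trip is value-exact.
    """
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            v = track.data[chrom]
            if not len(v):
                continue
            # run boundaries where the value changes
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                val = float(v[s])
                if val == 0.0:
                    continue
                fh.write(f"{chrom}\t{s}\t{e}\t{val!r}\n")


def read_bedgraph(path: str | Path, genome: GenomeIndex, units: str = "raw") -> SignalTrack:
    """Read a bedgraph into a dense track; unlisted positions are 0."""
    track = SignalTrack.zeros(genome, units=units)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedgraph columns")
            chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in genome:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if start < 0 or end > genome[chrom] or start >= end:
                raise ValueError(f"{path}:{lineno}: interval outside genome bounds")
            track.data[chrom][start:end] = value
    return track


# ---------------------------------------------------------------------------
# sequence access

def _clean_sequence(seq: str) -> str:
    seq = seq.upper()
    if not set(seq) <= _VALID_BASES:
        warnings.warn("non-ACGTN characters mapped to N", stacklevel=3)
        seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
    return seq


def fetch_sequence(fasta, chrom: str, start: int, end: int, strand: str = "+") -> str:
    """Fetch an uppercase genomic sequence; minus strand reverse complements.

    ``fasta`` may be a ``pyfaidx.Fasta`` handle or a plain mapping of
    chromosome name to sequence string (as produced by the simulator).
    """
    if start < 0 or start >= end:
        raise ValueError(f"bad interval [{start}, {end})")
    if strand not in ("+", "-"):
        raise ValueError(f"bad strand {strand!r}")
    record = fasta[chrom]
    if isinstance(record, str):
        if end > len(record):
            raise ValueError(f"interval [{start}, {end}) beyond {chrom} length {len(record)}")
        seq = record[start:end]
    else:  # pyfaidx-style record supporting slicing
        if end > len(record):
            raise ValueError(f"interval [{start}, {end}) beyond {chrom} length {len(record)}")
        seq = str(record[start:end])
    seq = _clean_sequence(seq)
    if strand == "-":
        seq = reverse_complement(seq)
    return seq


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
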