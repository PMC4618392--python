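"""Genome-wide threshold peak calling on composite maximum tracks.

The caller takes the per-position maximum across digestion time points,
thresholds at a multiple of the genome-wide mean (every base of every
chromosome, zeros included), and merges qualifying positions whose
coordinates differ by at most the interpeak distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import PeakSet, SignalTrack


@dataclass
class PeakCallParams:
    """Threshold and merge parameters.

    fold
        A base qualifies when its value is at least ``fold`` times the
        genome-wide average (inclusive).
    merge_distance
        Qualifying positions whose coordinates differ by at most this many
        bp belong to the same peak.
    """

    fold: float = 10.0
    merge_distance: int = 30

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold must be positive")
        if self.merge_distance < 0:
            raise ValueError("merge_distance must be >= 0")


def composite_max(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-position maximum over a set of time-point tracks."""
    if not tracks:
        raise ValueError("need at least one track")
    genome = tracks[0].genome
    for t in tracks[1:]:
        if t.genome != genome:
            raise ValueError("tracks cover different genomes")
    out = tracks[0].copy(units=tracks[0].units)
    for chrom in genome.names:
        out.data[chrom] = np.max([t.data[chrom] for t in tracks], axis=0)
    return out


def call_peaks(track: SignalTrack, params: PeakCallParams | None = None) -> PeakSet:
    """Threshold-and-merge peak calling.

    Returns peaks as ``[first, last + 1)`` over the merged qualifying
    positions, with midpoints ``floor((start + end) / 2)`` and per-peak
    occupancy (sum of track values over the peak extent).  The threshold
    used is recorded on the result.
    """
    params = params or PeakCallParams()
    mean = track.mean()
    if mean == 0.0:
        warnings.warn("all-zero track: no peaks called")
        empty = pd.DataFrame(columns=["chrom", "start", "end", "occupancy"])
        return PeakSet(empty.astype({"start": int, "end": int}), threshold=0.0,
                       params={"fold": params.fold, "merge_distance": params.merge_distance})
    threshold = params.fold * mean
    rows = []
    for chrom in track.genome.names:
        v = track.data[chrom]
        qual = np.flatnonzero(v >= threshold)
        if not len(qual):
            continue
        # break merged runs where the coordinate gap exceeds merge_distance
        breaks = np.flatnonzero(np.diff(qual) > params.merge_distance) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [len(qual)]))
        for a, b in zip(starts, ends):
            s = int(qual[a])
            e = int(qual[b - 1]) + 1
            rows.append((chrom, s, e, float(v[s:e].sum())))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "occupancy"])
    return PeakSet(df, threshold=threshold,
                   params={"fold": params.fold, "merge_distance": params.merge_distance,
                           "genome_mean": mean})


def window_bounds(midpoint: int, width: int, chrom_length: int) -> tuple[int, int]:
    """[m - floor(w/2), m + ceil(w/2)) clipped to the chromosome."""
    lo = midpoint - width // 2
    hi = midpoint + (width - width // 2)
    return max(0, lo), min(chrom_length, hi)


def window_sum(track: SignalTrack, peaks: PeakSet, width: int = 50) -> np.ndarray:
    """Sum of track values in a width-bp window centered on each midpoint.

    Windows are clipped at chromosome edges; the number of clipped windows
    is reported via a warning.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out = np.empty(len(peaks))
    clipped = 0
    df = peaks.frame
    for i, (chrom, m) in enumerate(zip(df["chrom"], df["midpoint"])):
        L = track.genome[chrom]
        lo, hi = window_bounds(int(m), width, L)
        if hi - lo < width:
            clipped += 1
        out[i] = track.data[chrom][lo:hi].sum()
    if clipped:
        warnings.warn(f"{clipped} window(s) clipped at chromosome edges")
    return out


def _overlaps_any(
    a_starts: np.ndarray, a_ends: np.ndarray,
    b_starts: np.ndarray, b_ends: np.ndarray,
) -> np.ndarray:
    """For each interval in a, does it share >= 1 bp with any interval in b?"""
    if not len(b_starts):
        return np.zeros(len(a_starts), dtype=bool)
    order = np.argsort(b_starts, kind="stable")
    bs = b_starts[order]
    be_cummax = np.maximum.accumulate(b_ends[order])
    # candidates: b intervals with start < a_end; overlap iff any end > a_start
    idx = np.searchsorted(bs, a_ends, side="left")
    hit = np.zeros(len(a_starts), dtype=bool)
    nz = idx > 0
    hit[nz] = be_cummax[idx[nz] - 1] > a_starts[nz]
    return hit


def _per_chrom_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in df.groupby("chrom", sort=False)
    }


def overlap_fdr(tf_peaks: PeakSet, control_peaks: PeakSet) -> float:
    """Percentage of TF peaks that share >= 1 bp with any control peak.

    This is the false-discovery proxy used for ChEC-seq: peaks also called
    in the untargeted free-MNase digestion are treated as potential
    artifacts.
    """
    if not len(tf_peaks):
        raise ValueError("empty TF peak set")
    if not len(control_peaks):
        return 0.0
    ctrl = _per_chrom_arrays(control_peaks.frame)
    n_hit = 0
    for chrom, sub in tf_peaks.frame.groupby("chrom", sort=False):
        if chrom not in ctrl:
            continue
        bs, be = ctrl[chrom]
        n_hit += int(_overlaps_any(sub["start"].to_numpy(), sub["end"].to_numpy(), bs, be).sum())
    return 100.0 * n_hit / len(tf_peaks)


def intersect_window_sets(
    a_sites: PeakSet, b_sites: PeakSet, width: int = 100,
    genome=None,
) -> tuple[int, float]:
    """Overlap of two site sets via width-bp windows centered on midpoints.

    Returns the number of ``b`` sites whose window shares >= 1 bp with any
    ``a`` window, and that count as a percentage of ``b``.  Windows are
    half-open, so exactly abutting windows (zero shared bp) do not overlap.
    """
    if not len(b_sites):
        return 0, 0.0

    def windows(df):
        out = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            m = sub["midpoint"].to_numpy()
            lo = m - width // 2
            hi = m + (width - width // 2)
            if genome is not None:
                lo = np.maximum(lo, 0)
                hi = np.minimum(hi, genome[chrom])
            out[chrom] = (lo, hi)
        return out

    wa = windows(a_sites.frame)
    wb = windows(b_sites.frame)
    n_hit = 0
    for chrom, (bs, be) in wb.items():
        if chrom not in wa:
            continue
        a_lo, a_hi = wa[chrom]
        n_hit += int(_overlaps_any(bs, be, a_lo, a_hi).sum())
    return n_hit, 100.0 * n_hit / len(b_sites)


def unique_fraction(
    own_sites: PeakSet, other_site_sets: Sequence[PeakSet], width: int = 100
) -> tuple[int, float]:
    """Sites of one factor whose window overlaps no other factor's windows.

    Returns the unique count and its percentage of ``own_sites`` (the
    slow-site specificity statistic).
    """
    if not len(own_sites):
        raise ValueError("empty site set")
    hit = np.zeros(len(own_sites), dtype=bool)
    for other in other_site_sets:
        own_hit = np.zeros(len(own_sites), dtype=bool)
        wo = _window_arrays(own_sites, width)
        wt = _window_arrays(other, width)
        offset = 0
        for chrom, sub in own_sites.frame.groupby("chrom", sort=False):
            n = len(sub)
            lo, hi = wo[chrom]
            if chrom in wt:
                bs, be = wt[chrom]
                own_hit[offset : offset + n] = _overlaps_any(lo, hi, bs, be)
            offset += n
        hit |= own_hit
    n_unique = int((~hit).sum())
    return n_unique, 100.0 * n_unique / len(own_sites)


def _window_arrays(sites: PeakSet, width: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, sub in sites.frame.groupby("chrom", sort=False):
        m = sub["midpoint"].to_numpy()
        out[chrom] = (m - width // 2, m + (width - width // 2))
    return out


def spearman_reproducibility(occ_rep1: np.ndarray, occ_rep2: np.ndarray) -> float:
    """Spearman rank correlation of peak occupancies between replicates."""
    a = np.asarray(occ_rep1, dtype=float)
    b = np.asarray(occ_rep2, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("replicate occupancy vectors must be equal-length 1-D")
    if len(a) < 3:
        raise ValueError("need at least 3 peaks")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant occupancy vector: correlation undefined")
    rho, _ = stats.spearmanr(a, b)
    return float(rho)
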