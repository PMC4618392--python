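"""Time-course occupancy matrices and fast/slow kinetic classification.

Each called peak gets a row of 50-bp window cleavage sums across the
ordered digestion time points.  Rows are Z-scored (population standard
deviation) so that shape, not amplitude, drives the clustering; k-means
with k=2 then partitions sites, and the class whose rows reach their
maximum earlier on average is labelled "fast".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genome import PeakSet, SignalTrack
from .peaks import window_sum

FAST = "fast"
SLOW = "slow"


@dataclass
class TimeCourseMatrix:
    values: np.ndarray  # peaks x time points
    times: tuple[float, ...]  # seconds, strictly increasing
    peak_index: pd.DataFrame  # chrom / start / end / midpoint per row
    zscored: bool = False
    constant_rows: np.ndarray | None = None  # mask, set by zscore_rows

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("matrix must be 2-D (peaks x time points)")
        if self.values.shape[1] != len(self.times):
            raise ValueError("column count != number of time points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("time points must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"t{t:g}s" for t in self.times])
        df.insert(0, "midpoint", self.peak_index["midpoint"].to_numpy())
        df.insert(0, "chrom", self.peak_index["chrom"].to_numpy())
        df.to_csv(path, sep="\t", index=False)


@dataclass
class KineticClasses:
    labels: np.ndarray  # per peak, "fast" | "slow"
    mean_argmax_time: dict[str, float]  # per class, seconds
    k: int = 2
    seed: int = 0
    inertia: float = float("nan")
    cluster_id: np.ndarray | None = None


def build_time_matrix(
    tracks_by_time: Mapping[float, SignalTrack],
    peaks: PeakSet,
    width: int = 50,
) -> TimeCourseMatrix:
    """Entry (i, j) = cleavage sum in a width-bp window at peak i, time j."""
    if len(tracks_by_time) < 2:
        raise ValueError("need at least 2 time points")
    times = tuple(sorted(tracks_by_time))
    cols = [window_sum(tracks_by_time[t], peaks, width=width) for t in times]
    values = np.column_stack(cols) if len(peaks) else np.empty((0, len(times)))
    return TimeCourseMatrix(values, times, peaks.frame[["chrom", "start", "end", "midpoint"]].copy())


def zscore_rows(matrix: TimeCourseMatrix) -> TimeCourseMatrix:
    """Per-row (x - mean) / sd with population sd; constant rows become 0."""
    if matrix.values.shape[1] < 2:
        raise ValueError("need >= 2 columns to Z-score")
    v = matrix.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population (ddof=0)
    constant = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (v - mean) / sd_safe
    z[constant] = 0.0
    return TimeCourseMatrix(
        z, matrix.times, matrix.peak_index, zscored=True, constant_rows=constant
    )


def argmax_time(matrix: TimeCourseMatrix) -> np.ndarray:
    """Index of the earliest time point attaining each row's maximum."""
    if matrix.n_peaks == 0:
        raise ValueError("empty matrix")
    return np.argmax(matrix.values, axis=1)  # np.argmax returns first maximum


def cluster_kinetics(
    matrix: TimeCourseMatrix, k: int = 2, seed: int = 0, n_init: int = 10
) -> KineticClasses:
    """k-means partition of Z-scored rows into kinetic classes.

    The cluster whose members reach their row maximum earlier (mean over
    the actual time values) is labelled fast.  Rows flagged constant are
    assigned to the slow class: a flat time course has no detectable early
    maximum.
    """
    if not matrix.zscored:
        raise ValueError("cluster_kinetics expects a Z-scored matrix")
    if matrix.n_peaks < k:
        raise ValueError(f"{matrix.n_peaks} rows < k={k}")
    if k == 1:
        warnings.warn("k=1: single class labelled fast")
        labels = np.full(matrix.n_peaks, FAST, dtype=object)
        t = np.asarray(matrix.times)[argmax_time(matrix)]
        return KineticClasses(labels, {FAST: float(t.mean())}, k=1, seed=seed,
                              cluster_id=np.zeros(matrix.n_peaks, dtype=int))
    if k != 2:
        raise ValueError("only k=2 (fast/slow) or k=1 supported")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    cid = km.fit_predict(matrix.values)
    times = np.asarray(matrix.times)
    tmax = times[argmax_time(matrix)]
    means = [tmax[cid == c].mean() for c in range(k)]
    fast_cluster = int(np.argmin(means))
    labels = np.where(cid == fast_cluster, FAST, SLOW).astype(object)
    if matrix.constant_rows is not None:
        labels[matrix.constant_rows] = SLOW
    mean_argmax = {
        FAST: float(tmax[labels == FAST].mean()) if (labels == FAST).any() else float("nan"),
        SLOW: float(tmax[labels == SLOW].mean()) if (labels == SLOW).any() else float("nan"),
    }
    return KineticClasses(labels, mean_argmax, k=2, seed=seed,
                          inertia=float(km.inertia_), cluster_id=cid)
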