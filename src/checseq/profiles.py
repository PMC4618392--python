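"""Strand-oriented average cleavage-end profiles around motif matches.

Sites are oriented so the best match to the consensus reads left to right
on the top strand: windows at minus-strand matches are reversed before
averaging, so negative offsets are always 5' (upstream) of the motif.
The asymmetry index quantifies the upstream/downstream imbalance of
cleavage that reflects the MNase fusion geometry on DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import NormalizationSpec, genome_scale_normalize
from .genome import SignalTrack


@dataclass
class CleavageProfile:
    offsets: np.ndarray      # -flank .. flank-1 relative to the match center
    mean: np.ndarray         # mean end count per offset
    n_sites: int
    units: str = "raw"
    control_subtracted: bool = False
    lo: np.ndarray | None = None  # bootstrap band, if computed
    hi: np.ndarray | None = None

    @property
    def flank(self) -> int:
        return len(self.offsets) // 2

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"offset": self.offsets, "mean": self.mean})
        if self.lo is not None:
            df["ci_lo"] = self.lo
            df["ci_hi"] = self.hi
        return df


def _site_window_matrix(track: SignalTrack, sites: pd.DataFrame, flank: int):
    """Per-site oriented windows [center-flank, center+flank); skips edges."""
    rows = []
    skipped = 0
    for _, site in sites.iterrows():
        chrom = site["chrom"]
        c = int(site["midpoint"])
        L = track.genome[chrom]
        if c - flank < 0 or c + flank > L:
            skipped += 1
            continue
        win = track.data[chrom][c - flank : c + flank]
        if site.get("strand", "+") == "-":
            win = win[::-1]
        rows.append(win)
    if skipped:
        warnings.warn(f"{skipped} site(s) skipped: window exceeds chromosome")
    if not rows:
        return np.empty((0, 2 * flank)), skipped
    return np.array(rows), skipped


def oriented_end_profile(
    end_track: SignalTrack, matches: pd.DataFrame, flank: int = 50
) -> CleavageProfile:
    """Average end counts at each offset of a 2*flank window around matches.

    ``matches`` needs columns ``chrom``, ``midpoint`` (match center) and
    ``strand``.  Minus-strand windows are reversed so offsets increase in
    the motif's 5'->3' direction.
    """
    mat, _ = _site_window_matrix(end_track, matches, flank)
    if not len(mat):
        raise ValueError("no site window fits inside the genome")
    return CleavageProfile(
        offsets=np.arange(-flank, flank),
        mean=mat.mean(axis=0),
        n_sites=len(mat),
        units=end_track.units,
    )


def normalize_and_subtract(
    profile_tf: CleavageProfile,
    profile_control: CleavageProfile,
    spec_tf: NormalizationSpec,
    spec_control: NormalizationSpec,
) -> CleavageProfile:
    """Genome-scale each profile with its own fragment count, then subtract."""
    if len(profile_tf.offsets) != len(profile_control.offsets):
        raise ValueError("profiles have different flank sizes")
    for spec in (spec_tf, spec_control):
        if not spec.fragments_mapped:
            raise ValueError("normalization spec missing fragments_mapped")
    tf = profile_tf.mean * (spec_tf.genome_size / spec_tf.fragments_mapped)
    ctrl = profile_control.mean * (spec_control.genome_size / spec_control.fragments_mapped)
    return CleavageProfile(
        offsets=profile_tf.offsets.copy(),
        mean=tf - ctrl,
        n_sites=profile_tf.n_sites,
        units="genome_scaled",
        control_subtracted=True,
    )


def average_signal_ci(
    track: SignalTrack,
    sites: pd.DataFrame,
    flank: int = 50,
    n_boot: int = 1000,
    seed: int = 0,
) -> CleavageProfile:
    """Mean profile over sites with a 95% percentile-bootstrap band.

    Resamples sites with replacement ``n_boot`` times; the band is the
    2.5/97.5 percentile of the resampled means at each offset.
    """
    mat, _ = _site_window_matrix(track, sites, flank)
    n = len(mat)
    if n == 0:
        raise ValueError("no usable sites")
    mean = mat.mean(axis=0)
    if n < 2:
        warnings.warn("fewer than 2 sites: returning mean without a band")
        return CleavageProfile(np.arange(-flank, flank), mean, n, units=track.units)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = mat[idx].mean(axis=1)  # n_boot x offsets
    lo = np.percentile(boot_means, 2.5, axis=0)
    hi = np.percentile(boot_means, 97.5, axis=0)
    return CleavageProfile(
        np.arange(-flank, flank), mean, n, units=track.units, lo=lo, hi=hi
    )


def asymmetry_index(profile: CleavageProfile, motif_width: int) -> float:
    """(U - D) / (U + D): upstream vs downstream cleavage imbalance.

    A symmetric interior margin of ceil(w/2) bp on each side of the match
    center is excluded, so strand reflection negates the index exactly for
    any motif width.  Returns NaN when U + D = 0.
    """
    import math

    h = (motif_width + 1) // 2
    # fsum is summation-order independent, so reflection negates bit-exactly
    up = math.fsum(profile.mean[profile.offsets < -h])
    down = math.fsum(profile.mean[profile.offsets >= h])
    total = up + down
    if total == 0:
        return float("nan")
    return float((up - down) / total)


def reflect_profile(profile: CleavageProfile) -> CleavageProfile:
    """Profile after flipping every site's strand (offset o -> -(o+1))."""
    return CleavageProfile(
        offsets=profile.offsets.copy(),
        mean=profile.mean[::-1].copy(),
        n_sites=profile.n_sites,
        units=profile.units,
        control_subtracted=profile.control_subtracted,
        lo=None if profile.lo is None else profile.lo[::-1].copy(),
        hi=None if profile.hi is None else profile.hi[::-1].copy(),
    )
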