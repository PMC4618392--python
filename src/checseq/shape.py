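"""Pentamer-based DNA shape prediction and profile comparison.

Four structural features are predicted from sequence by a sliding-pentamer
lookup: minor groove width (MGW, Angstrom) and propeller twist (ProT,
degrees) are properties of the pentamer's center base; roll and helix
twist (Roll, HelT, degrees) belong to the two dinucleotide steps flanking
the center base.  An interior step is covered by the central steps of at
most two pentamers and receives their average.

The pentamer query table is consumed as data in a simple TSV dialect
(``pentamer  MGW  ProT  Roll1  Roll2  HelT1  HelT2``); a synthetic
reverse-complement-symmetric table generator is provided for testing and
simulation.  Physical derivation of the table values is out of scope.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import reverse_complement

FEATURES = ("MGW", "ProT", "Roll", "HelT")
BASE_FEATURES = ("MGW", "ProT")   # one value per pentamer center base
STEP_FEATURES = ("Roll", "HelT")  # two values per pentamer (flanking steps)


@dataclass
class ShapeTable:
    """Pentamer -> structural feature values.

    ``base``: {pentamer: (MGW, ProT)};
    ``step``: {pentamer: (Roll1, Roll2, HelT1, HelT2)} where 1 is the step
    left of the center base and 2 the step right of it.
    """

    base: dict[str, tuple[float, float]]
    step: dict[str, tuple[float, float, float, float]]

    def __post_init__(self):
        if set(self.base) != set(self.step):
            raise ValueError("base and step tables cover different pentamers")

    @property
    def complete(self) -> bool:
        return len(self.base) == 1024

    def is_symmetric(self, atol: float = 1e-9) -> bool:
        """Reverse-complement consistency of every covered pentamer pair."""
        for p, (mgw, prot) in self.base.items():
            rc = reverse_complement(p)
            if rc not in self.base:
                return False
            mgw2, prot2 = self.base[rc]
            if abs(mgw - mgw2) > atol or abs(prot - prot2) > atol:
                return False
            r1, r2, h1, h2 = self.step[p]
            r1c, r2c, h1c, h2c = self.step[rc]
            if abs(r1 - r2c) > atol or abs(r2 - r1c) > atol:
                return False
            if abs(h1 - h2c) > atol or abs(h2 - h1c) > atol:
                return False
        return True


def all_pentamers():
    for tup in itertools.product("ACGT", repeat=5):
        yield "".join(tup)


def make_symmetric_shape_table(seed: int = 0) -> ShapeTable:
    """Synthetic shape table: random values in physically plausible ranges.

    Values are drawn once per reverse-complement pentamer pair so the table
    satisfies the feature symmetries exactly (MGW/ProT equal between a
    pentamer and its reverse complement; Roll/HelT step values swap).  This
    is a synthetic stand-in for a published pentamer query table — it has
    the right structure and ranges, not measured values.
    """
    rng = np.random.default_rng(seed)
    base: dict[str, tuple[float, float]] = {}
    step: dict[str, tuple[float, float, float, float]] = {}
    for p in all_pentamers():
        if p in base:
            continue
        rc = reverse_complement(p)
        mgw = float(rng.uniform(3.0, 6.2))       # Angstrom
        prot = float(rng.uniform(-16.0, -2.0))   # degrees
        r1, r2 = rng.uniform(-6.0, 8.0, size=2)  # degrees
        h1, h2 = rng.uniform(30.0, 38.0, size=2)
        base[p] = (mgw, prot)
        step[p] = (float(r1), float(r2), float(h1), float(h2))
        if rc != p:
            base[rc] = (mgw, prot)
            step[rc] = (float(r2), float(r1), float(h2), float(h1))
    return ShapeTable(base, step)


def write_shape_table(table: ShapeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pentamer\tMGW\tProT\tRoll1\tRoll2\tHelT1\tHelT2\n")
        for p in sorted(table.base):
            mgw, prot = table.base[p]
            r1, r2, h1, h2 = table.step[p]
            fh.write(f"{p}\t{mgw!r}\t{prot!r}\t{r1!r}\t{r2!r}\t{h1!r}\t{h2!r}\n")


def read_shape_table(path: str | Path) -> ShapeTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"pentamer", "MGW", "ProT", "Roll1", "Roll2", "HelT1", "HelT2"}
    if not required.issubset(df.columns):
        raise ValueError(f"shape table needs columns {sorted(required)}")
    base = {}
    step = {}
    for row in df.itertuples(index=False):
        base[row.pentamer] = (float(row.MGW), float(row.ProT))
        step[row.pentamer] = (float(row.Roll1), float(row.Roll2),
                              float(row.HelT1), float(row.HelT2))
    return ShapeTable(base, step)


def predict_shape(sequence: str, table: ShapeTable) -> dict[str, np.ndarray]:
    """Slide a pentamer window along a sequence and look up shape values.

    Returns per-feature vectors with NaN where no pentamer covers a
    position: MGW/ProT have length L (NaN at the 2-bp margins); Roll/HelT
    have length L-1 (one value per dinucleotide step, NaN at the outermost
    steps).  Positions whose pentamer contains N, or is absent from a
    partial table, are NaN and counted in a warning.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < 5:
        raise ValueError("sequence shorter than a pentamer")
    mgw = np.full(L, np.nan)
    prot = np.full(L, np.nan)
    roll_sum = np.zeros(L - 1)
    roll_n = np.zeros(L - 1, dtype=int)
    helt_sum = np.zeros(L - 1)
    helt_n = np.zeros(L - 1, dtype=int)
    missing = 0
    for c in range(2, L - 2):
        pent = seq[c - 2 : c + 3]
        entry = table.base.get(pent)
        if entry is None:
            missing += 1
            continue
        mgw[c], prot[c] = entry
        r1, r2, h1, h2 = table.step[pent]
        roll_sum[c - 1] += r1
        roll_n[c - 1] += 1
        roll_sum[c] += r2
        roll_n[c] += 1
        helt_sum[c - 1] += h1
        helt_n[c - 1] += 1
        helt_sum[c] += h2
        helt_n[c] += 1
    if missing:
        warnings.warn(f"{missing} pentamer(s) unresolved (N or absent from table)")
    with np.errstate(invalid="ignore"):
        roll = np.where(roll_n > 0, roll_sum / np.maximum(roll_n, 1), np.nan)
        helt = np.where(helt_n > 0, helt_sum / np.maximum(helt_n, 1), np.nan)
    return {"MGW": mgw, "ProT": prot, "Roll": roll, "HelT": helt}


@dataclass
class ShapeProfile:
    """Per-offset mean shape values over an oriented site set."""

    features: dict[str, np.ndarray]  # feature -> mean vector
    counts: dict[str, np.ndarray]    # feature -> per-offset n used
    n_sites: int

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for feat, v in self.features.items():
            data[feat] = pd.Series(v)
        return pd.DataFrame(data)


def class_average_shape(site_sequences, table: ShapeTable) -> ShapeProfile:
    """Per-offset mean of predicted shape over equal-length oriented sites."""
    seqs = list(site_sequences)
    if not seqs:
        raise ValueError("no sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("site sequences must be equal length")
    acc: dict[str, list[np.ndarray]] = {f: [] for f in FEATURES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in seqs:
            pred = predict_shape(s, table)
            for f in FEATURES:
                acc[f].append(pred[f])
    features = {}
    counts = {}
    for f in FEATURES:
        mat = np.array(acc[f])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            features[f] = np.nanmean(mat, axis=0)
        counts[f] = np.sum(~np.isnan(mat), axis=0)
    return ShapeProfile(features, counts, n_sites=len(seqs))


def compare_shape_profiles(
    profile_a: ShapeProfile, profile_b: ShapeProfile
) -> dict[str, tuple[float, float, float]]:
    """Per-feature (PCC, KS statistic, KS p) between two mean profiles.

    The Pearson correlation is over aligned offsets; the two-sample KS test
    compares the value distributions of the two mean vectors.  PCC close to
    1 together with a large KS p indicates similar shape profiles.  A
    constant profile yields NaN for the PCC.
    """
    out = {}
    for f in FEATURES:
        a = profile_a.features[f]
        b = profile_b.features[f]
        if len(a) != len(b):
            raise ValueError(f"{f}: profiles have different lengths")
        ok = ~np.isnan(a) & ~np.isnan(b)
        if ok.sum() < 3:
            raise ValueError(f"{f}: fewer than 3 shared offsets")
        av, bv = a[ok], b[ok]
        if np.ptp(av) == 0 or np.ptp(bv) == 0:
            pcc = float("nan")
        else:
            pcc = float(stats.pearsonr(av, bv)[0])
        ks_stat, ks_p = stats.ks_2samp(av, bv)
        out[f] = (pcc, float(ks_stat), float(ks_p))
    return out
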