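"""PSSM scanning with exact p-values and high/low site classification.

A position frequency matrix is converted to log-odds against a zero-order
background.  Scores are discretized onto an integer grid and the exact
null distribution of the best-possible word score is obtained by dynamic
programming: per-position integer score distributions under the background
are convolved, and the p-value of a match is the tail probability that a
background-generated w-mer scores at least as high.  Sites with a best
match p-value < 0.001 are "high-scoring"; p >= 0.001 is "low-scoring".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeIndex, Interval, PeakSet, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_ALPHA = 0.001
HIGH = "high"
LOW = "low"


@dataclass
class MotifModel:
    """Probability matrix + background with an exact score-to-p lookup."""

    probs: np.ndarray          # w x 4, rows sum to 1
    background: np.ndarray     # 4 probabilities, sums to 1
    log_odds: np.ndarray       # w x 4, log2(p / bg)
    int_matrix: np.ndarray     # w x 4 integer-scaled scores, row-min 0
    scale: float               # integer units per log2 unit
    offset: float              # sum of per-row log-odds minima
    pvalue_by_int: np.ndarray  # survival function over integer total scores

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    @property
    def max_int_score(self) -> int:
        return int(self.int_matrix.max(axis=1).sum())

    def score_window(self, seq: str) -> tuple[int, float] | None:
        """Integer and log-odds score of a width-w sequence; None if any N."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != motif width {self.width}")
        total_int = 0
        total_lo = 0.0
        for i, b in enumerate(seq):
            j = _BASE_INDEX.get(b)
            if j is None:
                return None
            total_int += self.int_matrix[i, j]
            total_lo += self.log_odds[i, j]
        return int(total_int), float(total_lo)

    def pvalue(self, int_score: int) -> float:
        """P(background w-mer integer score >= int_score); in (0, 1]."""
        if int_score <= 0:
            return 1.0
        if int_score > self.max_int_score:
            int_score = self.max_int_score
        return float(self.pvalue_by_int[int_score])


@dataclass
class MotifMatch:
    chrom: str | None
    start: int        # genome coordinate of match start (or window-relative)
    strand: str
    score: float      # log2 odds
    int_score: int
    pvalue: float
    peak_id: int | None = None
    site_class: str | None = None


def match_center(match: MotifMatch, width: int) -> int:
    """Anchor base of a match: start + floor(width/2)."""
    return match.start + width // 2


def build_motif(
    counts: np.ndarray,
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    n_bins: int = 1000,
) -> MotifModel:
    """Build a scoring model from a count (or probability) matrix.

    probabilities = (count + pseudocount * bg) / (colsum + pseudocount);
    log-odds = log2(p / bg), discretized to ``n_bins`` integer bins spanning
    the attainable score range so that exact p-values can be tabulated.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("count matrix must be w x 4 (A, C, G, T)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    w = counts.shape[0]
    if w < 1:
        raise ValueError("motif width must be >= 1")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    colsum = counts.sum(axis=1, keepdims=True)
    if pseudocount == 0 and (colsum == 0).any():
        raise ValueError("zero column sum with zero pseudocount")
    with np.errstate(divide="ignore"):
        probs = (counts + pseudocount * bg) / (colsum + pseudocount)
        log_odds = np.log2(probs / bg)
    # a zero probability (possible only at pseudocount 0) scores -inf; pin it
    # to a finite floor far below any attainable score for the integer grid
    floor = np.log2(1e-10 / bg.max())
    lo_finite = np.where(np.isneginf(log_odds), floor, log_odds)

    row_min = lo_finite.min(axis=1)
    row_max = lo_finite.max(axis=1)
    span = float((row_max - row_min).sum())
    scale = (n_bins / span) if span > 0 else 1.0
    int_matrix = np.rint((lo_finite - row_min[:, None]) * scale).astype(np.int64)

    # DP over the integer score distribution under the background
    max_total = int(int_matrix.max(axis=1).sum())
    pmf = np.zeros(max_total + 1)
    pmf[0] = 1.0
    for i in range(w):
        new = np.zeros_like(pmf)
        for j in range(4):
            s = int(int_matrix[i, j])
            new[s:] += pmf[: max_total + 1 - s] * bg[j]
        pmf = new
    sf = np.cumsum(pmf[::-1])[::-1]  # sf[s] = P(score >= s)
    sf = np.minimum(sf, 1.0)
    return MotifModel(
        probs=probs,
        background=bg,
        log_odds=log_odds,
        int_matrix=int_matrix,
        scale=scale,
        offset=float(row_min.sum()),
        pvalue_by_int=sf,
    )


def best_match(model: MotifModel, window: str, chrom: str | None = None,
               window_start: int = 0) -> MotifMatch | None:
    """Best-scoring motif match over both strands and all offsets.

    Ties break to the leftmost offset, then the + strand.  Offsets whose
    w-mer contains N are skipped; a window with no scoreable offset (or
    shorter than the motif) yields None.
    """
    w = model.width
    window = window.upper()
    if len(window) < w:
        return None
    best: tuple[int, int, int] | None = None  # (-int_score, offset, strand_rank)
    best_payload = None
    for off in range(len(window) - w + 1):
        sub = window[off : off + w]
        for strand_rank, strand in ((0, "+"), (1, "-")):
            seq = sub if strand == "+" else reverse_complement(sub)
            scored = model.score_window(seq)
            if scored is None:
                continue
            int_score, lo = scored
            key = (-int_score, off, strand_rank)
            if best is None or key < best:
                best = key
                best_payload = (off, strand, int_score, lo)
    if best_payload is None:
        return None
    off, strand, int_score, lo = best_payload
    return MotifMatch(
        chrom=chrom,
        start=window_start + off,
        strand=strand,
        score=lo,
        int_score=int_score,
        pvalue=model.pvalue(int_score),
    )


def classify_sites(matches, alpha: float = DEFAULT_ALPHA):
    """Partition matches into high (p < alpha, strict) and low (p >= alpha)."""
    high, low = [], []
    for m in matches:
        if m.pvalue < alpha:
            m.site_class = HIGH
            high.append(m)
        else:
            m.site_class = LOW
            low.append(m)
    return high, low


def scan_peaks(model: MotifModel, peaks: PeakSet, fasta, window: int = 50,
               alpha: float = DEFAULT_ALPHA):
    """Score a window-bp sequence around each peak midpoint.

    Returns (matches, n_dropped) where dropped peaks had no scoreable
    offset (all-N or edge-truncated below motif width).
    """
    from .genome import fetch_sequence
    from .peaks import window_bounds

    matches = []
    dropped = 0
    for i, row in peaks.frame.iterrows():
        chrom = row["chrom"]
        record = fasta[chrom]
        L = len(record)
        lo, hi = window_bounds(int(row["midpoint"]), window, L)
        seq = fetch_sequence(fasta, chrom, lo, hi, "+")
        m = best_match(model, seq, chrom=chrom, window_start=lo)
        if m is None:
            dropped += 1
            continue
        m.peak_id = i
        matches.append(m)
    classify_sites(matches, alpha=alpha)
    return matches, dropped


def matches_to_frame(matches, width: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in matches],
            "start": [m.start for m in matches],
            "end": [m.start + width for m in matches],
            "midpoint": [match_center(m, width) for m in matches],
            "strand": [m.strand for m in matches],
            "score": [m.score for m in matches],
            "pvalue": [m.pvalue for m in matches],
            "site_class": [m.site_class for m in matches],
            "peak_id": [m.peak_id for m in matches],
        }
    )


def generate_random_sites(
    genome: GenomeIndex,
    n: int,
    width: int,
    exclude_sets=(),
    seed: int = 0,
    max_attempts_factor: int = 1000,
) -> PeakSet:
    """n uniform-random width-bp windows avoiding all excluded intervals.

    Rejection-samples windows (length-weighted chromosome choice, uniform
    start) against >= 1 bp overlap with any interval of any exclude set.
    Raises after ``max_attempts_factor * n`` failed draws, reporting how
    many sites were achievable.
    """
    rng = np.random.default_rng(seed)
    names = [c for c in genome.names if genome[c] >= width]
    if not names:
        raise ValueError(f"no chromosome can hold a {width}-bp window")
    weights = np.array([genome[c] - width + 1 for c in names], dtype=float)
    weights /= weights.sum()

    exclude: dict[str, list[tuple[int, int]]] = {}
    for ps in exclude_sets:
        df = ps.frame if isinstance(ps, PeakSet) else ps
        for chrom, sub in df.groupby("chrom", sort=False):
            exclude.setdefault(chrom, []).extend(
                zip(sub["start"].to_numpy(), sub["end"].to_numpy())
            )
    excl_arr = {
        c: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
        for c, ivs in exclude.items()
    }

    rows = []
    attempts = 0
    limit = max_attempts_factor * max(n, 1)
    while len(rows) < n:
        if attempts >= limit:
            raise RuntimeError(
                f"random-site rejection sampling failed: placed {len(rows)} of {n} "
                f"after {attempts} attempts"
            )
        attempts += 1
        chrom = names[int(rng.choice(len(names), p=weights))]
        start = int(rng.integers(0, genome[chrom] - width + 1))
        end = start + width
        if chrom in excl_arr:
            s, e = excl_arr[chrom]
            if bool(np.any((s < end) & (e > start))):
                continue
        rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(df, params={"seed": seed, "width": width})


# ---------------------------------------------------------------------------
# PFM file parsing

def read_pfm(path: str | Path) -> np.ndarray:
    """Read a count/frequency matrix in MEME or plain-text dialects.

    Accepted layouts (auto-detected):
    * MEME minimal format (``letter-probability matrix`` block, w rows x 4)
    * 4 rows x w columns with an optional leading base letter per row
      (``A | 1 2 3`` or ``A: 1 2 3`` or ``A 1 2 3``), rows in any order
    * w rows x 4 columns with an optional ``A C G T`` header
    Returns a w x 4 array in A, C, G, T order.
    """
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]

    if any("letter-probability matrix" in ln for ln in lines):
        start = next(i for i, ln in enumerate(lines) if "letter-probability matrix" in ln)
        rows = []
        for ln in lines[start + 1 :]:
            parts = ln.split()
            if len(parts) == 4:
                try:
                    rows.append([float(x) for x in parts])
                    continue
                except ValueError:
                    pass
            if rows:
                break
        if not rows:
            raise ValueError(f"{path}: empty letter-probability matrix")
        return np.array(rows)

    labelled: dict[str, list[float]] = {}
    numeric_rows: list[list[float]] = []
    for ln in lines:
        if not ln or ln.startswith(("#", ">")):
            continue
        parts = ln.replace("|", " ").replace(":", " ").replace("[", " ").replace("]", " ").split()
        if not parts:
            continue
        if parts[0].upper() in ("A", "C", "G", "T") and len(parts) > 1:
            try:
                labelled[parts[0].upper()] = [float(x) for x in parts[1:]]
                continue
            except ValueError:
                pass
        if set(p.upper() for p in parts) == set("ACGT"):
            continue  # header row
        try:
            numeric_rows.append([float(x) for x in parts])
        except ValueError:
            continue
    if len(labelled) == 4:
        widths = {len(v) for v in labelled.values()}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged base rows")
        return np.array([labelled[b] for b in BASES]).T
    if numeric_rows:
        arr = np.array(numeric_rows)
        if arr.shape[1] == 4:
            return arr
        if arr.shape[0] == 4:
            return arr.T
    raise ValueError(f"{path}: could not parse a position frequency matrix")


def genome_background(sequences) -> np.ndarray:
    """Zero-order background from genome composition (N ignored)."""
    counts = np.zeros(4)
    for seq in (sequences.values() if isinstance(sequences, dict) else sequences):
        s = str(seq).upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    if counts.sum() == 0:
        raise ValueError("no ACGT bases found")
    return counts / counts.sum()
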