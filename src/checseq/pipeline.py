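"""End-to-end orchestration: tracks -> peaks -> kinetics -> motifs -> shape.

``run_pipeline`` executes the stages in order on in-memory inputs and
returns a result bundle; the CLI is a thin wrapper that reads files,
calls this, and writes each stage's outputs.  Stage parameters default to
the study's values (fold 10, merge 30, 50-bp temporal windows, 100-bp
profile/shape windows, alpha 0.001).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import coverage, discriminate, kinetics, motifs, peaks, profiles, shape
from .genome import FragmentSet, GenomeIndex, PeakSet, SignalTrack, fetch_sequence
from .peaks import PeakCallParams, window_bounds


@dataclass
class PipelineParams:
    fold: float = 10.0
    merge_distance: int = 30
    temporal_window: int = 50
    profile_window: int = 100
    motif_scan_window: int = 50
    alpha: float = 0.001
    flank: int = 50
    pseudocount: float = 0.1
    ridge_lambda: float = 1.0
    folds: int = 10
    seed: int = 0


@dataclass
class PipelineResult:
    params: PipelineParams
    tracks_by_time: dict[float, SignalTrack]
    composite: SignalTrack
    peaks: PeakSet
    control_peaks: PeakSet | None
    fdr_pct: float | None
    matrix: "kinetics.TimeCourseMatrix"
    classes: "kinetics.KineticClasses"
    matches: list
    match_frame: pd.DataFrame
    high_sites: PeakSet | None
    low_sites: PeakSet | None
    random_sites: PeakSet | None
    shape_comparison: dict | None
    aurocs: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)


def fragments_to_normalized_track(frags: FragmentSet) -> SignalTrack:
    raw = coverage.end_counts(frags)
    spec = coverage.NormalizationSpec.from_fragments(frags, coverage.DEPTH_SCALED)
    return coverage.depth_normalize(raw, spec)


def _sites_from_matches(match_frame: pd.DataFrame, cls: str) -> PeakSet | None:
    sub = match_frame[match_frame["site_class"] == cls]
    if not len(sub):
        return None
    return PeakSet(sub[["chrom", "start", "end", "midpoint"]].reset_index(drop=True))


def _site_sequences(sites: pd.DataFrame, fasta, genome: GenomeIndex, width: int) -> list[str]:
    out = []
    for _, row in sites.iterrows():
        chrom = row["chrom"]
        lo, hi = window_bounds(int(row["midpoint"]), width, genome[chrom])
        if hi - lo < width:
            continue
        out.append(fetch_sequence(fasta, chrom, lo, hi, row.get("strand", "+")))
    return out


def run_pipeline(
    fragments_by_time: Mapping[float, FragmentSet],
    control_fragments: FragmentSet | None,
    fasta,
    genome: GenomeIndex,
    motif_counts: np.ndarray,
    shape_table: "shape.ShapeTable | None" = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    params = params or PipelineParams()
    counts: dict[str, int] = {}

    # normalize + composite maximum across the time course
    tracks = {t: fragments_to_normalized_track(f) for t, f in fragments_by_time.items()}
    composite = peaks.composite_max(list(tracks.values()))

    # peak calling (+ free-MNase FDR)
    pk = peaks.call_peaks(composite, PeakCallParams(params.fold, params.merge_distance))
    counts["n_peaks"] = len(pk)
    control_pk = None
    fdr = None
    if control_fragments is not None:
        ctrl_track = fragments_to_normalized_track(control_fragments)
        control_pk = peaks.call_peaks(
            ctrl_track, PeakCallParams(params.fold, params.merge_distance)
        )
        counts["n_control_peaks"] = len(control_pk)
        fdr = peaks.overlap_fdr(pk, control_pk) if len(pk) else None

    # kinetics
    mat = kinetics.build_time_matrix(tracks, pk, width=params.temporal_window)
    matz = kinetics.zscore_rows(mat)
    classes = kinetics.cluster_kinetics(matz, k=2, seed=params.seed)
    counts["n_fast"] = int((classes.labels == kinetics.FAST).sum())
    counts["n_slow"] = int((classes.labels == kinetics.SLOW).sum())

    # motif scan on peak windows
    background = motifs.genome_background(fasta if isinstance(fasta, dict) else
                                          {c: str(fasta[c][:]) for c in genome.names})
    model = motifs.build_motif(motif_counts, background=background,
                               pseudocount=params.pseudocount)
    match_list, dropped = motifs.scan_peaks(
        model, pk, fasta, window=params.motif_scan_window, alpha=params.alpha
    )
    counts["n_peaks_unscoreable"] = dropped
    match_frame = motifs.matches_to_frame(match_list, model.width)
    high = _sites_from_matches(match_frame, motifs.HIGH)
    low = _sites_from_matches(match_frame, motifs.LOW)
    counts["n_high"] = 0 if high is None else len(high)
    counts["n_low"] = 0 if low is None else len(low)

    # random control sites matched in number to the low-scoring set
    random_sites = None
    if low is not None:
        exclude = [s for s in (high, low) if s is not None]
        random_sites = motifs.generate_random_sites(
            genome, n=len(low), width=params.profile_window,
            exclude_sets=exclude, seed=params.seed + 1,
        )

    # DNA shape comparison of high vs low vs random site windows
    shape_cmp = None
    aurocs: dict[str, float] = {}
    if shape_table is not None and high is not None and low is not None:
        seq_sets = {}
        for name, sites in (("high", high), ("low", low), ("random", random_sites)):
            if sites is None:
                continue
            frame = sites.frame.copy()
            if "strand" not in frame.columns:
                strands = (
                    match_frame.loc[match_frame["site_class"] == name, "strand"].to_numpy()
                    if name in ("high", "low") else "+"
                )
                frame["strand"] = strands
            seqs = _site_sequences(frame, fasta, genome, params.profile_window)
            if seqs:
                seq_sets[name] = seqs
        if "high" in seq_sets and "low" in seq_sets:
            prof_high = shape.class_average_shape(seq_sets["high"], shape_table)
            prof_low = shape.class_average_shape(seq_sets["low"], shape_table)
            shape_cmp = {"high_vs_low": shape.compare_shape_profiles(prof_high, prof_low)}
            if "random" in seq_sets:
                prof_rand = shape.class_average_shape(seq_sets["random"], shape_table)
                shape_cmp["high_vs_random"] = shape.compare_shape_profiles(
                    prof_high, prof_rand
                )
            # sequence vs shape discrimination, high vs low
            seqs_all = seq_sets["high"] + seq_sets["low"]
            labels = np.array([1] * len(seq_sets["high"]) + [0] * len(seq_sets["low"]))
            Xs, kept_s = discriminate.encode_sequence(seqs_all)
            Xh, kept_h, _ = discriminate.encode_shape(seqs_all, shape_table)
            aurocs["sequence_high_vs_low"] = discriminate.ridge_auroc(
                Xs, labels[kept_s], lam=params.ridge_lambda,
                folds=params.folds, seed=params.seed,
            )["auroc_cv"]
            aurocs["shape_high_vs_low"] = discriminate.ridge_auroc(
                Xh, labels[kept_h], lam=params.ridge_lambda,
                folds=params.folds, seed=params.seed,
            )["auroc_cv"]
            if "random" in seq_sets:
                seqs_hr = seq_sets["high"] + seq_sets["random"]
                labels_hr = np.array(
                    [1] * len(seq_sets["high"]) + [0] * len(seq_sets["random"])
                )
                Xs2, kept2 = discriminate.encode_sequence(seqs_hr)
                aurocs["sequence_high_vs_random"] = discriminate.ridge_auroc(
                    Xs2, labels_hr[kept2], lam=params.ridge_lambda,
                    folds=params.folds, seed=params.seed,
                )["auroc_cv"]
                Xh2, kept2h, _ = discriminate.encode_shape(seqs_hr, shape_table)
                aurocs["shape_high_vs_random"] = discriminate.ridge_auroc(
                    Xh2, labels_hr[kept2h], lam=params.ridge_lambda,
                    folds=params.folds, seed=params.seed,
                )["auroc_cv"]

    return PipelineResult(
        params=params,
        tracks_by_time=tracks,
        composite=composite,
        peaks=pk,
        control_peaks=control_pk,
        fdr_pct=fdr,
        matrix=matz,
        classes=classes,
        matches=match_list,
        match_frame=match_frame,
        high_sites=high,
        low_sites=low,
        random_sites=random_sites,
        shape_comparison=shape_cmp,
        aurocs=aurocs,
        counts=counts,
    )


def write_manifest(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "params": vars(result.params),
        "threshold": result.peaks.threshold,
        "counts": result.counts,
        "fdr_pct": result.fdr_pct,
        "aurocs": result.aurocs,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
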