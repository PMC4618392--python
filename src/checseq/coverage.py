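"""Cleavage-end counting and track normalization.

Two distinct normalization schemes are used downstream:

* ``depth_scaled`` — for track visualization and cross-time-point
  comparison: each position is divided by the total number of mapped read
  ends in the sample and scaled back up by the total mapped bases.
* ``genome_scaled`` — for average cleavage-profile analysis: each position
  is multiplied by the genome size (yeast: 12,495,000 bp) divided by the
  number of fragments mapped in the sample.

Free-MNase control tracks are subtracted elementwise after normalization;
negative differences are retained, not clipped, so that site-averaged
profiles stay unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import YEAST_GENOME_SIZE, FragmentSet, GenomeIndex, SignalTrack

DEPTH_SCALED = "depth_scaled"
GENOME_SCALED = "genome_scaled"


@dataclass
class NormalizationSpec:
    """Constants needed to normalize one sample's track."""

    scheme: str
    genome_size: int = YEAST_GENOME_SIZE
    total_ends: int | None = None
    total_mapped_bases: int | None = None
    fragments_mapped: int | None = None

    def __post_init__(self):
        if self.scheme not in (DEPTH_SCALED, GENOME_SCALED):
            raise ValueError(f"unknown normalization scheme {self.scheme!r}")

    @classmethod
    def from_fragments(
        cls, fragments: FragmentSet, scheme: str, genome_size: int = YEAST_GENOME_SIZE
    ) -> "NormalizationSpec":
        return cls(
            scheme=scheme,
            genome_size=genome_size,
            total_ends=fragments.n_ends,
            total_mapped_bases=fragments.mapped_bases,
            fragments_mapped=fragments.n_fragments,
        )


def end_counts(fragments: FragmentSet, genome: GenomeIndex | None = None) -> SignalTrack:
    """Count fragment ends per base position.

    Each fragment ``[start, end)`` contributes +1 at ``start`` and +1 at
    ``end - 1`` (both cut sites land on real bases; a length-1 fragment
    contributes 2 at its single base).  The track sum is therefore exactly
    twice the fragment count.
    """
    genome = genome or fragments.genome
    track = SignalTrack.zeros(genome, units="raw")
    df = fragments.frame
    for chrom, sub in df.groupby("chrom", sort=False):
        v = track.data[chrom]
        np.add.at(v, sub["start"].to_numpy(), 1.0)
        np.add.at(v, sub["end"].to_numpy() - 1, 1.0)
    return track


def depth_normalize(track: SignalTrack, spec: NormalizationSpec) -> SignalTrack:
    """v' = v / total_ends * total_mapped_bases (sequencing-depth scaling)."""
    if spec.scheme != DEPTH_SCALED:
        raise ValueError(f"spec scheme is {spec.scheme!r}, expected {DEPTH_SCALED!r}")
    if not spec.total_ends:
        raise ValueError("total_ends is zero; cannot depth-normalize")
    if spec.total_mapped_bases is None:
        raise ValueError("total_mapped_bases missing from spec")
    factor = spec.total_mapped_bases / spec.total_ends
    out = track.copy(units=DEPTH_SCALED)
    for v in out.data.values():
        v *= factor
    return out


def genome_scale_normalize(track: SignalTrack, spec: NormalizationSpec) -> SignalTrack:
    """v' = v * genome_size / fragments_mapped (profile-analysis scaling)."""
    if spec.scheme != GENOME_SCALED:
        raise ValueError(f"spec scheme is {spec.scheme!r}, expected {GENOME_SCALED!r}")
    if not spec.fragments_mapped:
        raise ValueError("fragments_mapped is zero; cannot genome-scale")
    factor = spec.genome_size / spec.fragments_mapped
    out = track.copy(units=GENOME_SCALED)
    for v in out.data.values():
        v *= factor
    return out


def subtract_control(tf_track: SignalTrack, control_track: SignalTrack) -> SignalTrack:
    """Elementwise TF minus control; negative values are retained."""
    if tf_track.genome != control_track.genome:
        raise ValueError("tracks cover different genomes")
    if tf_track.units != control_track.units:
        raise ValueError(
            f"normalization mismatch: {tf_track.units!r} vs {control_track.units!r}"
        )
    out = tf_track.copy()
    for chrom in out.genome.names:
        out.data[chrom] = tf_track.data[chrom] - control_track.data[chrom]
    return out
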