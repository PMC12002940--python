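"""Chromatin-state enrichment over gene features.

Overlap enrichment: mean state posterior inside a region set divided by
the genome-wide mean posterior, with partial bins weighted by overlap
fraction (exact per-base semantics).  Neighborhood enrichment: the same
fold as a function of signed, strand-aware offset from anchor positions
(TSS/TES) in bin-size steps.  Both can be min-max scaled to [0,1], per
state by default.

All interval arithmetic here is 0-based half-open; gene models arrive
with 1-based inclusive coordinates and are converted at entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, StatePosteriorTrack, merge_intervals

__all__ = [
    "EnrichmentParams",
    "EnrichmentMatrix",
    "GeneFeatures",
    "gene_features",
    "overlap_enrichment",
    "neighborhood_enrichment",
    "unit_scale",
]

RegionSet = dict[str, np.ndarray]  # chrom -> (n, 2) array, 0-based half-open
Anchor = tuple[str, int, str]      # chrom, 0-based position, strand


@dataclass
class EnrichmentParams:
    bin_size: int = 200
    window: int = 2000
    anchor_flank: int = 2000
    scale_to_unit: bool = True

    def __post_init__(self) -> None:
        for name in ("window", "anchor_flank"):
            v = getattr(self, name)
            if v <= 0 or v % self.bin_size:
                raise ValueError(f"{name} must be a positive multiple of bin_size")


@dataclass
class EnrichmentMatrix:
    """States x columns fold enrichments (columns: annotation names or
    signed bp offsets).  ``anchor_counts`` records, per column of a
    neighborhood profile, how many anchors contributed."""

    states: list[str]
    columns: list
    values: np.ndarray
    scaled: bool = False
    anchor_counts: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.states, columns=self.columns)


@dataclass
class GeneFeatures:
    regions: dict[str, RegionSet]
    anchors: dict[str, list[Anchor]] = field(default_factory=dict)


def _merge_0based(intervals: list[tuple[int, int]]) -> np.ndarray:
    if not intervals:
        return np.empty((0, 2), dtype=np.int64)
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.array(out, dtype=np.int64)


def gene_features(
    models: list[GeneModel], params: EnrichmentParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> GeneFeatures:
    """Extract gene bodies, merged exons, TSS windows and TSS/TES anchors.

    TSS is the gene start for + strand genes and the gene end for -
    strand genes; TES is the opposite end.  The TSS window spans
    ``window`` bp on both sides of the TSS and is clipped to chromosome
    bounds.  Intervals are emitted 0-based half-open.
    """
    if params is None:
        params = EnrichmentParams()
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        "gene_body": {}, "exon": {}, "tss_window": {}}
    anchors: dict[str, list[Anchor]] = {"tss": [], "tes": []}
    for m in models:
        start0, end0 = m.gene_start - 1, m.gene_end  # to 0-based half-open
        raw["gene_body"].setdefault(m.chrom, []).append((start0, end0))
        all_exons = [iv for _, ivs in m.transcripts for iv in ivs]
        for s, e in merge_intervals(all_exons):
            raw["exon"].setdefault(m.chrom, []).append((s - 1, e))
        tss = start0 if m.strand == "+" else end0 - 1
        tes = end0 - 1 if m.strand == "+" else start0
        anchors["tss"].append((m.chrom, tss, m.strand))
        anchors["tes"].append((m.chrom, tes, m.strand))
        lo = max(0, tss - params.window)
        hi = tss + params.window + 1
        if chrom_lengths and m.chrom in chrom_lengths:
            hi = min(hi, chrom_lengths[m.chrom])
        raw["tss_window"].setdefault(m.chrom, []).append((lo, hi))
    regions = {
        name: {chrom: _merge_0based(ivs) for chrom, ivs in per_chrom.items()}
        for name, per_chrom in raw.items()
    }
    return GeneFeatures(regions=regions, anchors=anchors)


def _as_tracks(track) -> dict[str, StatePosteriorTrack]:
    if isinstance(track, StatePosteriorTrack):
        return {track.chrom: track}
    tracks = dict(track)
    states = None
    for t in tracks.values():
        if states is None:
            states = t.states
        elif t.states != states:
            raise ValueError("all tracks must share the same state labels")
    return tracks


def _genome_mean(tracks: dict[str, StatePosteriorTrack]) -> np.ndarray:
    """Base-pair-weighted genome-wide mean posterior per state."""
    num = 0.0
    den = 0.0
    for t in tracks.values():
        lens = t.bin_lengths()
        num = num + lens @ t.posteriors
        den += lens.sum()
    return num / den


def _region_weights(track: StatePosteriorTrack, regions: np.ndarray) -> np.ndarray:
    """Per-bin overlap (in bp) of a merged region array with the track."""
    w = np.zeros(track.n_bins)
    bs = track.bin_size
    clipped = False
    for s, e in regions:
        s = max(0, int(s))
        e = int(e)
        if e > track.chrom_length:
            clipped = True
            e = track.chrom_length
        if e <= s:
            continue
        b0, b1 = s // bs, (e - 1) // bs
        bins = np.arange(b0, b1 + 1)
        lo = np.maximum(s, bins * bs)
        hi = np.minimum(e, (bins + 1) * bs)
        w[bins] += hi - lo
    if clipped:
        warnings.warn(f"region beyond end of {track.chrom}; clipped")
    return w


def overlap_enrichment(track, regions: RegionSet | np.ndarray) -> EnrichmentMatrix:
    """Per-state fold enrichment of posterior mass inside a region set.

    fold(s) = mean posterior of s over the bases in the regions divided
    by the genome-wide mean posterior of s.  Accepts one track or a
    ``{chrom: track}`` mapping (the genome-wide mean then spans all
    tracks); ``regions`` is ``{chrom: (n,2) array}`` or a bare array for
    a single track.
    """
    tracks = _as_tracks(track)
    if isinstance(regions, np.ndarray):
        if len(tracks) != 1:
            raise ValueError("bare region array is ambiguous with multiple tracks")
        regions = {next(iter(tracks)): regions}
    states = next(iter(tracks.values())).states
    num = np.zeros(len(states))
    den = 0.0
    for chrom, ivs in regions.items():
        if chrom not in tracks:
            raise ValueError(f"regions on {chrom!r} but no track for it")
        t = tracks[chrom]
        w = _region_weights(t, np.asarray(ivs))
        num += w @ t.posteriors
        den += w.sum()
    if den == 0:
        raise ValueError("empty region set")
    gmean = _genome_mean(tracks)
    return EnrichmentMatrix(list(states), ["region"], ((num / den) / gmean)[:, None])


def overlap_enrichment_table(track, region_sets: dict[str, RegionSet]) -> EnrichmentMatrix:
    """Overlap enrichment for several named annotations side by side."""
    tracks = _as_tracks(track)
    states = next(iter(tracks.values())).states
    cols = list(region_sets)
    vals = np.empty((len(states), len(cols)))
    for j, name in enumerate(cols):
        vals[:, j] = overlap_enrichment(tracks, region_sets[name]).values[:, 0]
    return EnrichmentMatrix(list(states), cols, vals)


def neighborhood_enrichment(
    track, anchors: list[Anchor], params: EnrichmentParams | None = None
) -> EnrichmentMatrix:
    """States x signed-offset fold enrichment around anchor positions.

    For each offset o in bin-size steps over ±anchor_flank, the posterior
    of the bin containing ``anchor + o`` (``anchor - o`` on the minus
    strand, so offsets read 5'->3') is averaged over anchors and divided
    by the genome-wide mean.  Anchors whose offset bin falls off the
    chromosome are excluded at that offset; per-offset anchor counts are
    reported on the result.
    """
    if params is None:
        params = EnrichmentParams()
    if not anchors:
        raise ValueError("empty anchor set")
    tracks = _as_tracks(track)
    states = next(iter(tracks.values())).states
    offsets = np.arange(-params.anchor_flank, params.anchor_flank + 1, params.bin_size)
    sums = np.zeros((len(states), offsets.size))
    counts = np.zeros(offsets.size, dtype=np.int64)
    for chrom, pos, strand in anchors:
        if chrom not in tracks:
            raise ValueError(f"anchor on {chrom!r} but no track for it")
        t = tracks[chrom]
        signed = offsets if strand == "+" else -offsets
        p = pos + signed
        b = p // t.bin_size
        ok = (p >= 0) & (p < t.chrom_length)
        sums[:, ok] += t.posteriors[b[ok]].T
        counts += ok
    if np.any(counts == 0):
        warnings.warn("some offsets have no on-chromosome anchors")
    gmean = _genome_mean(tracks)
    with np.errstate(invalid="ignore"):
        folds = (sums / counts[None, :]) / gmean[:, None]
    return EnrichmentMatrix(list(states), [int(o) for o in offsets], folds,
                            anchor_counts=counts)


def unit_scale(matrix: EnrichmentMatrix, group: str = "per_state") -> EnrichmentMatrix:
    """Min-max scale folds to [0,1]; per state (row-wise) or globally.

    Idempotent on already-scaled input; a constant scaling group maps to
    all zeros with a warning.
    """
    if group not in ("per_state", "global"):
        raise ValueError("group must be 'per_state' or 'global'")
    v = matrix.values
    if group == "per_state":
        lo = v.min(axis=1, keepdims=True)
        hi = v.max(axis=1, keepdims=True)
    else:
        lo = v.min()
        hi = v.max()
    span = hi - lo
    if np.any(span == 0):
        warnings.warn("constant scaling group; mapped to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span == 0, 0.0, (v - lo) / np.where(span == 0, 1.0, span))
    return EnrichmentMatrix(matrix.states, matrix.columns, scaled, scaled=True,
                            anchor_counts=matrix.anchor_counts)
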