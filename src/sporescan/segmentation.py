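"""Cohort-wide segmentation of each parental genome.

Breakpoints observed in any spore are pooled per chromosome and every
spore's chromosome is cut at the pooled locations, whether or not that
spore recombined there. A chromosome with k pooled breakpoints therefore
yields exactly k+1 segments. Each segment of each spore is scored 1
(inherited from this genome's species), 0 (from the other species) or 2
(aneuploid chromosome); ties in the within-segment probe vote are recorded
as missing (-1) and excluded pairwise downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import GenotypeTrack
from .panel import ProbePanel

MISSING = -1
ANEUPLOID = 2


def collect_breakpoints(
    tracks: list[GenotypeTrack],
    species: str,
    merge_tol_bp: float = 2_000.0,
) -> dict[int, np.ndarray]:
    """Pool breakpoint bp positions across spores, per chromosome.

    Breakpoints from different spores closer than ``merge_tol_bp`` are
    merged to the midpoint of their cluster; the result is sorted and
    deduplicated.
    """
    chroms = sorted({c for t in tracks for (sp, c) in t.chromosomes
                     if sp == species})
    pooled: dict[int, np.ndarray] = {}
    for chrom in chroms:
        pts: list[float] = []
        for t in tracks:
            if (species, chrom) in t.chromosomes:
                pts.extend(t.call(species, chrom).breakpoints_bp)
        if not pts:
            pooled[chrom] = np.array([], dtype=float)
            continue
        pts_arr = np.sort(np.asarray(pts, dtype=float))
        merged: list[float] = []
        cluster = [pts_arr[0]]
        for p in pts_arr[1:]:
            if p - cluster[-1] < merge_tol_bp:
                cluster.append(p)
            else:
                merged.append((cluster[0] + cluster[-1]) / 2.0)
                cluster = [p]
        merged.append((cluster[0] + cluster[-1]) / 2.0)
        pooled[chrom] = np.unique(np.asarray(merged))
    return pooled


def cut_chromosome(length: float, breakpoints: np.ndarray
                   ) -> list[tuple[float, float]]:
    """Half-open segment intervals from pooled breakpoints: k cuts -> k+1."""
    bps = np.sort(np.asarray(breakpoints, dtype=float))
    if np.any((bps <= 0) | (bps >= length)):
        raise ValueError("breakpoints must lie strictly inside the chromosome")
    edges = np.concatenate(([0.0], bps, [float(length)]))
    return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class SegmentMatrix:
    """Spores x segments scores in {0, 1, 2} for one parental genome.

    ``segments`` has columns ``chrom``, ``start``, ``end`` (bp, half-open);
    ``scores`` is int8 with -1 marking missing (tied-vote) entries.
    """

    genome: str
    segments: pd.DataFrame
    scores: np.ndarray
    spore_ids: list[str]

    def __post_init__(self) -> None:
        if self.scores.shape != (len(self.spore_ids), len(self.segments)):
            raise ValueError("scores shape does not match spores x segments")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_spores(self) -> int:
        return len(self.spore_ids)

    @property
    def chrom(self) -> np.ndarray:
        return self.segments["chrom"].to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.segments["start"] + self.segments["end"]) / 2.0).to_numpy()

    def segment_ids(self) -> list[str]:
        return [f"{self.genome}:{int(c)}:{s:.10g}-{e:.10g}"
                for c, s, e in self.segments.itertuples(index=False)]


def build_segment_matrix(
    tracks: list[GenotypeTrack],
    pooled_breakpoints: dict[int, np.ndarray],
    panel: ProbePanel,
    genome: str,
) -> SegmentMatrix:
    """Score every spore over the pooled segmentation of one genome.

    Scores: 2 if the spore is aneuploid for the chromosome; otherwise the
    majority of this genome's binarized probe calls inside the segment
    (1 = present from this species, 0 = from the other); an exact tie is
    missing (-1). Segments containing zero probes of this species are
    rejected at build time.
    """
    seg_rows: list[tuple[int, float, float]] = []
    seg_slices: list[tuple[int, int, int]] = []   # (chrom, lo, hi) probe idx
    for chrom in panel.chromosomes:
        positions = panel.positions(genome, chrom)
        length = panel.chromosome_lengths[chrom]
        bps = pooled_breakpoints.get(chrom, np.array([]))
        for start, end in cut_chromosome(length, bps):
            lo, hi = np.searchsorted(positions, [start, end])
            if hi <= lo:
                raise ValueError(
                    f"segment {genome} chr{chrom}:{start:.0f}-{end:.0f} "
                    f"contains no probes")
            seg_rows.append((chrom, start, end))
            seg_slices.append((chrom, int(lo), int(hi)))

    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end"])
    scores = np.empty((len(tracks), len(segments)), dtype=np.int8)
    for i, t in enumerate(tracks):
        for j, (chrom, lo, hi) in enumerate(seg_slices):
            if t.aneuploid.get(chrom, False):
                scores[i, j] = ANEUPLOID
                continue
            calls = t.call(genome, chrom).calls[lo:hi]
            frac1 = float(np.mean(calls == 1))
            if frac1 > 0.5:
                scores[i, j] = 1
            elif frac1 < 0.5:
                scores[i, j] = 0
            else:
                scores[i, j] = MISSING
    return SegmentMatrix(genome=genome, segments=segments, scores=scores,
                         spore_ids=[t.spore_id for t in tracks])


def segment_cohort(tracks: list[GenotypeTrack], panel: ProbePanel,
                   merge_tol_bp: float = 2_000.0
                   ) -> dict[str, SegmentMatrix]:
    """Segment both parental genomes independently (pool, cut, score)."""
    out = {}
    for genome in ("cer", "par"):
        pooled = collect_breakpoints(tracks, genome, merge_tol_bp)
        out[genome] = build_segment_matrix(tracks, pooled, panel, genome)
    return out
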