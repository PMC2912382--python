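"""Genotype calling from per-spore log10-ratio vectors.

Probe ratios are binarized at a fixed threshold (default -0.05): below the
threshold a probed locus is absent from the spore, at or above it is
present. A species' chromosome is called wholly absent when >=80% of its
probes are absent. Chromosomes that are not absent are partitioned into
majority-value regions of at least ``min_region_probes`` probes with
>``region_purity`` agreement; region borders are the inferred meiotic
recombination breakpoints. A chromosome carried from both species at once
(neither copy absent, both predominantly present) is flagged aneuploid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import SPECIES, ProbePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeParams:
    binarize_threshold: float = -0.05
    min_region_probes: int = 10
    region_purity: float = 0.70      # strict >
    absence_fraction: float = 0.80   # >=

    def __post_init__(self) -> None:
        if not 0.5 < self.region_purity < 1.0:
            raise ValueError("region_purity must be in (0.5, 1)")
        if not 0.5 < self.absence_fraction <= 1.0:
            raise ValueError("absence_fraction must be in (0.5, 1]")
        if self.min_region_probes < 2:
            raise ValueError("min_region_probes must be >= 2")


@dataclass
class ChromosomeCall:
    """Per-(species, chromosome) probe calls, regions and breakpoints.

    Regions are half-open probe-index intervals ``[start, end)`` with a
    majority value; breakpoints are the inter-probe boundary indices
    between consecutive regions (boundary ``b`` separates probes ``b-1``
    and ``b``), plus the bp midpoint between the flanking probes.
    """

    species: str
    chrom: int
    calls: np.ndarray                       # int8, 1 present / 0 absent
    absent: bool
    regions: list[tuple[int, int, int]]     # (start, end, value)
    breakpoints_idx: list[int] = field(default_factory=list)
    breakpoints_bp: list[float] = field(default_factory=list)

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints_idx)

    @property
    def present_fraction(self) -> float:
        return float(np.mean(self.calls == 1)) if len(self.calls) else 0.0


@dataclass
class GenotypeTrack:
    """Binary presence calls for one spore over both species' genomes."""

    spore_id: str
    chromosomes: dict[tuple[str, int], ChromosomeCall]
    aneuploid: dict[int, bool]

    def call(self, species: str, chrom: int) -> ChromosomeCall:
        return self.chromosomes[(species, chrom)]

    @property
    def n_crossovers(self) -> int:
        """Breakpoints on the cer tracks of non-aneuploid chromosomes."""
        return sum(c.n_breakpoints
                   for (sp, ch), c in self.chromosomes.items()
                   if sp == "cer" and not self.aneuploid.get(ch, False))

    @property
    def aneuploid_chromosomes(self) -> list[int]:
        return sorted(c for c, flag in self.aneuploid.items() if flag)


def binarize_probes(logratios: np.ndarray, threshold: float = -0.05,
                    probe_ids=None) -> np.ndarray:
    """0 where ratio < threshold, 1 where ratio >= threshold.

    A ratio exactly at the threshold is called present (1). Non-finite
    ratios are rejected, naming the offending probe when ids are given.
    """
    arr = np.asarray(logratios, dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        name = probe_ids[i] if probe_ids is not None else f"index {i}"
        raise ValueError(f"non-finite log ratio at probe {name}")
    return (arr >= threshold).astype(np.int8)


def call_chromosome_absence(calls: np.ndarray,
                            absence_fraction: float = 0.80) -> bool:
    """Absent iff the fraction of 0-calls is >= ``absence_fraction``."""
    calls = np.asarray(calls)
    if calls.size == 0:
        raise ValueError("cannot call absence on an empty chromosome")
    return bool(np.mean(calls == 0) >= absence_fraction)


def _window_commits(calls: np.ndarray, w: int, purity: float) -> np.ndarray:
    """Commit value of every length-``w`` sliding window (stride 1).

    Entry i covers probes [i, i+w): 1 or 0 when that value exceeds the
    purity fraction within the window, -1 otherwise.
    """
    ones = np.concatenate(([0], np.cumsum(calls == 1)))
    wsum = ones[w:] - ones[:-w]
    commit = np.full(len(calls) - w + 1, -1, dtype=np.int8)
    commit[wsum > purity * w] = 1
    commit[(w - wsum) > purity * w] = 0
    return commit


def _refine_boundary(calls: np.ndarray, win_lo: int, win_hi: int,
                     v_left: int, v_right: int, lo: int, hi: int) -> int:
    """Place a region border inside the ambiguous zone [win_lo, win_hi).

    Chooses the cut minimizing the number of probes disagreeing with their
    side's majority value inside the zone (on a clean signal this is the
    exact step location); ties resolve to the middle tying cut, rounded
    left. Clamped to [lo, hi]."""
    win = calls[win_lo:win_hi]
    mis_left = np.concatenate(([0], np.cumsum(win != v_left)))
    mis_right_rev = np.concatenate(([0], np.cumsum((win != v_right)[::-1])))
    cost = mis_left + mis_right_rev[::-1]     # cost of cutting before offset
    ties = np.flatnonzero(cost == cost.min())
    b = win_lo + int(ties[(len(ties) - 1) // 2])
    return int(np.clip(b, lo, hi))


def detect_recombination_regions(
    calls: np.ndarray, params: GenotypeParams | None = None,
) -> tuple[list[tuple[int, int, int]], list[int]]:
    """Partition one chromosome's probe calls into majority-value regions.

    Returns ``(regions, breakpoints)`` where regions are half-open
    ``(start, end, value)`` probe-index intervals partitioning ``[0, n)``
    and breakpoints are the boundary indices between consecutive regions.

    A length-``min_region_probes`` window slides over the chromosome; a
    window is committed to 0 or 1 when that value exceeds the purity
    fraction of its probes. Consecutive committed windows of one value —
    including same-value windows separated only by uncommitted ones —
    merge into runs, so any pure stretch of at least ``min_region_probes``
    probes is found regardless of its offset. Each border between
    opposite-value runs is then placed inside the uncommitted zone between
    them at the cut minimizing probe-majority disagreement.
    """
    if params is None:
        params = GenotypeParams()
    calls = np.asarray(calls)
    n = len(calls)
    w = params.min_region_probes
    if n == 0:
        raise ValueError("empty chromosome")
    if n < w:
        logger.warning("chromosome with %d probes (< %d): single region", n, w)
        value = 1 if np.mean(calls == 1) >= 0.5 else 0
        return [(0, n, value)], []

    commit = _window_commits(calls, w, params.region_purity)
    committed = np.flatnonzero(commit != -1)
    if len(committed) == 0:
        value = 1 if np.mean(calls == 1) >= 0.5 else 0
        return [(0, n, value)], []

    # runs of committed windows: [value, first window, last window]
    runs: list[list[int]] = []
    for i in committed:
        v = int(commit[i])
        if runs and runs[-1][0] == v:
            runs[-1][2] = int(i)
        else:
            runs.append([v, int(i), int(i)])
    if len(runs) == 1:
        return [(0, n, runs[0][0])], []

    boundaries: list[int] = []
    prev = 0
    for left, right in zip(runs, runs[1:]):
        # the border lies between the last committed left window and the
        # end of the first committed right window
        win_lo = left[2]
        win_hi = min(right[1] + w, n)
        b = _refine_boundary(calls, win_lo, win_hi, left[0], right[0],
                             lo=prev + 1, hi=n - 1)
        boundaries.append(b)
        prev = b

    regions = []
    starts = [0] + boundaries
    ends = boundaries + [n]
    for (s, e), run in zip(zip(starts, ends), runs):
        regions.append((s, e, run[0]))
    return regions, boundaries


def _breakpoint_bp(positions: np.ndarray, boundary_idx: int) -> float:
    """Breakpoint bp coordinate: midpoint between the flanking probes."""
    return float((positions[boundary_idx - 1] + positions[boundary_idx]) / 2.0)


def call_genotype(logratios: np.ndarray, panel: ProbePanel,
                  params: GenotypeParams | None = None,
                  spore_id: str = "spore") -> GenotypeTrack:
    """Full genotype call for one spore: binarize, absence, regions, aneuploidy.

    ``logratios`` must be aligned to ``panel.probes`` rows.
    """
    if params is None:
        params = GenotypeParams()
    logratios = np.asarray(logratios, dtype=float)
    if logratios.shape != (panel.n_probes,):
        raise ValueError(
            f"log-ratio vector length {logratios.shape} does not match "
            f"panel with {panel.n_probes} probes")

    chromosomes: dict[tuple[str, int], ChromosomeCall] = {}
    for species in SPECIES:
        for chrom in panel.chromosomes:
            idx = panel.row_index(species, chrom)
            if len(idx) == 0:
                continue
            ids = panel.probes["probe_id"].to_numpy()[idx]
            calls = binarize_probes(logratios[idx],
                                    params.binarize_threshold, probe_ids=ids)
            absent = call_chromosome_absence(calls, params.absence_fraction)
            if absent:
                regions, bps = [(0, len(calls), 0)], []
            else:
                regions, bps = detect_recombination_regions(calls, params)
            positions = panel.positions(species, chrom)
            chromosomes[(species, chrom)] = ChromosomeCall(
                species=species, chrom=chrom, calls=calls, absent=absent,
                regions=regions, breakpoints_idx=list(bps),
                breakpoints_bp=[_breakpoint_bp(positions, b) for b in bps])

    aneuploid: dict[int, bool] = {}
    for chrom in panel.chromosomes:
        cer = chromosomes.get(("cer", chrom))
        par = chromosomes.get(("par", chrom))
        if cer is None or par is None:
            aneuploid[chrom] = False
            continue
        both_present = (cer.present_fraction >= params.absence_fraction and
                        par.present_fraction >= params.absence_fraction)
        aneuploid[chrom] = (not cer.absent and not par.absent and both_present)
        if (not aneuploid[chrom]
                and cer.present_fraction + par.present_fraction > 1.2):
            logger.warning(
                "%s chr%d: partial double presence (cer %.2f + par %.2f) — "
                "not called aneuploid", spore_id, chrom,
                cer.present_fraction, par.present_fraction)
    return GenotypeTrack(spore_id=spore_id, chromosomes=chromosomes,
                         aneuploid=aneuploid)


def call_cohort(logratios: np.ndarray, panel: ProbePanel,
                params: GenotypeParams | None = None,
                spore_ids: list[str] | None = None) -> list[GenotypeTrack]:
    """Genotype every column of a (probes x spores) log-ratio matrix."""
    n_spores = logratios.shape[1]
    if spore_ids is None:
        spore_ids = [f"spore_{i:04d}" for i in range(n_spores)]
    return [call_genotype(logratios[:, j], panel, params, spore_ids[j])
            for j in range(n_spores)]


def summarize_cohort(tracks: list[GenotypeTrack],
                     chromosomes: list[int] | None = None) -> pd.DataFrame:
    """Per-(species, chromosome) event tallies across a cohort.

    Returns a DataFrame with recombination (breakpoint) counts per species
    track and aneuploidy counts (identical for the two species rows of a
    chromosome, since an aneuploid chromosome is seen on both arrays).
    """
    if chromosomes is None:
        chromosomes = sorted({c for t in tracks for (_, c) in t.chromosomes})
    rows = []
    for species in SPECIES:
        for chrom in chromosomes:
            recomb = sum(t.call(species, chrom).n_breakpoints
                         for t in tracks if (species, chrom) in t.chromosomes)
            aneu = sum(1 for t in tracks if t.aneuploid.get(chrom, False))
            rows.append({"species": species, "chrom": chrom,
                         "recombination": recomb, "aneuploidy": aneu})
    return pd.DataFrame(rows)
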