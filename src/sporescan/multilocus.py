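"""Three-locus joint-inheritance scan.

For every triple of segments (by default on three distinct chromosomes)
the informative spores fall into 8 categories — the 2^3 parental-origin
patterns of the three loci. A triple with at least one empty category is a
candidate higher-order incompatibility. Because empty cells arise by
chance at these sample sizes, only the cohort-level count of flagged
triples is compared against a permutation baseline (segment-wise shuffles,
as in the pairwise scan); no per-triple significance is attached.

The inner loop runs on Python big-integer bitmasks (one presence bit per
spore), so full enumeration handles millions of triples in seconds; above
``max_triples`` a seeded uniform sample of triples is scored instead and
the count is reported as a rate with a Clopper-Pearson interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import binomtest

from .segmentation import SegmentMatrix


@dataclass
class TripleScanResult:
    flagged: int               # triples with >= 1 empty category
    examined: int              # triples actually scored
    total: int                 # triples in the full enumeration space
    sampled: bool              # True when examined < total
    rate: float                # flagged / examined
    rate_ci: tuple[float, float]   # 95% Clopper-Pearson on the rate

    @property
    def estimated_flagged(self) -> float:
        """Flagged count scaled to the full triple space."""
        return self.rate * self.total


@dataclass
class TripleBaseline:
    mean: float
    sd: float
    counts: np.ndarray         # estimated flagged count per permutation

    def z_score(self, observed: float) -> float:
        return (observed - self.mean) / self.sd if self.sd > 0 else float("inf")


def _segment_bitmasks(scores: np.ndarray) -> tuple[list[int], list[int]]:
    """Per-segment (present, informative) spore bitmasks as Python ints."""
    n_spores, n_seg = scores.shape
    present_masks: list[int] = []
    informative_masks: list[int] = []
    for j in range(n_seg):
        col = scores[:, j]
        p = np.packbits((col == 1).astype(np.uint8), bitorder="little")
        i = np.packbits(((col == 0) | (col == 1)).astype(np.uint8),
                        bitorder="little")
        present_masks.append(int.from_bytes(p.tobytes(), "little"))
        informative_masks.append(int.from_bytes(i.tobytes(), "little"))
    return present_masks, informative_masks


def count_triple_categories(present: tuple[int, int, int],
                            informative: tuple[int, int, int]) -> list[int]:
    """The 8 joint-origin category counts for one triple (bitmask form)."""
    pa, pb, pc = present
    inf = informative[0] & informative[1] & informative[2]
    qa, qb, qc = (inf & ~pa, inf & ~pb, inf & ~pc)
    pa, pb, pc = pa & inf, pb & inf, pc & inf
    return [
        (pa & pb & pc).bit_count(),
        (pa & pb & qc).bit_count(),
        (pa & qb & pc).bit_count(),
        (pa & qb & qc).bit_count(),
        (qa & pb & pc).bit_count(),
        (qa & pb & qc).bit_count(),
        (qa & qb & pc).bit_count(),
        (qa & qb & qc).bit_count(),
    ]


def _has_empty_category(pa: int, pb: int, pc: int,
                        ia: int, ib: int, ic: int) -> bool:
    inf = ia & ib & ic
    a, b, c = pa & inf, pb & inf, pc & inf
    na, nb, nc = inf & ~a, inf & ~b, inf & ~c
    return (
        (a & b & c).bit_count() == 0 or (a & b & nc).bit_count() == 0
        or (a & nb & c).bit_count() == 0 or (a & nb & nc).bit_count() == 0
        or (na & b & c).bit_count() == 0 or (na & b & nc).bit_count() == 0
        or (na & nb & c).bit_count() == 0 or (na & nb & nc).bit_count() == 0
    )


def _triple_space(chrom: np.ndarray, distinct_chromosomes: bool) -> int:
    n = len(chrom)
    total = comb(n, 3)
    if not distinct_chromosomes:
        return total
    # inclusion-exclusion over same-chromosome collisions
    sizes = np.unique(chrom, return_counts=True)[1]
    same2 = sum(comb(int(s), 2) * (n - int(s)) for s in sizes)
    same3 = sum(comb(int(s), 3) for s in sizes)
    return total - same2 - same3


def _iter_triples(chrom: np.ndarray, distinct_chromosomes: bool):
    n = len(chrom)
    for i, j, k in combinations(range(n), 3):
        if distinct_chromosomes and (
                chrom[i] == chrom[j] or chrom[j] == chrom[k]
                or chrom[i] == chrom[k]):
            continue
        yield i, j, k


def _sample_triples(chrom: np.ndarray, distinct_chromosomes: bool,
                    n_sample: int, rng: np.random.Generator):
    n = len(chrom)
    drawn = 0
    while drawn < n_sample:
        i, j, k = sorted(rng.choice(n, size=3, replace=False))
        if distinct_chromosomes and (
                chrom[i] == chrom[j] or chrom[j] == chrom[k]
                or chrom[i] == chrom[k]):
            continue
        drawn += 1
        yield int(i), int(j), int(k)


def count_zero_category_triples(
    matrix: SegmentMatrix,
    distinct_chromosomes: bool = True,
    max_triples: int = 10_000_000,
    seed: int | None = None,
) -> TripleScanResult:
    """Count segment triples with at least one empty joint-origin category.

    Spores aneuploid or missing at any of the three segments are excluded
    per triple. With more than ``max_triples`` candidate triples, a seeded
    uniform sample of that size is scored instead.
    """
    if matrix.n_segments < 3:
        raise ValueError("need at least 3 segments")
    chrom = matrix.chrom
    present, informative = _segment_bitmasks(matrix.scores)
    total = _triple_space(chrom, distinct_chromosomes)
    sampled = total > max_triples
    if sampled:
        rng = np.random.default_rng(seed)
        triples = _sample_triples(chrom, distinct_chromosomes,
                                  max_triples, rng)
        examined = max_triples
    else:
        triples = _iter_triples(chrom, distinct_chromosomes)
        examined = total

    flagged = 0
    for i, j, k in triples:
        if _has_empty_category(present[i], present[j], present[k],
                               informative[i], informative[j], informative[k]):
            flagged += 1
    if examined == 0:
        raise ValueError("no eligible triples (too few distinct chromosomes)")
    ci = binomtest(flagged, examined).proportion_ci(0.95, method="exact")
    return TripleScanResult(flagged=flagged, examined=examined, total=total,
                            sampled=sampled, rate=flagged / examined,
                            rate_ci=(float(ci.low), float(ci.high)))


def permutation_baseline_triples(
    matrix: SegmentMatrix,
    n_perm: int = 20,
    seed: int | None = None,
    distinct_chromosomes: bool = True,
    max_triples: int = 10_000_000,
) -> TripleBaseline:
    """Mean/SD of the flagged-triple count under segment-wise shuffling.

    Each permutation independently shuffles every segment's score vector
    across spores (the same null as the pairwise permutation FDR) and the
    zero-category count is recomputed with the same enumeration/sampling
    controls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ss = np.random.SeedSequence(seed)
    counts = np.empty(n_perm)
    for p, child in enumerate(ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        shuffled = SegmentMatrix(
            genome=matrix.genome, segments=matrix.segments,
            scores=rng.permuted(matrix.scores, axis=0),
            spore_ids=matrix.spore_ids)
        res = count_zero_category_triples(
            shuffled, distinct_chromosomes=distinct_chromosomes,
            max_triples=max_triples,
            seed=int(rng.integers(2**31)))
        counts[p] = res.estimated_flagged
    return TripleBaseline(mean=float(np.mean(counts)),
                          sd=float(np.std(counts, ddof=1)) if n_perm > 1 else 0.0,
                          counts=counts)
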