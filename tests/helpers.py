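"""Shared test utilities: independent oracles and matrix builders."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from sporescan import PairCategoryCounts, SegmentMatrix


def brute_force_expected(counts: PairCategoryCounts) -> np.ndarray:
    """Independent re-derivation of the normalized expectations."""
    N = counts.n_informative
    nA = counts.n11 + counts.n10
    nB = counts.n11 + counts.n01
    return np.array([
        (nA / N) * (nB / N) * N,
        (nA / N) * ((N - nB) / N) * N,
        ((N - nA) / N) * (nB / N) * N,
        ((N - nA) / N) * ((N - nB) / N) * N,
    ])


def brute_force_chi_square(counts: PairCategoryCounts) -> float:
    """Cell-by-cell (O-E)^2/E with explicit zero-expectation handling."""
    expected = brute_force_expected(counts)
    observed = [counts.n11, counts.n10, counts.n01, counts.n00]
    total = 0.0
    for o, e in zip(observed, expected):
        if e == 0:
            if o > 0:
                return float("inf")
            continue
        total += (o - e) ** 2 / e
    return total


def exact_binomial_lower_tail(k: int, n: int, num: int = 1, den: int = 2
                              ) -> Fraction:
    """Big-integer P(X <= k) for X ~ Binomial(n, num/den)."""
    p = Fraction(num, den)
    return sum((Fraction(comb(n, i)) * p**i * (1 - p)**(n - i)
                for i in range(k + 1)), Fraction(0))


def iid_matrix(n_spores: int, n_segments: int, seed: int,
               n_chrom: int | None = None) -> SegmentMatrix:
    """Segment matrix of independent fair-coin scores (one segment per
    chromosome unless n_chrom is given)."""
    rng = np.random.default_rng(seed)
    scores = rng.integers(0, 2, size=(n_spores, n_segments)).astype(np.int8)
    if n_chrom is None:
        n_chrom = n_segments
    chroms = np.arange(n_segments) % n_chrom + 1
    order = np.argsort(chroms, kind="stable")
    segments = pd.DataFrame({
        "chrom": chroms[order],
        "start": [10_000.0 * (i // n_chrom) for i in range(n_segments)],
        "end": [10_000.0 * (i // n_chrom) + 10_000.0
                for i in range(n_segments)],
    })
    return SegmentMatrix(genome="cer", segments=segments,
                         scores=scores[:, order],
                         spore_ids=[f"s{i}" for i in range(n_spores)])


def truth_matrix(gametes, lengths: dict[int, int], segments_per_chrom: int,
                 genome: str = "cer") -> SegmentMatrix:
    """Score a fixed segmentation grid directly from gamete truth."""
    rows = []
    for chrom in sorted(lengths):
        edges = np.linspace(0, lengths[chrom], segments_per_chrom + 1)
        for a, b in zip(edges[:-1], edges[1:]):
            rows.append((chrom, float(a), float(b)))
    segments = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    mids = ((segments["start"] + segments["end"]) / 2).to_numpy()
    chroms = segments["chrom"].to_numpy()
    scores = np.empty((len(gametes), len(segments)), dtype=np.int8)
    for i, g in enumerate(gametes):
        for j, (chrom, mid) in enumerate(zip(chroms, mids)):
            gc = g[chrom]
            if gc.aneuploid:
                scores[i, j] = 2
            else:
                scores[i, j] = int(gc.origin_is(np.array([mid]), genome)[0])
    return SegmentMatrix(genome=genome, segments=segments, scores=scores,
                         spore_ids=[f"s{i}" for i in range(len(gametes))])
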