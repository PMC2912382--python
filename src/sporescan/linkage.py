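"""Pairwise linkage scan for genic incompatibilities.

For every (by default interchromosomal) pair of segments, the viable
spores are tallied into four joint-inheritance categories — both segments
from this genome's species (11), mixed (10 and 01), or both from the other
species (00) — after excluding spores aneuploid or missing at either
segment. Expected counts are normalized by each segment's inheritance
frequency: with nA and nB of N informative spores carrying segments A and
B, E11 = (nA/N)(nB/N)N and so on. The chi-square statistic over the four
cells is referred to a 3-df distribution (1-df p is also reported) and to
a permutation null in which every segment's score vector is independently
shuffled across spores; FDR(x) is the mean number of permuted pairs with
statistic >= x divided by the observed number.

A Dobzhansky-Muller dependency leaves empty mixed cells: both 10 and 01
empty is a two-way dependency, exactly one empty is one-way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .segmentation import SegmentMatrix

DF_PRIMARY = 3


@dataclass(frozen=True)
class PairCategoryCounts:
    """Four-category tally for one segment pair (aneuploid/missing excluded)."""

    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def n_informative(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def nA(self) -> int:
        return self.n11 + self.n10

    @property
    def nB(self) -> int:
        return self.n11 + self.n01

    def as_array(self) -> np.ndarray:
        return np.array([self.n11, self.n10, self.n01, self.n00], dtype=float)


def categorize_pair(scores_a: np.ndarray, scores_b: np.ndarray
                    ) -> PairCategoryCounts:
    """Tally spores into the four joint-inheritance cells.

    Spores scoring 2 (aneuploid) or -1 (missing) at either segment are
    excluded from all cells.
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.shape != b.shape:
        raise ValueError("score vectors must cover the same spores")
    mask = np.isin(a, (0, 1)) & np.isin(b, (0, 1))
    a = a[mask]
    b = b[mask]
    return PairCategoryCounts(
        n11=int(np.sum((a == 1) & (b == 1))),
        n10=int(np.sum((a == 1) & (b == 0))),
        n01=int(np.sum((a == 0) & (b == 1))),
        n00=int(np.sum((a == 0) & (b == 0))),
    )


def expected_counts(counts: PairCategoryCounts,
                    n_total: int | None = None) -> np.ndarray:
    """Inheritance-frequency-normalized expectations (E11, E10, E01, E00).

    ``n_total`` overrides the informative-spore count N (to reproduce an
    analysis that normalizes by the whole cohort size instead).
    """
    N = counts.n_informative if n_total is None else n_total
    if N <= 0:
        raise ValueError("no informative spores for this pair")
    pA = counts.nA / N
    pB = counts.nB / N
    return np.array([pA * pB * N,
                     pA * (1 - pB) * N,
                     (1 - pA) * pB * N,
                     (1 - pA) * (1 - pB) * N])


@dataclass
class LinkageResult:
    counts: PairCategoryCounts
    expected: np.ndarray
    chi_square: float
    p_value: float          # 3 df (primary)
    p_value_df1: float
    dependency_class: str = "none"
    fdr: float = float("nan")


def chi_square_pair(counts: PairCategoryCounts,
                    n_total: int | None = None) -> LinkageResult:
    """Chi-square of observed vs normalized expected counts (3 df).

    Cells with expectation 0 contribute 0 when the observation is also 0;
    an observation in a zero-expectation cell gives an infinite statistic.
    """
    expected = expected_counts(counts, n_total)
    observed = counts.as_array()
    x = 0.0
    for o, e in zip(observed, expected):
        if e > 0:
            x += (o - e) ** 2 / e
        elif o > 0:
            x = float("inf")
            break
    p3 = float(stats.chi2.sf(x, DF_PRIMARY)) if np.isfinite(x) else 0.0
    p1 = float(stats.chi2.sf(x, 1)) if np.isfinite(x) else 0.0
    return LinkageResult(counts=counts, expected=expected, chi_square=float(x),
                         p_value=p3, p_value_df1=p1,
                         dependency_class=classify_dependency(counts))


def classify_dependency(counts: PairCategoryCounts) -> str:
    """'two_way' if both mixed cells are empty, 'one_way' if exactly one is."""
    if counts.n_informative <= 0:
        raise ValueError("no informative spores")
    empty10 = counts.n10 == 0
    empty01 = counts.n01 == 0
    if empty10 and empty01:
        return "two_way"
    if empty10 or empty01:
        return "one_way"
    return "none"


# ---------------------------------------------------------------------------
# vectorized scan machinery

def _pair_tables(scores: np.ndarray) -> dict[str, np.ndarray]:
    """All-pairs four-cell counts via boolean matrix products.

    ``scores`` is (n_spores, n_segments) int8 in {0, 1, 2, -1}. Returns
    square matrices n11, n10, n01, n00, N over segment pairs.
    """
    informative = ((scores == 0) | (scores == 1)).astype(np.float64)
    present = (scores == 1).astype(np.float64)
    N = informative.T @ informative
    n11 = present.T @ present
    nA = present.T @ informative      # a present, b informative
    nB = informative.T @ present
    n10 = nA - n11
    n01 = nB - n11
    n00 = N - nA - nB + n11
    return {"n11": n11, "n10": n10, "n01": n01, "n00": n00, "N": N,
            "nA": nA, "nB": nB}


def _chi_square_matrix(t: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorized chi-square over the four cells for all pairs."""
    N = t["N"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = t["nA"] / N
        pB = t["nB"] / N
        chi = np.zeros_like(N)
        for key, e in (("n11", pA * pB * N),
                       ("n10", pA * (1 - pB) * N),
                       ("n01", (1 - pA) * pB * N),
                       ("n00", (1 - pA) * (1 - pB) * N)):
            o = t[key]
            term = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
            chi = chi + term
    chi[N == 0] = np.nan
    return chi


def _pair_selection(matrix: SegmentMatrix, interchromosomal_only: bool
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices (i < j), optionally cross-chromosome only.

    Segments are stored in (chrom, start) order, so the returned pairs are
    in deterministic lexicographic order.
    """
    n = matrix.n_segments
    i, j = np.triu_indices(n, k=1)
    if interchromosomal_only:
        chrom = matrix.chrom
        keep = chrom[i] != chrom[j]
        i, j = i[keep], j[keep]
    return i, j


def scan_pairs(matrix: SegmentMatrix,
               interchromosomal_only: bool = True) -> pd.DataFrame:
    """Chi-square linkage scan over all (unordered) segment pairs.

    Returns one row per pair with the four observed counts, the normalized
    expectations, the statistic, 3-df and 1-df p-values and the dependency
    class. Pairs with no informative spores are dropped.
    """
    t = _pair_tables(matrix.scores)
    chi = _chi_square_matrix(t)
    i, j = _pair_selection(matrix, interchromosomal_only)
    ids = matrix.segment_ids()
    chrom = matrix.chrom

    N = t["N"][i, j]
    keep = N > 0
    i, j = i[keep], j[keep]
    n11 = t["n11"][i, j].astype(int)
    n10 = t["n10"][i, j].astype(int)
    n01 = t["n01"][i, j].astype(int)
    n00 = t["n00"][i, j].astype(int)
    nA, nB, Nij = t["nA"][i, j], t["nB"][i, j], t["N"][i, j]
    pA, pB = nA / Nij, nB / Nij
    x = chi[i, j]
    dep = np.where((n10 == 0) & (n01 == 0), "two_way",
                   np.where((n10 == 0) | (n01 == 0), "one_way", "none"))
    return pd.DataFrame({
        "seg_a": [ids[k] for k in i], "seg_b": [ids[k] for k in j],
        "idx_a": i, "idx_b": j,
        "chrom_a": chrom[i], "chrom_b": chrom[j],
        "n11": n11, "n10": n10, "n01": n01, "n00": n00,
        "e11": pA * pB * Nij, "e10": pA * (1 - pB) * Nij,
        "e01": (1 - pA) * pB * Nij, "e00": (1 - pA) * (1 - pB) * Nij,
        "n_informative": Nij.astype(int),
        "chi_square": x,
        "p_df3": stats.chi2.sf(x, DF_PRIMARY),
        "p_df1": stats.chi2.sf(x, 1),
        "dependency_class": dep,
    })


def _permuted_scores(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle every segment's score vector independently across spores."""
    return rng.permuted(scores, axis=0)


def permutation_fdr(results: pd.DataFrame, matrix: SegmentMatrix,
                    n_perm: int = 1000, seed: int | None = None,
                    interchromosomal_only: bool = True) -> np.ndarray:
    """Permutation FDR for every scanned pair.

    Each permutation independently shuffles every segment's score vector
    across spores (preserving its 0/1/2/missing multiset), the full pair
    scan is repeated, and FDR(x) = mean permuted exceedance count at x
    divided by the observed exceedance count at x. Ties (statistic == x)
    count in both numerator and denominator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    i, j = _pair_selection(matrix, interchromosomal_only)

    perm_stats = np.empty(n_perm * len(i))
    for p in range(n_perm):
        shuffled = _permuted_scores(matrix.scores, rng)
        t = _pair_tables(shuffled)
        chi = _chi_square_matrix(t)[i, j]
        perm_stats[p * len(i):(p + 1) * len(i)] = chi
    perm_sorted = np.sort(perm_stats[~np.isnan(perm_stats)])

    obs = results["chi_square"].to_numpy()
    obs_sorted = np.sort(obs)
    n_ge_perm = len(perm_sorted) - np.searchsorted(perm_sorted, obs, "left")
    n_ge_obs = len(obs_sorted) - np.searchsorted(obs_sorted, obs, "left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = (n_ge_perm / n_perm) / n_ge_obs
    fdr[n_ge_obs == 0] = np.nan
    return fdr


def scan_with_fdr(matrix: SegmentMatrix, n_perm: int = 1000,
                  seed: int | None = None,
                  interchromosomal_only: bool = True) -> pd.DataFrame:
    """Convenience: scan_pairs + permutation_fdr in one call."""
    results = scan_pairs(matrix, interchromosomal_only)
    results["fdr"] = permutation_fdr(results, matrix, n_perm, seed,
                                     interchromosomal_only)
    return results


def nine_category_table(scores_a: np.ndarray, scores_b: np.ndarray
                        ) -> pd.DataFrame:
    """Descriptive 3x3 tally over {1, 0, 2} x {1, 0, 2} (no test attached)."""
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    cats = (1, 0, 2)
    table = [[int(np.sum((a == ca) & (b == cb))) for cb in cats] for ca in cats]
    return pd.DataFrame(table, index=[f"a={c}" for c in cats],
                        columns=[f"b={c}" for c in cats])


def intrachromosomal_distance_scan(
    matrix: SegmentMatrix, fdr_threshold: float = 0.01,
    n_perm: int = 1000, seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Distance vs chi-square for same-chromosome pairs; linkage horizon.

    Returns the per-pair table (midpoint distance in bp, statistic, FDR)
    and the minimum unlinked distance: the smallest observed distance d
    such that no pair at distance >= d has FDR < ``fdr_threshold``
    (0.0 when no pair is significant, +inf when even the most distant
    pairs remain linked).
    """
    n = matrix.n_segments
    i, j = np.triu_indices(n, k=1)
    chrom = matrix.chrom
    keep = chrom[i] == chrom[j]
    i, j = i[keep], j[keep]
    if len(i) == 0:
        return pd.DataFrame(columns=["chrom", "distance_bp", "chi_square",
                                     "fdr"]), 0.0

    mid = matrix.midpoints
    t = _pair_tables(matrix.scores)
    chi = _chi_square_matrix(t)[i, j]

    rng = np.random.default_rng(seed)
    perm_stats = np.empty(n_perm * len(i))
    for p in range(n_perm):
        shuffled = _permuted_scores(matrix.scores, rng)
        tp = _pair_tables(shuffled)
        perm_stats[p * len(i):(p + 1) * len(i)] = _chi_square_matrix(tp)[i, j]
    perm_sorted = np.sort(perm_stats[~np.isnan(perm_stats)])
    obs_sorted = np.sort(chi[~np.isnan(chi)])
    n_ge_perm = len(perm_sorted) - np.searchsorted(perm_sorted, chi, "left")
    n_ge_obs = len(obs_sorted) - np.searchsorted(obs_sorted, chi, "left")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = (n_ge_perm / n_perm) / n_ge_obs

    table = pd.DataFrame({
        "chrom": chrom[i],
        "distance_bp": np.abs(mid[i] - mid[j]),
        "chi_square": chi,
        "fdr": fdr,
    })
    sig = table["fdr"] < fdr_threshold
    if not sig.any():
        return table, 0.0
    d_max_sig = table.loc[sig, "distance_bp"].max()
    beyond = table.loc[table["distance_bp"] > d_max_sig, "distance_bp"]
    min_unlinked = float(beyond.min()) if len(beyond) else float("inf")
    return table, min_unlinked
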