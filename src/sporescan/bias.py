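"""Whole-chromosome transmission-bias and aneuploidy-deficit tests.

Segregation of each chromosome among non-recombinant, non-aneuploid
spores is tested against a fair 50:50 binomial; exact tail probabilities
are authoritative, with the (continuity-uncorrected) normal approximation
reported alongside. Per-chromosome aneuploidy counts are tested for a
deficit against a uniform (or optionally length-weighted) allocation of
the cohort's total events over the 16 chromosomes, Bonferroni-corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import GenotypeTrack


@dataclass
class TransmissionBias:
    n_cer: int
    n_par: int
    p_one_sided: float       # exact binomial lower tail at the smaller count
    p_two_sided: float       # min(1, 2 * one-sided)
    p_normal: float          # normal approximation, no continuity correction

    @property
    def n(self) -> int:
        return self.n_cer + self.n_par


def binomial_transmission_test(n_cer: int, n_par: int) -> TransmissionBias:
    """Exact and approximate binomial tails for a 50:50 inheritance null."""
    if n_cer < 0 or n_par < 0:
        raise ValueError("counts must be non-negative")
    n = n_cer + n_par
    if n == 0:
        raise ValueError("no informative spores")
    k = min(n_cer, n_par)
    p_one = float(stats.binom.cdf(k, n, 0.5))
    p_two = min(1.0, 2.0 * p_one)
    z = (k - n / 2.0) / math.sqrt(n / 4.0)
    p_norm = float(stats.norm.cdf(z))
    return TransmissionBias(n_cer=n_cer, n_par=n_par, p_one_sided=p_one,
                            p_two_sided=p_two, p_normal=p_norm)


def chromosome_inheritance_bias(tracks: list[GenotypeTrack]) -> pd.DataFrame:
    """Per-chromosome 50:50 test over non-recombinant spores.

    A spore contributes to a chromosome's tally only if it is not
    aneuploid there, shows zero breakpoints on both species' tracks, and
    exactly one species' copy is called absent (so the inherited parent is
    unambiguous). Chromosomes with no such spores are marked
    not-applicable (NaN p-values).
    """
    chroms = sorted({c for t in tracks for (_, c) in t.chromosomes})
    rows = []
    for chrom in chroms:
        n_cer = n_par = 0
        for t in tracks:
            if t.aneuploid.get(chrom, False):
                continue
            cer = t.call("cer", chrom)
            par = t.call("par", chrom)
            if cer.n_breakpoints or par.n_breakpoints:
                continue
            if cer.absent == par.absent:
                continue
            if par.absent:
                n_cer += 1
            else:
                n_par += 1
        row = {"chrom": chrom, "n_cer": n_cer, "n_par": n_par}
        if n_cer + n_par == 0:
            row.update(p_one_sided=np.nan, p_two_sided=np.nan, p_normal=np.nan)
        else:
            r = binomial_transmission_test(n_cer, n_par)
            row.update(p_one_sided=r.p_one_sided, p_two_sided=r.p_two_sided,
                       p_normal=r.p_normal)
        rows.append(row)
    return pd.DataFrame(rows)


def aneuploidy_deficit_test(
    aneuploidy_counts,
    alpha: float = 0.05,
    chromosome_lengths: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Per-chromosome lower-tail binomial test for an aneuploidy deficit.

    With T total events over the chromosomes, each chromosome's observed
    count is referred to Binomial(T, p_c) with p_c = 1/16 under the
    uniform null (or proportional to length when ``chromosome_lengths`` is
    given); the lower tail P(X <= observed) is Bonferroni-multiplied by
    the number of chromosomes, clipped at 1, and a deficit is flagged at
    corrected p < ``alpha``.
    """
    if isinstance(aneuploidy_counts, dict):
        counts = dict(aneuploidy_counts)
    else:
        counts = {c + 1: int(v) for c, v in enumerate(aneuploidy_counts)}
    n_chrom = len(counts)
    total = sum(counts.values())
    rows = []
    for chrom in sorted(counts):
        obs = counts[chrom]
        if chromosome_lengths is not None:
            p_c = chromosome_lengths[chrom] / sum(chromosome_lengths.values())
        else:
            p_c = 1.0 / n_chrom
        if total == 0:
            rows.append({"chrom": chrom, "observed": obs,
                         "expected": np.nan, "p_lower": np.nan,
                         "p_bonferroni": np.nan, "deficit": False})
            continue
        p_lower = float(stats.binom.cdf(obs, total, p_c))
        p_bonf = min(1.0, n_chrom * p_lower)
        rows.append({"chrom": chrom, "observed": obs,
                     "expected": total * p_c, "p_lower": p_lower,
                     "p_bonferroni": p_bonf, "deficit": p_bonf < alpha})
    return pd.DataFrame(rows)


def aneuploidy_counts_from_tracks(tracks: list[GenotypeTrack]) -> dict[int, int]:
    """Tally aneuploidy events per chromosome across a cohort."""
    chroms = sorted({c for t in tracks for (_, c) in t.chromosomes})
    return {c: sum(1 for t in tracks if t.aneuploid.get(c, False))
            for c in chroms}
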