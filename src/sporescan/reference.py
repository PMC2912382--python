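"""Published per-chromosome event tallies of the two hybrid-spore cohorts.

These are the printed recombination and aneuploidy counts per chromosome
(as seen on each species' half of the array) for the 58 spores from
mismatch-repair proficient F1 hybrids and the 48 spores from MSH2-deleted
hybrids, together with the cohort-summary arithmetic that turns them into
per-spore event rates. An aneuploid chromosome is present from both
species at once, so the cer and par aneuploidy rows tally the same events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CohortEventTable:
    """Per-chromosome event counts for one cohort (chromosomes 1..16)."""

    name: str
    n_spores: int
    recombination: dict[str, tuple[int, ...]]   # species -> 16 counts
    aneuploidy: dict[str, tuple[int, ...]]

    def events_per_spore(self, kind: str) -> float:
        """Mean events per spore, averaging the two species' tallies."""
        table = getattr(self, kind)
        per_species = [sum(table[sp]) for sp in ("cer", "par")]
        return float(np.mean(per_species)) / self.n_spores

    @property
    def crossovers_per_spore(self) -> float:
        return self.events_per_spore("recombination")

    @property
    def aneuploidies_per_spore(self) -> float:
        return self.events_per_spore("aneuploidy")

    def aneuploidy_counts(self, species: str = "cer") -> dict[int, int]:
        return {c + 1: v for c, v in enumerate(self.aneuploidy[species])}


#: 58 spores from mismatch-repair proficient (wild-type) F1 hybrids.
WILD_TYPE_COHORT = CohortEventTable(
    name="wild_type",
    n_spores=58,
    recombination={
        "cer": (4, 11, 1, 23, 12, 5, 12, 5, 4, 10, 8, 14, 15, 9, 13, 10),
        "par": (4, 11, 1, 22, 12, 5, 12, 5, 6, 10, 7, 13, 14, 10, 12, 9),
    },
    aneuploidy={
        "cer": (10, 9, 9, 0, 12, 2, 4, 8, 16, 8, 14, 9, 7, 10, 5, 10),
        "par": (9, 9, 9, 1, 12, 2, 4, 8, 14, 8, 14, 9, 8, 10, 5, 11),
    },
)

#: 48 spores from MSH2-deleted (mismatch-repair deficient) F1 hybrids.
MMR_DEFICIENT_COHORT = CohortEventTable(
    name="mmr_deficient",
    n_spores=48,
    recombination={
        "cer": (23, 63, 27, 126, 46, 20, 74, 42, 28, 53, 37, 75, 68, 47, 71, 60),
        "par": (19, 62, 27, 124, 45, 20, 74, 42, 27, 53, 37, 72, 71, 48, 70, 61),
    },
    aneuploidy={
        "cer": (4, 2, 0, 0, 0, 0, 0, 2, 2, 0, 1, 1, 1, 0, 0, 1),
        "par": (4, 2, 0, 0, 0, 0, 0, 2, 2, 0, 1, 2, 0, 0, 0, 1),
    },
)

#: Chromosome-4 inheritance among the 39 wild-type spores without a
#: chromosome-4 crossover: 30 carried the cer copy, 9 the par copy.
CHR4_INHERITANCE = (30, 9)


def recombination_fold_change() -> float:
    """Mutant-over-wild-type fold change in crossovers per spore."""
    return (MMR_DEFICIENT_COHORT.crossovers_per_spore
            / WILD_TYPE_COHORT.crossovers_per_spore)
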