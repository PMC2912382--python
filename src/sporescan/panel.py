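"""Dual-species probe panels: the genomic scaffold of the pipeline.

A panel tiles every chromosome of both parental species (*S. cerevisiae*,
``cer``, and *S. paradoxus*, ``par``) with species-specific oligo probes at
roughly even spacing. The two species' genomes are treated as collinear, so
a single coordinate system (the 16 chromosomes with their physical lengths)
serves both probe sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

SPECIES = ("cer", "par")

#: Physical chromosome lengths (bp) of the S. cerevisiae reference genome,
#: used as the default collinear coordinate system for both species.
SCER_CHROMOSOME_LENGTHS: dict[int, int] = {
    1: 230_218, 2: 813_184, 3: 316_620, 4: 1_531_933,
    5: 576_874, 6: 270_161, 7: 1_090_940, 8: 562_643,
    9: 439_888, 10: 745_751, 11: 666_816, 12: 1_078_177,
    13: 924_431, 14: 784_333, 15: 1_091_291, 16: 948_066,
}

DEFAULT_SPACING = 2_000.0


@dataclass(frozen=True)
class ProbePanel:
    """Ordered dual-species probe coordinates.

    Parameters
    ----------
    probes
        DataFrame with columns ``probe_id``, ``species`` (``cer``/``par``),
        ``chrom`` (1-based integer) and ``pos`` (bp, 0-based), sorted by
        (species, chrom, pos) with strictly increasing positions within each
        (species, chrom).
    chromosome_lengths
        Mapping chromosome -> length in bp.
    """

    probes: pd.DataFrame
    chromosome_lengths: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.probes
        required = ["probe_id", "species", "chrom", "pos"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"panel missing columns: {missing}")
        if df["probe_id"].duplicated().any():
            dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        bad = set(df["species"].unique()) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")
        for (sp, chrom), grp in df.groupby(["species", "chrom"], sort=False):
            pos = grp["pos"].to_numpy()
            if len(pos) and not np.all(np.diff(pos) > 0):
                raise ValueError(
                    f"probe positions not strictly increasing on {sp} chr{chrom}"
                )
            length = self.chromosome_lengths.get(int(chrom))
            if length is not None and len(pos) and pos[-1] >= length:
                raise ValueError(
                    f"probe beyond chromosome end on {sp} chr{chrom}"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.chromosome_lengths)

    def species_probes(self, species: str) -> pd.DataFrame:
        return self.probes[self.probes["species"] == species]

    def positions(self, species: str, chrom: int) -> np.ndarray:
        df = self.probes
        sel = (df["species"] == species) & (df["chrom"] == chrom)
        return df.loc[sel, "pos"].to_numpy()

    def row_index(self, species: str, chrom: int) -> np.ndarray:
        """Integer row indices (into ``probes``) of one species-chromosome."""
        df = self.probes
        sel = (df["species"] == species) & (df["chrom"] == chrom)
        return np.flatnonzero(sel.to_numpy())


def generate_probe_panel(
    chromosome_lengths: Mapping[int, int] | None = None,
    spacing: float = DEFAULT_SPACING,
    jitter: float = 0.25,
    seed: int | np.random.Generator | None = None,
) -> ProbePanel:
    """Tile both species' chromosomes with probes at jittered ~``spacing`` bp.

    Inter-probe gaps are drawn uniformly from
    ``[(1 - jitter) * spacing, (1 + jitter) * spacing]``; with ``jitter=0``
    probes sit exactly at ``spacing/2 + i*spacing``. Deterministic given
    ``seed``.
    """
    if chromosome_lengths is None:
        chromosome_lengths = SCER_CHROMOSOME_LENGTHS
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must be in [0, 1)")
    rng = np.random.default_rng(seed)

    records: list[tuple[str, str, int, int]] = []
    for species in SPECIES:
        for chrom in sorted(chromosome_lengths):
            length = chromosome_lengths[chrom]
            n_max = int(np.ceil(length / ((1 - jitter) * spacing))) + 2
            if jitter > 0:
                gaps = rng.uniform((1 - jitter) * spacing,
                                   (1 + jitter) * spacing, size=n_max)
            else:
                gaps = np.full(n_max, spacing)
            pos = np.cumsum(gaps) - spacing / 2.0
            pos = pos[pos < length]
            pos = np.unique(np.round(pos).astype(np.int64))
            pos = pos[(pos >= 0) & (pos < length)]
            for i, p in enumerate(pos):
                records.append(
                    (f"{species}_chr{chrom:02d}_{i:05d}", species, chrom, int(p))
                )
    df = pd.DataFrame(records, columns=["probe_id", "species", "chrom", "pos"])
    return ProbePanel(probes=df, chromosome_lengths=dict(chromosome_lengths))
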