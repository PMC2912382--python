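"""Hybrid F1 meiosis and array-CGH simulator.

Models the production of rare viable haploid spores from an interspecific
yeast hybrid (cer x par):

* crossovers — Poisson per chromosome, mean proportional to chromosome
  length with a genome-wide mean ``crossover_mean_per_genome``; positions
  uniform along the chromosome; parental origin alternates across
  crossovers, starting parent chosen by a fair coin;
* whole-chromosome aneuploidy — with probability
  ``aneuploidy_prob_per_chromosome`` a spore retains both homeologs of a
  chromosome (disomy across species), in which case both species' probes
  on that chromosome read "present";
* viability selection — planted genic incompatibilities kill spores whose
  joint parental-origin pattern at the specified loci matches a lethal
  pattern, with a given penetrance; cohorts are assembled by rejection
  sampling over gametes until the requested number of viable spores exist;
* measurement — each probe's log10 ratio is Gaussian around ``mu_present``
  where the probed locus is inherited from that probe's species (or the
  chromosome is aneuploid) and around ``mu_absent`` otherwise.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so identical (params, specs, seed) give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import (SCER_CHROMOSOME_LENGTHS, SPECIES, ProbePanel,
                    generate_probe_panel)

ORIGIN_CER = "cer"
ORIGIN_PAR = "par"


@dataclass
class SimParams:
    """Study-condition parameters of the hybrid meiosis + aCGH generator.

    The two named regimes mirror the two published cohorts: a
    mismatch-repair proficient ("wild type") hybrid with few crossovers and
    frequent aneuploidy, and an MSH2-deleted hybrid with ~6.7x more
    recombination and ~8x less aneuploidy.
    """

    n_spores: int = 58
    crossover_mean_per_genome: float = 2.66
    aneuploidy_prob_per_chromosome: float = 2.29 / 16
    chromosome_lengths: dict[int, int] = field(
        default_factory=lambda: dict(SCER_CHROMOSOME_LENGTHS))
    mu_present: float = 0.30
    mu_absent: float = -1.0
    noise_sd: float = 0.15
    max_attempts: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_spores < 1:
            raise ValueError("n_spores must be >= 1")
        if self.crossover_mean_per_genome < 0:
            raise ValueError("crossover_mean_per_genome must be >= 0")
        if not 0.0 <= self.aneuploidy_prob_per_chromosome <= 1.0:
            raise ValueError("aneuploidy_prob_per_chromosome must be in [0, 1]")
        if not self.mu_absent < -0.05 < self.mu_present:
            raise ValueError("need mu_absent < -0.05 < mu_present")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    @classmethod
    def wild_type(cls, **overrides) -> "SimParams":
        """MMR-proficient regime: 2.66 crossovers and 2.29 aneuploidies/spore."""
        kw = dict(n_spores=58, crossover_mean_per_genome=2.66,
                  aneuploidy_prob_per_chromosome=2.29 / 16)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def mmr_deficient(cls, **overrides) -> "SimParams":
        """msh2 regime: 17.83 crossovers and 0.29 aneuploidies/spore."""
        kw = dict(n_spores=48, crossover_mean_per_genome=17.83,
                  aneuploidy_prob_per_chromosome=0.29 / 16)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class IncompatibilitySpec:
    """A planted genic incompatibility.

    ``loci`` are (chromosome, position) pairs; each ``lethal_pattern`` is a
    tuple of parental origins of the same length as ``loci``; a spore whose
    origin at every locus is compatible with the pattern (aneuploid loci
    carry both origins, hence match anything) is killed with probability
    ``penetrance``.
    """

    loci: list[tuple[int, int]]
    lethal_patterns: list[tuple[str, ...]]
    penetrance: float = 1.0

    def __post_init__(self) -> None:
        if len(self.loci) < 2:
            raise ValueError("an incompatibility needs >= 2 loci")
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        if not self.lethal_patterns:
            raise ValueError("at least one lethal pattern is required")
        for pat in self.lethal_patterns:
            if len(pat) != len(self.loci):
                raise ValueError("lethal pattern length must match loci")
            if any(o not in SPECIES for o in pat):
                raise ValueError(f"pattern origins must be in {SPECIES}")

    @classmethod
    def two_way(cls, locus_a: tuple[int, int], locus_b: tuple[int, int],
                penetrance: float = 1.0) -> "IncompatibilitySpec":
        """Both mixed-origin genotypes (Ab and aB) are lethal."""
        return cls(loci=[locus_a, locus_b],
                   lethal_patterns=[(ORIGIN_CER, ORIGIN_PAR),
                                    (ORIGIN_PAR, ORIGIN_CER)],
                   penetrance=penetrance)

    @classmethod
    def one_way(cls, locus_a: tuple[int, int], locus_b: tuple[int, int],
                lethal: tuple[str, str] = (ORIGIN_PAR, ORIGIN_CER),
                penetrance: float = 1.0) -> "IncompatibilitySpec":
        """Exactly one mixed-origin genotype (default aB) is lethal."""
        return cls(loci=[locus_a, locus_b], lethal_patterns=[lethal],
                   penetrance=penetrance)

    @classmethod
    def three_way(cls, loci: Sequence[tuple[int, int]],
                  lethal_pattern: tuple[str, str, str],
                  penetrance: float = 1.0) -> "IncompatibilitySpec":
        """A single lethal joint pattern over three loci."""
        if len(loci) != 3:
            raise ValueError("three_way needs exactly 3 loci")
        return cls(loci=list(loci), lethal_patterns=[lethal_pattern],
                   penetrance=penetrance)

    def validate_against(self, lengths: Mapping[int, int]) -> None:
        for chrom, pos in self.loci:
            if chrom not in lengths:
                raise ValueError(f"locus chromosome {chrom} not in genome")
            if not 0 <= pos < lengths[chrom]:
                raise ValueError(
                    f"locus position {pos} outside chromosome {chrom} bounds")


@dataclass
class GameteChromosome:
    """Parental-origin track of one chromosome of one gamete."""

    chrom: int
    first_origin: str            # origin of [0, crossovers[0])
    crossovers: np.ndarray       # sorted crossover positions, bp
    aneuploid: bool              # both homeologs present over full length

    def origin_at(self, pos) -> np.ndarray | str:
        """Origin at bp position(s): 'cer', 'par', or 'both' if aneuploid."""
        scalar = np.isscalar(pos)
        pos = np.atleast_1d(np.asarray(pos))
        if self.aneuploid:
            out = np.full(pos.shape, "both", dtype=object)
        else:
            flips = np.searchsorted(self.crossovers, pos, side="right")
            other = ORIGIN_PAR if self.first_origin == ORIGIN_CER else ORIGIN_CER
            out = np.where(flips % 2 == 0, self.first_origin, other).astype(object)
        return out[0] if scalar else out

    def origin_is(self, pos: np.ndarray, species: str) -> np.ndarray:
        """Boolean: does this gamete carry ``species`` material at ``pos``?"""
        if self.aneuploid:
            return np.ones(len(pos), dtype=bool)
        flips = np.searchsorted(self.crossovers, pos, side="right")
        first_is = self.first_origin == species
        return (flips % 2 == 0) == first_is


Gamete = dict[int, GameteChromosome]


@dataclass
class SporeTruth:
    spore_id: str
    gamete: Gamete
    viable: bool = True
    killed_by: int | None = None   # index into the spec list, or None

    @property
    def n_crossovers(self) -> int:
        return sum(len(c.crossovers) for c in self.gamete.values())

    @property
    def aneuploid_chromosomes(self) -> list[int]:
        return [c for c, g in self.gamete.items() if g.aneuploid]


@dataclass
class SimulationTruth:
    """Ground truth for a simulated cohort of viable spores."""

    spores: list[SporeTruth]
    n_rejected: int = 0

    @property
    def mean_crossovers(self) -> float:
        return float(np.mean([s.n_crossovers for s in self.spores]))

    @property
    def mean_aneuploidies(self) -> float:
        return float(np.mean([len(s.aneuploid_chromosomes)
                              for s in self.spores]))


def simulate_gamete(params: SimParams,
                    seed: int | np.random.Generator | None = None) -> Gamete:
    """Draw one haploid meiotic product (no viability selection)."""
    rng = np.random.default_rng(seed)
    lengths = params.chromosome_lengths
    total = sum(lengths.values())
    gamete: Gamete = {}
    for chrom in sorted(lengths):
        length = lengths[chrom]
        mean = params.crossover_mean_per_genome * length / total
        n_co = rng.poisson(mean)
        crossovers = np.sort(rng.uniform(0, length, size=n_co))
        first = ORIGIN_CER if rng.random() < 0.5 else ORIGIN_PAR
        aneuploid = rng.random() < params.aneuploidy_prob_per_chromosome
        gamete[chrom] = GameteChromosome(
            chrom=chrom, first_origin=first, crossovers=crossovers,
            aneuploid=aneuploid)
    return gamete


def apply_viability_filter(
    gamete: Gamete,
    specs: Sequence[IncompatibilitySpec],
    seed: int | np.random.Generator | None = None,
) -> tuple[bool, int | None]:
    """Return (viable, index of the killing spec or None).

    A spore matches a lethal pattern when, at every locus, it carries the
    pattern's parental origin; aneuploid loci carry both origins and so
    satisfy either requirement.
    """
    rng = np.random.default_rng(seed)
    for i, spec in enumerate(specs):
        lethal = False
        for pattern in spec.lethal_patterns:
            ok = True
            for (chrom, pos), origin in zip(spec.loci, pattern):
                if chrom not in gamete:
                    raise ValueError(f"locus chromosome {chrom} not simulated")
                gc = gamete[chrom]
                if not (0 <= pos < 2**63):
                    raise ValueError("locus position out of bounds")
                carried = gc.aneuploid or gc.origin_at(pos) == origin
                if not carried:
                    ok = False
                    break
            if ok:
                lethal = True
                break
        if lethal and rng.random() < spec.penetrance:
            return False, i
    return True, None


def emit_cgh(gamete: Gamete, panel: ProbePanel, params: SimParams,
             seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Noisy log10-ratio vector over ``panel.probes`` rows for one gamete."""
    rng = np.random.default_rng(seed)
    n = panel.n_probes
    present = np.zeros(n, dtype=bool)
    for species in SPECIES:
        for chrom in panel.chromosomes:
            idx = panel.row_index(species, chrom)
            if len(idx) == 0:
                continue
            if chrom not in gamete:
                raise ValueError(f"gamete lacks chromosome {chrom}")
            pos = panel.probes["pos"].to_numpy()[idx]
            present[idx] = gamete[chrom].origin_is(pos, species)
    mu = np.where(present, params.mu_present, params.mu_absent)
    if params.noise_sd > 0:
        ratios = rng.normal(mu, params.noise_sd)
    else:
        ratios = mu.astype(float)
    return ratios


@dataclass
class CohortSim:
    """A simulated cohort: log-ratio matrix plus ground truth."""

    panel: ProbePanel
    logratios: np.ndarray          # (n_probes, n_spores)
    spore_ids: list[str]
    truth: SimulationTruth


def simulate_cohort(
    params: SimParams,
    specs: Sequence[IncompatibilitySpec] = (),
    panel: ProbePanel | None = None,
    seed: int | None = None,
) -> CohortSim:
    """Assemble ``params.n_spores`` viable spores by rejection sampling.

    Gametes failing the viability filter are discarded and counted in
    ``truth.n_rejected``. Aborts with ``RuntimeError`` after
    ``params.max_attempts`` draws (e.g. every pattern lethal at penetrance 1).
    """
    for spec in specs:
        spec.validate_against(params.chromosome_lengths)
    ss = np.random.SeedSequence(seed)
    panel_ss, spore_ss = ss.spawn(2)
    if panel is None:
        panel = generate_probe_panel(
            params.chromosome_lengths, seed=np.random.default_rng(panel_ss))

    spores: list[SporeTruth] = []
    columns: list[np.ndarray] = []
    n_rejected = 0
    attempts = 0
    while len(spores) < params.n_spores:
        if attempts >= params.max_attempts:
            raise RuntimeError(
                f"viability filter rejected {n_rejected} of {attempts} gametes; "
                f"attempt cap {params.max_attempts} reached before "
                f"{params.n_spores} viable spores were found")
        child = spore_ss.spawn(1)[0]
        g_rng, v_rng, e_rng = (np.random.default_rng(s) for s in child.spawn(3))
        attempts += 1
        gamete = simulate_gamete(params, g_rng)
        viable, killed_by = apply_viability_filter(gamete, specs, v_rng)
        if not viable:
            n_rejected += 1
            continue
        sid = f"spore_{len(spores):04d}"
        spores.append(SporeTruth(spore_id=sid, gamete=gamete, viable=True))
        columns.append(emit_cgh(gamete, panel, params, e_rng))

    logratios = np.column_stack(columns)
    truth = SimulationTruth(spores=spores, n_rejected=n_rejected)
    return CohortSim(panel=panel, logratios=logratios,
                     spore_ids=[s.spore_id for s in spores], truth=truth)
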