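import numpy as np
import pytest

from sporescan import (GenotypeParams, SimParams, call_cohort,
                       generate_probe_panel, segment_cohort, simulate_cohort)

# Reduced study genome used for simulation-heavy tests: 8 chromosomes,
# ~2.2 Mb total, probes every ~4 kb.
REDUCED_LENGTHS = {1: 250_000, 2: 300_000, 3: 200_000, 4: 350_000,
                   5: 280_000, 6: 220_000, 7: 320_000, 8: 260_000}
REDUCED_SPACING = 4_000.0


def reduced_params(n_spores=100, crossover_mean=1.0, aneuploidy_prob=0.01,
                   noise_sd=0.15, **kw) -> SimParams:
    return SimParams(n_spores=n_spores,
                     crossover_mean_per_genome=crossover_mean,
                     aneuploidy_prob_per_chromosome=aneuploidy_prob,
                     chromosome_lengths=dict(REDUCED_LENGTHS),
                     noise_sd=noise_sd, **kw)


@pytest.fixture(scope="session")
def reduced_panel():
    return generate_probe_panel(REDUCED_LENGTHS, spacing=REDUCED_SPACING,
                                seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort(reduced_panel):
    params = reduced_params(n_spores=30, crossover_mean=3.0,
                            aneuploidy_prob=0.05, noise_sd=0.0)
    return simulate_cohort(params, panel=reduced_panel, seed=11)


@pytest.fixture(scope="session")
def noiseless_tracks(noiseless_cohort):
    return call_cohort(noiseless_cohort.logratios, noiseless_cohort.panel,
                       GenotypeParams(),
                       spore_ids=noiseless_cohort.spore_ids)


@pytest.fixture(scope="session")
def noiseless_matrices(noiseless_tracks, noiseless_cohort):
    return segment_cohort(noiseless_tracks, noiseless_cohort.panel,
                          merge_tol_bp=REDUCED_SPACING)


@pytest.fixture(scope="session")
def noisy_cohort(reduced_panel):
    params = reduced_params(n_spores=40, crossover_mean=2.0,
                            aneuploidy_prob=0.02, noise_sd=0.15)
    return simulate_cohort(params, panel=reduced_panel, seed=23)


@pytest.fixture(scope="session")
def noisy_tracks(noisy_cohort):
    return call_cohort(noisy_cohort.logratios, noisy_cohort.panel,
                       GenotypeParams(), spore_ids=noisy_cohort.spore_ids)


def truth_origin_is(gamete, chrom, pos, species):
    """Boolean: gamete carries `species` material at (chrom, pos)."""
    return bool(gamete[chrom].origin_is(np.array([pos]), species)[0])
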