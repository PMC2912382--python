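import numpy as np
import pytest

from sporescan import (GenotypeParams, binarize_probes,
                       call_chromosome_absence, call_genotype,
                       detect_recombination_regions, emit_cgh,
                       summarize_cohort)
from sporescan.simulate import GameteChromosome


class TestBinarize:
    @pytest.mark.parametrize("ratio,expected", [
        (-0.20, 0), (0.30, 1), (-0.05, 1), (-0.051, 0), (0.0, 1),
    ])
    def test_threshold_rule(self, ratio, expected):
        assert binarize_probes(np.array([ratio]))[0] == expected

    def test_non_finite_rejected_with_probe_name(self):
        with pytest.raises(ValueError, match="probe_x"):
            binarize_probes(np.array([0.1, np.nan]),
                            probe_ids=["probe_a", "probe_x"])


class TestAbsence:
    @pytest.mark.parametrize("n_zero,expected", [
        (85, True), (50, False), (80, True), (79, False),
    ])
    def test_eighty_percent_rule(self, n_zero, expected):
        calls = np.array([0] * n_zero + [1] * (100 - n_zero))
        assert call_chromosome_absence(calls, 0.80) is expected

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError):
            call_chromosome_absence(np.array([]))


class TestRegions:
    def test_clean_step_breakpoint_between_14_and_15(self):
        calls = np.array([1] * 15 + [0] * 15, dtype=np.int8)
        regions, breakpoints = detect_recombination_regions(calls)
        assert breakpoints == [15]      # boundary between probes 14 and 15
        assert regions == [(0, 15, 1), (15, 30, 0)]

    def test_uniform_signal_single_region(self):
        regions, breakpoints = detect_recombination_regions(
            np.ones(40, dtype=np.int8))
        assert breakpoints == []
        assert regions == [(0, 40, 1)]

    def test_short_chromosome_single_region(self, caplog):
        calls = np.array([1, 1, 0, 1], dtype=np.int8)
        regions, breakpoints = detect_recombination_regions(calls)
        assert regions == [(0, 4, 1)] and breakpoints == []

    def test_regions_partition_probe_range(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 300))
            calls = rng.integers(0, 2, size=n).astype(np.int8)
            regions, breakpoints = detect_recombination_regions(calls)
            assert regions[0][0] == 0 and regions[-1][1] == n
            for (s1, e1, _), (s2, e2, _) in zip(regions, regions[1:]):
                assert e1 == s2
            assert [r[0] for r in regions[1:]] == breakpoints

    def test_step_recovery_under_probe_flips(self):
        # planted step in 200 probes with 5% independent flips: the
        # breakpoint must land within +/-5 probes in >=95% of trials
        rng = np.random.default_rng(99)
        n, trials, hits = 200, 1_000, 0
        for _ in range(trials):
            true_bp = int(rng.integers(20, 180))
            calls = np.array([1] * true_bp + [0] * (n - true_bp),
                             dtype=np.int8)
            flips = rng.random(n) < 0.05
            calls[flips] ^= 1
            _, breakpoints = detect_recombination_regions(calls)
            if any(abs(b - true_bp) <= 5 for b in breakpoints):
                hits += 1
        assert hits / trials >= 0.95

    def test_idempotent_on_own_reconstruction(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            true_bp = int(rng.integers(30, 170))
            calls = np.array([1] * true_bp + [0] * (200 - true_bp),
                             dtype=np.int8)
            calls[rng.random(200) < 0.03] ^= 1
            regions, _ = detect_recombination_regions(calls)
            rebuilt = np.empty(200, dtype=np.int8)
            for s, e, v in regions:
                rebuilt[s:e] = v
            regions2, _ = detect_recombination_regions(rebuilt)
            assert regions2 == [(s, e, v) for s, e, v in regions]


class TestCallGenotype:
    def test_noiseless_interior_crossovers_recovered_exactly(
            self, reduced_panel):
        # crossovers placed well inside the chromosome and > one detection
        # window apart reconstruct the origin track exactly without noise
        from conftest import reduced_params
        params = reduced_params(noise_sd=0.0)
        rng = np.random.default_rng(55)
        for trial in range(10):
            gamete = {}
            for c in reduced_panel.chromosomes:
                length = reduced_panel.chromosome_lengths[c]
                a = rng.uniform(0.20 * length, 0.45 * length)
                xo = np.array([a, a + rng.uniform(0.30, 0.35) * length])
                gamete[c] = GameteChromosome(
                    chrom=c, first_origin=("cer", "par")[trial % 2],
                    crossovers=xo, aneuploid=False)
            ratios = emit_cgh(gamete, reduced_panel, params,
                              seed=trial)
            track = call_genotype(ratios, reduced_panel)
            for (species, chrom), call in track.chromosomes.items():
                pos = reduced_panel.positions(species, chrom)
                truth = gamete[chrom].origin_is(pos, species)
                rebuilt = np.empty(len(pos), dtype=bool)
                for s, e, v in call.regions:
                    rebuilt[s:e] = bool(v)
                assert np.array_equal(rebuilt, truth)

    def test_noiseless_cohort_track_accuracy(self, noiseless_cohort,
                                             noiseless_tracks):
        # random cohorts include telomere-proximal and sub-window events
        # that the 10-probe rule cannot resolve; probe-level accuracy
        # nevertheless stays high
        panel = noiseless_cohort.panel
        accs = []
        for spore, track in zip(noiseless_cohort.truth.spores,
                                noiseless_tracks):
            for (species, chrom), call in track.chromosomes.items():
                pos = panel.positions(species, chrom)
                truth = spore.gamete[chrom].origin_is(pos, species)
                rebuilt = np.empty(len(pos), dtype=bool)
                for s, e, v in call.regions:
                    rebuilt[s:e] = bool(v)
                accs.append(np.mean(rebuilt == truth))
        assert np.mean(accs) > 0.97
        assert min(accs) > 0.75

    def test_aneuploid_chromosome_flagged(self, reduced_panel):
        from conftest import reduced_params
        params = reduced_params(noise_sd=0.0, crossover_mean=0.0)
        gamete = {
            c: GameteChromosome(chrom=c, first_origin="cer",
                                crossovers=np.array([]), aneuploid=(c == 3))
            for c in reduced_panel.chromosomes}
        ratios = emit_cgh(gamete, reduced_panel, params, seed=1)
        track = call_genotype(ratios, reduced_panel)
        assert track.aneuploid[3] is True
        assert all(track.aneuploid[c] is False
                   for c in reduced_panel.chromosomes if c != 3)

    def test_noisy_planted_crossovers_recovered(self, reduced_panel):
        # default noise (sd 0.15): breakpoint positions of detectable
        # (interior, well-separated) crossovers recovered within +/-5
        # probes, and per-chromosome counts exact, in >=95% of cases
        from conftest import reduced_params
        params = reduced_params(noise_sd=0.15)
        rng = np.random.default_rng(77)
        n_chrom_trials = n_count_ok = n_xo = n_pos_ok = 0
        for trial in range(12):
            gamete = {}
            for c in reduced_panel.chromosomes:
                length = reduced_panel.chromosome_lengths[c]
                a = rng.uniform(0.20 * length, 0.45 * length)
                xo = np.array([a, a + rng.uniform(0.30, 0.35) * length])
                gamete[c] = GameteChromosome(
                    chrom=c, first_origin="cer", crossovers=xo,
                    aneuploid=False)
            ratios = emit_cgh(gamete, reduced_panel, params, seed=trial + 100)
            track = call_genotype(ratios, reduced_panel)
            for c in reduced_panel.chromosomes:
                pos = reduced_panel.positions("cer", c)
                truth_idx = np.searchsorted(pos, gamete[c].crossovers)
                called = track.call("cer", c).breakpoints_idx
                n_chrom_trials += 1
                n_count_ok += len(called) == 2
                for t_idx in truth_idx:
                    n_xo += 1
                    n_pos_ok += any(abs(b - t_idx) <= 5 for b in called)
        assert n_count_ok / n_chrom_trials >= 0.95
        assert n_pos_ok / n_xo >= 0.95

    def test_breakpoint_count_parity_noiseless(self, noiseless_tracks):
        # reciprocal tracks: cer and par breakpoint counts agree within
        # +/-1 on >=95% of non-aneuploid chromosomes, and exactly whenever
        # neither copy is silenced by the whole-chromosome absence rule
        n = agree = 0
        for track in noiseless_tracks:
            for chrom in {c for (_, c) in track.chromosomes}:
                if track.aneuploid[chrom]:
                    continue
                cer = track.call("cer", chrom)
                par = track.call("par", chrom)
                n += 1
                agree += abs(cer.n_breakpoints - par.n_breakpoints) <= 1
                if not cer.absent and not par.absent:
                    assert cer.n_breakpoints == par.n_breakpoints
        assert agree / n >= 0.95

    def test_misclassification_monotone_in_noise(self, reduced_panel):
        from conftest import reduced_params
        g = {c: GameteChromosome(chrom=c, first_origin="cer",
                                 crossovers=np.array([]), aneuploid=False)
             for c in reduced_panel.chromosomes}
        idx = reduced_panel.row_index("cer", 4)
        rates = []
        for sd in (0.05, 0.10, 0.15, 0.25):
            params = reduced_params(noise_sd=sd)
            errs = 0
            for seed in (1, 2, 3):
                ratios = emit_cgh(g, reduced_panel, params, seed=seed)
                errs += int(np.sum(binarize_probes(ratios)[idx] == 0))
            rates.append(errs)
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_summarize_cohort_counts_events(self, noiseless_tracks):
        df = summarize_cohort(noiseless_tracks)
        assert set(df["species"]) == {"cer", "par"}
        total = df.loc[df["species"] == "cer", "recombination"].sum()
        assert total == sum(t.n_crossovers for t in noiseless_tracks)
        # aneuploidy tallies identical on the two species' rows
        cer = df[df["species"] == "cer"].set_index("chrom")["aneuploidy"]
        par = df[df["species"] == "par"].set_index("chrom")["aneuploidy"]
        assert (cer == par).all()

    def test_length_mismatch_rejected(self, reduced_panel):
        with pytest.raises(ValueError, match="does not match"):
            call_genotype(np.zeros(10), reduced_panel)
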