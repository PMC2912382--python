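"""Three-locus scan: zero-category triples against a permutation baseline.

Every segment triple on three distinct chromosomes defines 8 joint-origin
categories; a triple with an empty category is a candidate higher-order
incompatibility. Individual triples are not tested (empty cells arise by
chance at realistic cohort sizes) — only the cohort-level count is
compared with segment-shuffled permutations. A planted three-locus lethal
pattern pushes the observed count far above the baseline.
"""

from sporescan import (IncompatibilitySpec, SimParams, call_cohort,
                       count_zero_category_triples,
                       permutation_baseline_triples, segment_cohort,
                       simulate_cohort)

LENGTHS = {1: 250_000, 2: 300_000, 3: 200_000, 4: 350_000,
           5: 280_000, 6: 220_000, 7: 320_000, 8: 260_000}
params = SimParams(n_spores=150, crossover_mean_per_genome=0.6,
                   aneuploidy_prob_per_chromosome=0.01,
                   chromosome_lengths=LENGTHS, noise_sd=0.15)
spec = IncompatibilitySpec.three_way(
    [(1, 125_000), (2, 150_000), (3, 100_000)],
    lethal_pattern=("cer", "cer", "par"), penetrance=1.0)

cohort = simulate_cohort(params, [spec], seed=42)
tracks = call_cohort(cohort.logratios, cohort.panel,
                     spore_ids=cohort.spore_ids)
matrix = segment_cohort(tracks, cohort.panel, merge_tol_bp=4_000)["cer"]

obs = count_zero_category_triples(matrix)
base = permutation_baseline_triples(matrix, n_perm=20, seed=42)
print(f"{matrix.n_segments} segments -> {obs.total} distinct-chromosome "
      "triples")
print(f"observed triples with an empty category: {obs.flagged}")
print(f"permutation baseline: {base.mean:.1f} +/- {base.sd:.1f} (20 shuffles)")
print(f"z-score of the excess: {base.z_score(obs.flagged):.1f}")
print("\nthe excess reflects the planted cer/cer/par lethal pattern (and "
      "segments linked to it); without a planted pattern the observed "
      "count sits inside the baseline band")
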