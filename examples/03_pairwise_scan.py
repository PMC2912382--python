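"""Pairwise linkage scan with a planted two-way incompatibility.

Plants a penetrance-1 two-way Dobzhansky-Muller pair (both mixed-origin
genotypes lethal), simulates 100 viable spores, runs the four-category
chi-square scan over interchromosomal segment pairs with a permutation
FDR, and shows that the planted pair tops the ranking with both mixed
cells empty.
"""

from sporescan import (IncompatibilitySpec, SimParams, call_cohort,
                       scan_with_fdr, segment_cohort, simulate_cohort)

LENGTHS = {1: 250_000, 2: 300_000, 3: 200_000, 4: 350_000,
           5: 280_000, 6: 220_000, 7: 320_000, 8: 260_000}
params = SimParams(n_spores=100, crossover_mean_per_genome=1.0,
                   aneuploidy_prob_per_chromosome=0.01,
                   chromosome_lengths=LENGTHS, noise_sd=0.15)
spec = IncompatibilitySpec.two_way((1, 125_000), (2, 150_000),
                                   penetrance=1.0)

cohort = simulate_cohort(params, [spec], seed=11)
print(f"{len(cohort.spore_ids)} viable spores kept; "
      f"{cohort.truth.n_rejected} gametes rejected by the incompatibility")

tracks = call_cohort(cohort.logratios, cohort.panel,
                     spore_ids=cohort.spore_ids)
matrix = segment_cohort(tracks, cohort.panel, merge_tol_bp=4_000)["cer"]
results = scan_with_fdr(matrix, n_perm=200, seed=11)

top = results.sort_values("chi_square", ascending=False).head(5)
cols = ["seg_a", "seg_b", "n11", "n10", "n01", "n00", "chi_square", "fdr",
        "dependency_class"]
print(f"\ntop pairs of {len(results)} scanned "
      "(n10/n01 are the mixed-origin cells a D-M pair empties):")
print(top[cols].to_string(index=False))
print("\nthe top pair spans the planted loci chr1:125kb x chr2:150kb; "
      "empty mixed cells + FDR < 0.01 classify it two_way")
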