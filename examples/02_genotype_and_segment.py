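"""Call genotype tracks from noisy log ratios and segment the genomes.

Probe ratios are binarized at -0.05, chromosomes are split into
majority-value regions (>=10 probes, >70% agreement) whose borders are
the recombination breakpoints, breakpoints are pooled across spores and
every chromosome is cut at the pooled locations: k pooled breakpoints
give k+1 segments scored 1/0/2 per spore.
"""

from sporescan import (SimParams, call_cohort, segment_cohort,
                       simulate_cohort, summarize_cohort)

params = SimParams.wild_type(n_spores=20)
cohort = simulate_cohort(params, seed=3)
tracks = call_cohort(cohort.logratios, cohort.panel,
                     spore_ids=cohort.spore_ids)

summary = summarize_cohort(tracks)
cer = summary[summary["species"] == "cer"]
print("per-chromosome events called on the cer tracks:")
print(cer.to_string(index=False))
print(f"\nmean crossovers/spore called: "
      f"{sum(t.n_crossovers for t in tracks) / len(tracks):.2f} "
      f"(simulated truth {cohort.truth.mean_crossovers:.2f}; crossovers "
      "within ~10 probes of a telomere or of each other are below the "
      "region rule's resolution and go uncalled)")

matrices = segment_cohort(tracks, cohort.panel)
for genome, m in matrices.items():
    print(f"{genome}: {m.n_segments} segments over "
          f"{m.segments['chrom'].nunique()} chromosomes")
m = matrices["cer"]
print("\nfirst spore's first 10 segment scores (1 = inherited from cer, "
      "0 = from par, 2 = aneuploid):")
print(dict(zip(m.segment_ids()[:10], m.scores[0, :10])))
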