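"""Generate a synthetic bone cohort, filter it, and identify each sample.

Builds a 58-sample cohort at the default study conditions, applies per-sample
decoy FDR filtering, tallies spectra per candidate species, and prints each
sample's "winner" species with its spectra ratio. The ratio is the fraction
of the sample's distinct high-confidence spectra attributed to that species;
poorly database-represented species (e.g. white-tailed deer) are expected to
be misidentified as well-represented relatives.
"""

from osteoproba import pipeline, synthetic

config = synthetic.CohortConfig(seed=42)
samples, truth, taxonomy, _ = synthetic.generate_cohort(config)
filtered, fdr_report = pipeline.filter_cohort(samples)

print(f"{len(samples)} samples; E-value thresholds all <= "
      f"{fdr_report['chosen_e_threshold'].max():.3g}")

ratios = pipeline.ratio_table(filtered, "species", "spectra", taxonomy)
calls = pipeline.winner_table(ratios)
truth_map = {r["sample_id"]: r.to_dict() for _, r in truth.iterrows()}

print(f"{'sample':8}{'true species':26}{'winner':26}{'ratio':>6}")
for call in calls[:10]:
    true_sp = truth_map[call.sample_id]["true_species"] or "(unknown)"
    print(f"{call.sample_id:8}{true_sp:26}{call.winner_taxon:26}"
          f"{call.winner_ratio:6.2f}")

acc = pipeline.winner_accuracy(calls, truth_map, "species")
print(f"\nspectra-ratio winner accuracy over known-species samples: {acc:.1%}")
# A high winner ratio (~0.8) marks a confident identification; misidentified
# low-representation samples sit noticeably lower.
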