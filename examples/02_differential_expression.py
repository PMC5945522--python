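"""Discovery-phase differential expression: one subtype versus controls.

Applies the low-count filter, estimates median-of-ratios size factors and
surrogate variables, fits the NB Wald test for MIBC vs control and prints
the strongest hits.  The planted miRNAs should top the table with fold
changes near their planted values.
"""

from mirpanel import (
    SimulationConfig,
    estimate_sv,
    filter_low_counts,
    generate_counts,
    nb_wald_test,
)

config = SimulationConfig(
    n_per_class={"control": 40, "MIBC": 40},
    n_mirna=300,
    planted_de=[("miR-30a-5p", "MIBC", -1.8), ("miR-486-5p", "MIBC", 3.4)],
    batch_effect_sd=0.5,
    seed=2,
)
counts, metadata = generate_counts(config)

filtered = filter_low_counts(counts, min_total=20)
print(f"low-count filter: {filtered.shape[0]}/{counts.shape[0]} miRNAs kept "
      "(>= 20 reads summed over all samples)")

sv = estimate_sv(filtered, metadata, seed=2)
print(f"surrogate variables detected: {sv.n_sv} "
      "(the planted batch factor, recovered without using the batch label)")

result = nb_wald_test(filtered, metadata, "MIBC", sv=sv)
top = result.sort_values("p").head(5)
print("\ntop 5 miRNAs by Wald p (MIBC vs control):")
print(top[["mean_read_count", "log2FC", "p", "fdr"]].round(3).to_string())
print("\nlog2FC is subtype-over-control; the planted -1.8 and +3.4 effects")
print("should be recovered within ~0.1-0.2 log2 units.")
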