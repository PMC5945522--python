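"""Does adding the miRNA panel improve case-control discrimination?

Fits Model 0 (age + smoking) and Model 1 (Model 0 + three panel miRNAs as
-ΔCt covariates) on the same samples and compares their in-sample ROC AUCs
with the DeLong test for paired curves.
"""

from mirpanel import (
    CtMatrix,
    SimulationConfig,
    compare_models,
    delta_ct,
    generate_counts,
    generate_ct,
)

panel = ["miR-30a-5p", "let-7c-5p", "miR-486-5p"]
controls = ["miR-28-3p", "miR-361-3p"]
config = SimulationConfig(
    n_per_class={"control": 65, "NMIBC_G1G2": 82, "NMIBC_G3": 20, "MIBC": 10},
    n_mirna=50,
    planted_de=[(m, c, lfc) for m, lfc in
                zip(panel, [-0.7, -0.7, 0.7]) for c in
                ("NMIBC_G1G2", "NMIBC_G3", "MIBC")],
    planted_stable=controls,
    ct_noise_sd=0.8,
    seed=6,
)
counts, metadata = generate_counts(config)
ct = generate_ct(config, counts, metadata, panel, controls)
d = delta_ct(CtMatrix(ct, controls=controls, spike_in="UniSp6"))

mc = compare_models(d, metadata, panel)
print(f"n = {mc.n_cases} cases / {mc.n_controls} controls")
print(f"Model 0 (age + smoking):        AUC {mc.auc0:.2f} "
      f"(95% CI {mc.ci0[0]:.2f}-{mc.ci0[1]:.2f})")
print(f"Model 1 (Model 0 + 3 miRNAs):   AUC {mc.auc1:.2f} "
      f"(95% CI {mc.ci1[0]:.2f}-{mc.ci1[1]:.2f})")
print(f"DeLong test for the paired AUC difference: p = {mc.delong_p:.3g}")
print("\nAge and smoking are simulated independent of disease, so Model 0")
print("hovers near 0.5; the planted panel lifts discrimination well above it.")
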