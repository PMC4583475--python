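"""In-vitro dose-response pipeline for one receptor allele.

Simulates six replicate days of calcium-imaging plates for
TAS2R30-H1/amarogentin, applies the three corrections (well baseline,
empty-vector subtraction, positive-control day scaling), calls the
activation threshold against empty vector (ANOVA + Bonferroni), and fits
the Hill equation.
"""
import bittermap as bm

scenario = bm.default_scenario(seed=1)
plates = bm.simulate_plates(scenario, compounds=["amarogentin"], alleles=["TAS2R30-H1"], seed=1)
fits = bm.analyze_plates(plates, ceilings=scenario.artefact_ceilings)
fit = next(f for f in fits if f.allele == "TAS2R30-H1")

print(f"TAS2R30-H1 / amarogentin ({plates.shape[0]} wells over 6 days):")
print(f"  activation threshold : {fit.threshold_conc:.1e} M")
print(f"  EC50                 : {fit.ec50:.2e} M")
print(f"  maximal amplitude    : {fit.amplitude:.2f} dF/F")
print(f"  Hill coefficient     : {fit.hill_n:.2f}")
print("The threshold is the first concentration significantly above the")
print("empty-vector control; EC50/amplitude come from the Hill fit to the")
print("corrected mean responses (generating values 1.0e-8 M / 4.1e-7 M / 0.50).")
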