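"""Genotype-phenotype association and the causal-vs-linkage verdict.

Runs block-level mixed-model scans for an amarogentin-style (single causal
locus) and an absinthin-style (repulsion-phase) phenotype, then combines
association, the receptor responsiveness inventory and in-vitro allele
classes into per-gene causal calls.
"""
import numpy as np
import pandas as pd

import bittermap as bm

scenario = bm.default_scenario(seed=1)
cohort = bm.sample_cohort(scenario, 48, seed=1)


def phenotype(compound, seed):
    lat = bm.latent_sensitivity(cohort, [compound], seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for r in lat.itertuples():
        for rep in (1, 2, 3):
            rows.append({"subject": r.subject, "repetition": rep,
                         "recognition": 10 ** (r.latent_log10_threshold + rng.normal(0, 0.05))})
    return pd.DataFrame(rows)


def function_table(compound, subj_range):
    fits = [bm.DoseResponseFit(a, compound, p.ec50 or np.nan, p.amplitude, p.hill_n,
                               p.activation_threshold, p.activation_threshold is not None,
                               0.0, True)
            for (a, c), p in scenario.receptor_table.items() if c == compound]
    return bm.classify_alleles(fits, subj_range)


block_genes = {b.block_id: b.gene_names for b in scenario.blocks}
for compound, subj_range in [("amarogentin", (1.2e-8, 2.0e-7)), ("absinthin", (5.2e-8, 2.0e-6))]:
    pheno = phenotype(compound, seed=1)
    res = bm.scan(pheno, cohort.block_phases, level="block", measures=("recognition",))
    res = [r for r in res if r.skipped_reason is None]
    best = min(res, key=lambda r: r.p)
    print(f"\n{compound}: best block {best.unit}, p = {best.p:.2e}")
    table = function_table(compound, subj_range)
    report = bm.candidate_filter(res, scenario.inventory, table, block_genes, compound)
    print(report[report["classification"] != "not_implicated"][
        ["gene", "classification"]].to_string(index=False))
    if compound == "absinthin":
        summary = bm.phase_summary(cohort.block_phases, "TAS2R31-42", table, compound)
        print(f"phase mode: {summary.phase_mode}; "
              f"two-sensitive-copy subjects: {100 * summary.dosage_fractions.get(2, 0):.0f}%")

print("\nAmarogentin: the causal gene separates from its linked passengers.")
print("Absinthin: repulsion-phase haplotypes give everyone two sensitive copies,")
print("masking association despite real functional variation (phase_masked).")
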