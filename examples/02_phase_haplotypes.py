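"""Phase a gene's coding SNPs by EM and compare to the simulated truth.

The EM maximises the multinomial haplotype-frequency likelihood under
random mating and reports each subject's maximum-posterior diplotype;
haplotypes are named by descending frequency (H1 = most common).
"""
import bittermap as bm

scenario = bm.default_scenario(seed=1)
cohort = bm.sample_cohort(scenario, 48, seed=1)

sites = [s for s in cohort.genotypes.sites if s.startswith("TAS2R46")]
geno = cohort.genotypes.subset_sites(sites)
hset, phases = bm.phase_em(geno, "TAS2R46", seed=1)

print("Inferred TAS2R46 haplotypes:")
for i in range(len(hset.haplotypes)):
    print(f"  {hset.name_of(i):4s} alleles={hset.haplotypes[i]} f={hset.frequencies[i]:.3f}")

truth_sp = cohort.gene_phases.scopes["TAS2R46"]
truth = [tuple(truth_sp.haplotype_set.haplotypes[i] for i in p) for p in truth_sp.pairs]
err = bm.diplotype_error_rate(phases, truth)
print(f"\nDiplotype reconstruction error vs simulated truth: {100 * err:.1f}%")
print(f"Mean phase posterior: {phases.posterior.mean():.3f}")
print("A low error and high posterior mean the two-site gene phases almost")
print("deterministically at these haplotype frequencies.")
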