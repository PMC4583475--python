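"""Mixed-model association: oracle identities, calibration, thresholds."""
import numpy as np
import pandas as pd
import pytest

import bittermap as bm


def make_balanced(n_per_class=6, reps=3, delta=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for c, cls in enumerate(["AA", "AB"]):
        for s in range(n_per_class):
            subj = f"{cls}_{s}"
            mu = rng.normal(c * delta, 0.3)
            for _ in range(reps):
                rows.append((mu + rng.normal(0, 0.1), subj, cls))
    y, subj, geno = map(np.array, zip(*rows))
    return y, subj, geno


class TestFitLMM:
    def test_balanced_equals_subject_means_anova(self):
        from scipy import stats

        y, subj, geno = make_balanced(delta=0.5, seed=1)
        res = bm.fit_lmm(y, subj, geno)
        means = pd.DataFrame({"y": y, "s": subj, "g": geno}).groupby(["g", "s"])["y"].mean()
        f, p = stats.f_oneway(means["AA"].to_numpy(), means["AB"].to_numpy())
        assert res.p == pytest.approx(p, abs=1e-6)
        assert res.f_stat == pytest.approx(f, rel=1e-6)

    def test_matches_statsmodels_nested_ols(self):
        """Independent route: the containment F equals MS(genotype) /
        MS(subject|genotype) from a statsmodels OLS type-I decomposition."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from scipy import stats

        y, subj, geno = make_balanced(delta=0.4, seed=2)
        within = np.array([s.split("_")[1] for s in subj])  # subject index within class
        df = pd.DataFrame({"y": y.astype(float), "geno": geno, "swg": within})
        fit = smf.ols("y ~ C(geno) + C(geno):C(swg)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=1)
        ms_g = tab.loc["C(geno)", "sum_sq"] / tab.loc["C(geno)", "df"]
        ms_s = tab.loc["C(geno):C(swg)", "sum_sq"] / tab.loc["C(geno):C(swg)", "df"]
        f = ms_g / ms_s
        p = stats.f.sf(
            f, int(tab.loc["C(geno)", "df"]), int(tab.loc["C(geno):C(swg)", "df"])
        )
        res = bm.fit_lmm(y, subj, geno)
        assert res.f_stat == pytest.approx(f, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_constant_phenotype_degenerate(self):
        y = np.zeros(12)
        subj = np.repeat([f"s{i}" for i in range(4)], 3)
        geno = np.repeat(["A", "A", "B", "B"], 3)
        res = bm.fit_lmm(y, subj, geno)
        assert res.degenerate and res.p == 1.0

    def test_null_type_one_error_calibrated(self):
        """Rejection rate at alpha = 0.05 stays within [0.03, 0.07] over
        1,000 null replicates."""
        rng = np.random.default_rng(20)
        rejections = 0
        n_rep = 1000
        subj = np.repeat([f"s{i}" for i in range(16)], 3)
        geno = np.repeat(["A"] * 8 + ["B"] * 8, 3)
        for _ in range(n_rep):
            mu = rng.normal(0, 0.3, 16)
            y = np.repeat(mu, 3) + rng.normal(0, 0.1, 48)
            if bm.fit_lmm(y, subj, geno).p <= 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


class TestBonferroni:
    def test_single_test_unchanged(self):
        assert bm.bonferroni([0.04], 1).tolist() == [True]

    def test_reject_and_fail_around_cutoff(self):
        assert bm.bonferroni([0.004, 0.006], 10).tolist() == [True, False]


def null_phenotypes(subjects, seed=0, reps=3):
    rng = np.random.default_rng(seed)
    rows = []
    for s in subjects:
        mu = rng.normal(-5, 0.3)
        for r in range(1, reps + 1):
            rows.append(
                {"subject": s, "repetition": r, "recognition": 10 ** (mu + rng.normal(0, 0.1))}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def independent_snp_cohort():
    """Ten unlinked biallelic genes at 50/50 frequency."""
    from bittermap.scenario import (
        BlockDef, LinkModel, LongRangeHaplotype, PlateDesign, PsychDesign,
        ReceptorParams, Scenario, _generic_gene,
    )

    blocks, pools = [], {}
    for i in range(10):
        g = _generic_gene(f"G{i}", "chr1", 2, 1_000 + 10_000 * i)
        blocks.append(BlockDef(f"G{i}", "chr1", [g]))
        pools[f"G{i}"] = [
            LongRangeHaplotype("LR1", 0.5, {f"G{i}": "H1"}),
            LongRangeHaplotype("LR2", 0.5, {f"G{i}": "H2"}),
        ]
    scn = Scenario(
        blocks, pools,
        {("G0-H1", "probe"): ReceptorParams(1e-6, 0.5, 1, 1e-6, "sensitive")},
        {"probe": LinkModel()},
        PsychDesign(starts={"probe": 1e-7}),
        PlateDesign(),
    )
    return bm.sample_cohort(scn, 48, seed=2)


class TestExperimentwideThreshold:
    def test_independent_snps_match_sidak_closed_form(self, independent_snp_cohort):
        co = independent_snp_cohort
        pheno = null_phenotypes(co.subjects, seed=3)
        cfg = bm.ScanConfig(n_perm=4000, seed=4)
        alpha = bm.experimentwide_threshold(pheno, co.block_phases, co.genotypes, "recognition", cfg)
        sidak = 1 - 0.95 ** (1 / 10)
        assert alpha == pytest.approx(sidak, abs=0.0025)

    def test_duplicating_a_snp_leaves_threshold_unchanged(self, independent_snp_cohort):
        co = independent_snp_cohort
        pheno = null_phenotypes(co.subjects, seed=5)
        cfg = bm.ScanConfig(n_perm=2000, seed=6)
        a1 = bm.experimentwide_threshold(pheno, co.block_phases, co.genotypes, "recognition", cfg)
        g = co.genotypes
        dup = bm.GenotypeMatrix(
            g.subjects,
            g.sites + ["G0_s1_copy"],
            [row + [row[g.sites.index("G0_s1")]] for row in g.calls],
        )
        a2 = bm.experimentwide_threshold(pheno, co.block_phases, dup, "recognition", cfg)
        assert a2 == pytest.approx(a1, abs=0.002)

    def test_single_snp_threshold_near_alpha(self, independent_snp_cohort):
        co = independent_snp_cohort
        g = co.genotypes.subset_sites(["G0_s1"])
        pheno = null_phenotypes(co.subjects, seed=7)
        cfg = bm.ScanConfig(n_perm=3000, seed=8)
        alpha = bm.experimentwide_threshold(pheno, co.block_phases, g, "recognition", cfg)
        assert alpha == pytest.approx(0.05, abs=0.012)


class TestScan:
    def test_single_causal_locus_scenario(self, cohort48):
        """An amarogentin-style single-causal-gene scenario puts the minimum
        p at the causal gene's block, with linked in-block genes also
        significant."""
        lat = bm.latent_sensitivity(cohort48, ["amarogentin"], seed=1)
        rng = np.random.default_rng(1)
        rows = []
        for r in lat.itertuples():
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "subject": r.subject,
                        "repetition": rep,
                        "recognition": 10 ** (r.latent_log10_threshold + rng.normal(0, 0.05)),
                    }
                )
        pheno = pd.DataFrame(rows)
        block_res = bm.scan(pheno, cohort48.block_phases, level="block", measures=("recognition",))
        block_res = [r for r in block_res if r.skipped_reason is None]
        best = min(block_res, key=lambda r: r.p)
        assert best.unit == "TAS2R31-42"
        gene_res = bm.scan(pheno, cohort48.gene_phases, level="gene", measures=("recognition",))
        by_gene = {r.unit: r for r in gene_res if r.skipped_reason is None}
        assert by_gene["TAS2R30"].p < 1e-6
        # linked passengers inside the block also reach nominal significance
        assert by_gene["TAS2R46"].significant_at_alpha
        assert by_gene["TAS2R43"].significant_at_alpha

    def test_disjoint_subjects_error(self, cohort48):
        pheno = pd.DataFrame(
            {"subject": ["X1"], "repetition": [1], "recognition": [1e-5]}
        )
        with pytest.raises(ValueError, match="intersect"):
            bm.scan(pheno, cohort48.block_phases, level="block", measures=("recognition",))

    def test_permuted_phenotypes_lose_signal(self, cohort48):
        lat = bm.latent_sensitivity(cohort48, ["amarogentin"], seed=1)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(lat))
        rows = []
        for latv, subj in zip(
            lat["latent_log10_threshold"].to_numpy()[perm], lat["subject"]
        ):
            for rep in (1, 2, 3):
                rows.append(
                    {"subject": subj, "repetition": rep, "recognition": 10 ** (latv + rng.normal(0, 0.05))}
                )
        pheno = pd.DataFrame(rows)
        res = bm.scan(pheno, cohort48.block_phases, level="block", measures=("recognition",))
        ps = [r.p for r in res if r.skipped_reason is None]
        assert min(ps) > 1e-4
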