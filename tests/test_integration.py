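"""Causal-vs-linkage integration: allele classes, phase summaries, filters."""
import numpy as np
import pandas as pd
import pytest

import bittermap as bm
from bittermap.invitro import DoseResponseFit


def fit(allele, compound, thr, ec50=1e-6, amp=0.5):
    return DoseResponseFit(
        allele=allele, compound=compound, ec50=ec50, amplitude=amp, hill_n=1.0,
        threshold_conc=thr, activated=thr is not None, rss=0.0, converged=True,
    )


AMARO_FITS = [
    fit("TAS2R30-H1", "amarogentin", 1.0e-8, 4.1e-7, 0.50),
    fit("TAS2R30-H2", "amarogentin", 3.0e-7, 3.9e-7, 0.12),
    fit("TAS2R43-H1", "amarogentin", 3.0e-4),
    fit("TAS2R43-H2", "amarogentin", 3.0e-4),
    fit("TAS2R46-H1", "amarogentin", 3.0e-5, 6.7e-5, 0.57),
    fit("TAS2R46-H3", "amarogentin", 1.0e-4),
    fit("TAS2R46-H2", "amarogentin", None),
]
AMARO_RANGE = (1.2e-8, 2.0e-7)  # printed recognition-threshold span


class TestClassifyAlleles:
    def test_explanatory_calls_match_subject_range(self):
        table = bm.classify_alleles(AMARO_FITS, AMARO_RANGE)
        df = table.frame.set_index("allele")
        assert df.loc["TAS2R30-H1", "explanatory"]       # 1e-8 <= 2e-7
        assert not df.loc["TAS2R46-H1", "explanatory"]   # 3e-5 > 2e-7
        assert df.loc["TAS2R46-H2", "class"] == "nonfunctional"

    def test_class_ordering_consistent_with_thresholds(self):
        table = bm.classify_alleles(AMARO_FITS, AMARO_RANGE)
        df = table.frame.set_index("allele")
        assert df.loc["TAS2R30-H1", "class"] == "sensitive"
        assert df.loc["TAS2R30-H2", "class"] == "intermediate"  # 30x best
        assert df.loc["TAS2R43-H1", "class"] == "insensitive"

    def test_missing_common_allele_raises_gap_report(self):
        with pytest.raises(bm.MissingFitError, match="TAS2R30-H2"):
            bm.classify_alleles(
                AMARO_FITS[:1],
                AMARO_RANGE,
                common_alleles={"TAS2R30": ["TAS2R30-H1", "TAS2R30-H2"]},
            )


def build_lrh_cohort(lrh_defs, pairs):
    """Cohort with explicit long-range haplotypes over TAS2R30/TAS2R46."""
    genes = ["TAS2R30", "TAS2R46"]
    haps = [tuple(d) for d in lrh_defs]
    freqs = np.zeros(len(haps))
    for a, b in pairs:
        freqs[a] += 1
        freqs[b] += 1
    hset = bm.name_haplotypes(
        bm.HaplotypeSet("TAS2R31-42", genes, haps, freqs / freqs.sum()), prefix="H-LR"
    )
    sp = bm.ScopePhase(hset, list(pairs), np.ones(len(pairs)))
    subjects = [f"S{i}" for i in range(len(pairs))]
    return bm.PhasedCohort(subjects, {"TAS2R31-42": sp})


ABSINTHIN_TABLE = bm.ReceptorFunctionTable(
    pd.DataFrame(
        [
            {"allele": "TAS2R30-H1", "gene": "TAS2R30", "compound": "absinthin",
             "class": "sensitive", "threshold_conc": 3e-7, "ec50": 3.1e-6,
             "amplitude": 0.41, "explanatory": True},
            {"allele": "TAS2R30-H2", "gene": "TAS2R30", "compound": "absinthin",
             "class": "insensitive", "threshold_conc": 1e-6, "ec50": 1.3e-6,
             "amplitude": 0.15, "explanatory": True},
            {"allele": "TAS2R46-H1", "gene": "TAS2R46", "compound": "absinthin",
             "class": "sensitive", "threshold_conc": 3e-6, "ec50": 1.1e-5,
             "amplitude": 0.63, "explanatory": True},
            {"allele": "TAS2R46-H2", "gene": "TAS2R46", "compound": "absinthin",
             "class": "nonfunctional", "threshold_conc": None, "ec50": np.nan,
             "amplitude": 0.0, "explanatory": False},
            {"allele": "TAS2R46-H3", "gene": "TAS2R46", "compound": "absinthin",
             "class": "intermediate", "threshold_conc": 1e-5, "ec50": 1.4e-5,
             "amplitude": 0.48, "explanatory": True},
        ]
    )
)


class TestPhaseSummary:
    def test_repulsion_phase_all_subjects_carry_two_sensitive_copies(self):
        """With only the four common TAS2R31-42 haplotypes present, every
        diplotype carries exactly two sensitive copies and the mode is
        repulsion — the masking pattern behind the absent absinthin
        association."""
        lrhs = [
            ("H1", "H2"),  # 30-H1 sensitive, 46 truncated
            ("H2", "H1"),  # 46-H1 sensitive
            ("H1", "H3"),  # 30-H1 sensitive
            ("H2", "H1"),  # 46-H1 sensitive (second carrier haplotype)
        ]
        import itertools

        pairs = list(itertools.combinations_with_replacement(range(4), 2))
        cohort = build_lrh_cohort(lrhs, pairs)
        summary = bm.phase_summary(cohort, "TAS2R31-42", ABSINTHIN_TABLE, "absinthin")
        assert summary.phase_mode == "repulsion"
        assert summary.dosage_fractions == {2: 1.0}

    def test_coupling_phase_for_co_resident_sensitive_alleles(self):
        table = bm.ReceptorFunctionTable(
            pd.DataFrame(
                [
                    {"allele": "TAS2R30-H1", "gene": "TAS2R30", "compound": "c",
                     "class": "sensitive", "threshold_conc": 1e-6, "ec50": 1e-6,
                     "amplitude": 0.5, "explanatory": True},
                    {"allele": "TAS2R46-H1", "gene": "TAS2R46", "compound": "c",
                     "class": "sensitive", "threshold_conc": 1e-6, "ec50": 1e-6,
                     "amplitude": 0.5, "explanatory": True},
                ]
            )
        )
        lrhs = [("H1", "H1"), ("H2", "H2")]
        pairs = [(0, 0), (0, 1), (1, 1), (0, 1)]
        cohort = build_lrh_cohort(lrhs, pairs)
        summary = bm.phase_summary(cohort, "TAS2R31-42", table, "c")
        assert summary.phase_mode == "coupling"
        assert summary.dosage_fractions[0] == pytest.approx(0.25)

    def test_single_locus_mode(self):
        table = bm.ReceptorFunctionTable(
            pd.DataFrame(
                [
                    {"allele": "TAS2R30-H1", "gene": "TAS2R30", "compound": "c",
                     "class": "sensitive", "threshold_conc": 1e-6, "ec50": 1e-6,
                     "amplitude": 0.5, "explanatory": True},
                ]
            )
        )
        cohort = build_lrh_cohort([("H1", "H1"), ("H2", "H1")], [(0, 1), (0, 0)])
        summary = bm.phase_summary(cohort, "TAS2R31-42", table, "c")
        assert summary.phase_mode == "single_locus"

    def test_dosage_conserved(self, cohort48):
        summary = bm.phase_summary(
            cohort48.block_phases, "TAS2R31-42", ABSINTHIN_TABLE, "absinthin"
        )
        assert set(summary.per_subject_dosage) <= {0, 1, 2}
        assert sum(summary.dosage_fractions.values()) == pytest.approx(1.0)


class TestPhaseModesFromPrintedParameters:
    """Phase modes derived end-to-end from the published receptor
    parameters of the default scenario."""

    @staticmethod
    def table_for(scenario, compound, subj_range):
        fits = [
            bm.DoseResponseFit(
                a, compound, p.ec50 or np.nan, p.amplitude, p.hill_n,
                p.activation_threshold, p.activation_threshold is not None, 0.0, True,
            )
            for (a, c), p in scenario.receptor_table.items()
            if c == compound
        ]
        return bm.classify_alleles(fits, subj_range)

    def test_absinthin_is_repulsion_with_saturated_dosage(self, cohort48):
        table = self.table_for(cohort48.scenario, "absinthin", (5.2e-8, 2.0e-6))
        summary = bm.phase_summary(cohort48.block_phases, "TAS2R31-42", table, "absinthin")
        assert summary.phase_mode == "repulsion"
        # nearly all subjects carry exactly two sensitive copies (the
        # published pattern: 96% two copies, remainder from rare haplotypes)
        assert summary.dosage_fractions.get(2, 0.0) >= 0.9

    def test_grosheimin_is_coupling_with_spread_dosage(self, cohort48):
        table = self.table_for(cohort48.scenario, "grosheimin", (2.0e-6, 5.0e-5))
        summary = bm.phase_summary(cohort48.block_phases, "TAS2R31-42", table, "grosheimin")
        assert summary.phase_mode == "coupling"
        assert set(summary.dosage_fractions) >= {0, 2}


def assoc(level, unit, p, ew):
    return bm.AssociationResult(level, unit, "weak", 2, {}, p, p <= 0.05, ew)


class TestCandidateFilter:
    BLOCK_GENES = {"TAS2R31-42": ["TAS2R31", "TAS2R46", "TAS2R43", "TAS2R45", "TAS2R30", "TAS2R42"]}

    def test_amarogentin_pattern_causal_and_passengers(self):
        table = bm.classify_alleles(AMARO_FITS, AMARO_RANGE)
        results = [assoc("block", "TAS2R31-42", 1e-6, True)]
        report = bm.candidate_filter(
            results,
            {"amarogentin": ("TAS2R43", "TAS2R46", "TAS2R30")},
            table,
            self.BLOCK_GENES,
            "amarogentin",
        ).set_index("gene")
        assert report.loc["TAS2R30", "classification"] == "causal"
        assert report.loc["TAS2R43", "classification"] == "linked_passenger"
        assert report.loc["TAS2R46", "classification"] == "linked_passenger"

    def test_absinthin_pattern_phase_masked(self):
        results = [assoc("block", "TAS2R31-42", 0.2, False)]
        report = bm.candidate_filter(
            results,
            {"absinthin": ("TAS2R30", "TAS2R46")},
            ABSINTHIN_TABLE,
            self.BLOCK_GENES,
            "absinthin",
        ).set_index("gene")
        assert report.loc["TAS2R30", "classification"] == "phase_masked"
        assert report.loc["TAS2R46", "classification"] == "phase_masked"

    def test_empty_inventory_leaves_blocks_unexplained(self):
        table = bm.classify_alleles(AMARO_FITS, AMARO_RANGE)
        results = [assoc("block", "TAS2R31-42", 1e-6, True)]
        report = bm.candidate_filter(results, {}, table, self.BLOCK_GENES, "amarogentin")
        assert (report["classification"] == "unexplained").all()

    def test_report_is_pure_function(self):
        table = bm.classify_alleles(AMARO_FITS, AMARO_RANGE)
        results = [assoc("block", "TAS2R31-42", 1e-6, True)]
        args = (results, {"amarogentin": ("TAS2R30",)}, table, self.BLOCK_GENES, "amarogentin")
        assert bm.candidate_filter(*args).equals(bm.candidate_filter(*args))


class TestPhaseContrast:
    def test_repulsion_masks_association_relative_to_coupling(self):
        """Identical allele effects, opposite linkage arrangement: the
        repulsion cohort's best SNP p-value is weaker than the coupling
        cohort's in nearly all paired replicates."""
        wins = 0
        n_pairs = 20
        for seed in range(n_pairs):
            ps = {}
            for phase in ("coupling", "repulsion"):
                scn = bm.two_locus_scenario(phase, seed=seed)
                co = bm.sample_cohort(scn, 48, seed=seed)
                lat = bm.latent_sensitivity(co, ["probe"], seed=seed)
                rng = np.random.default_rng(1000 + seed)
                rows = []
                for r in lat.itertuples():
                    for rep in (1, 2, 3):
                        rows.append(
                            {"subject": r.subject, "repetition": rep,
                             "recognition": 10 ** (r.latent_log10_threshold + rng.normal(0, 0.05))}
                        )
                res = bm.scan(
                    pd.DataFrame(rows), co.block_phases, level="snp",
                    genotypes=co.genotypes, measures=("recognition",),
                )
                ps[phase] = min(
                    [r.p for r in res if r.skipped_reason is None], default=1.0
                )
            wins += ps["repulsion"] > ps["coupling"]
        assert wins >= 18
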