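"""Linkage disequilibrium measures and four-gamete block partitioning."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bittermap as bm
from conftest import gene_chrom_matrix


class TestPairwiseLD:
    def test_complete_ld(self):
        res = bm.pairwise_ld(np.array([[50, 0], [0, 50]]))
        assert res.d_prime == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # counts exactly proportional to marginal products
        res = bm.pairwise_ld(np.array([[36, 24], [24, 16]]))
        assert res.d_prime == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_biallelic_closed_form_oracle(self):
        counts = np.array([[40, 10], [10, 40]])
        n = counts.sum()
        p_a, p_b = 50 / n, 50 / n
        p_ab = 40 / n
        d = p_ab - p_a * p_b
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        r = d / np.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
        res = bm.pairwise_ld(counts)
        assert res.d_prime == pytest.approx(abs(d) / d_max)
        assert res.r2 == pytest.approx(r**2)

    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=2, max_size=4),
            min_size=2,
            max_size=4,
        ).filter(
            lambda rows: len({len(r) for r in rows}) == 1 and sum(map(sum, rows)) > 0
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_measures_bounded(self, rows):
        res = bm.pairwise_ld(np.array(rows), n_mc=200)
        assert 0 <= res.d_prime <= 1 and 0 <= res.r2 <= 1 and 0 < res.p <= 1

    def test_three_gametes_give_dprime_one(self):
        res = bm.pairwise_ld(np.array([[30, 10], [20, 0]]))
        assert res.d_prime == pytest.approx(1.0)

    def test_biallelic_r2_bounded_by_dprime_squared(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 30, size=(2, 2))
            if counts.sum() == 0 or (counts.sum(0) > 0).sum() < 2 or (counts.sum(1) > 0).sum() < 2:
                continue
            res = bm.pairwise_ld(counts, n_mc=100)
            assert res.r2 <= res.d_prime**2 + 1e-9


class TestLDMatrix:
    def test_duplicated_site_has_complete_ld(self):
        haps = [("A", "A"), ("G", "G")]  # site two duplicates site one
        hset = bm.name_haplotypes(bm.HaplotypeSet("g", ["s1", "s2"], haps, [0.5, 0.5]))
        pairs = [(0, 0), (0, 1), (1, 1), (0, 1), (1, 0), (0, 0)]
        cohort = bm.PhasedCohort(
            [f"S{i}" for i in range(6)],
            {"g": bm.ScopePhase(hset, pairs, np.ones(6))},
        )
        mats = bm.ld_matrix(cohort, level="snp", n_mc=200)
        assert mats["d_prime"].loc["s1", "s2"] == pytest.approx(1.0)
        assert mats["r2"].loc["s1", "s2"] == pytest.approx(1.0)

    def test_high_mean_ld_within_12p13(self, cohort48):
        """The proximal chromosome-12 cluster shows strong mean pairwise LD
        (the study region's hallmark: mean D' 0.66, r² 0.52 at 12p13)."""
        block_genes = [
            g.name for b in cohort48.scenario.blocks
            if b.block_id == "TAS2R31-42" for g in b.genes
        ]
        sites = [
            s for s in cohort48.genotypes.sites
            if any(s.startswith(g + "_") for g in block_genes)
        ]
        sub = bm.PhasedCohort(
            cohort48.subjects,
            {g: cohort48.gene_phases.scopes[g] for g in block_genes},
        )
        mats = bm.ld_matrix(sub, level="snp", n_mc=200)
        assert bm.mean_offdiagonal(mats["d_prime"]) > 0.56
        assert bm.mean_offdiagonal(mats["r2"]) > 0.3

    def test_permuted_labels_destroy_ld(self, cohort48):
        rng = np.random.default_rng(5)
        sp = cohort48.gene_phases.scopes["TAS2R30"]
        perm = rng.permutation(len(sp.pairs))
        shuffled = bm.ScopePhase(
            sp.haplotype_set, [sp.pairs[i] for i in perm], sp.posterior
        )
        sub = bm.PhasedCohort(
            cohort48.subjects,
            {"TAS2R30": shuffled, "TAS2R46": cohort48.gene_phases.scopes["TAS2R46"]},
        )
        mats = bm.ld_matrix(sub, level="gene", n_mc=500, seed=5)
        assert mats["r2"].loc["TAS2R30", "TAS2R46"] < 0.1


def brute_force_partition(chroms, units, cutoff=0.05):
    """Independent four-gamete oracle: recombination evidence from explicit
    gamete enumeration, maximal runs grown by direct checking."""
    cols = []
    for j in range(len(units)):
        vals, cnt = np.unique(chroms[:, j].astype(str), return_counts=True)
        major = vals[np.argmax(cnt)]
        cols.append((chroms[:, j].astype(str) != major).astype(int))

    def evidence(i, j):
        gametes = list(zip(cols[i], cols[j]))
        n = len(gametes)
        return all(
            gametes.count(g) / n >= cutoff - 1e-12
            for g in [(0, 0), (0, 1), (1, 0), (1, 1)]
        )

    blocks, lo = [], 0
    for j in range(1, len(units) + 1):
        if j == len(units):
            blocks.append((lo, j - 1))
        elif any(evidence(i, j) for i in range(lo, j)):
            blocks.append((lo, j - 1))
            lo = j
    return blocks


class TestFourGameteBlocks:
    def test_three_gametes_single_block(self):
        chroms = np.array([["A", "C"]] * 6 + [["G", "T"]] * 6 + [["A", "T"]] * 4)
        part = bm.four_gamete_blocks(chroms, ["u1", "u2"])
        assert part.blocks == [(0, 1)]

    def test_single_recombinant_pair_splits_once(self):
        """Four sites where only the middle pair shows all four common
        gametes: partition {1,2},{3,4}."""
        h = [
            (0, 0, 0, 0),
            (0, 0, 1, 1),
            (1, 1, 0, 0),
            (1, 1, 1, 1),
        ]
        chroms = np.array(h * 5)
        part = bm.four_gamete_blocks(chroms, ["a", "b", "c", "d"])
        assert part.members() == [["a", "b"], ["c", "d"]]
        assert part.blocks == brute_force_partition(chroms, ["a", "b", "c", "d"])

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        units = [f"u{j}" for j in range(6)]
        for _ in range(30):
            haps = rng.integers(0, 2, size=(5, 6))
            freqs = rng.dirichlet(np.ones(5))
            draws = rng.choice(5, size=200, p=freqs)
            chroms = haps[draws]
            part = bm.four_gamete_blocks(chroms, units)
            assert part.blocks == brute_force_partition(chroms, units)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(3)
        chroms = rng.integers(0, 2, size=(100, 5))
        units = list("abcde")
        fwd = bm.four_gamete_blocks(chroms, units)
        rev = bm.four_gamete_blocks(chroms[:, ::-1], units[::-1])
        fwd_members = [tuple(m) for m in fwd.members()]
        rev_members = [tuple(reversed(m)) for m in reversed(rev.members())]
        assert fwd_members == rev_members

    def test_raising_cutoff_never_adds_boundaries(self):
        rng = np.random.default_rng(8)
        chroms = rng.integers(0, 2, size=(120, 6))
        units = [f"u{j}" for j in range(6)]
        n_blocks = [
            len(bm.four_gamete_blocks(chroms, units, cutoff=c).blocks)
            for c in (0.02, 0.05, 0.10, 0.20)
        ]
        assert n_blocks == sorted(n_blocks, reverse=True)

    def test_default_scenario_recovers_six_multigene_blocks(self, cohort_big):
        """Gene-level four-gamete partition of the default scenario yields
        the six multi-gene blocks of the receptor clusters."""
        scenario = cohort_big.scenario
        expected = {
            "chr7": [["TAS2R3", "TAS2R4", "TAS2R5"], ["TAS2R39", "TAS2R40", "TAS2R60"]],
            "chr12": [
                ["TAS2R7", "TAS2R8", "TAS2R9", "TAS2R10"],
                ["TAS2R13", "TAS2R14"],
                ["TAS2R50", "TAS2R20", "TAS2R19"],
                ["TAS2R31", "TAS2R46", "TAS2R43", "TAS2R45", "TAS2R30", "TAS2R42"],
            ],
        }
        found = []
        for chrom in ("chr7", "chr12"):
            genes = [
                g.name for b in scenario.blocks if b.chrom == chrom for g in b.genes
            ]
            chroms = gene_chrom_matrix(cohort_big, genes)
            part = bm.four_gamete_blocks(chroms, genes)
            found.extend(m for m in part.members() if len(m) > 1)
        assert found == expected["chr7"] + expected["chr12"]

    def test_manual_overrides_win(self):
        chroms = np.array(
            [(0, 0, 0), (0, 1, 1), (1, 0, 0), (1, 1, 0), (1, 1, 1), (0, 0, 1)] * 20
        )
        units = ["a", "b", "c"]
        part = bm.four_gamete_blocks(chroms, units, overrides={"b": 99, "c": 99})
        assert part.members() == [["a"], ["b", "c"]]
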