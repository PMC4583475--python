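import numpy as np
import pytest

import bittermap as bm


@pytest.fixture(scope="session")
def scenario():
    return bm.default_scenario(seed=1)


@pytest.fixture(scope="session")
def cohort48(scenario):
    """The study-sized cohort: 48 diploid subjects."""
    return bm.sample_cohort(scenario, 48, seed=1)


@pytest.fixture(scope="session")
def cohort_big(scenario):
    """A larger cohort for Monte-Carlo-stable structural checks."""
    return bm.sample_cohort(scenario, 200, seed=1)


@pytest.fixture(scope="session")
def grosheimin_phenotypes(cohort48):
    """Full simulated trial table + fitted phenotype table for grosheimin."""
    trials = bm.simulate_psychophysics(cohort48, ["grosheimin"], seed=1)
    pheno = bm.build_phenotype_table(trials)
    return trials, pheno


def gene_chrom_matrix(cohort, genes):
    """Chromosome x gene matrix of gene-haplotype names for given genes."""
    from bittermap.ld import _chromosome_columns

    names, chroms = _chromosome_columns(cohort.gene_phases, "gene")
    cols = [names.index(g) for g in genes]
    return chroms[:, cols]
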