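"""Synthetic cohort, psychophysics and plate-data generation.

`sample_cohort` draws two long-range haplotypes per subject and block
i.i.d. from the scenario pool (random mating), fills the residual pool mass
with rare haplotypes obtained by mutating a pool haplotype at one random
site, and derives gene haplotypes, SNP genotypes and copy numbers
deterministically from the drawn chromosomes.  Whole-gene deletion
haplotypes set copy number: one deleted chromosome makes a subject
hemizygous (single-allele genotype calls), two make the gene's sites
missing.

`simulate_psychophysics` generates the 4-AFC staircase: per concentration
step the probability of a correct choice is 0.25 + 0.75 F((log10 c - mu_d)
/ sigma_d), recognition is a yes/no Bernoulli with its own logistic curve,
and gLMS intensity is a saturating logistic plus truncated Gaussian noise
clipped to [0, 100].  The subject's latent recognition threshold comes from
the compound's link model applied to the best (lowest) activation threshold
among carried functional receptor alleles.

`simulate_plates` generates six-day calcium-imaging plates with per-well
baselines, multiplicative day gains, empty-vector and positive-control
wells, and receptor responses on a Hill curve.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import derive_rng
from .genotypes import DELETION, CopyNumberTable, GenotypeMatrix, SiteTable
from .invitro import EMPTY_VECTOR, POSITIVE_CONTROL, hill
from .phasing import HaplotypeSet, PhasedCohort, ScopePhase, name_haplotypes
from .psychometrics import geometric_series
from .scenario import Scenario


@dataclass
class SimulatedCohort:
    """A sampled cohort with full phased truth at block and gene scope."""

    scenario: Scenario
    subjects: list[str]
    block_phases: PhasedCohort
    gene_phases: PhasedCohort
    genotypes: GenotypeMatrix
    copy_number: CopyNumberTable
    site_table: SiteTable

    def carried_alleles(self, subject: str) -> set[str]:
        """Gene-level allele ids ('TAS2R30-H1') on either chromosome,
        excluding deletions."""
        i = self.subjects.index(subject)
        out = set()
        for gene, sp in self.gene_phases.scopes.items():
            pair = sp.pairs[i]
            if pair is None:
                continue
            for h in pair:
                name = sp.haplotype_set.name_of(h)
                if name != DELETION:
                    out.add(f"{gene}-{name}")
        return out


def _site_table(scenario: Scenario) -> SiteTable:
    rows = []
    for block in scenario.blocks:
        for gene in block.genes:
            for s in gene.sites:
                rows.append(
                    {
                        "site_id": s.site_id,
                        "chrom": gene.chrom,
                        "pos": s.pos,
                        "gene": gene.name,
                        "ref": s.ref,
                        "alt": s.alt,
                        "consequence": s.consequence,
                    }
                )
    columns = ["site_id", "chrom", "pos", "gene", "ref", "alt", "consequence"]
    frame = pd.DataFrame(rows, columns=columns).sort_values(
        ["chrom", "pos"], kind="stable"
    )
    return SiteTable(frame.reset_index(drop=True))


def sample_cohort(scenario: Scenario, n_subjects: int = 48, seed: int | None = None) -> SimulatedCohort:
    """Draw a random-mating cohort of ``n_subjects`` diploid subjects."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seed = scenario.seed if seed is None else seed
    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    site_table = _site_table(scenario)

    # chromosome draws per block: each chromosome is a dict gene -> (hap name, allele vector)
    block_chroms: dict[str, list[list[dict]]] = {}
    rare_names: dict[str, dict[tuple, str]] = {g.name: {} for g in scenario.genes}

    for block in scenario.blocks:
        pool = scenario.lrh_pools[block.block_id]
        freqs = np.array([h.frequency for h in pool])
        p_rare = max(0.0, 1.0 - freqs.sum())
        probs = np.append(freqs, p_rare)
        rng = derive_rng(seed, "cohort", block.block_id)
        draws = rng.choice(len(pool) + 1, size=(n_subjects, 2), p=probs / probs.sum())
        mutable = [g for g in block.genes if g.sites]
        chroms: list[list[dict]] = []
        for i in range(n_subjects):
            pair = []
            for c in range(2):
                k = draws[i, c]
                if k < len(pool):
                    src = pool[k]
                else:  # rare haplotype: mutate a pool haplotype at one random site
                    src = pool[rng.choice(len(pool), p=freqs / freqs.sum())]
                chrom = {}
                for gene in block.genes:
                    hap = src.gene_haps[gene.name]
                    chrom[gene.name] = (hap, gene.hap_vector(hap))
                if k == len(pool) and mutable:
                    # mutate a site of a gene actually present on this
                    # chromosome (a deleted gene has no sequence to mutate)
                    present = [g for g in mutable if chrom[g.name][0] != DELETION]
                    if present:
                        gene = present[rng.integers(len(present))]
                        hap, vec = chrom[gene.name]
                        j = rng.integers(len(gene.sites))
                        site = gene.sites[j]
                        vec = list(vec)
                        vec[j] = site.alt if vec[j] == site.ref else site.ref
                        vec = tuple(vec)
                        name = gene.name_of_vector(vec)
                        if name is None:
                            reg = rare_names[gene.name]
                            if vec not in reg:
                                reg[vec] = f"r{len(reg) + 1}"
                            name = reg[vec]
                        chrom[gene.name] = (name, vec)
                pair.append(chrom)
            chroms.append(pair)
        block_chroms[block.block_id] = chroms

    # block-scope truth phases (alleles = gene haplotype names)
    block_scopes: dict[str, ScopePhase] = {}
    for block in scenario.blocks:
        chroms = block_chroms[block.block_id]
        vectors = []
        for pair in chroms:
            for chrom in pair:
                vectors.append(tuple(chrom[g][0] for g in block.gene_names))
        uniq = sorted(set(vectors))
        index = {v: i for i, v in enumerate(uniq)}
        counts = np.zeros(len(uniq))
        for v in vectors:
            counts[index[v]] += 1
        hset = name_haplotypes(
            HaplotypeSet(block.block_id, list(block.gene_names), uniq, counts / counts.sum()),
            prefix="H-LR",
        )
        pairs = [
            (index[tuple(pair[0][g][0] for g in block.gene_names)],
             index[tuple(pair[1][g][0] for g in block.gene_names)])
            for pair in chroms
        ]
        block_scopes[block.block_id] = ScopePhase(hset, pairs, np.ones(n_subjects))

    # gene-scope truth phases (alleles = per-site alleles, designed names kept)
    gene_scopes: dict[str, ScopePhase] = {}
    for block in scenario.blocks:
        chroms = block_chroms[block.block_id]
        for gene in block.genes:
            names_vecs = {}
            for name, vec in [c[gene.name] for pair in chroms for c in pair]:
                names_vecs.setdefault(name, vec)
            uniq_names = sorted(names_vecs)
            index = {n: i for i, n in enumerate(uniq_names)}
            counts = np.zeros(len(uniq_names))
            for pair in chroms:
                for c in pair:
                    counts[index[c[gene.name][0]]] += 1
            hset = HaplotypeSet(
                gene.name,
                [s.site_id for s in gene.sites],
                [names_vecs[n] for n in uniq_names],
                counts / counts.sum(),
                names=list(uniq_names),
            )
            pairs = [
                (index[pair[0][gene.name][0]], index[pair[1][gene.name][0]])
                for pair in chroms
            ]
            gene_scopes[gene.name] = ScopePhase(hset, pairs, np.ones(n_subjects))

    # SNP genotypes + copy number, derived deterministically
    block_of_gene = {g.name: b.block_id for b in scenario.blocks for g in b.genes}
    site_meta = [
        (row.gene, block_of_gene[row.gene],
         [s.site_id for s in scenario.gene(row.gene).sites].index(row.site_id))
        for row in site_table.frame.itertuples()
    ]
    calls = []
    cn_rows = []
    cnv_genes = tuple(g.name for g in scenario.genes if g.cnv_capable)
    for i, subj in enumerate(subjects):
        row = []
        for gene_name, block_id, j in site_meta:
            pair = block_chroms[block_id][i]
            alleles = [c[gene_name][1][j] for c in pair]
            alleles = [a for a in alleles if a != DELETION]
            row.append(tuple(sorted(alleles)) if alleles else None)
        calls.append(row)
        for gene_name in cnv_genes:
            pair = block_chroms[block_of_gene[gene_name]][i]
            copies = sum(1 for c in pair if c[gene_name][0] != DELETION)
            cn_rows.append({"subject": subj, "gene": gene_name, "copies": copies})

    return SimulatedCohort(
        scenario=scenario,
        subjects=subjects,
        block_phases=PhasedCohort(subjects, block_scopes),
        gene_phases=PhasedCohort(subjects, gene_scopes),
        genotypes=GenotypeMatrix(subjects, site_table.site_ids, calls),
        copy_number=CopyNumberTable(
            pd.DataFrame(cn_rows, columns=["subject", "gene", "copies"]), cnv_genes
        ),
        site_table=site_table,
    )


def latent_sensitivity(
    cohort: SimulatedCohort, compounds: list[str] | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Latent log10 recognition threshold per subject and compound.

    The deterministic part is the link model applied to the best carried
    activation threshold; subject-level noise N(0, subject_sd) is added from
    a stream keyed by (seed, compound).
    """
    scenario = cohort.scenario
    seed = scenario.seed if seed is None else seed
    compounds = compounds or scenario.compounds
    rows = []
    for compound in compounds:
        link = scenario.links[compound]
        rng = derive_rng(seed, "latent", compound)
        noise = rng.normal(0.0, link.subject_sd, size=len(cohort.subjects))
        for i, subj in enumerate(cohort.subjects):
            thresholds = [
                p.activation_threshold
                for allele in cohort.carried_alleles(subj)
                if (p := scenario.receptor_params(allele, compound)) is not None
                and p.activation_threshold is not None
            ]
            best = min(thresholds) if thresholds else link.nonresponder_threshold
            latent = link.offset + link.slope * np.log10(best) + noise[i]
            rows.append(
                {
                    "subject": subj,
                    "compound": compound,
                    "best_activation_threshold": best,
                    "latent_log10_threshold": latent,
                }
            )
    return pd.DataFrame(rows)


def simulate_psychophysics(
    cohort: SimulatedCohort,
    compounds: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the full 4-AFC / recognition / gLMS trial table."""
    scenario = cohort.scenario
    seed = scenario.seed if seed is None else seed
    design = scenario.psych
    compounds = compounds or scenario.compounds
    latent = latent_sensitivity(cohort, compounds, seed=seed)
    latent_map = {
        (r.subject, r.compound): r.latent_log10_threshold for r in latent.itertuples()
    }
    rows = []
    for compound in compounds:
        link = scenario.links[compound]
        series = geometric_series(design.starts[compound], design.ratio, design.n_steps)
        x = np.log10(series)
        rng = derive_rng(seed, "psychophysics", compound)
        for subj in cohort.subjects:
            mu_rec = latent_map[(subj, compound)]
            mu_det = mu_rec - link.detection_shift
            imax = float(np.clip(rng.normal(design.imax_mean, design.imax_sd), 60.0, 100.0))
            mu_int = mu_rec + design.intensity_shift
            for rep in range(1, design.n_repetitions + 1):
                p_correct = design.guess_rate + (1 - design.guess_rate) * expit(
                    (x - mu_det) / design.detection_sigma
                )
                p_yes = expit((x - mu_rec) / design.recognition_sigma)
                correct = rng.random(design.n_steps) < p_correct
                recognized = rng.random(design.n_steps) < p_yes
                inten = imax * expit((x - mu_int) / design.intensity_sigma)
                inten = np.clip(
                    inten + rng.normal(0.0, design.intensity_noise_sd, design.n_steps),
                    0.0,
                    100.0,
                )
                for k in range(design.n_steps):
                    rec: float | None
                    if design.recognition_mode == "chosen" and not correct[k]:
                        rec = np.nan
                    else:
                        rec = int(recognized[k])
                    rows.append(
                        {
                            "subject": subj,
                            "compound": compound,
                            "repetition": rep,
                            "step": k + 1,
                            "conc": series[k],
                            "correct_4afc": int(correct[k]),
                            "recognized": rec,
                            "intensity": inten[k],
                        }
                    )
    return pd.DataFrame(rows)


def simulate_plates(
    scenario: Scenario,
    compounds: list[str] | None = None,
    alleles: list[str] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate raw calcium-imaging plates for every (allele, compound) pair
    in the receptor table (optionally restricted)."""
    if not scenario.receptor_table:
        raise ValueError("scenario has an empty receptor table")
    seed = scenario.seed if seed is None else seed
    design = scenario.plate
    pairs = sorted(scenario.receptor_table)
    if compounds is not None:
        pairs = [p for p in pairs if p[1] in compounds]
    if alleles is not None:
        pairs = [p for p in pairs if p[0] in alleles]
    by_compound: dict[str, list[str]] = {}
    for allele, compound in pairs:
        by_compound.setdefault(compound, []).append(allele)

    def artefact(conc: float) -> float:
        return design.artefact_slope * max(0.0, np.log10(conc / design.artefact_onset))

    rows = []
    well = 0
    for compound, allele_list in sorted(by_compound.items()):
        rng = derive_rng(seed, "plates", compound)
        for day in range(1, design.n_days + 1):
            day_gain = max(0.2, rng.normal(1.0, design.day_sd))

            def add_well(construct: str, conc: float, response: float) -> None:
                nonlocal well
                well += 1
                f0 = design.f0_mean * rng.lognormal(0.0, design.f0_cv)
                eps = rng.normal(0.0, design.noise_sd)
                rows.append(
                    {
                        "day": day,
                        "plate": day,
                        "well": f"W{well:05d}",
                        "construct": construct,
                        "compound": compound,
                        "conc": conc,
                        "F": f0 * (1.0 + day_gain * response + eps),
                        "F0": f0,
                    }
                )

            for conc in design.concentrations:
                for allele in allele_list:
                    params = scenario.receptor_table[(allele, compound)]
                    resp = artefact(conc)
                    # receptor signal rises along the Hill curve once the
                    # activation threshold is crossed; below it the evoked
                    # calcium signal stays within baseline
                    if params.amplitude > 0 and params.ec50 is not None and (
                        params.activation_threshold is None
                        or conc >= params.activation_threshold * (1 - 1e-9)
                    ):
                        resp += hill(conc, params.ec50, params.amplitude, params.hill_n)
                    add_well(allele, float(conc), float(resp))
                for _ in range(design.n_empty_per_group):
                    add_well(EMPTY_VECTOR, float(conc), artefact(conc))
            for _ in range(design.n_pc_per_day):
                add_well(POSITIVE_CONTROL, np.nan, design.pc_amplitude)
    return pd.DataFrame(rows)
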