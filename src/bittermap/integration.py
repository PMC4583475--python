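"""Integrating association, receptor function and linkage phase.

Association scans alone cannot separate causal receptor alleles from
passengers riding the same long-range haplotypes.  This module implements
the decision logic that combines three evidence layers:

* which blocks/genes reach experiment-wide association significance;
* which receptors respond to the compound at all (an independently
  published responsiveness inventory, shipped as an editable table);
* which alleles are activated in vitro at concentrations low enough to
  explain the subjects' perceptual thresholds ("phenotype-explanatory").

Loci where all three intersect are called causal; responsive loci inside a
significant block whose alleles activate only far above subject thresholds
are linked passengers; responsive, explanatory loci that nonetheless show
no association are phase-masked — the repulsion-phase signature where every
common long-range haplotype carries a sensitive allele of at least one
locus, so genotype classes do not separate phenotypically.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationResult
from .genotypes import DELETION
from .invitro import DoseResponseFit
from .phasing import PhasedCohort


class MissingFitError(ValueError):
    """A common allele has no dose-response fit: the functional evidence is
    incomplete and the classification must not silently pass."""

    def __init__(self, missing: list[tuple[str, str]]):
        self.missing = missing
        super().__init__(f"no dose-response fit for common alleles: {missing}")


@dataclass
class ReceptorFunctionTable:
    """(allele, compound) -> functional class and fitted parameters.

    Classes are assigned within a compound by the ratio of an allele's
    activation threshold to the best (lowest) threshold observed: <= 3x
    best is 'sensitive', <= 30x 'intermediate', otherwise 'insensitive';
    alleles never activated are 'nonfunctional'.  An allele is
    phenotype-explanatory iff it activates at or below the top of the
    subjects' recognition-threshold range.
    """

    frame: pd.DataFrame  # allele, gene, compound, class, threshold_conc, ec50, amplitude, explanatory

    def alleles_of_class(self, compound: str, cls: str) -> list[str]:
        sel = self.frame[(self.frame["compound"] == compound) & (self.frame["class"] == cls)]
        return list(sel["allele"])

    def sensitive_alleles(self, compound: str) -> set[str]:
        return set(self.alleles_of_class(compound, "sensitive"))

    def gene_sensitive_alleles(self, compound: str) -> set[str]:
        """Each gene's own high-sensitivity alleles (lowest-threshold class
        within the gene).  Falls back to the compound-global 'sensitive'
        class when the per-gene column is absent (hand-built tables)."""
        sel = self.frame[self.frame["compound"] == compound]
        if "gene_sensitive" in sel.columns and sel["gene_sensitive"].notna().any():
            return set(sel[sel["gene_sensitive"].fillna(False)]["allele"])
        return self.sensitive_alleles(compound)

    def classify(self, allele: str, compound: str) -> str:
        sel = self.frame[(self.frame["allele"] == allele) & (self.frame["compound"] == compound)]
        if sel.empty:
            raise KeyError((allele, compound))
        return str(sel["class"].iloc[0])


def classify_alleles(
    fits: list[DoseResponseFit],
    subject_threshold_range: tuple[float, float],
    common_alleles: dict[str, list[str]] | None = None,
    sensitive_ratio: float = 3.0,
    intermediate_ratio: float = 30.0,
) -> ReceptorFunctionTable:
    """Assign functional classes to dose-response fits.

    ``common_alleles``: gene -> allele ids expected to have fits (frequency
    >= 0.05 in the cohort); any gap raises MissingFitError.
    """
    have = {(f.allele, f.compound) for f in fits}
    if common_alleles:
        compounds = {f.compound for f in fits}
        missing = [
            (allele, compound)
            for compound in sorted(compounds)
            for alleles in common_alleles.values()
            for allele in alleles
            if (allele, compound) not in have
        ]
        if missing:
            raise MissingFitError(missing)
    lo, hi = subject_threshold_range
    rows = []
    for compound in sorted({f.compound for f in fits}):
        comp_fits = [f for f in fits if f.compound == compound]
        thresholds = [f.threshold_conc for f in comp_fits if f.activated and f.threshold_conc]
        best = min(thresholds) if thresholds else None
        # each gene's own best threshold, for the within-gene
        # high-sensitivity call used in linkage-phase summaries
        gene_best: dict[str, float] = {}
        for f in comp_fits:
            if f.activated and f.threshold_conc:
                g = f.allele.rsplit("-", 1)[0]
                gene_best[g] = min(gene_best.get(g, np.inf), f.threshold_conc)
        for f in comp_fits:
            gene = f.allele.rsplit("-", 1)[0]
            if not f.activated or f.threshold_conc is None:
                cls = "nonfunctional"
                explanatory = False
                gene_sensitive = False
            else:
                ratio = f.threshold_conc / best
                if ratio <= sensitive_ratio:
                    cls = "sensitive"
                elif ratio <= intermediate_ratio:
                    cls = "intermediate"
                else:
                    cls = "insensitive"
                explanatory = f.threshold_conc <= hi * (1 + 1e-9)
                gene_sensitive = f.threshold_conc <= sensitive_ratio * gene_best[gene]
            rows.append(
                {
                    "allele": f.allele,
                    "gene": gene,
                    "compound": compound,
                    "class": cls,
                    "gene_sensitive": gene_sensitive,
                    "threshold_conc": f.threshold_conc,
                    "ec50": f.ec50 if f.activated else np.nan,
                    "amplitude": f.amplitude if f.activated else 0.0,
                    "explanatory": explanatory,
                }
            )
    return ReceptorFunctionTable(pd.DataFrame(rows))


@dataclass
class PhaseSummary:
    compound: str
    block_id: str
    genes: list[str]  # genes carrying sensitive alleles for the compound
    lrh_sensitive_content: dict[str, list[str]]  # LRH name -> sensitive-bearing genes
    dosage_fractions: dict[int, float]  # sensitive-copy count -> subject fraction
    per_subject_dosage: list[int]
    phase_mode: str  # single_locus / coupling / repulsion / mixed

    def __post_init__(self) -> None:
        if abs(sum(self.dosage_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("dosage fractions must sum to 1")


def phase_summary(
    cohort: PhasedCohort,
    block_id: str,
    function_table: ReceptorFunctionTable,
    compound: str,
    min_freq: float = 0.05,
) -> PhaseSummary:
    """Sensitive-allele dosage and linkage-phase mode for one block.

    A subject's dosage is the number of carried long-range haplotype copies
    bearing at least one sensitive allele for the compound (sensitivity is
    each gene's own lowest-threshold class).  The phase mode is read off
    the common (frequency >= ``min_freq``) LRHs: 'repulsion' when every
    common LRH carries exactly one implicated gene's sensitive allele (so
    dosage saturates and association is masked), 'coupling' when sensitive
    alleles co-reside on some LRHs while others carry none (dosage spreads
    and association shows), 'single_locus' when only one gene is
    implicated.
    """
    sp = cohort.scopes[block_id]
    hs = sp.haplotype_set
    sens = function_table.gene_sensitive_alleles(compound)
    genes_in_block = list(hs.markers)
    known = {
        a.rsplit("-", 1)[0]
        for a in function_table.frame[function_table.frame["compound"] == compound]["allele"]
    }
    unannotated = sorted(
        g for g in genes_in_block
        if g in {s.rsplit("-", 1)[0] for s in sens} - known
    )
    sens_genes = sorted({a.rsplit("-", 1)[0] for a in sens} & set(genes_in_block))
    if not sens_genes:
        raise ValueError(
            f"no sensitive alleles annotated for {compound!r} among block genes "
            f"{genes_in_block}; missing genes: {unannotated or genes_in_block}"
        )

    def sensitive_content(hap_idx: int) -> list[str]:
        vec = hs.haplotypes[hap_idx]
        out = []
        for gene, hap_name in zip(genes_in_block, vec):
            if hap_name != DELETION and f"{gene}-{hap_name}" in sens:
                out.append(gene)
        return out

    content = {hs.name_of(i): sensitive_content(i) for i in range(len(hs.haplotypes))}
    dosages = []
    for pair in sp.pairs:
        if pair is None:
            continue
        dosages.append(sum(1 for i in pair if content[hs.name_of(i)]))
    counts = pd.Series(dosages).value_counts(normalize=True).to_dict()
    fractions = {int(k): float(v) for k, v in counts.items()}

    if len(sens_genes) == 1:
        mode = "single_locus"
    else:
        common = [i for i in range(len(hs.haplotypes)) if hs.frequencies[i] >= min_freq]
        per_lrh = [content[hs.name_of(i)] for i in common]
        if all(len(c) == 1 for c in per_lrh) and len({tuple(c) for c in per_lrh}) > 1:
            # every common haplotype carries exactly one gene's sensitive
            # allele: dosage saturates for all diplotypes, masking association
            mode = "repulsion"
        elif any(len(c) == len(sens_genes) for c in per_lrh) and any(
            len(c) == 0 for c in per_lrh
        ):
            # sensitive alleles co-reside on some haplotypes while others
            # carry none: dosage spreads 0..2 and association shows
            mode = "coupling"
        else:
            mode = "mixed"
    return PhaseSummary(
        compound=compound,
        block_id=block_id,
        genes=sens_genes,
        lrh_sensitive_content=content,
        dosage_fractions=fractions,
        per_subject_dosage=dosages,
        phase_mode=mode,
    )


def candidate_filter(
    association_results: list[AssociationResult],
    inventory: dict[str, tuple[str, ...]],
    function_table: ReceptorFunctionTable,
    block_genes: dict[str, list[str]],
    compound: str,
) -> pd.DataFrame:
    """Per-gene causal classification for one compound.

    causal: the gene sits in an experiment-wide-significant block, is in the
    responsiveness inventory, and carries a phenotype-explanatory allele.
    linked_passenger: in a significant block and responsive, but no allele
    explains subject thresholds (or not responsive at all yet associated).
    phase_masked: responsive with an explanatory allele but no significant
    association anywhere.  unexplained: a significant block containing no
    responsive gene.
    """
    responsive = set(inventory.get(compound, ()))
    ft = function_table.frame
    explanatory_genes = set(
        ft[(ft["compound"] == compound) & ft["explanatory"]]["gene"]
    )
    sig_blocks = {
        r.unit
        for r in association_results
        if r.level == "block" and r.measure and r.significant_experimentwide
    }
    sig_genes = {g for b in sig_blocks for g in block_genes.get(b, [])}
    blocks_with_responsive = {
        b for b in sig_blocks if responsive & set(block_genes.get(b, []))
    }
    shadowed = {g for b in blocks_with_responsive for g in block_genes.get(b, [])}
    rows = []
    candidates = sorted(responsive | sig_genes)
    for gene in candidates:
        in_sig = gene in sig_genes
        is_resp = gene in responsive
        expl = gene in explanatory_genes
        if in_sig and is_resp and expl:
            call = "causal"
        elif in_sig and is_resp:
            call = "linked_passenger"
        elif in_sig:
            # non-responsive gene riding a block that holds a responsive
            # gene is a pure linkage shadow; a block with no responsive
            # gene at all stays unexplained
            call = "linked_passenger" if gene in shadowed else "unexplained"
        elif is_resp and expl:
            call = "phase_masked"
        else:
            call = "not_implicated"
        rows.append(
            {
                "compound": compound,
                "gene": gene,
                "in_significant_block": in_sig,
                "inventory_responsive": is_resp,
                "has_explanatory_allele": expl,
                "classification": call,
            }
        )
    if not sig_blocks and not responsive:
        # empty inventory and no signal: report every scanned block unexplained
        for b in sorted({r.unit for r in association_results if r.level == "block"}):
            rows.append(
                {
                    "compound": compound,
                    "gene": None,
                    "in_significant_block": False,
                    "inventory_responsive": False,
                    "has_explanatory_allele": False,
                    "classification": "unexplained",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "compound", "gene", "in_significant_block", "inventory_responsive",
            "has_explanatory_allele", "classification",
        ],
    )
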