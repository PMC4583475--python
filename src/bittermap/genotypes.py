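"""Genotype-level data model: sites, genotype calls, copy number, and HWE.

Genotypes are unordered allele pairs per subject and site; subjects
hemizygous for a whole-gene deletion carry a single allele, and subjects
with two deleted copies carry none (missing at every site of the gene).
"""
from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd

#: symbolic allele state for a whole-gene deletion
DELETION = "Δ"

CONSEQUENCES = ("synonymous", "missense", "nonsense", "inframe_indel")


class NoCallError(ValueError):
    """Raised when a multiplex-PCR pattern carries no information (assay failure)."""


def call_copy_number(internal_present: bool, spanning_present: bool) -> int:
    """Call gene copy number from a multiplex-PCR product pattern.

    ``internal_present`` — products from primers inside the deletable region;
    ``spanning_present`` — product from primers spanning the deletion
    breakpoints (only amplifiable when a deleted chromosome is present).

    Returns 0, 1 or 2 copies.  Both products absent is an assay failure.
    """
    if not internal_present and not spanning_present:
        raise NoCallError("no PCR product observed: assay failure, no copy-number call")
    if internal_present and spanning_present:
        return 1
    if internal_present:
        return 2
    return 0


def hwe_exact_test(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional test for Hardy-Weinberg equilibrium at a biallelic site.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more probable than the observed one
    (two-sided by probability mass), which is the appropriate small-sample
    test for a 48-subject panel.
    """
    counts = (n_hom_major, n_het, n_hom_minor)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes observed")
    n_minor = 2 * n_hom_minor + n_het
    n_minor = min(n_minor, 2 * n - n_minor)

    def log_prob(het: int) -> float:
        # P(het | n, n_minor) on the log scale, from the hypergeometric-type
        # conditional distribution of heterozygote counts.
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        return (
            lgamma(n + 1)
            - lgamma(hom_major + 1)
            - lgamma(het + 1)
            - lgamma(hom_minor + 1)
            + het * log(2.0)
            + lgamma(n_minor + 1)
            + lgamma(2 * n - n_minor + 1)
            - lgamma(2 * n + 1)
        )

    parity = n_minor % 2
    hets = range(parity, n_minor + 1, 2)
    logps = np.array([log_prob(h) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs_het = n_het  # het count is invariant under swapping the allele labels
    idx = (obs_het - parity) // 2
    if obs_het % 2 != parity or obs_het > n_minor:
        raise ValueError(
            f"heterozygote count {n_het} inconsistent with allele counts"
        )
    p_obs = probs[idx]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


@dataclass
class SiteTable:
    """Catalogue of polymorphic coding sites.

    ``frame`` columns: site_id, chrom, pos (1-based), gene, ref, alt,
    consequence, maf.  Positions must be strictly increasing within a
    chromosome.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"site_id", "chrom", "pos", "gene", "ref", "alt", "consequence"}
        missing = req - set(self.frame.columns)
        if missing:
            raise ValueError(f"SiteTable missing columns: {sorted(missing)}")
        for chrom, sub in self.frame.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        bad = set(self.frame["consequence"]) - set(CONSEQUENCES)
        if bad:
            raise ValueError(f"unknown consequence labels: {sorted(bad)}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame["site_id"])

    def sites_of_gene(self, gene: str) -> list[str]:
        return list(self.frame.loc[self.frame["gene"] == gene, "site_id"])


Call = tuple  # alleles as a tuple: len 2 diploid, len 1 hemizygous


@dataclass
class GenotypeMatrix:
    """Subjects x sites matrix of unordered allele calls.

    Each entry is a tuple of alleles — length 2 for a diploid call, length 1
    for a hemizygous call (single gene copy), or ``None`` where the gene is
    absent (copy number 0) or the call is missing.
    """

    subjects: list[str]
    sites: list[str]
    calls: list[list[Call | None]]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.subjects):
            raise ValueError("one call row per subject required")
        for row in self.calls:
            if len(row) != len(self.sites):
                raise ValueError("one call per site required")

    def column(self, site: str) -> list[Call | None]:
        j = self.sites.index(site)
        return [row[j] for row in self.calls]

    def subset_sites(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sites.index(s) for s in keep]
        return GenotypeMatrix(
            subjects=list(self.subjects),
            sites=list(keep),
            calls=[[row[j] for j in idx] for row in self.calls],
        )

    def genotype_labels(self, site: str) -> list[str | None]:
        """Unordered genotype label ('A/C', hemizygous 'A', missing None) per subject."""
        out = []
        for call in self.column(site):
            out.append(None if call is None else "/".join(sorted(call)))
        return out


@dataclass
class CopyNumberTable:
    """Per subject and gene: number of gene copies (0, 1 or 2)."""

    frame: pd.DataFrame  # columns: subject, gene, copies
    cnv_genes: tuple[str, ...] = ("TAS2R43", "TAS2R45")

    def __post_init__(self) -> None:
        req = {"subject", "gene", "copies"}
        if req - set(self.frame.columns):
            raise ValueError("CopyNumberTable needs subject/gene/copies columns")
        if not self.frame["copies"].isin([0, 1, 2]).all():
            raise ValueError("copies must be 0, 1 or 2")
        low = self.frame[self.frame["copies"] < 2]
        bad = set(low["gene"]) - set(self.cnv_genes)
        if bad:
            raise ValueError(f"copy number < 2 at non-CNV genes: {sorted(bad)}")

    def copies(self, subject: str, gene: str) -> int:
        sel = self.frame[(self.frame["subject"] == subject) & (self.frame["gene"] == gene)]
        if sel.empty:
            return 2
        return int(sel["copies"].iloc[0])
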