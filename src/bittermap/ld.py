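"""Pairwise linkage disequilibrium and four-gamete haplotype blocks.

Works on phased chromosomes at two levels: individual coding SNPs, or whole
genes treated as multi-allelic markers whose alleles are gene-haplotype
names.  D' for a multi-allelic pair is the frequency-weighted mean of the
per-allele-pair |D'_ij|; r² is the chi-square-based squared Cramér's V
analogue, which reduces to the classical r² for biallelic pairs.
Significance comes from a seeded Monte-Carlo chi-square independence test
with margins held fixed, valid at small sample sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import random_table

from ._rng import derive_rng
from .phasing import PhasedCohort


@dataclass
class LDResult:
    unit_a: str
    unit_b: str
    d_prime: float
    r2: float
    p: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.d_prime <= 1 + 1e-9 and -1e-9 <= self.r2 <= 1 + 1e-9):
            raise ValueError("D' and r2 must lie in [0, 1]")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def pairwise_ld(
    counts: np.ndarray,
    unit_a: str = "A",
    unit_b: str = "B",
    n_mc: int = 10_000,
    seed: int = 0,
) -> LDResult:
    """LD summary for a k x l table of joint two-locus gamete counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 1:
        raise ValueError("counts must be a 2-D table")
    # collapse empty allele classes before computing
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    k, l = counts.shape
    n = counts.sum()
    if n < 1:
        raise ValueError("empty gamete table")
    if k < 2 or l < 2:
        # monomorphic after collapsing: no disequilibrium is defined; report
        # the degenerate complete-LD convention
        return LDResult(unit_a, unit_b, 1.0, 1.0, 1.0)
    p = counts.sum(axis=1) / n
    q = counts.sum(axis=0) / n
    pij = counts / n
    d = pij - np.outer(p, q)
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_pos = np.minimum(np.outer(p, 1 - q), np.outer(1 - p, q))
        dmax_neg = np.minimum(np.outer(p, q), np.outer(1 - p, 1 - q))
        dmax = np.where(d >= 0, dmax_pos, dmax_neg)
        dprime_ij = np.where(dmax > 0, np.abs(d) / dmax, 0.0)
    d_prime = float(np.sum(np.outer(p, q) * dprime_ij))
    expected = n * np.outer(p, q)
    chi2 = float(np.sum(d**2 / np.outer(p, q)) * n)
    r2 = chi2 / (n * min(k - 1, l - 1))
    # Monte-Carlo chi-square independence test, margins fixed
    rng = derive_rng(seed, "ld_mc", unit_a, unit_b)
    tables = random_table(counts.sum(axis=1), counts.sum(axis=0)).rvs(
        n_mc, random_state=rng
    )
    chi2_mc = ((tables - expected) ** 2 / expected).sum(axis=(1, 2))
    p_val = (1 + np.sum(chi2_mc >= chi2 - 1e-12)) / (n_mc + 1)
    return LDResult(unit_a, unit_b, min(d_prime, 1.0), min(r2, 1.0), float(p_val))


def _chromosome_columns(
    cohort: PhasedCohort, level: str
) -> tuple[list[str], np.ndarray]:
    """Flatten phased diplotypes into a (2n_chromosomes x units) allele array.

    level 'snp': one column per site across all gene scopes; level 'gene':
    one multi-allelic column per gene, alleles being haplotype names.
    Scopes are taken to be gene scopes (markers = site ids).
    """
    if level not in ("snp", "gene"):
        raise ValueError("level must be 'snp' or 'gene'")
    unit_names: list[str] = []
    columns: list[list] = []
    for scope, sp in cohort.scopes.items():
        hs = sp.haplotype_set
        chroms = []  # allele tuples, one per phased chromosome
        for pair in sp.pairs:
            if pair is None:
                continue
            for i in pair:
                chroms.append(hs.haplotypes[i])
        if level == "gene":
            unit_names.append(scope)
            columns.append([hs.name_of(hs.haplotypes.index(h)) for h in chroms])
        else:
            for j, marker in enumerate(hs.markers):
                unit_names.append(marker)
                columns.append([h[j] for h in chroms])
    length = {len(c) for c in columns}
    if len(length) != 1:
        raise ValueError("scopes disagree on chromosome count; missing data unsupported here")
    return unit_names, np.array(columns, dtype=object).T


def ld_matrix(
    cohort: PhasedCohort,
    level: str = "snp",
    min_freq: float = 0.05,
    n_mc: int = 10_000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Symmetric pairwise D', r² and p matrices over common polymorphic units.

    Units whose minor-allele (or minor-haplotype) frequency is below
    ``min_freq``, or that are monomorphic, are excluded.
    """
    names, chroms = _chromosome_columns(cohort, level)
    keep = []
    for j, name in enumerate(names):
        vals, cnt = np.unique(chroms[:, j].astype(str), return_counts=True)
        freqs = cnt / cnt.sum()
        if len(vals) >= 2 and np.sort(freqs)[-2] >= min_freq:
            keep.append(j)
    kept = [names[j] for j in keep]
    m = len(kept)
    mats = {key: pd.DataFrame(np.eye(m), index=kept, columns=kept) for key in ("d_prime", "r2")}
    mats["p"] = pd.DataFrame(np.ones((m, m)), index=kept, columns=kept)
    for a in range(m):
        for b in range(a + 1, m):
            ja, jb = keep[a], keep[b]
            tab = pd.crosstab(
                pd.Series(chroms[:, ja].astype(str)), pd.Series(chroms[:, jb].astype(str))
            ).to_numpy()
            res = pairwise_ld(tab, kept[a], kept[b], n_mc=n_mc, seed=seed)
            for key, val in (("d_prime", res.d_prime), ("r2", res.r2), ("p", res.p)):
                mats[key].iloc[a, b] = mats[key].iloc[b, a] = val
    return mats


def mean_offdiagonal(mat: pd.DataFrame) -> float:
    a = mat.to_numpy()
    mask = ~np.eye(len(a), dtype=bool)
    return float(a[mask].mean())


@dataclass
class BlockPartition:
    units: list[str]
    blocks: list[tuple[int, int]]  # inclusive index ranges

    def __post_init__(self) -> None:
        covered = []
        for lo, hi in self.blocks:
            if not 0 <= lo <= hi < len(self.units):
                raise ValueError("block range out of bounds")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(len(self.units))):
            raise ValueError("blocks must be disjoint, contiguous, and cover all units")

    def members(self) -> list[list[str]]:
        return [self.units[lo : hi + 1] for lo, hi in self.blocks]

    def block_of(self, unit: str) -> int:
        j = self.units.index(unit)
        for b, (lo, hi) in enumerate(self.blocks):
            if lo <= j <= hi:
                return b
        raise KeyError(unit)


def _biallelic_collapse(column: np.ndarray) -> np.ndarray:
    """Major allele vs pooled others, as 0/1 ints (four-gamete rule is
    defined for biallelic markers)."""
    vals, cnt = np.unique(column.astype(str), return_counts=True)
    major = vals[np.argmax(cnt)]
    return (column.astype(str) != major).astype(int)


def recombination_evidence(
    a: np.ndarray, b: np.ndarray, cutoff: float = 0.05
) -> bool:
    """True iff all four two-locus gametes are observed at frequency >= cutoff."""
    n = len(a)
    freqs = [
        np.mean((a == i) & (b == j)) for i in (0, 1) for j in (0, 1)
    ]
    return all(f >= cutoff - 1e-12 for f in freqs)


def four_gamete_blocks(
    chromosomes: np.ndarray,
    units: list[str],
    cutoff: float = 0.05,
    overrides: dict[str, int] | None = None,
) -> BlockPartition:
    """Partition ordered units into haplotype blocks by the four-gamete rule.

    ``chromosomes``: (n_chromosomes x n_units) allele array, units in
    chromosomal order.  A pair of units shows recombination evidence iff all
    four gametes (after major-vs-rest collapsing) reach the frequency
    cutoff.  Blocks are maximal contiguous runs, grown greedily left to
    right, in which no within-run pair shows evidence.  ``overrides`` maps
    unit id to a forced block label applied after the algorithm (manual
    adjustment for units whose SNPs straddle block boundaries); contiguous
    runs of equal labels form the final partition.
    """
    if not 0 < cutoff < 0.5:
        raise ValueError("cutoff must be in (0, 0.5)")
    chromosomes = np.asarray(chromosomes, dtype=object)
    if chromosomes.shape[1] != len(units):
        raise ValueError("one column per unit required, in chromosomal order")
    cols = [_biallelic_collapse(chromosomes[:, j]) for j in range(len(units))]
    labels = np.empty(len(units), dtype=int)
    block = 0
    start = 0
    for j in range(len(units)):
        if j == start:
            labels[j] = block
            continue
        # monomorphic columns never show four gametes, so they extend runs
        if any(
            recombination_evidence(cols[i], cols[j], cutoff) for i in range(start, j)
        ):
            block += 1
            start = j
        labels[j] = block
    if overrides:
        unknown = set(overrides) - set(units)
        if unknown:
            raise ValueError(f"override for unknown units: {sorted(unknown)}")
        for unit, lab in overrides.items():
            labels[units.index(unit)] = lab
    # contiguous runs of equal labels
    blocks = []
    lo = 0
    for j in range(1, len(units) + 1):
        if j == len(units) or labels[j] != labels[j - 1]:
            blocks.append((lo, j - 1))
            lo = j
    return BlockPartition(list(units), blocks)


def partition_to_frame(
    partition: BlockPartition, chrom_of: dict[str, str] | None = None
) -> pd.DataFrame:
    """BED-like summary of a partition (one row per block)."""
    rows = []
    for b, (lo, hi) in enumerate(partition.blocks):
        members = partition.units[lo : hi + 1]
        rows.append(
            {
                "block_id": f"B{b + 1}",
                "chrom": chrom_of.get(members[0], "NA") if chrom_of else "NA",
                "start_unit": members[0],
                "end_unit": members[-1],
                "n_units": len(members),
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(rows)
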