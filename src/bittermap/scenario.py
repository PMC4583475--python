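"""Scenario model: the generative description of a simulated bitter-taste study.

A Scenario bundles everything the synthetic cohort generator needs:

* gene and site definitions grouped into linkage blocks, with per-block
  pools of long-range haplotypes (LRHs) and their population frequencies —
  the genomic structure of the 25-member TAS2R bitter-receptor family on
  chromosomes 5, 7 and 12, where within-block gene haplotypes co-segregate
  and whole-gene deletion alleles at TAS2R43/TAS2R45 ride on specific LRHs;
* a receptor table mapping (receptor allele, compound) to in-vitro
  dose-response parameters (EC50, maximal amplitude ΔF/F, Hill coefficient,
  activation threshold);
* per-compound link models translating the best (lowest) activation
  threshold among a subject's carried functional alleles into that
  subject's latent perceptual threshold;
* the psychophysical design (12-step geometric series, ratio 1.5, three
  repetitions, 4-AFC guess rate 0.25) and the plate design (half-log
  concentration grid, six replicate days).

The default scenario encodes the published study conditions: 48 subjects,
six multi-gene LD blocks, the four common TAS2R31-42 long-range haplotypes
at frequencies 0.30/0.22/0.20/0.16 carrying the deletion/truncation/
sensitive-allele combinations that produce the coupling (grosheimin) and
repulsion (absinthin) phase contrasts, and the printed receptor parameters.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import DELETION

COMPOUNDS = (
    "absinthin",
    "amarogentin",
    "cascarillin",
    "grosheimin",
    "quassin",
    "quinine",
)


@dataclass(frozen=True)
class SiteDef:
    site_id: str
    pos: int
    ref: str
    alt: str
    consequence: str = "missense"


@dataclass
class GeneDef:
    name: str
    chrom: str
    sites: list[SiteDef]
    haplotypes: dict[str, tuple[str, ...]]  # name -> allele vector over sites
    cnv_capable: bool = False

    def __post_init__(self) -> None:
        for name, vec in self.haplotypes.items():
            if len(vec) != len(self.sites):
                raise ValueError(f"{self.name}/{name}: allele vector length mismatch")

    def hap_vector(self, hap_name: str) -> tuple[str, ...]:
        if hap_name == DELETION:
            return tuple(DELETION for _ in self.sites)
        return self.haplotypes[hap_name]

    def name_of_vector(self, vec: tuple[str, ...]) -> str | None:
        if all(a == DELETION for a in vec):
            return DELETION
        for name, v in self.haplotypes.items():
            if v == vec:
                return name
        return None


@dataclass
class BlockDef:
    block_id: str
    chrom: str
    genes: list[GeneDef]

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]


@dataclass
class LongRangeHaplotype:
    name: str
    frequency: float
    gene_haps: dict[str, str]  # gene name -> gene-haplotype name (or deletion)


@dataclass
class ReceptorParams:
    ec50: float | None
    amplitude: float
    hill_n: float
    activation_threshold: float | None  # M; None = never activated
    functional_class: str  # sensitive / intermediate / insensitive / nonfunctional

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.activation_threshold is not None and self.activation_threshold <= 0:
            raise ValueError("activation threshold must be positive")


@dataclass
class LinkModel:
    """Latent perceptual threshold model for one compound:

    latent log10 threshold = offset + slope * log10(best activation
    threshold among carried functional alleles) + N(0, subject_sd);
    subjects carrying no functional allele fall back to
    ``nonresponder_threshold``.  Detection sits ``detection_shift`` log10
    units below recognition.
    """

    offset: float = 0.0
    slope: float = 1.0
    subject_sd: float = 0.12
    nonresponder_threshold: float = 1e-4
    detection_shift: float = 0.2


@dataclass
class PsychDesign:
    starts: dict[str, float]
    n_steps: int = 12
    ratio: float = 1.5
    n_repetitions: int = 3
    guess_rate: float = 0.25
    detection_sigma: float = 0.10  # logistic scale, log10 units
    recognition_sigma: float = 0.10
    intensity_shift: float = 0.55  # gLMS curve midpoint above recognition mu
    intensity_sigma: float = 0.30
    imax_mean: float = 85.0
    imax_sd: float = 5.0
    intensity_noise_sd: float = 4.0
    recognition_mode: str = "all"  # yes/no asked at every step, or 'chosen'

    def __post_init__(self) -> None:
        if self.ratio <= 1:
            raise ValueError("common ratio must exceed 1")
        if any(c <= 0 for c in self.starts.values()):
            raise ValueError("start concentrations must be positive")
        if self.recognition_mode not in ("all", "chosen"):
            raise ValueError("recognition_mode must be 'all' or 'chosen'")


@dataclass
class PlateDesign:
    concentrations: tuple[float, ...] = (
        1e-9, 3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6, 1e-5, 3e-5, 1e-4, 3e-4,
    )
    n_days: int = 6
    day_sd: float = 0.12  # sd of the multiplicative day gain around 1
    noise_sd: float = 0.003  # relative fluorescence noise per well
    f0_mean: float = 1000.0  # RFU
    f0_cv: float = 0.10
    n_empty_per_group: int = 3  # empty-vector wells per (day, compound, conc)
    n_pc_per_day: int = 4
    pc_amplitude: float = 1.0
    artefact_onset: float = 3e-4  # receptor-independent artefacts above this
    artefact_slope: float = 0.15

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("plate concentrations must be positive")


@dataclass
class Scenario:
    blocks: list[BlockDef]
    lrh_pools: dict[str, list[LongRangeHaplotype]]
    receptor_table: dict[tuple[str, str], ReceptorParams]  # (allele id, compound)
    links: dict[str, LinkModel]
    psych: PsychDesign
    plate: PlateDesign
    inventory: dict[str, tuple[str, ...]] = field(default_factory=dict)
    artefact_ceilings: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        block_ids = {b.block_id for b in self.blocks}
        if set(self.lrh_pools) != block_ids:
            raise ValueError("every block needs an LRH pool and vice versa")
        for bid, pool in self.lrh_pools.items():
            tot = sum(h.frequency for h in pool)
            if any(not 0 <= h.frequency <= 1 for h in pool) or tot > 1 + 1e-9:
                raise ValueError(f"block {bid}: LRH frequencies must lie in [0,1] and sum <= 1")
            block = self.block(bid)
            for h in pool:
                if set(h.gene_haps) != set(block.gene_names):
                    raise ValueError(f"LRH {h.name}: gene set mismatch in block {bid}")
                for g in block.genes:
                    hap = h.gene_haps[g.name]
                    if hap == DELETION:
                        if not g.cnv_capable:
                            raise ValueError(f"deletion allele at non-CNV gene {g.name}")
                    elif hap not in g.haplotypes:
                        raise ValueError(f"unknown haplotype {g.name}-{hap} on LRH {h.name}")

    def block(self, block_id: str) -> BlockDef:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)

    def gene(self, name: str) -> GeneDef:
        for b in self.blocks:
            for g in b.genes:
                if g.name == name:
                    return g
        raise KeyError(name)

    @property
    def genes(self) -> list[GeneDef]:
        return [g for b in self.blocks for g in b.genes]

    @property
    def compounds(self) -> list[str]:
        return sorted(self.psych.starts)

    def receptor_params(self, allele: str, compound: str) -> ReceptorParams | None:
        return self.receptor_table.get((allele, compound))


def _generic_gene(
    name: str, chrom: str, n_haps: int, pos0: int, step: int = 400
) -> GeneDef:
    """A gene with ``n_haps`` haplotypes over n_haps - 1 biallelic sites:
    H1 is all-reference and H_i carries the alternate at site i-1."""
    n_sites = max(n_haps - 1, 0)
    sites = [
        SiteDef(f"{name}_s{j + 1}", pos0 + j * step, "C", "T") for j in range(n_sites)
    ]
    haps = {}
    for i in range(n_haps):
        vec = ["C"] * n_sites
        if i > 0:
            vec[i - 1] = "T"
        haps[f"H{i + 1}"] = tuple(vec)
    return GeneDef(name, chrom, sites, haps)


def default_scenario(seed: int = 0) -> Scenario:
    """The calibrated study scenario (see module docstring)."""
    pos = {"chr5": [100_000], "chr7": [100_000], "chr12": [100_000]}

    def nextpos(chrom: str, n: int = 1, gap: int = 20_000) -> int:
        p = pos[chrom][0] + gap
        pos[chrom][0] = p + n * 400
        return p

    # --- chromosome 5: single gene ---
    r1 = _generic_gene("TAS2R1", "chr5", 2, nextpos("chr5"))

    # --- chromosome 7: TAS2R16 | TAS2R3-5 block | TAS2R38 | TAS2R39-60 block | TAS2R41 ---
    r16 = _generic_gene("TAS2R16", "chr7", 2, nextpos("chr7"))
    r3 = _generic_gene("TAS2R3", "chr7", 2, nextpos("chr7"))
    r4 = _generic_gene("TAS2R4", "chr7", 2, nextpos("chr7"))
    r5 = _generic_gene("TAS2R5", "chr7", 2, nextpos("chr7"))
    r38 = _generic_gene("TAS2R38", "chr7", 2, nextpos("chr7"))
    r39 = _generic_gene("TAS2R39", "chr7", 2, nextpos("chr7"))
    r40 = _generic_gene("TAS2R40", "chr7", 2, nextpos("chr7"))
    r60 = _generic_gene("TAS2R60", "chr7", 2, nextpos("chr7"))
    r41 = _generic_gene("TAS2R41", "chr7", 2, nextpos("chr7"))

    # --- chromosome 12, in chromosomal order ---
    r7 = _generic_gene("TAS2R7", "chr12", 3, nextpos("chr12", 2))
    r8 = _generic_gene("TAS2R8", "chr12", 2, nextpos("chr12"))
    r9 = _generic_gene("TAS2R9", "chr12", 2, nextpos("chr12"))
    r10 = _generic_gene("TAS2R10", "chr12", 1, nextpos("chr12", 0))
    r13 = _generic_gene("TAS2R13", "chr12", 2, nextpos("chr12"))
    r14 = _generic_gene("TAS2R14", "chr12", 2, nextpos("chr12"))
    r50 = _generic_gene("TAS2R50", "chr12", 4, nextpos("chr12", 3))
    r20 = _generic_gene("TAS2R20", "chr12", 4, nextpos("chr12", 3))
    r19 = _generic_gene("TAS2R19", "chr12", 3, nextpos("chr12", 2))
    r31 = _generic_gene("TAS2R31", "chr12", 4, nextpos("chr12", 3))
    # TAS2R46: a nonsense truncation distinguishes H2, a missense site H3
    p46 = nextpos("chr12", 2)
    r46 = GeneDef(
        "TAS2R46",
        "chr12",
        [
            SiteDef("TAS2R46_W250X", p46, "G", "A", "nonsense"),
            SiteDef("TAS2R46_L228M", p46 + 400, "C", "A", "missense"),
        ],
        {"H1": ("G", "C"), "H2": ("A", "C"), "H3": ("G", "A")},
    )
    p43 = nextpos("chr12", 2)
    r43 = GeneDef(
        "TAS2R43",
        "chr12",
        [
            SiteDef("TAS2R43_W35S", p43, "G", "C", "missense"),
            SiteDef("TAS2R43_H212R", p43 + 400, "A", "G", "missense"),
        ],
        {"H1": ("G", "A"), "H2": ("C", "G")},
        cnv_capable=True,
    )
    r45 = GeneDef(
        "TAS2R45",
        "chr12",
        [SiteDef("TAS2R45_s1", nextpos("chr12"), "T", "C", "synonymous")],
        {"H1": ("T",)},
        cnv_capable=True,
    )
    p30 = nextpos("chr12")
    r30 = GeneDef(
        "TAS2R30",
        "chr12",
        [SiteDef("TAS2R30_L252F", p30, "C", "T", "missense")],
        {"H1": ("C",), "H2": ("T",)},
    )
    r42 = _generic_gene("TAS2R42", "chr12", 2, nextpos("chr12"))

    blocks = [
        BlockDef("TAS2R1", "chr5", [r1]),
        BlockDef("TAS2R16", "chr7", [r16]),
        BlockDef("TAS2R3-5", "chr7", [r3, r4, r5]),
        BlockDef("TAS2R38", "chr7", [r38]),
        BlockDef("TAS2R39-60", "chr7", [r39, r40, r60]),
        BlockDef("TAS2R41", "chr7", [r41]),
        BlockDef("TAS2R7-10", "chr12", [r7, r8, r9, r10]),
        BlockDef("TAS2R13-14", "chr12", [r13, r14]),
        BlockDef("TAS2R50-19", "chr12", [r50, r20, r19]),
        BlockDef("TAS2R31-42", "chr12", [r31, r46, r43, r45, r30, r42]),
    ]

    def lrh(name, freq, **gene_haps):
        return LongRangeHaplotype(name, freq, gene_haps)

    def singleton_pool(gene: str, f1: float, f2: float):
        return [
            lrh("LR1", f1, **{gene: "H1"}),
            lrh("LR2", f2, **{gene: "H2"}),
        ]

    lrh_pools = {
        "TAS2R1": singleton_pool("TAS2R1", 0.58, 0.38),
        "TAS2R16": singleton_pool("TAS2R16", 0.56, 0.40),
        "TAS2R38": singleton_pool("TAS2R38", 0.55, 0.41),
        "TAS2R41": singleton_pool("TAS2R41", 0.56, 0.40),
        "TAS2R3-5": [
            lrh("LR1", 0.65, TAS2R3="H1", TAS2R4="H1", TAS2R5="H1"),
            lrh("LR2", 0.30, TAS2R3="H2", TAS2R4="H2", TAS2R5="H2"),
        ],
        "TAS2R39-60": [
            lrh("LR1", 0.60, TAS2R39="H1", TAS2R40="H1", TAS2R60="H1"),
            lrh("LR2", 0.35, TAS2R39="H2", TAS2R40="H2", TAS2R60="H2"),
        ],
        "TAS2R7-10": [
            lrh("LR1", 0.35, TAS2R7="H1", TAS2R8="H1", TAS2R9="H1", TAS2R10="H1"),
            lrh("LR2", 0.25, TAS2R7="H2", TAS2R8="H2", TAS2R9="H1", TAS2R10="H1"),
            lrh("LR3", 0.20, TAS2R7="H3", TAS2R8="H2", TAS2R9="H1", TAS2R10="H1"),
            lrh("LR4", 0.15, TAS2R7="H1", TAS2R8="H1", TAS2R9="H2", TAS2R10="H1"),
        ],
        "TAS2R13-14": [
            lrh("LR1", 0.45, TAS2R13="H1", TAS2R14="H1"),
            lrh("LR2", 0.30, TAS2R13="H2", TAS2R14="H2"),
            lrh("LR3", 0.20, TAS2R13="H1", TAS2R14="H2"),
        ],
        "TAS2R50-19": [
            lrh("LR1", 0.30, TAS2R50="H1", TAS2R20="H1", TAS2R19="H1"),
            lrh("LR2", 0.25, TAS2R50="H2", TAS2R20="H2", TAS2R19="H2"),
            lrh("LR3", 0.20, TAS2R50="H3", TAS2R20="H2", TAS2R19="H2"),
            lrh("LR4", 0.12, TAS2R50="H1", TAS2R20="H3", TAS2R19="H1"),
            lrh("LR5", 0.08, TAS2R50="H4", TAS2R20="H2", TAS2R19="H3"),
        ],
        # the central block: deletion + truncation on LRH1, sensitive combos
        # arranged so grosheimin alleles couple and absinthin alleles repulse
        "TAS2R31-42": [
            lrh("LR1", 0.30, TAS2R31="H1", TAS2R46="H2", TAS2R43=DELETION,
                TAS2R45="H1", TAS2R30="H1", TAS2R42="H1"),
            lrh("LR2", 0.22, TAS2R31="H2", TAS2R46="H1", TAS2R43="H1",
                TAS2R45="H1", TAS2R30="H2", TAS2R42="H1"),
            lrh("LR3", 0.20, TAS2R31="H3", TAS2R46="H3", TAS2R43=DELETION,
                TAS2R45=DELETION, TAS2R30="H1", TAS2R42="H2"),
            lrh("LR4", 0.16, TAS2R31="H4", TAS2R46="H1", TAS2R43="H2",
                TAS2R45="H1", TAS2R30="H2", TAS2R42="H1"),
        ],
    }

    def rp(ec50, amp, thr, cls, n=1.0):
        return ReceptorParams(ec50, amp, n, thr, cls)

    nonfunc = ReceptorParams(None, 0.0, 1.0, None, "nonfunctional")
    receptor_table = {
        # amarogentin
        ("TAS2R30-H1", "amarogentin"): rp(4.1e-7, 0.50, 1.0e-8, "sensitive"),
        ("TAS2R30-H2", "amarogentin"): rp(3.9e-7, 0.12, 3.0e-7, "intermediate"),
        ("TAS2R43-H1", "amarogentin"): rp(1.0e-3, 0.30, 3.0e-4, "insensitive"),
        ("TAS2R43-H2", "amarogentin"): rp(1.0e-3, 0.30, 3.0e-4, "insensitive"),
        ("TAS2R46-H1", "amarogentin"): rp(6.7e-5, 0.57, 3.0e-5, "intermediate"),
        ("TAS2R46-H3", "amarogentin"): rp(2.0e-4, 0.35, 1.0e-4, "insensitive"),
        ("TAS2R46-H2", "amarogentin"): nonfunc,
        # quassin
        ("TAS2R30-H1", "quassin"): rp(3.0e-7, 0.45, 3.0e-8, "sensitive"),
        ("TAS2R30-H2", "quassin"): rp(1.0e-6, 0.12, 1.0e-6, "insensitive"),
        ("TAS2R46-H1", "quassin"): rp(7.0e-5, 0.50, 3.0e-5, "intermediate"),
        ("TAS2R46-H3", "quassin"): rp(2.0e-4, 0.30, 1.0e-4, "insensitive"),
        ("TAS2R46-H2", "quassin"): nonfunc,
        # grosheimin (coupling phase across TAS2R43 / TAS2R46)
        ("TAS2R43-H1", "grosheimin"): rp(1.6e-5, 0.60, 1.0e-5, "intermediate"),
        ("TAS2R43-H2", "grosheimin"): rp(6.9e-6, 0.81, 3.0e-6, "sensitive"),
        ("TAS2R46-H1", "grosheimin"): rp(5.6e-6, 0.87, 1.0e-6, "sensitive"),
        ("TAS2R46-H3", "grosheimin"): rp(7.6e-6, 0.50, 3.0e-6, "intermediate"),
        ("TAS2R46-H2", "grosheimin"): nonfunc,
        # absinthin (repulsion phase across TAS2R30 / TAS2R46)
        ("TAS2R30-H1", "absinthin"): rp(3.1e-6, 0.41, 3.0e-7, "sensitive"),
        ("TAS2R30-H2", "absinthin"): rp(1.3e-6, 0.15, 1.0e-6, "intermediate"),
        ("TAS2R46-H1", "absinthin"): rp(1.1e-5, 0.63, 3.0e-6, "sensitive"),
        ("TAS2R46-H3", "absinthin"): rp(1.4e-5, 0.48, 1.0e-5, "intermediate"),
        ("TAS2R46-H2", "absinthin"): nonfunc,
        # cascarillin
        ("TAS2R30-H1", "cascarillin"): rp(1.0e-4, 0.40, 3.0e-5, "sensitive"),
        ("TAS2R30-H2", "cascarillin"): rp(5.0e-4, 0.10, 3.0e-4, "insensitive"),
        ("TAS2R46-H1", "cascarillin"): rp(1.0e-4, 0.50, 3.0e-5, "sensitive"),
        ("TAS2R46-H3", "cascarillin"): rp(2.0e-4, 0.30, 1.0e-4, "intermediate"),
        ("TAS2R46-H2", "cascarillin"): nonfunc,
        # quinine
        ("TAS2R30-H1", "quinine"): rp(3.0e-5, 0.40, 1.0e-5, "sensitive"),
        ("TAS2R30-H2", "quinine"): rp(3.0e-5, 0.15, 3.0e-5, "intermediate"),
        ("TAS2R31-H2", "quinine"): rp(2.0e-5, 0.50, 1.0e-5, "sensitive"),
        ("TAS2R31-H1", "quinine"): rp(5.0e-5, 0.35, 3.0e-5, "intermediate"),
        ("TAS2R31-H4", "quinine"): rp(6.0e-5, 0.30, 3.0e-5, "intermediate"),
        ("TAS2R31-H3", "quinine"): rp(3.0e-4, 0.10, 3.0e-4, "insensitive"),
        ("TAS2R43-H1", "quinine"): rp(6.0e-5, 0.40, 3.0e-5, "intermediate"),
        ("TAS2R43-H2", "quinine"): rp(3.0e-5, 0.50, 1.0e-5, "sensitive"),
        ("TAS2R46-H1", "quinine"): rp(2.0e-5, 0.60, 1.0e-5, "sensitive"),
        ("TAS2R46-H3", "quinine"): rp(5.0e-5, 0.40, 3.0e-5, "intermediate"),
        ("TAS2R46-H2", "quinine"): nonfunc,
    }

    # per-compound links: calibrated so that the in-vitro activation
    # thresholds of the common alleles map onto the printed phenotype modes
    links = {
        "amarogentin": LinkModel(offset=-4.288, slope=0.389, nonresponder_threshold=3.0e-7),
        "quassin": LinkModel(offset=-2.671, slope=0.605, nonresponder_threshold=1.0e-6),
        "grosheimin": LinkModel(offset=-0.643, slope=0.727, nonresponder_threshold=8.0e-6),
        "absinthin": LinkModel(offset=-4.263, slope=0.356, nonresponder_threshold=3.0e-5),
        "cascarillin": LinkModel(offset=-2.579, slope=0.602, nonresponder_threshold=3.0e-4),
        "quinine": LinkModel(offset=-0.032, slope=1.073, nonresponder_threshold=1.0e-4),
    }

    psych = PsychDesign(
        starts={
            "absinthin": 2.3e-8,
            "amarogentin": 3.5e-9,
            "cascarillin": 4.6e-7,
            "grosheimin": 5.8e-7,
            "quassin": 1.2e-8,
            "quinine": 4.6e-7,
        }
    )

    inventory = {
        "amarogentin": ("TAS2R1", "TAS2R4", "TAS2R39", "TAS2R43", "TAS2R46", "TAS2R30", "TAS2R50"),
        "grosheimin": ("TAS2R43", "TAS2R46"),
        "absinthin": ("TAS2R30", "TAS2R46"),
        "cascarillin": ("TAS2R30", "TAS2R46"),
        "quassin": ("TAS2R30", "TAS2R46"),
        "quinine": ("TAS2R30", "TAS2R31", "TAS2R43", "TAS2R46"),
    }
    artefact_ceilings = {c: 3.0e-4 for c in COMPOUNDS}

    return Scenario(
        blocks=blocks,
        lrh_pools=lrh_pools,
        receptor_table=receptor_table,
        links=links,
        psych=psych,
        plate=PlateDesign(),
        inventory=inventory,
        artefact_ceilings=artefact_ceilings,
        seed=seed,
    )


def two_locus_scenario(
    phase: str,
    thr_sensitive: float = 1e-6,
    thr_nonresponder: float = 1e-4,
    freq: float = 0.5,
    subject_sd: float = 0.12,
    seed: int = 0,
) -> Scenario:
    """Minimal paired scenario for the linkage-phase contrast.

    Two genes, GA and GB, each with one sensitive (H1) and one
    nonfunctional (H2) allele of identical effect.  In 'coupling' phase the
    two sensitive alleles ride on the same long-range haplotype, so
    H2/H2-homozygous subjects carry no functional allele and fall to the
    nonresponder threshold; in 'repulsion' phase every haplotype carries
    exactly one gene's sensitive allele, so every subject is sensitive and
    the genotype-phenotype signal is masked.
    """
    if phase not in ("coupling", "repulsion"):
        raise ValueError("phase must be 'coupling' or 'repulsion'")
    ga = _generic_gene("GA", "chr12", 2, 100_000)
    gb = _generic_gene("GB", "chr12", 2, 120_000)
    if phase == "coupling":
        pool = [
            LongRangeHaplotype("LR1", freq, {"GA": "H1", "GB": "H1"}),
            LongRangeHaplotype("LR2", 1 - freq, {"GA": "H2", "GB": "H2"}),
        ]
    else:
        pool = [
            LongRangeHaplotype("LR1", freq, {"GA": "H1", "GB": "H2"}),
            LongRangeHaplotype("LR2", 1 - freq, {"GA": "H2", "GB": "H1"}),
        ]
    nonfunc = ReceptorParams(None, 0.0, 1.0, None, "nonfunctional")
    receptor_table = {
        ("GA-H1", "probe"): ReceptorParams(3e-6, 0.5, 1.0, thr_sensitive, "sensitive"),
        ("GA-H2", "probe"): nonfunc,
        ("GB-H1", "probe"): ReceptorParams(3e-6, 0.5, 1.0, thr_sensitive, "sensitive"),
        ("GB-H2", "probe"): nonfunc,
    }
    return Scenario(
        blocks=[BlockDef("GA-GB", "chr12", [ga, gb])],
        lrh_pools={"GA-GB": pool},
        receptor_table=receptor_table,
        links={"probe": LinkModel(subject_sd=subject_sd, nonresponder_threshold=thr_nonresponder)},
        psych=PsychDesign(starts={"probe": 1e-7}),
        plate=PlateDesign(),
        inventory={"probe": ("GA", "GB")},
        seed=seed,
    )
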