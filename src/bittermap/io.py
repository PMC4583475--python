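"""File interchange: VCF v4.2, copy-number / trial / plate / phenotype TSVs.

SNP genotypes travel as a multi-sample VCF with 1-based positions, unphased
"/" genotypes and one contig line per chromosome; whole-gene deletions are
symbolic <DEL> records (one per CNV-capable gene), so a hemizygous subject
shows `a/.` at the gene's SNP sites and `0/1` at the <DEL> record.  Reading
uses cyvcf2.  Tables are plain TSV via pandas.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import CopyNumberTable, GenotypeMatrix, SiteTable

_SV_ID_PREFIX = "DEL_"


def write_vcf(
    path: str,
    site_table: SiteTable,
    genotypes: GenotypeMatrix,
    copy_number: CopyNumberTable | None = None,
    gene_spans: dict[str, tuple[str, int]] | None = None,
) -> None:
    """Write sites + genotypes (and symbolic <DEL> records per CNV gene)."""
    frame = site_table.frame
    subjects = genotypes.subjects
    lines = [
        "##fileformat=VCFv4.2",
        '##ALT=<ID=DEL,Description="Whole-gene deletion">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in pd.unique(frame["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(subjects))

    records: list[tuple[str, int, str]] = []
    for row in frame.itertuples():
        gts = []
        for call in genotypes.column(row.site_id):
            if call is None:
                gts.append("./.")
            else:
                idx = ["0" if a == row.ref else "1" for a in call]
                if len(idx) == 1:
                    idx.append(".")
                gts.append("/".join(sorted(idx)))
        rec = (
            f"{row.chrom}\t{row.pos}\t{row.site_id}\t{row.ref}\t{row.alt}\t.\tPASS\t"
            f"GENE={row.gene};CSQ={row.consequence}\tGT\t" + "\t".join(gts)
        )
        records.append((row.chrom, int(row.pos), rec))
    if copy_number is not None and not copy_number.frame.empty:
        spans = gene_spans or {}
        for gene in sorted(set(copy_number.frame["gene"])):
            gene_sites = frame[frame["gene"] == gene]
            if gene in spans:
                chrom, pos = spans[gene]
            elif not gene_sites.empty:
                chrom = gene_sites["chrom"].iloc[0]
                pos = int(gene_sites["pos"].min()) - 1
            else:
                raise ValueError(f"no position known for CNV gene {gene}")
            gts = []
            for subj in subjects:
                copies = copy_number.copies(subj, gene)
                gts.append({2: "0/0", 1: "0/1", 0: "1/1"}[copies])
            rec = (
                f"{chrom}\t{pos}\t{_SV_ID_PREFIX}{gene}\tN\t<DEL>\t.\tPASS\t"
                f"GENE={gene};SVTYPE=DEL\tGT\t" + "\t".join(gts)
            )
            records.append((chrom, pos, rec))
    records.sort(key=lambda r: (r[0], r[1]))
    lines.extend(r[2] for r in records)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str) -> tuple[SiteTable, GenotypeMatrix, CopyNumberTable]:
    """Read a VCF written by :func:`write_vcf` back into the data model."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    subjects = list(vcf.samples)
    site_rows = []
    site_calls: list[list[tuple | None]] = []
    cn_rows = []
    for var in vcf:
        info = dict(var.INFO)
        gene = info.get("GENE", "NA")
        if var.ID and var.ID.startswith(_SV_ID_PREFIX):
            for subj, g in zip(subjects, var.genotypes):
                alleles = [a for a in g[:-1] if a >= 0]
                copies = 2 - sum(1 for a in alleles if a == 1)
                cn_rows.append({"subject": subj, "gene": gene, "copies": copies})
            continue
        site_rows.append(
            {
                "site_id": var.ID,
                "chrom": var.CHROM,
                "pos": var.POS,
                "gene": gene,
                "ref": var.REF,
                "alt": var.ALT[0],
                "consequence": info.get("CSQ", "missense"),
            }
        )
        col = []
        for g in var.genotypes:
            alleles = [a for a in g[:-1] if a >= 0]
            if not alleles:
                col.append(None)
            else:
                col.append(tuple(sorted(var.REF if a == 0 else var.ALT[0] for a in alleles)))
        site_calls.append(col)
    site_table = SiteTable(pd.DataFrame(site_rows))
    calls = [[site_calls[j][i] for j in range(len(site_calls))] for i in range(len(subjects))]
    genotypes = GenotypeMatrix(subjects, site_table.site_ids, calls)
    cn_frame = pd.DataFrame(cn_rows, columns=["subject", "gene", "copies"])
    cnv_genes = tuple(sorted(set(cn_frame["gene"]))) or ("TAS2R43", "TAS2R45")
    return site_table, genotypes, CopyNumberTable(cn_frame, cnv_genes)


def save_scenario(scenario, path: str) -> None:
    """Serialise a Scenario to YAML (JSON-compatible structure)."""
    import yaml

    from .scenario import Scenario  # noqa: F401

    doc = {
        "seed": scenario.seed,
        "blocks": [
            {
                "block_id": b.block_id,
                "chrom": b.chrom,
                "genes": [
                    {
                        "name": g.name,
                        "chrom": g.chrom,
                        "cnv_capable": g.cnv_capable,
                        "sites": [
                            {"site_id": s.site_id, "pos": s.pos, "ref": s.ref,
                             "alt": s.alt, "consequence": s.consequence}
                            for s in g.sites
                        ],
                        "haplotypes": {k: list(v) for k, v in g.haplotypes.items()},
                    }
                    for g in b.genes
                ],
            }
            for b in scenario.blocks
        ],
        "lrh_pools": {
            bid: [
                {"name": h.name, "frequency": h.frequency, "gene_haps": dict(h.gene_haps)}
                for h in pool
            ]
            for bid, pool in scenario.lrh_pools.items()
        },
        "receptor_table": [
            {"allele": a, "compound": c, "ec50": p.ec50, "amplitude": p.amplitude,
             "hill_n": p.hill_n, "activation_threshold": p.activation_threshold,
             "functional_class": p.functional_class}
            for (a, c), p in scenario.receptor_table.items()
        ],
        "links": {
            c: {"offset": l.offset, "slope": l.slope, "subject_sd": l.subject_sd,
                "nonresponder_threshold": l.nonresponder_threshold,
                "detection_shift": l.detection_shift}
            for c, l in scenario.links.items()
        },
        "psych": {
            "starts": dict(scenario.psych.starts),
            "n_steps": scenario.psych.n_steps,
            "ratio": scenario.psych.ratio,
            "n_repetitions": scenario.psych.n_repetitions,
            "guess_rate": scenario.psych.guess_rate,
            "detection_sigma": scenario.psych.detection_sigma,
            "recognition_sigma": scenario.psych.recognition_sigma,
            "intensity_shift": scenario.psych.intensity_shift,
            "intensity_sigma": scenario.psych.intensity_sigma,
            "imax_mean": scenario.psych.imax_mean,
            "imax_sd": scenario.psych.imax_sd,
            "intensity_noise_sd": scenario.psych.intensity_noise_sd,
            "recognition_mode": scenario.psych.recognition_mode,
        },
        "plate": {
            "concentrations": list(scenario.plate.concentrations),
            "n_days": scenario.plate.n_days,
            "day_sd": scenario.plate.day_sd,
            "noise_sd": scenario.plate.noise_sd,
            "f0_mean": scenario.plate.f0_mean,
            "f0_cv": scenario.plate.f0_cv,
            "n_empty_per_group": scenario.plate.n_empty_per_group,
            "n_pc_per_day": scenario.plate.n_pc_per_day,
            "pc_amplitude": scenario.plate.pc_amplitude,
            "artefact_onset": scenario.plate.artefact_onset,
            "artefact_slope": scenario.plate.artefact_slope,
        },
        "inventory": {c: list(g) for c, g in scenario.inventory.items()},
        "artefact_ceilings": dict(scenario.artefact_ceilings),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scenario(path: str):
    import yaml

    from .scenario import (
        BlockDef, GeneDef, LinkModel, LongRangeHaplotype, PlateDesign,
        PsychDesign, ReceptorParams, Scenario, SiteDef,
    )

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    blocks = [
        BlockDef(
            b["block_id"],
            b["chrom"],
            [
                GeneDef(
                    g["name"],
                    g["chrom"],
                    [SiteDef(**s) for s in g["sites"]],
                    {k: tuple(v) for k, v in g["haplotypes"].items()},
                    cnv_capable=g["cnv_capable"],
                )
                for g in b["genes"]
            ],
        )
        for b in doc["blocks"]
    ]
    return Scenario(
        blocks=blocks,
        lrh_pools={
            bid: [LongRangeHaplotype(h["name"], h["frequency"], h["gene_haps"]) for h in pool]
            for bid, pool in doc["lrh_pools"].items()
        },
        receptor_table={
            (r["allele"], r["compound"]): ReceptorParams(
                r["ec50"], r["amplitude"], r["hill_n"],
                r["activation_threshold"], r["functional_class"],
            )
            for r in doc["receptor_table"]
        },
        links={c: LinkModel(**l) for c, l in doc["links"].items()},
        psych=PsychDesign(**doc["psych"]),
        plate=PlateDesign(**{**doc["plate"], "concentrations": tuple(doc["plate"]["concentrations"])}),
        inventory={c: tuple(g) for c, g in doc["inventory"].items()},
        artefact_ceilings=doc["artefact_ceilings"],
        seed=doc["seed"],
    )


def write_tsv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_haplotype_set(hset, path: str) -> None:
    rows = [
        {
            "scope": hset.scope,
            "name": hset.name_of(i),
            "alleles": ",".join(map(str, hset.haplotypes[i])),
            "frequency": hset.frequencies[i],
        }
        for i in range(len(hset.haplotypes))
    ]
    write_tsv(pd.DataFrame(rows), path)
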