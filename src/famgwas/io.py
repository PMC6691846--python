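"""Standard-format I/O: VCF, pedigree/phenotype TSV, report files.

Dosage convention for diploid GT fields: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
./. -> missing. Multi-allelic and non-SNP records are skipped on read
(counted and logged). Writing produces minimal VCF v4.2 with 1-based
positions and "./." for missing calls; the writer round-trips exactly
against the reader.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import GenotypeMatrix, Pedigree

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
]

log = logging.getLogger("famgwas")

_GT_CODE = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}  # cyvcf2 gt_types


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid biallelic SNPs from a VCF into a genotype matrix.

    Records that are multi-allelic, symbolic, or not single-nucleotide
    are skipped; the count is logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows, meta = [], []
    n_skipped = 0
    for v in vcf:
        alts = v.ALT
        if (
            len(alts) != 1
            or len(v.REF) != 1
            or len(alts[0]) != 1
            or v.REF not in "ACGT"
            or alts[0] not in "ACGT"
        ):
            n_skipped += 1
            continue
        rows.append([_GT_CODE.get(int(t), np.nan) for t in v.gt_types])
        meta.append(
            (
                v.CHROM,
                v.POS,
                v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}",
                v.REF,
                alts[0],
            )
        )
    vcf.close()
    if n_skipped:
        log.info("skipped %d multi-allelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "id", "ref", "alt"])
    dosages = (
        np.array(rows, dtype=float).T
        if rows
        else np.empty((len(samples), 0))
    )
    gm = GenotypeMatrix(samples, variants, dosages)
    gm.n_skipped_records = n_skipped
    return gm


_DOSE_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the genotype matrix as minimal VCF v4.2 (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, row in enumerate(gm.variants.itertuples(index=False)):
            gts = [
                "./." if np.isnan(d) else _DOSE_GT[d]
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_pedigree_tsv(ped: Pedigree, path) -> None:
    ped.table.to_csv(path, sep="\t", index=False, na_rep="")


def read_pedigree_tsv(path) -> Pedigree:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = table.replace({"": None})
    return Pedigree(table)


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
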