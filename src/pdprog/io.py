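"""Tabular and genotype I/O.

All tabular intermediates are tab-delimited text with a header row.
Genotypes travel either as VCF with a per-sample ``DS`` (dosage) FORMAT
field, or as a plain subjects x variants matrix with a sidecar variant table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .simulate import GenotypeMatrix


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF with a DS FORMAT field."""
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "DS"), ("Number", "1"), ("Type", "Float"),
                                     ("Description", "Alternate allele dosage")])
    for chrom in pd.unique(genotypes.variants["chrom"]):
        max_pos = int(genotypes.variants.loc[genotypes.variants["chrom"] == chrom, "pos"].max())
        header.contigs.add(str(chrom), length=max_pos + 1)
    for sid in genotypes.subject_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, row in enumerate(genotypes.variants.itertuples()):
            rec = vcf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1, stop=int(row.pos),
                alleles=(row.ref, row.alt), id=row.variant_id,
            )
            for i, sid in enumerate(genotypes.subject_ids):
                rec.samples[sid]["DS"] = float(genotypes.dosage[i, j])
            vcf.write(rec)


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with DS dosages (falling back to GT allele counts)."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows = []
        dosages = []
        for rec in vcf:
            has_ds = "DS" in rec.format
            if has_ds:
                d = np.array([rec.samples[s]["DS"] for s in samples], float)
            else:
                d = np.array(
                    [sum(a or 0 for a in rec.samples[s]["GT"]) for s in samples], float
                )
            dosages.append(d)
            rows.append(
                (
                    rec.id or f"{rec.chrom}:{rec.pos}",
                    str(rec.chrom),
                    int(rec.pos),
                    rec.ref,
                    rec.alts[0] if rec.alts else ".",
                )
            )
    dosage = np.array(dosages).T if dosages else np.empty((len(samples), 0))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    variants["freq"] = dosage.mean(axis=0) / 2.0 if len(rows) else []
    return GenotypeMatrix(dosage=dosage, variants=variants, subject_ids=samples)


# ---------------------------------------------------------------------------
# plain dosage matrix + sidecar


def write_dosage_matrix(genotypes: GenotypeMatrix, matrix_path, variants_path) -> None:
    mat = pd.DataFrame(
        genotypes.dosage,
        index=pd.Index(genotypes.subject_ids, name="subject_id"),
        columns=genotypes.variants["variant_id"],
    )
    mat.to_csv(matrix_path, sep="\t")
    genotypes.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_matrix(matrix_path, variants_path) -> GenotypeMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="subject_id")
    variants = pd.read_csv(variants_path, sep="\t", dtype={"chrom": str})
    if list(mat.columns) != list(variants["variant_id"]):
        raise ValueError("dosage matrix columns do not match the variant sidecar")
    return GenotypeMatrix(
        dosage=mat.to_numpy(float), variants=variants, subject_ids=[str(s) for s in mat.index]
    )
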