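"""Plain-text readers/writers for cohort tables.

Everything is TSV with header rows; genotypes can additionally go out as a
minimal haploid-style VCF and gene annotations as BED (0-based half-open,
converted to the package's 1-based inclusive intervals on read).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MetaboliteMatrix
from .simdata import GeneAnnotation, GenotypeMatrix, SyntheticCohort


# -- metabolome -------------------------------------------------------------

def write_metabolite_matrix(matrix: MetaboliteMatrix, path) -> None:
    df = matrix.data.reset_index()
    if matrix.batch is not None:
        df.insert(2, "batch", matrix.batch.to_numpy())
    df.to_csv(path, sep="\t", index=False)


def read_metabolite_matrix(path, stage: str = "raw") -> MetaboliteMatrix:
    df = pd.read_csv(path, sep="\t")
    batch = None
    if "batch" in df.columns:
        batch = df["batch"]
        df = df.drop(columns=["batch"])
    df = df.set_index(["line_id", "diet"])
    if batch is not None:
        batch = pd.Series(batch.to_numpy(), index=df.index, name="batch")
    return MetaboliteMatrix(data=df, batch=batch, stage=stage)


# -- genotypes --------------------------------------------------------------

def write_genotypes_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Lines x variants dosage table; variant ids are chrom_pos."""
    ids = [f"{c}_{p}" for c, p in
           zip(genotypes.variants["chrom"], genotypes.variants["pos"])]
    df = pd.DataFrame(genotypes.dosage, index=genotypes.line_ids, columns=ids)
    df.rename_axis("line_id").to_csv(path, sep="\t")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chrom, pos = zip(*(c.rsplit("_", 1) for c in df.columns))
    variants = pd.DataFrame({
        "chrom": chrom, "pos": [int(p) for p in pos],
        "ref": "N", "alt": "N",
        "monomorphic": [False] * len(pos),
    })
    return GenotypeMatrix(list(df.index), variants,
                          df.to_numpy(dtype=float))


def write_genotypes_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Minimal VCF with haploid GT calls (inbred lines: 0 or 1, . missing)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.line_ids) + "\n")
        for j, row in enumerate(genotypes.variants.itertuples(index=False)):
            calls = ["." if np.isnan(d) else str(int(d))
                     for d in genotypes.dosage[:, j]]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.chrom}_{row.pos}\t"
                     f"{row.ref}\t{row.alt}\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    header, rows, dosage = None, [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header = line.lstrip("#").split("\t")
                continue
            f = line.split("\t")
            rows.append({"chrom": f[0], "pos": int(f[1]),
                         "ref": f[3], "alt": f[4], "monomorphic": False})
            dosage.append([np.nan if c.split(":")[0] == "." else
                           float(c.split(":")[0]) for c in f[9:]])
    if header is None:
        raise ValueError(f"no #CHROM header line in {path}")
    line_ids = header[9:]
    return GenotypeMatrix(line_ids, pd.DataFrame(rows),
                          np.asarray(dosage, dtype=float).T)


# -- gene annotation --------------------------------------------------------

def write_annotation_bed(annotation: GeneAnnotation, path) -> None:
    """BED: 0-based half-open intervals."""
    df = annotation.genes
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"] - 1,   # 1-based inclusive -> 0-based half-open
        "end": df["end"],
        "name": df["gene_id"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path, window_bp: int = 1000) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    genes = pd.DataFrame({
        "gene_id": df["name"],
        "chrom": df["chrom"],
        "start": df["start"] + 1,   # back to 1-based inclusive
        "end": df["end"],
    })
    return GeneAnnotation(genes, window_bp=window_bp)


# -- whole cohort -----------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.config.to_json(out / "config.json")
    write_genotypes_tsv(cohort.genotypes, out / "genotypes.tsv")
    write_genotypes_vcf(cohort.genotypes, out / "genotypes.vcf")
    write_annotation_bed(cohort.annotation, out / "genes.bed")
    write_metabolite_matrix(cohort.metabolome_raw, out / "metabolome_raw.tsv")
    cohort.latent.reset_index().to_csv(out / "truth_latent_metabolome.tsv",
                                       sep="\t", index=False)
    cohort.lifespans.to_csv(out / "lifespans.tsv", sep="\t", index=False)
    cohort.covariates.reset_index().to_csv(out / "covariates.tsv",
                                           sep="\t", index=False)
    cohort.line_truth.to_csv(out / "truth_lines.tsv", sep="\t", index=False)
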