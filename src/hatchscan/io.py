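"""Plain-text I/O for the pipeline's tables.

Everything round-trips through TSV so runs are inspectable and diffable:
genotypes (individuals x loci, 0/1/2/NA), long-form allele depths,
phenotypes, linkage maps, BED-like alignments (0-based half-open), and a
GT-only VCF for interoperability with standard tooling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from hatchscan.containers import GenotypeMatrix


# -- genotypes ---------------------------------------------------------------


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    """Rows = individuals, columns = line/generation/sex then loci."""
    meta = gm.samples[["line", "generation", "sex"]]
    out = pd.concat([meta, gm.dosages], axis=1)
    out.to_csv(path, sep="\t", index_label="individual", na_rep="NA")


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="individual", na_values="NA")
    df.index.name = None
    meta = df[["line", "generation", "sex"]]
    dosages = df.drop(columns=["line", "generation", "sex"]).astype(float)
    return GenotypeMatrix(dosages, meta)


def write_vcf(gm: GenotypeMatrix, path, chrom_map: pd.DataFrame | None = None) -> None:
    """Minimal GT-only VCF; loci without map positions go on contig 'un'."""
    pos_lookup = {}
    if chrom_map is not None:
        for r in chrom_map.itertuples():
            pos_lookup[r.locus] = (str(r.chromosome), int(round(r.cM * 1e5)) + 1)
    inds = list(gm.individuals)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(inds)
            + "\n"
        )
        arr = gm.dosages.to_numpy(dtype=float)
        gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, locus in enumerate(gm.loci):
            chrom, pos = pos_lookup.get(locus, ("un", j + 1))
            gts = [
                gt_codes.get(arr[i, j], "./.")
                if not np.isnan(arr[i, j])
                else "./."
                for i in range(len(inds))
            ]
            fh.write(
                f"{chrom}\t{pos}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path, samples: pd.DataFrame | None = None):
    """Read a VCF back into a dosage matrix (alt-allele counts) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    loci = []
    rows = []
    for variant in vcf:
        loci.append(variant.ID)
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types.astype(float)
        dosage = np.where(gt == 3, 2.0, gt)
        dosage[gt == 2] = np.nan
        rows.append(dosage)
    vcf.close()
    dosages = pd.DataFrame(
        np.array(rows, dtype=float).T, index=pd.Index(inds), columns=loci
    )
    if samples is None:
        return dosages
    return GenotypeMatrix(dosages, samples.loc[dosages.index])


# -- simple tables -----------------------------------------------------------


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index_label="individual", na_rep="NA")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="individual", na_values="NA")
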