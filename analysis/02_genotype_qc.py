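"""Call genotypes from read depths and run the QC cascade.

Reads the depth table from 01, applies the depth-based caller
(heterozygote iff both alleles >= 2 reads and total > 10), then the MAF /
missingness / Hardy-Weinberg filters and population-conditional
imputation.  Reports caller concordance against the simulated truth and
the QC bookkeeping.

Run:  python analysis/02_genotype_qc.py [--datadir results/data] [--outdir results/qc]
"""

import argparse
from pathlib import Path

from hatchscan import genoqc as gq
from hatchscan import io as hio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/qc"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    depths = hio.read_table(args.datadir / "depths.tsv")
    truth = hio.read_genotypes_tsv(args.datadir / "genotypes_true.tsv")
    gm = gq.call_genotypes(depths, truth.samples)

    called = gm.dosages[truth.dosages.columns].loc[truth.dosages.index]
    mask = called.notna()
    concord = (called[mask] == truth.dosages[mask]).sum().sum() / mask.sum().sum()
    print(f"caller concordance with simulated truth: {concord:.4f} "
          f"({1 - mask.to_numpy().mean():.3%} calls missing)")

    clean, report = gq.run_qc(gm)
    hio.write_genotypes_tsv(clean, args.outdir / "genotypes_qc.tsv")
    hio.write_table(report.to_frame(), args.outdir / "qc_report.tsv", index=True)
    fis = gq.compute_fis(clean)
    hio.write_table(fis, args.outdir / "fis.tsv", index=True)

    print(f"QC cascade: {report.loci_in} loci in -> "
          f"{report.loci_removed_maf} removed by MAF, "
          f"{report.loci_removed_missingness} by call rate, "
          f"{report.loci_removed_hwe} by HWE -> {report.loci_out} out")
    print(f"individuals removed (>=50% missing): {report.individuals_removed}")
    print(f"imputation allele-frequency correlation: "
          f"{report.imputation_freq_correlation:.4f}")
    print(f"median F_IS in founders after QC: {fis['P1_F0'].median():.3f}")


if __name__ == "__main__":
    main()
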