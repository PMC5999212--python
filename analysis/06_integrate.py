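"""Line phenotype models, PCA trajectories, and the trait/outlier overlap.

Fits the line-difference models for the six traits on the F3 generation
(age-4 fish except for the age model), projects each trait's predictor
loci by PCA across all line x generation groups, and cross-tabulates
trait-associated loci against the outlier calls from 05.  The overlap
count by line is the study's headline comparison: selection on
spawn-timing loci in the segregated line should yield more segregated
than integrated overlap rows.

Run:  python analysis/06_integrate.py [--outdir results/integrate]
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from hatchscan import io as hio
from hatchscan.containers import TRAITS
from hatchscan.integrate import fit_line_models, overlap_report, pca_trajectories


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--qcdir", type=Path, default=Path("results/qc"))
    ap.add_argument("--mapdir", type=Path, default=Path("results/map"))
    ap.add_argument("--rfdir", type=Path, default=Path("results/rf"))
    ap.add_argument("--scandir", type=Path, default=Path("results/scan"))
    ap.add_argument("--outdir", type=Path, default=Path("results/integrate"))
    ap.add_argument("--proximity-cm", type=float, default=1.0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    pheno = hio.read_phenotypes(args.datadir / "phenotypes.tsv")
    gm = hio.read_genotypes_tsv(args.qcdir / "genotypes_qc.tsv")
    linkage_map = hio.read_table(args.mapdir / "linkage_map_augmented.tsv")
    locus_calls = hio.read_table(args.scandir / "outlier_loci.tsv")
    regions = hio.read_table(args.scandir / "outlier_regions.tsv")

    preds = {}
    for p in sorted(args.rfdir.glob("predictors_*.tsv")):
        preds[p.stem.replace("predictors_", "")] = hio.read_table(p)["locus"].tolist()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = []
        for trait in TRAITS:
            fit = fit_line_models(pheno, trait)
            t = fit.table.copy()
            t.insert(0, "trait", trait)
            t.insert(1, "term", t.index)
            fits.append(t.reset_index(drop=True))
        model_table = pd.concat(fits, ignore_index=True)
        hio.write_table(model_table, args.outdir / "line_models.tsv")

        traj = pca_trajectories(gm, preds, seed=1)
        dist_rows = []
        for trait, d in traj.items():
            dd = d["centroid_distances"].copy()
            dd.insert(0, "trait", trait)
            dist_rows.append(dd)
            hio.write_table(
                d["coordinates"].reset_index(names="individual"),
                args.outdir / f"pca_{trait}.tsv",
            )
        hio.write_table(pd.concat(dist_rows, ignore_index=True),
                        args.outdir / "centroid_distances.tsv")

        rep = overlap_report(preds, locus_calls, regions, linkage_map,
                             proximity_cM=args.proximity_cm)
    hio.write_table(rep, args.outdir / "overlap_report.tsv")

    sig = model_table[(model_table["term"] == "line") & (model_table["p"] < 0.05)]
    print("traits with a significant line effect (F3, age-4 fish): "
          + (", ".join(sig["trait"]) if len(sig) else "none"))
    print(f"overlap report: {len(rep)} rows")
    spawn = rep[rep["trait"] == "spawn_day"]
    for line in ("INT", "SEG"):
        print(f"  spawn-timing overlap rows in {line}: "
              f"{int((spawn['line'] == line).sum())}")


if __name__ == "__main__":
    main()
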