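"""Scan both hatchery lines for divergence outliers against the founders.

For every line x generation: per-locus Weir-Cockerham FST versus the
founders, a Gaussian-kernel smoothed track per chromosome with a
resampled 95% neutral envelope (outlier regions where the track exceeds
it), and the temporal drift-simulation test with each line's effective
size (outlier loci whose temporal FST exceeds the drift null).

Run:  python analysis/05_outlier_scan.py [--seed 7] [--outdir results/scan]
"""

import argparse
import warnings
from pathlib import Path

from hatchscan import io as hio
from hatchscan.popgen import scan_lines


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--qcdir", type=Path, default=Path("results/qc"))
    ap.add_argument("--mapdir", type=Path, default=Path("results/map"))
    ap.add_argument("--outdir", type=Path, default=Path("results/scan"))
    ap.add_argument("--ne-int", type=int, default=150)
    ap.add_argument("--ne-seg", type=int, default=60)
    ap.add_argument("--resamples", type=int, default=500)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    gm = hio.read_genotypes_tsv(args.qcdir / "genotypes_qc.tsv")
    linkage_map = hio.read_table(args.mapdir / "linkage_map_augmented.tsv")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = scan_lines(
            gm, linkage_map,
            ne={"INT": args.ne_int, "SEG": args.ne_seg},
            n_resamples=args.resamples, seed=args.seed,
        )

    hio.write_table(res["regions"], args.outdir / "outlier_regions.tsv")
    hio.write_table(res["locus_calls"], args.outdir / "outlier_loci.tsv")
    track_dir = args.outdir / "tracks"
    track_dir.mkdir(exist_ok=True)
    for (pop, chrom), track in res["tracks"].items():
        hio.write_table(track, track_dir / f"{pop}_chr{chrom}.tsv")

    regions = res["regions"]
    calls = res["locus_calls"]
    print(f"{len(regions)} outlier regions and {len(calls)} temporal outlier "
          f"loci across all line x generation comparisons")
    for line in ("INT", "SEG"):
        nr = int((regions["line"] == line).sum())
        nl = int((calls["line"] == line).sum())
        print(f"  {line}: {nr} regions, {nl} temporal outlier loci")


if __name__ == "__main__":
    main()
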