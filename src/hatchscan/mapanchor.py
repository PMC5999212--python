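"""Anchor unmapped loci to the linkage map via proxy-genome alignments.

Loci absent from the linkage map inherit the map position (chromosome and
cM) of the nearest *mapped* locus aligned to the same contig of the same
proxy genome, provided both alignments have mapping quality >= 10 and the
interval gap between them is at most 100 kb.  When a locus qualifies
through more than one proxy genome, the assignments are reconciled:
agreement on chromosome keeps the closer donor's position, disagreement
drops the locus.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_MIN_MAPQ = 10
DEFAULT_MAX_DISTANCE = 100_000

ASSIGNMENT_COLUMNS = [
    "locus",
    "donor",
    "genome",
    "distance",
    "chromosome",
    "cM",
]


def _interval_gap(
    start_a: np.ndarray, end_a: np.ndarray, start_b: np.ndarray, end_b: np.ndarray
) -> np.ndarray:
    """Gap in bp between [start_a, end_a) and [start_b, end_b); 0 if they overlap."""
    return np.maximum(
        0, np.maximum(start_b - end_a, start_a - end_b)
    )


def closest_mapped(
    alignments: pd.DataFrame,
    linkage_map: pd.DataFrame,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> pd.DataFrame:
    """Assign unmapped loci to the closest qualifying mapped locus.

    ``alignments`` is BED-like (``contig, start, end, locus, mapq, genome``);
    ``linkage_map`` has ``locus, chromosome, cM, mapped``.  Both the mapped
    and the unmapped alignment must reach ``min_mapq`` and lie within
    ``max_distance`` bp (interval gap) on the same contig of the same
    genome.  Ties are broken toward the lexicographically smallest donor
    locus id, so assignments are deterministic.  Returns one row per
    assigned unmapped locus per genome.
    """
    aln = alignments[alignments["mapq"] >= min_mapq]
    mapped_ids = set(linkage_map.loc[linkage_map["mapped"], "locus"])
    map_pos = linkage_map.set_index("locus")[["chromosome", "cM"]]

    is_mapped = aln["locus"].isin(mapped_ids)
    donors = aln[is_mapped]
    queries = aln[~is_mapped]

    rows = []
    donor_groups = {
        key: grp for key, grp in donors.groupby(["genome", "contig"], sort=False)
    }
    for key, qgrp in queries.groupby(["genome", "contig"], sort=False):
        dgrp = donor_groups.get(key)
        if dgrp is None:
            continue
        d_start = dgrp["start"].to_numpy()
        d_end = dgrp["end"].to_numpy()
        d_loc = dgrp["locus"].to_numpy()
        order = np.argsort(d_loc)  # lowest donor id wins ties
        d_start, d_end, d_loc = d_start[order], d_end[order], d_loc[order]
        for q in qgrp.itertuples():
            gaps = _interval_gap(
                np.full_like(d_start, q.start), np.full_like(d_end, q.end),
                d_start, d_end,
            )
            best = int(np.argmin(gaps))  # argmin takes first -> smallest donor id
            if gaps[best] <= max_distance:
                donor = d_loc[best]
                rows.append(
                    {
                        "locus": q.locus,
                        "donor": donor,
                        "genome": key[0],
                        "distance": int(gaps[best]),
                        "chromosome": map_pos.at[donor, "chromosome"],
                        "cM": map_pos.at[donor, "cM"],
                    }
                )
    out = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    return out.sort_values(["locus", "genome"], kind="stable").reset_index(drop=True)


def reconcile_genomes(assignments: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-genome assignments into one per locus.

    Loci assigned through a single genome keep that assignment; loci
    assigned through several keep it only when the chromosomes agree (the
    closer donor supplies the position).  Chromosome conflicts are dropped
    and returned separately for logging.
    """
    kept, dropped = [], []
    for locus, grp in assignments.groupby("locus", sort=True):
        if grp["chromosome"].nunique() == 1:
            kept.append(grp.sort_values(["distance", "donor"]).iloc[0])
        else:
            dropped.append(grp)
    kept_df = (
        pd.DataFrame(kept).reset_index(drop=True)
        if kept
        else pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    )
    dropped_df = (
        pd.concat(dropped).reset_index(drop=True)
        if dropped
        else pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    )
    return kept_df, dropped_df


def anchor_loci(
    alignment_sets: list[pd.DataFrame],
    linkage_map: pd.DataFrame,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run closest-mapped assignment over several genomes and reconcile.

    Returns ``(augmented_map, assignments)`` where the augmented linkage
    map contains the original mapped loci plus anchored loci at their
    donors' positions (still flagged ``mapped=False`` origin via the
    ``anchored`` column).
    """
    per_genome = [
        closest_mapped(aln, linkage_map, min_mapq, max_distance)
        for aln in alignment_sets
    ]
    all_assign = (
        pd.concat(per_genome, ignore_index=True)
        if per_genome
        else pd.DataFrame(columns=ASSIGNMENT_COLUMNS)
    )
    final, _conflicts = reconcile_genomes(all_assign)

    augmented = linkage_map.copy()
    augmented["anchored"] = False
    if not final.empty:
        pos = final.set_index("locus")
        idx = augmented["locus"].isin(pos.index)
        augmented.loc[idx, "chromosome"] = (
            pos.loc[augmented.loc[idx, "locus"], "chromosome"].to_numpy()
        )
        augmented.loc[idx, "cM"] = pos.loc[augmented.loc[idx, "locus"], "cM"].to_numpy()
        augmented.loc[idx, "anchored"] = True
    augmented["positioned"] = augmented["mapped"] | augmented["anchored"]
    return augmented, final
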