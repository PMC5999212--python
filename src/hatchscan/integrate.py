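"""Phenotype line models, PCA trajectories and the trait/outlier overlap.

Three questions are answered here.  Do the two hatchery lines differ
phenotypically?  Each trait is modeled as
``y ~ line + sex + line:sex`` (Gaussian identity link; Poisson log link
for the ordinal age at maturity), and weight additionally includes
``log(fork length)`` to account for allometric growth, fitted on the log
scale.  Has the multivariate composition of trait-associated genotypes
diverged?  The dosage matrix restricted to a trait's predictor loci is
projected by PCA with every line x generation group together, and the
per-generation distance between line centroids quantifies divergence.
Which traits sit where selection acted?  The overlap report cross-tabulates
trait-associated loci against outlier calls: exact locus identity, map
proximity within a configurable cM radius, and containment in outlier
regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from hatchscan.containers import GenotypeMatrix


# ---------------------------------------------------------------------------
# daily growth coefficient


def compute_dgc(initial_weight: float, final_weight: float, days: float):
    """Daily growth coefficient: 100 * (final^(1/3) - initial^(1/3)) / days.

    Weights in kg, days >= 1; negative when weight is lost.  Accepts
    scalars or arrays.
    """
    initial = np.asarray(initial_weight, dtype=float)
    final = np.asarray(final_weight, dtype=float)
    d = np.asarray(days, dtype=float)
    if (initial <= 0).any() or (final <= 0).any():
        raise ValueError("weights must be positive")
    if (d < 1).any():
        raise ValueError("days must be >= 1")
    out = 100.0 * (np.cbrt(final) - np.cbrt(initial)) / d
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# line models


@dataclass
class ModelFit:
    """Coefficients of one line-difference model.

    ``table`` rows are indexed by term (intercept, line, sex, line:sex and,
    for weight, log fork length) with columns ``coef, se, stat, p``.  The
    reference level is integrated females.
    """

    trait: str
    family: str  # gaussian_identity | poisson_log
    table: pd.DataFrame
    n_int: int
    n_seg: int
    aliased: list[str]


def _design(ph: pd.DataFrame, with_length: bool) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=ph.index)
    X["intercept"] = 1.0
    X["line"] = (ph["line"] == "SEG").astype(float)
    X["sex"] = (ph["sex"] == "M").astype(float)
    X["line:sex"] = X["line"] * X["sex"]
    if with_length:
        X["log_fork_length"] = np.log(ph["length_cm"].astype(float))
    aliased: list[str] = []
    arr = X.to_numpy(dtype=float)
    diag = np.abs(np.diag(np.linalg.qr(arr)[1]))
    keep = diag > 1e-9 * max(1.0, diag.max())
    if not keep.all():
        aliased = list(X.columns[~keep])
        X = X.loc[:, keep]
    return X, aliased


def fit_line_models(
    pheno: pd.DataFrame,
    trait: str,
    generation: int | None = 3,
    age4_only: bool = True,
) -> ModelFit:
    """Fit the line-difference model for one trait.

    By default the F3 generation is analyzed (the most recent with large
    samples in the emulated design) and, except for age at maturity, only
    age-4 fish.  Age uses a Poisson GLM with log link; weight is modeled as
    ``log(w) ~ line + sex + line:sex + log(fork length)``; the remaining
    traits are Gaussian with identity link.
    """
    ph = pheno[pheno["line"].isin(["INT", "SEG"])]
    if generation is not None:
        ph = ph[ph["generation"] == generation]
    if age4_only and trait != "age":
        ph = ph[ph["age"] == 4]
    ph = ph.dropna(subset=[trait])

    if trait == "weight_kg":
        y = np.log(ph[trait].astype(float).to_numpy())
        X, aliased = _design(ph, with_length=True)
        family = "gaussian_identity"
    elif trait == "age":
        y = ph[trait].astype(float).to_numpy()
        X, aliased = _design(ph, with_length=False)
        family = "poisson_log"
    else:
        y = ph[trait].astype(float).to_numpy()
        X, aliased = _design(ph, with_length=False)
        family = "gaussian_identity"
    if aliased:
        warnings.warn(f"aliased terms dropped for {trait}: {aliased}")

    if family == "poisson_log":
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        stat_name = "z"
    else:
        res = sm.OLS(y, X).fit()
        stat_name = "t"
    table = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            stat_name: res.tvalues,
            "p": res.pvalues,
        }
    )
    return ModelFit(
        trait=trait,
        family=family,
        table=table,
        n_int=int((ph["line"] == "INT").sum()),
        n_seg=int((ph["line"] == "SEG").sum()),
        aliased=aliased,
    )


# ---------------------------------------------------------------------------
# PCA trajectories


def pca_trajectories(
    gm: GenotypeMatrix,
    predictor_loci: dict[str, list[str]],
    n_components: int = 2,
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, dict]:
    """Project all line x generation groups on PCs of each trait's predictors.

    For every trait, PCA is run on the centered dosage matrix restricted to
    that trait's predictor loci with *all* individuals projected together.
    Returns per trait: per-individual coordinates, per-group centroids, and
    the per-generation INT-SEG centroid distance with a bootstrap SE.
    Predictor sets of a single locus yield a 1-D projection (logged).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for trait, loci in predictor_loci.items():
        loci = [l for l in loci if l in gm.loci]
        if not loci:
            continue
        if len(loci) == 1:
            warnings.warn(f"trait {trait!r} has a single predictor locus; 1-D projection")
        k = min(n_components, len(loci))
        M = gm.dosages[loci].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        # SVD-based PCA; loci order cannot matter because the projection is
        # a rotation of the same centered cloud
        u, s, _ = np.linalg.svd(M, full_matrices=False)
        coords = u[:, :k] * s[:k]
        cdf = pd.DataFrame(
            coords, index=gm.individuals, columns=[f"PC{i+1}" for i in range(k)]
        )
        cdf["population"] = gm.samples["population"].to_numpy()
        cdf["line"] = gm.samples["line"].to_numpy()
        cdf["generation"] = gm.samples["generation"].to_numpy()

        centroids = cdf.groupby("population")[[f"PC{i+1}" for i in range(k)]].mean()

        dist_rows = []
        for gen in sorted(cdf.loc[cdf["line"] != "P1", "generation"].unique()):
            a = cdf[(cdf["line"] == "INT") & (cdf["generation"] == gen)]
            b = cdf[(cdf["line"] == "SEG") & (cdf["generation"] == gen)]
            if a.empty or b.empty:
                continue
            pcs = [f"PC{i+1}" for i in range(k)]
            av, bv = a[pcs].to_numpy(), b[pcs].to_numpy()
            d = float(np.linalg.norm(av.mean(axis=0) - bv.mean(axis=0)))
            boots = np.empty(n_boot)
            for r in range(n_boot):
                ai = av[rng.integers(0, len(av), len(av))]
                bi = bv[rng.integers(0, len(bv), len(bv))]
                boots[r] = np.linalg.norm(ai.mean(axis=0) - bi.mean(axis=0))
            dist_rows.append(
                {
                    "generation": int(gen),
                    "distance": d,
                    "bootstrap_se": float(boots.std(ddof=1)),
                }
            )
        out[trait] = {
            "coordinates": cdf,
            "centroids": centroids,
            "centroid_distances": pd.DataFrame(
                dist_rows, columns=["generation", "distance", "bootstrap_se"]
            ),
        }
    return out


# ---------------------------------------------------------------------------
# overlap report

OVERLAP_COLUMNS = [
    "trait",
    "trait_locus",
    "overlap_type",  # identity | proximity | region
    "outlier_locus",
    "method",
    "line",
    "generation",
    "chromosome",
    "distance_cM",
    "region_start_cM",
    "region_end_cM",
]


def overlap_report(
    predictor_loci: dict[str, list[str]],
    locus_calls: pd.DataFrame,
    regions: pd.DataFrame | None = None,
    linkage_map: pd.DataFrame | None = None,
    proximity_cM: float = 1.0,
) -> pd.DataFrame:
    """Cross-tabulate trait-associated loci against outlier calls.

    Three overlap types are reported: (a) exact identity between a trait
    locus and an outlier locus; (b) a trait locus within ``proximity_cM``
    of an outlier locus on the same chromosome; (c) a trait locus inside a
    called outlier region.  Unmapped trait loci are eligible for (a) only.
    Rows are deterministically ordered.
    """
    pos = None
    if linkage_map is not None:
        lm = linkage_map
        col = "positioned" if "positioned" in lm.columns else "mapped"
        pos = lm.loc[lm[col]].set_index("locus")[["chromosome", "cM"]]

    rows = []
    for trait in sorted(predictor_loci):
        tloci = sorted(predictor_loci[trait])
        for tl in tloci:
            # (a) identity
            if not locus_calls.empty:
                hits = locus_calls[locus_calls["locus"] == tl]
                for h in hits.itertuples():
                    rows.append(
                        {
                            "trait": trait,
                            "trait_locus": tl,
                            "overlap_type": "identity",
                            "outlier_locus": tl,
                            "method": h.method,
                            "line": h.line,
                            "generation": h.generation,
                            "chromosome": np.nan,
                            "distance_cM": 0.0,
                            "region_start_cM": np.nan,
                            "region_end_cM": np.nan,
                        }
                    )
            if pos is None or tl not in pos.index:
                continue
            chrom, cm = pos.at[tl, "chromosome"], pos.at[tl, "cM"]
            # (b) proximity to outlier loci
            if not locus_calls.empty:
                for h in locus_calls.itertuples():
                    ol = h.locus
                    if ol == tl or ol not in pos.index:
                        continue
                    if pos.at[ol, "chromosome"] != chrom:
                        continue
                    d = abs(pos.at[ol, "cM"] - cm)
                    if d <= proximity_cM:
                        rows.append(
                            {
                                "trait": trait,
                                "trait_locus": tl,
                                "overlap_type": "proximity",
                                "outlier_locus": ol,
                                "method": h.method,
                                "line": h.line,
                                "generation": h.generation,
                                "chromosome": chrom,
                                "distance_cM": float(d),
                                "region_start_cM": np.nan,
                                "region_end_cM": np.nan,
                            }
                        )
            # (c) containment in outlier regions
            if regions is not None and not regions.empty:
                for r in regions.itertuples():
                    if r.chromosome != chrom:
                        continue
                    if r.start_cM <= cm <= r.end_cM:
                        rows.append(
                            {
                                "trait": trait,
                                "trait_locus": tl,
                                "overlap_type": "region",
                                "outlier_locus": np.nan,
                                "method": r.method,
                                "line": r.line,
                                "generation": r.generation,
                                "chromosome": chrom,
                                "distance_cM": np.nan,
                                "region_start_cM": float(r.start_cM),
                                "region_end_cM": float(r.end_cM),
                            }
                        )
    out = pd.DataFrame(rows, columns=OVERLAP_COLUMNS)
    return out.sort_values(
        ["trait", "trait_locus", "overlap_type", "line", "generation"],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
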