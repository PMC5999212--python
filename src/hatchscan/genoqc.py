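"""Depth-based genotype calling and the QC cascade.

The caller reproduces the depth rule used for RAD loci: a genotype is
heterozygous only when both alleles are seen at depth >= 2 and the combined
depth exceeds 10.  The rule defines only the heterozygote condition; for
the remaining cases this module calls a homozygote when the minority allele
is essentially absent (depth <= 1) and the total is deep enough
(>= ``min_hom_depth``), and otherwise leaves the genotype missing rather
than inventing a homozygote from an ambiguous depth split.

The cascade then applies, in order: a minor-allele-frequency screen
(retained if MAF >= threshold in at least one population), removal of
individuals with >= 50% missing genotypes, removal of loci called in fewer
than 50% of individuals of *any* population, imputation of remaining
missing genotypes from population-conditional genotype frequencies, and a
Hardy-Weinberg exact-test filter that drops loci out of equilibrium in two
or more populations (a guard against genotyping artefacts and residual
paralogs from the salmonid genome duplication).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from hatchscan.containers import GenotypeMatrix, QcReport

HET_MIN_ALLELE_DEPTH = 2
HET_MIN_TOTAL_DEPTH = 10  # combined depth must be strictly greater


# ---------------------------------------------------------------------------
# genotype calling


def call_genotype(
    depth_a1: int, depth_a2: int, min_hom_depth: int = 10
) -> float:
    """Call one dosage (copies of allele 2) from a pair of allele depths.

    Heterozygous iff ``min(d1, d2) >= 2`` and ``d1 + d2 > 10``; homozygous
    for the majority allele iff the minority depth is <= 1 and the total is
    >= ``min_hom_depth``; otherwise missing (NaN).
    """
    if depth_a1 < 0 or depth_a2 < 0:
        raise ValueError("allele depths must be non-negative")
    total = depth_a1 + depth_a2
    lo, hi = sorted((depth_a1, depth_a2))
    if lo >= HET_MIN_ALLELE_DEPTH and total > HET_MIN_TOTAL_DEPTH:
        return 1.0
    if lo <= 1 and total >= min_hom_depth:
        return 2.0 if depth_a2 > depth_a1 else 0.0
    return float("nan")


def call_genotypes(
    depths: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    min_hom_depth: int = 10,
) -> GenotypeMatrix | pd.DataFrame:
    """Vectorized caller over a long-form depth table.

    ``depths`` needs columns ``individual, locus, depth_a1, depth_a2``.
    Returns a :class:`GenotypeMatrix` when ``samples`` metadata is given,
    else the wide dosage DataFrame.
    """
    d1 = depths["depth_a1"].to_numpy()
    d2 = depths["depth_a2"].to_numpy()
    if (d1 < 0).any() or (d2 < 0).any():
        raise ValueError("allele depths must be non-negative")
    total = d1 + d2
    lo = np.minimum(d1, d2)
    dosage = np.full(len(depths), np.nan)
    het = (lo >= HET_MIN_ALLELE_DEPTH) & (total > HET_MIN_TOTAL_DEPTH)
    hom = ~het & (lo <= 1) & (total >= min_hom_depth)
    dosage[het] = 1.0
    dosage[hom] = np.where(d2[hom] > d1[hom], 2.0, 0.0)

    wide = (
        pd.DataFrame(
            {
                "individual": depths["individual"],
                "locus": depths["locus"],
                "dosage": dosage,
            }
        )
        .pivot(index="individual", columns="locus", values="dosage")
        .rename_axis(index=None, columns=None)
    )
    if samples is None:
        return wide
    return GenotypeMatrix(wide, samples.loc[wide.index])


# ---------------------------------------------------------------------------
# frequency-based filters


def _per_population_maf(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF in each population (NaN when no called genotypes)."""
    cols = {}
    for pop in gm.populations:
        p = gm.allele_freq(pop)
        cols[pop] = np.minimum(p, 1.0 - p)
    return pd.DataFrame(cols)


def filter_maf(
    gm: GenotypeMatrix, threshold: float = 0.05, report: QcReport | None = None
) -> GenotypeMatrix:
    """Retain loci with MAF >= threshold in at least one population."""
    maf = _per_population_maf(gm)
    keep = (maf >= threshold).any(axis=1)
    kept = gm.subset(loci=maf.index[keep])
    if report is not None:
        report.maf = maf.max(axis=1)
        report.loci_removed_maf = int((~keep).sum())
        report.loci_after_maf = int(keep.sum())
    return kept


def filter_missing_individuals(
    gm: GenotypeMatrix, max_missing: float = 0.5, report: QcReport | None = None
) -> GenotypeMatrix:
    """Remove individuals with >= ``max_missing`` missing genotypes."""
    frac = gm.dosages.isna().mean(axis=1)
    keep = frac < max_missing
    if report is not None:
        report.individuals_removed = int((~keep).sum())
    return gm.subset(individuals=gm.individuals[keep])


def filter_missing_loci(
    gm: GenotypeMatrix, min_call_rate: float = 0.5, report: QcReport | None = None
) -> GenotypeMatrix:
    """Retain loci genotyped in at least ``min_call_rate`` of each population."""
    rates = []
    for pop in gm.populations:
        d = gm.dosages.loc[gm.population_mask(pop)]
        rates.append(d.notna().mean(axis=0))
    rate = pd.concat(rates, axis=1).min(axis=1)
    keep = rate >= min_call_rate
    if report is not None:
        report.loci_removed_missingness = int((~keep).sum())
    return gm.subset(loci=gm.loci[keep])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided conditional exact test for Hardy-Weinberg proportions.

    Conditions on the observed allele counts and enumerates every
    heterozygote count with the same parity (Levene's distribution); the
    p-value sums the probabilities of all configurations no more probable
    than the observed one.  Monomorphic samples return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    hets = np.arange(rare % 2, rare + 1, 2)
    n_AA_c = (n_A - hets) // 2 if n_A <= n_a else (n_A - hets) // 2
    # counts for every admissible configuration
    aa_c = (rare - hets) // 2
    AA_c = (max(n_A, n_a) - hets) // 2
    # log Levene probability: 2^h * n! / (nAA! h! naa!) * nA! na! / (2n)!
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(AA_c + 1)
        - gammaln(hets + 1)
        - gammaln(aa_c + 1)
        + gammaln(n_A + 1)
        + gammaln(n_a + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.where(hets == n_Aa)[0][0]]
    return float(np.clip(probs[probs <= obs * (1 + 1e-12)].sum(), 0.0, 1.0))


def hwe_pvalues(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus, per-population HWE exact p-values."""
    out = {}
    for pop in gm.populations:
        counts = gm.genotype_counts(pop)
        out[pop] = [
            hwe_exact_test(int(r.n0), int(r.n1), int(r.n2))
            for r in counts.itertuples()
        ]
    return pd.DataFrame(out, index=gm.loci)


def filter_hwe(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    min_populations: int = 2,
    report: QcReport | None = None,
) -> GenotypeMatrix:
    """Drop loci out of Hardy-Weinberg in ``min_populations`` or more populations."""
    pvals = hwe_pvalues(gm)
    n_sig = (pvals < alpha).sum(axis=1)
    keep = n_sig < min_populations
    if report is not None:
        report.hwe_pvalues = pvals
        report.loci_removed_hwe = int((~keep).sum())
    return gm.subset(loci=gm.loci[keep])


# ---------------------------------------------------------------------------
# imputation


def impute_missing(
    gm: GenotypeMatrix,
    seed: int | None = 0,
    mode: bool = False,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, float]:
    """Fill missing dosages from population-conditional genotype frequencies.

    For each population the maximum-likelihood genotype frequencies at a
    locus are the observed proportions among called genotypes; each missing
    entry is drawn from that distribution (or set to its mode when
    ``mode=True``).  Loci with no calls in a population fall back to the
    global genotype frequencies at that locus (logged).  Returns the
    completed matrix and the Pearson correlation between per-locus allele
    frequencies before and after imputation — the diagnostic used to verify
    that imputation does not distort the frequency spectrum.
    """
    if not gm.dosages.isna().any().any():
        if report is not None:
            report.imputation_freq_correlation = 1.0
        return GenotypeMatrix(gm.dosages.copy(), gm.samples.copy()), 1.0

    rng = np.random.default_rng(seed)
    freq_before = gm.allele_freq()
    dos = gm.dosages.to_numpy(dtype=float).copy()
    pop_labels = gm.samples["population"].to_numpy()

    global_counts = np.vstack(
        [(dos == k).sum(axis=0) for k in (0.0, 1.0, 2.0)]
    ).astype(float)

    fallback_loci: set = set()
    for pop in pd.unique(pop_labels):
        rows = np.where(pop_labels == pop)[0]
        block = dos[rows]
        miss = np.isnan(block)
        if not miss.any():
            continue
        counts = np.vstack([(block == k).sum(axis=0) for k in (0.0, 1.0, 2.0)]).astype(
            float
        )
        tot = counts.sum(axis=0)
        empty = tot == 0
        if empty.any():
            fallback_loci.update(np.array(gm.loci)[empty])
            counts[:, empty] = global_counts[:, empty]
            tot = counts.sum(axis=0)
            zero = tot == 0  # locus uncalled everywhere: fill uniform
            counts[:, zero] = 1.0
            tot = counts.sum(axis=0)
        probs = counts / tot
        for j in np.where(miss.any(axis=0))[0]:
            idx = rows[miss[:, j]]
            if mode:
                dos[idx, j] = float(np.argmax(probs[:, j]))
            else:
                dos[idx, j] = rng.choice(3, size=len(idx), p=probs[:, j]).astype(float)

    out = GenotypeMatrix(
        pd.DataFrame(dos, index=gm.individuals, columns=gm.loci), gm.samples.copy()
    )
    freq_after = out.allele_freq()
    valid = freq_before.notna() & freq_after.notna()
    if valid.sum() >= 2 and freq_before[valid].std() > 0 and freq_after[valid].std() > 0:
        r = float(np.corrcoef(freq_before[valid], freq_after[valid])[0, 1])
    else:
        r = 1.0
    if report is not None:
        report.imputation_freq_correlation = r
        if fallback_loci:
            report.log(
                f"imputation fell back to global frequencies at "
                f"{len(fallback_loci)} (locus, population) gaps"
            )
    return out, r


# ---------------------------------------------------------------------------
# diagnostics


def compute_fis(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus, per-population inbreeding coefficient F_IS.

    F_IS = 1 - H_obs / H_exp with the small-sample correction
    H_exp = 2 p (1-p) * 2n / (2n - 1); undefined (NaN) where H_exp = 0.
    """
    out = {}
    for pop in gm.populations:
        counts = gm.genotype_counts(pop)
        n = counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (2 * counts["n2"] + counts["n1"]) / (2 * n)
            h_obs = counts["n1"] / n
            h_exp = 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
            fis = 1.0 - h_obs / h_exp
        fis[h_exp.fillna(0) == 0] = np.nan
        out[pop] = fis
    return pd.DataFrame(out, index=gm.loci)


# ---------------------------------------------------------------------------
# the full cascade


def run_qc(
    gm: GenotypeMatrix,
    maf_threshold: float = 0.05,
    hwe_alpha: float = 0.05,
    hwe_min_populations: int = 2,
    impute_seed: int = 0,
    impute_mode: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the full QC cascade and return the imputed matrix plus report.

    Order: MAF screen -> missing-individual removal -> per-population
    missing-locus removal -> imputation -> Hardy-Weinberg filter.
    """
    report = QcReport(loci_in=len(gm.loci), individuals_in=len(gm.individuals))
    gm = filter_maf(gm, maf_threshold, report)
    gm = filter_missing_individuals(gm, 0.5, report)
    gm = filter_missing_loci(gm, 0.5, report)
    gm, _ = impute_missing(gm, seed=impute_seed, mode=impute_mode, report=report)
    gm = filter_hwe(gm, hwe_alpha, hwe_min_populations, report)
    report.loci_out = len(gm.loci)
    return gm, report
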