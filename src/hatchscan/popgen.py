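"""Divergence statistics and outlier detection.

Three detectors are implemented:

* per-locus Weir-Cockerham (1984) theta between two population samples,
  returned with its variance components ``a`` (among populations), ``b``
  (among individuals within populations) and ``c`` (within individuals) so
  that multi-locus and windowed estimates aggregate as ratios of summed
  components rather than means of ratios;
* the temporal drift-simulation test: the temporal FST between a
  population sampled at two generations is compared against a null built
  by simulating binomial genetic drift of the configured effective size
  from the sample-estimated starting frequency, with binomial sampling
  noise at both ends;
* kernel-smoothed sliding-window FST along each chromosome with a
  resampled null: at each evaluation point the contributing loci's
  components are replaced by random draws from the genomewide pool,
  repeatedly, and the 95% envelope of the re-smoothed statistic marks the
  neutral band; runs of points above the upper bound are outlier regions.

Negative theta estimates are expected at weakly diverged loci with finite
samples and are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from hatchscan.containers import GenotypeMatrix, population_label


# ---------------------------------------------------------------------------
# Weir-Cockerham theta (two populations, diploid)


def wc_fst(counts_pop1: pd.DataFrame, counts_pop2: pd.DataFrame) -> pd.DataFrame:
    """Per-locus Weir-Cockerham theta with variance components.

    Inputs are per-locus genotype counts (columns ``n0, n1, n2`` = hom-ref,
    het, hom-alt) for the two samples.  Returns ``theta, a, b, c``; theta
    is NaN where fewer than two genotypes were called in either sample or
    the locus is monomorphic across both.
    """
    c1 = counts_pop1[["n0", "n1", "n2"]].to_numpy(dtype=float)
    c2 = counts_pop2[["n0", "n1", "n2"]].to_numpy(dtype=float)
    n1 = c1.sum(axis=1)
    n2 = c2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * c1[:, 2] + c1[:, 1]) / (2 * n1)
        p2 = (2 * c2[:, 2] + c2[:, 1]) / (2 * n2)
        h1 = c1[:, 1] / n1
        h2 = c2[:, 1] / n2

        r = 2.0
        nbar = (n1 + n2) / r
        nsum = n1 + n2
        nc = nsum - (n1 ** 2 + n2 ** 2) / nsum  # (r-1) = 1 divisor folded in
        pbar = (n1 * p1 + n2 * p2) / nsum
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / nsum
        qbar = 1.0 - pbar

        a = (nbar / nc) * (
            s2 - (pbar * qbar - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * qbar - s2 * (r - 1) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    bad = (n1 < 2) | (n2 < 2) | ((pbar <= 0) | (pbar >= 1))
    theta = np.where(bad, np.nan, theta)
    out = pd.DataFrame(
        {"theta": theta, "a": a, "b": b, "c": c}, index=counts_pop1.index
    )
    out.loc[bad, ["a", "b", "c"]] = np.nan
    return out


def pairwise_fst(
    gm: GenotypeMatrix, pop1: str, pop2: str
) -> pd.DataFrame:
    """Weir-Cockerham theta between two labeled populations of a matrix."""
    return wc_fst(gm.genotype_counts(pop1), gm.genotype_counts(pop2))


# ---------------------------------------------------------------------------
# temporal drift-simulation test


@dataclass
class DriftNullConfig:
    """Null model for the temporal test: Ne, horizon and sampling design."""

    ne: int
    generations: int
    n_sample_0: int  # diploid individuals at generation 0
    n_sample_t: int
    n_simulations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.ne, self.generations, self.n_sample_0, self.n_sample_t,
            self.n_simulations,
        ) <= 0:
            raise ValueError("all DriftNullConfig counts must be positive")


def _temporal_theta(
    x0: np.ndarray, m0: np.ndarray, xt: np.ndarray, mt: np.ndarray
) -> np.ndarray:
    """Weir-Cockerham-form FST between two allele-count samples.

    Operates on allele counts (sample sizes in alleles), i.e. the haploid
    variant of the 1984 estimator, which is the natural form for a temporal
    comparison where the null is simulated at the allele-frequency level.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = x0 / m0
        pt = xt / mt
        nbar = (m0 + mt) / 2.0
        msum = m0 + mt
        nc = msum - (m0 ** 2 + mt ** 2) / msum
        pbar = (x0 + xt) / msum
        s2 = (m0 * (p0 - pbar) ** 2 + mt * (pt - pbar) ** 2) / nbar
        pq = pbar * (1.0 - pbar)
        a = (nbar / nc) * (s2 - (pq - s2 / 2.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pq - s2 / 2.0)
        theta = np.where(a + b != 0, a / (a + b), np.nan)
    return np.where((pbar <= 0) | (pbar >= 1), np.nan, theta)


def ftemp_test(
    p0_counts: tuple[int, int],
    pt_counts: tuple[int, int],
    cfg: DriftNullConfig,
) -> tuple[float, float]:
    """Temporal outlier test for a single locus.

    ``p0_counts``/``pt_counts`` are (alternate-allele count, total allele
    count) at the first and second sampling points.  Returns the observed
    temporal FST and a one-sided Monte-Carlo p-value
    ``(1 + #{null >= obs}) / (1 + n_simulations)``.
    """
    res = ftemp_scan(
        np.array([p0_counts[0]]),
        np.array([p0_counts[1]]),
        np.array([pt_counts[0]]),
        np.array([pt_counts[1]]),
        cfg,
    )
    return float(res["fst"].iloc[0]), float(res["p"].iloc[0])


def ftemp_scan(
    x0: np.ndarray,
    m0: np.ndarray,
    xt: np.ndarray,
    mt: np.ndarray,
    cfg: DriftNullConfig,
) -> pd.DataFrame:
    """Vectorized temporal test across loci.

    For each locus the null is built by: estimating p0 from the first
    sample, simulating ``generations`` rounds of binomial(2 Ne) drift, and
    drawing binomial samples of the observed sizes at both ends before
    recomputing the statistic.  Loci whose estimated starting frequency is
    0 or 1 get p = 1 by convention.
    """
    if cfg.n_simulations < 100:
        import warnings

        warnings.warn("fewer than 100 null simulations; p-values are coarse")
    x0 = np.asarray(x0, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    xt = np.asarray(xt, dtype=float)
    mt = np.asarray(mt, dtype=float)
    n_loci = len(x0)
    obs = _temporal_theta(x0, m0, xt, mt)

    rng = np.random.default_rng(cfg.seed)
    p0_hat = np.where(m0 > 0, x0 / m0, np.nan)
    poly = (p0_hat > 0) & (p0_hat < 1)

    pvals = np.ones(n_loci)
    if poly.any():
        ph = p0_hat[poly]
        S = cfg.n_simulations
        two_ne = 2 * cfg.ne
        p = np.broadcast_to(ph[:, None], (ph.size, S)).copy()
        for _ in range(cfg.generations):
            p = rng.binomial(two_ne, p) / two_ne
        m0p = 2 * cfg.n_sample_0
        mtp = 2 * cfg.n_sample_t
        x0_null = rng.binomial(m0p, np.broadcast_to(ph[:, None], p.shape))
        xt_null = rng.binomial(mtp, p)
        null = _temporal_theta(
            x0_null.astype(float),
            np.full_like(p, m0p),
            xt_null.astype(float),
            np.full_like(p, mtp),
        )
        obs_poly = obs[poly][:, None]
        with np.errstate(invalid="ignore"):
            exceed = np.nansum(null >= obs_poly, axis=1)
        pvals[poly] = (1.0 + exceed) / (1.0 + S)
        pvals[poly & np.isnan(obs)] = 1.0
    return pd.DataFrame({"fst": obs, "p": pvals})


# ---------------------------------------------------------------------------
# kernel-smoothed windows


def smooth_fst(
    track: pd.DataFrame,
    bandwidth: float = 2.5,
    eval_step: float = 1.0,
    eval_points: np.ndarray | None = None,
    weight_tol: float = 1e-8,
) -> pd.DataFrame:
    """Gaussian-kernel smoothed FST along one chromosome.

    ``track`` needs columns ``cM, a, b, c`` (per-locus components; loci
    with NaN components are ignored).  The smoothed statistic at an
    evaluation point is the ratio of kernel-weighted component sums,
    sum(w*a) / sum(w*(a+b+c)).  The evaluation grid starts at the first
    locus and steps by ``eval_step`` cM, so smoothing is equivariant under
    translation of the map.  Points whose total kernel weight falls below
    ``weight_tol`` are NaN.
    """
    t = track.dropna(subset=["a", "b", "c"])
    if t.empty:
        return pd.DataFrame(columns=["cM", "smoothed", "n_loci"])
    pos = t["cM"].to_numpy(dtype=float)
    if eval_points is None:
        lo, hi = pos.min(), pos.max()
        eval_points = lo + np.arange(0.0, hi - lo + eval_step, eval_step)
    a = t["a"].to_numpy(dtype=float)
    abc = a + t["b"].to_numpy(dtype=float) + t["c"].to_numpy(dtype=float)

    d = eval_points[:, None] - pos[None, :]
    w = np.exp(-0.5 * (d / bandwidth) ** 2)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = (w @ a) / (w @ abc)
    sm[wsum < weight_tol] = np.nan
    return pd.DataFrame(
        {
            "cM": eval_points,
            "smoothed": sm,
            "n_loci": (w > weight_tol).sum(axis=1),
        }
    )


def window_null(
    track: pd.DataFrame,
    pool: pd.DataFrame,
    bandwidth: float = 2.5,
    eval_step: float = 1.0,
    n_resamples: int = 500,
    seed: int = 0,
    weight_tol: float = 1e-8,
) -> pd.DataFrame:
    """Resampled 95% neutral envelope for the smoothed track of one chromosome.

    ``pool`` holds the genomewide per-locus components (``a, b, c``); at
    each evaluation point the k loci contributing kernel weight are
    replaced by k draws (with replacement) from the pool, the smoothed
    statistic is recomputed with the same weights, and the 2.5/97.5
    percentiles over ``n_resamples`` replicates form the confidence band.
    Returns ``cM, smoothed, lower, upper, outlier`` where ``outlier`` marks
    points whose observed smoothed value exceeds the upper bound.
    """
    pool = pool.dropna(subset=["a", "b", "c"])
    if len(pool) < 50:
        import warnings

        warnings.warn("component pool has fewer than 50 loci; null CI is coarse")
    pa = pool["a"].to_numpy(dtype=float)
    pabc = pa + pool["b"].to_numpy(dtype=float) + pool["c"].to_numpy(dtype=float)

    obs = smooth_fst(track, bandwidth, eval_step, weight_tol=weight_tol)
    t = track.dropna(subset=["a", "b", "c"])
    pos = t["cM"].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    lower = np.full(len(obs), np.nan)
    upper = np.full(len(obs), np.nan)
    for i, x in enumerate(obs["cM"].to_numpy()):
        w = np.exp(-0.5 * ((x - pos) / bandwidth) ** 2)
        keep = w > weight_tol
        k = int(keep.sum())
        if k == 0:
            continue
        wk = w[keep]
        idx = rng.integers(0, len(pa), size=(n_resamples, k))
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = (pa[idx] @ wk) / (pabc[idx] @ wk)
        lower[i], upper[i] = np.nanpercentile(stat, [2.5, 97.5])
    out = obs.copy()
    out["lower"] = lower
    out["upper"] = upper
    out["outlier"] = (out["smoothed"] > out["upper"]).fillna(False)
    return out


def call_regions(null_track: pd.DataFrame) -> pd.DataFrame:
    """Maximal runs of consecutive outlier evaluation points -> regions."""
    flags = null_track["outlier"].to_numpy(dtype=bool)
    cm = null_track["cM"].to_numpy(dtype=float)
    rows = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            rows.append(
                {
                    "start_cM": cm[i],
                    "end_cM": cm[j],
                    "n_points": j - i + 1,
                    "peak_smoothed": float(
                        np.nanmax(null_track["smoothed"].to_numpy()[i : j + 1])
                    ),
                }
            )
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(rows, columns=["start_cM", "end_cM", "n_points", "peak_smoothed"])


# ---------------------------------------------------------------------------
# line scans

_LINE_CODES = {"P1": 0, "INT": 1, "SEG": 2}


def _line_code(line: str) -> int:
    """Stable integer code for seeding (str hashes are salted per process)."""
    return _LINE_CODES.get(line, 99)


def scan_lines(
    gm: GenotypeMatrix,
    linkage_map: pd.DataFrame,
    ne: dict[str, int],
    bandwidth: float = 2.5,
    eval_step: float = 1.0,
    n_resamples: int = 500,
    n_drift_sims: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    founder_population: str = "P1_F0",
) -> dict:
    """Scan every line x generation against the founders.

    For each hatchery generation: per-locus Weir-Cockerham theta vs. the
    founders, smoothed tracks and resampled nulls per chromosome, region
    calls, and the temporal drift test (with the line's configured Ne and
    t = generation index).  Returns a dict with ``tracks`` (per comparison,
    per chromosome), ``regions``, ``locus_calls`` and ``fst`` tables.
    """
    founders_counts = gm.genotype_counts(founder_population)
    founder_dos = gm.dosages.loc[gm.population_mask(founder_population)]
    x0 = founder_dos.sum(axis=0, skipna=True).to_numpy()
    m0 = 2.0 * founder_dos.notna().sum(axis=0).to_numpy()

    pos = linkage_map.set_index("locus")
    pos_col = "positioned" if "positioned" in pos.columns else "mapped"

    tracks: dict = {}
    region_rows = []
    locus_rows = []
    fst_tables: dict = {}
    for pop in gm.populations:
        if pop == founder_population:
            continue
        line = gm.samples.loc[gm.population_mask(pop), "line"].iloc[0]
        gen = int(gm.samples.loc[gm.population_mask(pop), "generation"].iloc[0])
        comp = wc_fst(founders_counts, gm.genotype_counts(pop))
        fst_tables[pop] = comp

        mapped_loci = [
            l for l in comp.index if l in pos.index and bool(pos.at[l, pos_col])
        ]
        table = comp.loc[mapped_loci].copy()
        table["chromosome"] = pos.loc[mapped_loci, "chromosome"].to_numpy()
        table["cM"] = pos.loc[mapped_loci, "cM"].to_numpy()
        pool = table[["a", "b", "c"]]

        for chrom, sub in table.groupby("chromosome"):
            nt = window_null(
                sub.sort_values("cM"),
                pool,
                bandwidth,
                eval_step,
                n_resamples,
                seed=np.random.SeedSequence(
                    [seed, gen, int(chrom), _line_code(line)]
                ).generate_state(1)[0],
            )
            tracks[(pop, int(chrom))] = nt
            regions = call_regions(nt)
            for r in regions.itertuples():
                region_rows.append(
                    {
                        "kind": "region",
                        "method": "window",
                        "line": line,
                        "generation": gen,
                        "chromosome": int(chrom),
                        "start_cM": r.start_cM,
                        "end_cM": r.end_cM,
                        "statistic": r.peak_smoothed,
                    }
                )

        # temporal test, founders -> this generation
        dos = gm.dosages.loc[gm.population_mask(pop)]
        xt = dos.sum(axis=0, skipna=True).to_numpy()
        mt = 2.0 * dos.notna().sum(axis=0).to_numpy()
        cfg = DriftNullConfig(
            ne=ne[line],
            generations=gen,
            n_sample_0=int(m0.max() // 2) or 1,
            n_sample_t=int(mt.max() // 2) or 1,
            n_simulations=n_drift_sims,
            seed=int(
                np.random.SeedSequence([seed, 7, gen, _line_code(line)])
                .generate_state(1)[0]
            ),
        )
        res = ftemp_scan(x0, m0, xt, mt, cfg)
        res.index = gm.loci
        for locus in res.index[res["p"] < alpha]:
            locus_rows.append(
                {
                    "kind": "locus",
                    "method": "ftemp",
                    "line": line,
                    "generation": gen,
                    "locus": locus,
                    "statistic": float(res.at[locus, "fst"]),
                    "p": float(res.at[locus, "p"]),
                }
            )

    return {
        "tracks": tracks,
        "fst": fst_tables,
        "regions": pd.DataFrame(
            region_rows,
            columns=[
                "kind", "method", "line", "generation", "chromosome",
                "start_cM", "end_cM", "statistic",
            ],
        ),
        "locus_calls": pd.DataFrame(
            locus_rows,
            columns=[
                "kind", "method", "line", "generation", "locus", "statistic", "p",
            ],
        ),
    }


def merge_external_calls(
    locus_calls: pd.DataFrame, external: pd.DataFrame
) -> pd.DataFrame:
    """Append externally supplied outlier calls (e.g. a Bayesian scan) as
    method='external' rows; expects columns ``locus`` and optionally
    ``line, generation, statistic``."""
    ext = external.copy()
    ext["kind"] = "locus"
    ext["method"] = "external"
    for col in ("line", "generation", "statistic", "p"):
        if col not in ext.columns:
            ext[col] = np.nan
    cols = ["kind", "method", "line", "generation", "locus", "statistic", "p"]
    return pd.concat([locus_calls, ext[cols]], ignore_index=True)
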