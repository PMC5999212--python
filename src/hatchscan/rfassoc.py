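"""Confounder-corrected random-forest association with backward purging.

The association strategy, suited to polygenic traits, is:

1. *Correction.*  Phenotypes and per-locus genotype dosages are replaced by
   their OLS residuals against the potential confounders — hatchery line,
   sex, age, year and the individuals' coordinate on PC1 of the genotype
   matrix — so that the forests see only variation not attributable to
   structure.  Age at maturity stays categorical: its genotypes are
   corrected with every factor except age while the phenotype is left as
   the raw {3,4,5} classes.
2. *ntree tuning.*  Replicate forests are grown at increasing tree counts
   until the Pearson correlation of locus importances between replicates
   exceeds a stability threshold (0.8).
3. *Importance averaging.*  Three forests are grown on all loci; per-tree
   out-of-bag permutation importances (increase in MSE for regression,
   decrease in accuracy for classification), z-scored over trees, are
   averaged across the forests.
4. *Top-fraction screening.*  Forests regrown on the top 0.5/1/2/3/5% of
   loci locate the fraction explaining the most out-of-bag variation (or
   the lowest out-of-bag classification error for age).
5. *Backward purging.*  Starting from 1.5x the best fraction, the least
   important locus is removed one at a time, regrowing three forests each
   step; the set anywhere along the trajectory with the best metric is the
   trait's predictor set.

"Percent variation explained" is operationalized as out-of-bag R^2
(1 - OOB MSE / Var(y)) x 100; it may be negative for pure noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from hatchscan.containers import GenotypeMatrix, TRAITS

DEFAULT_FRACTIONS = (0.005, 0.01, 0.02, 0.03, 0.05)
DEFAULT_NTREE_GRID = (100, 250, 500)
PURGE_EXPANSION = 1.5
STABILITY_THRESHOLD = 0.8

# R's randomForest defaults: mtry = p/3 and nodesize 5 for regression,
# sqrt(p) and nodesize 1 for classification.
REGRESSION_MAX_FEATURES = 1.0 / 3.0
REGRESSION_MIN_LEAF = 5


def _seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# confounder correction


@dataclass
class CorrectedData:
    """Residualized phenotypes and genotypes plus the covariate design."""

    pheno_resid: dict[str, np.ndarray]  # continuous traits -> residual vector
    age_raw: np.ndarray  # categorical, uncorrected
    geno_resid: pd.DataFrame  # corrected with the full design
    geno_resid_noage: pd.DataFrame  # corrected with all factors except age
    design: pd.DataFrame
    individuals: pd.Index
    pc1: np.ndarray

    def genotypes_for(self, trait: str) -> pd.DataFrame:
        return self.geno_resid_noage if trait == "age" else self.geno_resid

    def response_for(self, trait: str) -> np.ndarray:
        return self.age_raw if trait == "age" else self.pheno_resid[trait]


def _design_matrix(covars: pd.DataFrame) -> pd.DataFrame:
    """Intercept + dummy/numeric encoding, aliased columns dropped."""
    parts = [pd.Series(1.0, index=covars.index, name="intercept")]
    for col in covars.columns:
        s = covars[col]
        if s.dtype == object or str(s.dtype) == "category" or col in ("line", "sex", "year"):
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    # drop aliased (rank-deficient) columns, keeping the earliest
    arr = X.to_numpy(dtype=float)
    _, r = np.linalg.qr(arr)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        dropped = list(X.columns[~keep])
        warnings.warn(f"dropping aliased design columns: {dropped}")
        X = X.loc[:, keep]
    return X


def _residualize(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return Y - q @ (q.T @ Y)


def correct_confounders(
    pheno: pd.DataFrame,
    gm: GenotypeMatrix,
    traits: tuple[str, ...] = TRAITS,
    exclude_founders: bool = True,
) -> CorrectedData:
    """Residualize phenotypes and genotypes against line/sex/age/year/PC1.

    Founders are excluded (the design is paired across the two hatchery
    lines); PC1 is computed from the centered, imputed dosage matrix of the
    analyzed individuals.  Requires an imputed matrix (no missing calls).
    """
    samples = gm.samples
    keep = samples.index
    if exclude_founders:
        keep = samples.index[samples["line"] != "P1"]
    keep = keep.intersection(pheno.index)
    dos = gm.dosages.loc[keep]
    if dos.isna().any().any():
        raise ValueError("genotypes must be imputed before correction")
    ph = pheno.loc[keep]

    centered = dos.to_numpy(dtype=float)
    centered = centered - centered.mean(axis=0)
    # PC1 via SVD of the centered dosage matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pc1 = u[:, 0] * s[0]

    covars = pd.DataFrame(
        {
            "line": ph["line"].astype(str),
            "sex": ph["sex"].astype(str),
            "age": ph["age"].astype(float),
            "year": ph["year"].astype(str),
        },
        index=keep,
    )
    covars["pc1"] = pc1
    X_full = _design_matrix(covars)
    X_noage = _design_matrix(covars.drop(columns=["age"]))

    geno_resid = _residualize(X_full.to_numpy(dtype=float), centered)
    geno_resid_noage = _residualize(X_noage.to_numpy(dtype=float), centered)

    pheno_resid = {}
    for trait in traits:
        if trait == "age":
            continue
        y = ph[trait].to_numpy(dtype=float)
        pheno_resid[trait] = _residualize(
            X_full.to_numpy(dtype=float), y[:, None]
        ).ravel()

    return CorrectedData(
        pheno_resid=pheno_resid,
        age_raw=ph["age"].to_numpy() if "age" in ph.columns else np.array([]),
        geno_resid=pd.DataFrame(geno_resid, index=keep, columns=dos.columns),
        geno_resid_noage=pd.DataFrame(
            geno_resid_noage, index=keep, columns=dos.columns
        ),
        design=X_full,
        individuals=keep,
        pc1=pc1,
    )


# ---------------------------------------------------------------------------
# forests and permutation importance


def _grow_forest(X: np.ndarray, y: np.ndarray, ntree: int, mode: str, seed: int):
    if mode == "classification":
        classes, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValueError(f"class {small!r} has fewer than 2 members")
        model = RandomForestClassifier(
            n_estimators=ntree,
            class_weight="balanced_subsample",
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
    else:
        model = RandomForestRegressor(
            n_estimators=ntree,
            max_features=REGRESSION_MAX_FEATURES,
            min_samples_leaf=REGRESSION_MIN_LEAF,
            oob_score=True,
            random_state=seed,
            n_jobs=1,
        )
    model.fit(X, y)
    return model


def _oob_metric(model, mode: str) -> float:
    """OOB %variation explained (regression) or OOB error % (classification)."""
    if mode == "classification":
        return 100.0 * (1.0 - model.oob_score_)
    return 100.0 * model.oob_score_  # oob_score_ is OOB R^2


def permutation_importance_(
    model,
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    seed: int,
    chunk: int = 500,
    max_eval: int = 64,
    scale: bool = True,
) -> np.ndarray:
    """Out-of-bag permutation importance, per tree, z-scored over the forest.

    For every tree, the error on that tree's out-of-bag samples is compared
    before and after permuting each feature within the out-of-bag set
    (increase in MSE for regression, in misclassification rate for
    classification).  With ``scale=True`` (the standard importance of the
    reference forest implementation) each feature's per-tree mean is
    divided by its standard error across trees.  Both choices matter for
    honest screening on weak signals: evaluating on out-of-bag samples
    prevents rewarding loci that merely memorize the sample, and the
    z-scoring stops the ranking from latching onto loci with large but
    unstable spurious correlations — with raw importances, the top of the
    ranking on a pure-noise phenotype is strongly enriched for the most
    correlated noise loci and downstream subsets appear to explain
    phenotypic variation they do not have.

    ``max_eval`` caps the out-of-bag samples used per tree (cost control;
    the per-tree subsampling noise averages out across trees).  Features
    are permuted in blocks of ``chunk`` stacked into one predict call per
    tree, which is far faster than per-feature prediction.
    """
    from sklearn.ensemble._forest import _generate_unsampled_indices

    rng = np.random.default_rng(seed)
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y)
    n, p = X.shape
    imp = np.zeros(p)
    imp_sq = np.zeros(p)
    n_used = 0
    buf: np.ndarray | None = None
    for tree in model.estimators_:
        oob = _generate_unsampled_indices(tree.random_state, n, n, None)
        if len(oob) < 2:
            continue
        if max_eval and len(oob) > max_eval:
            oob = rng.choice(oob, size=max_eval, replace=False)
        Xo = X[oob]
        yo = y[oob]
        m = len(oob)
        pred = tree.predict(Xo)
        if mode == "classification":
            pred = pred.astype(yo.dtype) if pred.dtype != yo.dtype else pred
            base = np.mean(pred != yo)
        else:
            base = np.mean((pred - yo) ** 2)
        # permuting a feature the tree never splits on cannot change its
        # predictions, so only the tree's own split features need work
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for start in range(0, len(used), chunk):
            feats = used[start : start + chunk]
            k = len(feats)
            if buf is None or buf.shape != (k * m, p):
                buf = np.empty((k * m, p), dtype=np.float32)
            buf.reshape(k, m, p)[:] = Xo[None, :, :]
            for i, j in enumerate(feats):
                buf[i * m : (i + 1) * m, j] = Xo[rng.permutation(m), j]
            preds = tree.predict(buf)
            for i, j in enumerate(feats):
                pj = preds[i * m : (i + 1) * m]
                if mode == "classification":
                    d = np.mean(pj != yo) - base
                else:
                    d = np.mean((pj - yo) ** 2) - base
                imp[j] += d
                imp_sq[j] += d * d
        n_used += 1
    if not n_used:
        return imp
    mean = imp / n_used
    if not scale:
        return mean
    # z-score over trees; a feature a tree never uses contributes 0 there
    var = imp_sq / n_used - mean**2
    se = np.sqrt(np.maximum(var, 0.0) / n_used)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, mean / se, 0.0)
    return z


@dataclass
class ImportanceTable:
    """Averaged locus importances plus the replicate-forest agreement."""

    values: pd.Series  # mean importance per locus
    per_forest: pd.DataFrame  # one column per replicate forest
    pairwise_correlations: list[float] = field(default_factory=list)
    metric: float = float("nan")  # mean OOB metric of the replicate forests


def grow_importances(
    X: pd.DataFrame,
    y: np.ndarray,
    ntree: int,
    mode: str = "regression",
    n_forests: int = 3,
    seed: int = 0,
    max_eval: int = 64,
) -> ImportanceTable:
    """Grow replicate forests (differing only by seed) and average importances."""
    arr = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    cols = {}
    metrics = []
    for f in range(n_forests):
        s = _seed(seed, ntree, f)
        model = _grow_forest(arr, y, ntree, mode, s)
        cols[f"forest_{f}"] = permutation_importance_(
            model, arr, y, mode, s + 1, max_eval=max_eval
        )
        metrics.append(_oob_metric(model, mode))
    per_forest = pd.DataFrame(cols, index=X.columns)
    corr = per_forest.corr().to_numpy()
    pairs = [
        float(corr[i, j])
        for i in range(n_forests)
        for j in range(i + 1, n_forests)
    ]
    return ImportanceTable(
        values=per_forest.mean(axis=1),
        per_forest=per_forest,
        pairwise_correlations=pairs,
        metric=float(np.mean(metrics)),
    )


@dataclass
class TuneResult:
    ntree: int
    correlations: dict[int, list[float]]
    importances: ImportanceTable  # at the accepted ntree
    converged: bool = True


def tune_ntree(
    X: pd.DataFrame,
    y: np.ndarray,
    candidate_ntrees: tuple[int, ...] = DEFAULT_NTREE_GRID,
    threshold: float = STABILITY_THRESHOLD,
    n_forests: int = 3,
    mode: str = "regression",
    seed: int = 0,
    max_eval: int = 64,
) -> TuneResult:
    """Smallest ntree whose replicate-forest importances correlate > threshold.

    If no candidate qualifies the largest is returned with a warning.
    """
    correlations: dict[int, list[float]] = {}
    last = None
    for ntree in sorted(candidate_ntrees):
        table = grow_importances(X, y, ntree, mode, n_forests, seed, max_eval)
        correlations[ntree] = table.pairwise_correlations
        last = (ntree, table)
        if all(c > threshold for c in table.pairwise_correlations):
            return TuneResult(ntree, correlations, table, converged=True)
    warnings.warn(
        f"importance correlations never exceeded {threshold}; "
        f"using largest candidate ntree={last[0]}"
    )
    return TuneResult(last[0], correlations, last[1], converged=False)


# ---------------------------------------------------------------------------
# subset screening and backward purging


def evaluate_top_fractions(
    X: pd.DataFrame,
    y: np.ndarray,
    importances: pd.Series,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    ntree: int = 250,
    mode: str = "regression",
    n_forests: int = 3,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Regrow forests on top-importance subsets; pick the best fraction.

    The metric is mean OOB %variation explained (regression, maximized) or
    mean OOB classification error % (minimized).  Fractions yielding fewer
    than 2 loci are skipped.
    """
    order = importances.sort_values(ascending=False).index
    rows = []
    for frac in fractions:
        k = int(round(frac * len(order)))
        if k < 2:
            warnings.warn(f"fraction {frac} yields {k} loci; skipped")
            continue
        sub = X[order[:k]]
        arr = np.ascontiguousarray(sub.to_numpy(dtype=np.float32))
        metrics = [
            _oob_metric(
                _grow_forest(arr, y, ntree, mode, _seed(seed, 101, i, k)), mode
            )
            for i in range(n_forests)
        ]
        rows.append({"fraction": frac, "n_loci": k, "metric": float(np.mean(metrics))})
    table = pd.DataFrame(rows, columns=["fraction", "n_loci", "metric"])
    if table.empty:
        raise ValueError("no evaluable fraction (candidate sets all too small)")
    if mode == "classification":
        best = table.loc[table["metric"].idxmin(), "fraction"]
    else:
        best = table.loc[table["metric"].idxmax(), "fraction"]
    return float(best), table


@dataclass
class PredictorSet:
    """Purged predictor loci for one trait with the purge trajectory."""

    trait: str
    loci: list[str]
    metric_kind: str  # percent_variation_explained | oob_classification_error
    metric_value: float
    trajectory: pd.DataFrame  # columns: n_loci, metric
    importances: pd.Series | None = None
    n_individuals: int = 0


def backward_purge(
    X: pd.DataFrame,
    y: np.ndarray,
    candidate_loci: list[str],
    ntree: int = 250,
    mode: str = "regression",
    n_forests: int = 3,
    seed: int = 0,
    min_size: int = 2,
    trait: str = "",
    max_eval: int = 64,
) -> PredictorSet:
    """Iteratively drop the least-important locus, keeping the best set seen.

    At each step three forests are regrown on the current set; the mean OOB
    metric is recorded and mean permutation importance decides the next
    removal.  The returned set is the one along the whole trajectory with
    the maximum %variation explained (regression) or minimum OOB error
    (classification).
    """
    metric_kind = (
        "oob_classification_error" if mode == "classification"
        else "percent_variation_explained"
    )
    current = list(candidate_loci)
    if len(current) < 3:
        warnings.warn("candidate set smaller than 3 loci; returned unpurged")
        arr = np.ascontiguousarray(X[current].to_numpy(dtype=np.float32))
        try:
            metric = float(
                np.mean(
                    [
                        _oob_metric(
                            _grow_forest(arr, y, ntree, mode, _seed(seed, 202, i)),
                            mode,
                        )
                        for i in range(n_forests)
                    ]
                )
            )
        except Exception:
            metric = float("nan")
        return PredictorSet(
            trait, current, metric_kind, metric,
            pd.DataFrame({"n_loci": [len(current)], "metric": [metric]}),
        )

    traj_rows = []
    best_metric = None
    best_set: list[str] = list(current)
    step = 0
    while len(current) >= min_size:
        sub = X[current]
        table = grow_importances(
            sub, y, ntree, mode, n_forests, _seed(seed, 303, step), max_eval
        )
        traj_rows.append({"n_loci": len(current), "metric": table.metric})
        better = (
            best_metric is None
            or (mode == "classification" and table.metric < best_metric)
            or (mode != "classification" and table.metric > best_metric)
        )
        if better:
            best_metric = table.metric
            best_set = list(current)
        if len(current) == min_size:
            break
        drop = table.values.idxmin()
        current.remove(drop)
        step += 1

    # The trajectory maximum is an optimistically biased estimate (the best
    # of many noisy values); the reported performance of the selected set is
    # re-estimated with fresh forests grown only on that set.
    arr = np.ascontiguousarray(X[best_set].to_numpy(dtype=np.float32))
    final_metric = float(
        np.mean(
            [
                _oob_metric(
                    _grow_forest(arr, y, ntree, mode, _seed(seed, 404, i)), mode
                )
                for i in range(n_forests)
            ]
        )
    )
    return PredictorSet(
        trait=trait,
        loci=best_set,
        metric_kind=metric_kind,
        metric_value=final_metric,
        trajectory=pd.DataFrame(traj_rows),
    )


# ---------------------------------------------------------------------------
# orchestration


def run_association(
    pheno: pd.DataFrame,
    gm: GenotypeMatrix,
    traits: tuple[str, ...] = TRAITS,
    linkage_map: pd.DataFrame | None = None,
    candidate_ntrees: tuple[int, ...] = DEFAULT_NTREE_GRID,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    expansion: float = PURGE_EXPANSION,
    n_forests: int = 3,
    seed: int = 0,
    max_eval: int = 64,
    purge_ntree: int | None = None,
) -> tuple[dict[str, PredictorSet], pd.DataFrame]:
    """Full association chain per trait; founders excluded.

    Returns the per-trait predictor sets and a summary table (trait,
    n individuals, n predictors, n mapped, metric kind/value).
    ``purge_ntree`` optionally uses smaller forests during the purge steps
    than the tuned all-loci stage (the purge works on a few dozen loci where
    trees stabilize faster); ``None`` re-uses the tuned ntree.
    """
    corrected = correct_confounders(pheno, gm, traits)
    positioned = set()
    if linkage_map is not None:
        col = "positioned" if "positioned" in linkage_map.columns else "mapped"
        positioned = set(linkage_map.loc[linkage_map[col], "locus"])

    results: dict[str, PredictorSet] = {}
    rows = []
    for t_idx, trait in enumerate(traits):
        if trait != "age" and trait not in corrected.pheno_resid:
            warnings.warn(f"trait {trait!r} absent from phenotype table; skipped")
            continue
        mode = "classification" if trait == "age" else "regression"
        X = corrected.genotypes_for(trait)
        y = corrected.response_for(trait)
        ok = ~pd.isna(y)
        Xt, yt = X.loc[ok], np.asarray(y)[ok]

        tuned = tune_ntree(
            Xt, yt, candidate_ntrees, mode=mode, n_forests=n_forests,
            seed=_seed(seed, 11, t_idx), max_eval=max_eval,
        )
        best_frac, _table = evaluate_top_fractions(
            Xt, yt, tuned.importances.values, fractions, tuned.ntree, mode,
            n_forests, _seed(seed, 22, t_idx),
        )
        k = max(3, int(round(best_frac * expansion * len(Xt.columns))))
        candidates = (
            tuned.importances.values.sort_values(ascending=False).index[:k].tolist()
        )
        pset = backward_purge(
            Xt, yt, candidates, purge_ntree or tuned.ntree, mode, n_forests,
            _seed(seed, 33, t_idx), trait=trait, max_eval=max_eval,
        )
        pset.importances = tuned.importances.values.loc[pset.loci]
        pset.n_individuals = int(ok.sum())
        results[trait] = pset
        rows.append(
            {
                "trait": trait,
                "n_individuals": pset.n_individuals,
                "n_predictors": len(pset.loci),
                "n_mapped": sum(1 for l in pset.loci if l in positioned),
                "metric_kind": pset.metric_kind,
                "metric_value": pset.metric_value,
            }
        )
    summary = pd.DataFrame(
        rows,
        columns=[
            "trait", "n_individuals", "n_predictors", "n_mapped",
            "metric_kind", "metric_value",
        ],
    )
    return results, summary
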