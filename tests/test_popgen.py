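"""Weir-Cockerham theta, the temporal drift test and windowed outliers."""

import numpy as np
import pandas as pd
import pytest

from hatchscan import popgen as pg
from hatchscan.config import SimConfig
from hatchscan.simulate import place_loci, simulate_study


def wc_oracle(c1, c2):
    """Independent transcription of the 1984 two-population estimator.

    Written directly from the variance-component definitions (sample sizes
    n_i, frequencies p_i, observed heterozygosities h_i; r = 2) without
    reference to the library code.
    """
    n1, n2 = sum(c1), sum(c2)
    p1 = (2 * c1[2] + c1[1]) / (2 * n1)
    p2 = (2 * c2[2] + c2[1]) / (2 * n2)
    h1, h2 = c1[1] / n1, c2[1] / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a / (a + b + c), a, b, c


def _counts(rows):
    return pd.DataFrame(rows, columns=["n0", "n1", "n2"])


def test_theta_fixed_difference_is_one():
    res = pg.wc_fst(_counts([(50, 0, 0)]), _counts([(0, 0, 50)]))
    assert res["theta"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_theta_identical_samples_nonpositive():
    rng = np.random.default_rng(0)
    for _ in range(20):
        c = tuple(int(x) for x in rng.integers(1, 30, 3))
        res = pg.wc_fst(_counts([c]), _counts([c]))
        assert res["theta"].iloc[0] <= 1e-12


def test_theta_matches_independent_transcription():
    rng = np.random.default_rng(1)
    rows1, rows2 = [], []
    for _ in range(100):
        rows1.append(tuple(int(x) for x in rng.integers(0, 30, 3) + [1, 0, 0]))
        rows2.append(tuple(int(x) for x in rng.integers(0, 30, 3) + [0, 0, 1]))
    res = pg.wc_fst(_counts(rows1), _counts(rows2))
    for i, (c1, c2) in enumerate(zip(rows1, rows2)):
        t, a, b, c = wc_oracle(c1, c2)
        if np.isnan(res["theta"].iloc[i]):
            # only monomorphic-across-both loci may be undefined
            p = (2 * (c1[2] + c2[2]) + c1[1] + c2[1]) / (2 * (sum(c1) + sum(c2)))
            assert p in (0.0, 1.0)
            continue
        assert res["theta"].iloc[i] == pytest.approx(t, abs=1e-10)
        assert res["a"].iloc[i] == pytest.approx(a, abs=1e-10)
        assert res["b"].iloc[i] == pytest.approx(b, abs=1e-10)
        assert res["c"].iloc[i] == pytest.approx(c, abs=1e-10)


def test_multilocus_aggregation_is_ratio_of_sums():
    # the multi-locus estimate aggregates summed components, not mean ratios
    rows1 = [(10, 5, 5), (2, 6, 12), (8, 8, 4)]
    rows2 = [(2, 6, 12), (10, 5, 5), (3, 9, 8)]
    res = pg.wc_fst(_counts(rows1), _counts(rows2))
    agg = res["a"].sum() / (res["a"] + res["b"] + res["c"]).sum()
    mean_of_ratios = res["theta"].mean()
    assert agg != pytest.approx(mean_of_ratios, abs=1e-6)
    oracle = [wc_oracle(c1, c2) for c1, c2 in zip(rows1, rows2)]
    agg_oracle = sum(o[1] for o in oracle) / sum(o[1] + o[2] + o[3] for o in oracle)
    assert agg == pytest.approx(agg_oracle, abs=1e-10)


# -- temporal test -----------------------------------------------------------


def test_ftemp_pvalue_conventions():
    cfg = pg.DriftNullConfig(ne=100, generations=4, n_sample_0=50, n_sample_t=50,
                             n_simulations=200, seed=1)
    # fixed starting sample -> p = 1 by convention
    stat, p = pg.ftemp_test((0, 100), (10, 100), cfg)
    assert p == 1.0
    # identical samples: observed statistic at the bottom of the null -> p ~ 1
    stat, p = pg.ftemp_test((50, 100), (50, 100), cfg)
    assert p > 0.9
    # drastic change far beyond drift at huge Ne -> small p
    cfg2 = pg.DriftNullConfig(ne=10_000, generations=4, n_sample_0=50,
                              n_sample_t=50, n_simulations=200, seed=2)
    stat, p = pg.ftemp_test((50, 100), (98, 100), cfg2)
    assert p <= 2 / 201 + 1e-9


def test_ftemp_determinism():
    rng = np.random.default_rng(3)
    x0 = rng.integers(10, 90, 50).astype(float)
    xt = rng.integers(10, 90, 50).astype(float)
    m = np.full(50, 100.0)
    cfg = pg.DriftNullConfig(ne=50, generations=4, n_sample_0=50, n_sample_t=50,
                             n_simulations=300, seed=11)
    a = pg.ftemp_scan(x0, m, xt, m, cfg)
    b = pg.ftemp_scan(x0, m, xt, m, cfg)
    pd.testing.assert_frame_equal(a, b)


# -- smoothing ---------------------------------------------------------------


def _track(cms, comps):
    return pd.DataFrame(
        {"cM": cms, "a": [c[0] for c in comps], "b": [c[1] for c in comps],
         "c": [c[2] for c in comps]}
    )


def test_smooth_constant_components_is_constant():
    tr = _track([5.0, 10.0, 20.0, 33.0], [(0.02, 0.05, 0.13)] * 4)
    out = pg.smooth_fst(tr, bandwidth=2.5, eval_step=1.0)
    expected = 0.02 / 0.20
    assert np.allclose(out["smoothed"].dropna(), expected)


def test_smooth_single_locus_equals_its_theta():
    tr = _track([12.0], [(0.03, 0.06, 0.01)])
    out = pg.smooth_fst(tr, bandwidth=2.5, eval_step=1.0)
    at = out.loc[np.isclose(out["cM"], 12.0), "smoothed"].iloc[0]
    assert at == pytest.approx(0.03 / 0.10, abs=1e-12)


def test_smooth_three_locus_hand_calculation():
    tr = _track([0.0, 2.0, 5.0], [(0.1, 0.2, 0.1), (0.05, 0.1, 0.1), (-0.02, 0.3, 0.2)])
    bw = 2.5
    out = pg.smooth_fst(tr, bandwidth=bw, eval_step=1.0)
    x = 2.0
    w = np.exp(-0.5 * ((x - np.array([0.0, 2.0, 5.0])) / bw) ** 2)
    num = (w * np.array([0.1, 0.05, -0.02])).sum()
    den = (w * np.array([0.4, 0.25, 0.48])).sum()
    got = out.loc[np.isclose(out["cM"], 2.0), "smoothed"].iloc[0]
    assert got == pytest.approx(num / den, abs=1e-10)


def test_smoothing_shift_equivariance():
    rng = np.random.default_rng(4)
    cms = np.sort(rng.uniform(0, 60, 40))
    comps = [(rng.normal(0.02, 0.01), 0.1, 0.1) for _ in range(40)]
    a = pg.smooth_fst(_track(cms, comps), 2.5, 1.0)
    b = pg.smooth_fst(_track(cms + 17.3, comps), 2.5, 1.0)
    assert np.allclose(a["smoothed"], b["smoothed"], equal_nan=True)
    assert np.allclose(a["cM"] + 17.3, b["cM"])


def test_window_null_flags_planted_block_and_calls_region():
    cfg = SimConfig(n_loci=800, samples_per_population=50, n_founders=50,
                    mapped_fraction=1.0,
                    selected_loci=[(f"L{i:05d}", 0.8) for i in range(10)],
                    seed=77)
    study = simulate_study(cfg)
    lm = place_loci(study.linkage_map, [f"L{i:05d}" for i in range(10)], 1, 40.0, 45.0)
    comp = pg.pairwise_fst(study.genotypes, "P1_F0", "SEG_F4")
    pos = lm.set_index("locus")
    table = comp.copy()
    table["chromosome"] = pos.loc[table.index, "chromosome"].to_numpy()
    table["cM"] = pos.loc[table.index, "cM"].to_numpy()
    sub = table[table["chromosome"] == 1].sort_values("cM")
    nt = pg.window_null(sub, table[["a", "b", "c"]], 2.5, 1.0, 400, seed=5)
    regions = pg.call_regions(nt)
    assert any(r.start_cM <= 45 and r.end_cM >= 40 for r in regions.itertuples())
    # region bookkeeping: runs are maximal and within the track
    assert (regions["end_cM"] >= regions["start_cM"]).all()


def test_scan_lines_outputs_consistent(small_study):
    res = pg.scan_lines(
        small_study.genotypes, small_study.linkage_map,
        ne={"INT": 150, "SEG": 60}, n_resamples=100, n_drift_sims=200, seed=3,
    )
    assert set(res["regions"].columns) >= {"line", "generation", "chromosome"}
    assert set(res["fst"].keys()) == {
        p for p in small_study.genotypes.populations if p != "P1_F0"
    }
    if not res["locus_calls"].empty:
        assert res["locus_calls"]["p"].between(0, 1).all()


def test_merge_external_calls():
    base = pd.DataFrame(
        [{"kind": "locus", "method": "ftemp", "line": "SEG", "generation": 3,
          "locus": "L1", "statistic": 0.2, "p": 0.01}]
    )
    ext = pd.DataFrame([{"locus": "L9", "line": "INT"}])
    out = pg.merge_external_calls(base, ext)
    assert len(out) == 2
    assert (out["method"] == "external").sum() == 1
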