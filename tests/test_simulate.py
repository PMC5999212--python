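"""Generator properties: conservation, determinism, drift and heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hatchscan.config import DepthModel, SimConfig, TraitArchitecture
from hatchscan.containers import TRAITS
from hatchscan.simulate import (
    Population,
    combine_populations,
    domestication_scenario,
    propagate_lines,
    simulate_alignments,
    simulate_depths,
    simulate_founders,
    simulate_linkage_map,
    simulate_phenotypes,
    simulate_study,
)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(founder_maf_dist=(0.0, 1.0))
    with pytest.raises(ValueError):
        SimConfig(gene_flow_integrated=1.5)
    with pytest.raises(ValueError):
        TraitArchitecture(h2=1.2).validate()


def test_founders_shape_and_conservation():
    cfg = SimConfig(n_loci=1000, n_chromosomes=34, n_founders=60, seed=1)
    founders = simulate_founders(cfg)
    assert founders.dosages.shape == (60, 1000)
    lm = simulate_linkage_map(cfg)
    assert len(lm) == 1000
    # with 1000 uniform loci every one of 34 chromosomes is hit w.h.p.
    assert lm["chromosome"].nunique() == 34
    assert set(np.unique(founders.dosages)) <= {0.0, 1.0, 2.0}


def test_degenerate_maf_gives_half_heterozygosity():
    # Beta parameters enormous and equal -> allele frequency ~0.5 -> HWE
    # heterozygosity ~0.5 at every locus
    cfg = SimConfig(
        n_loci=300, n_founders=400, founder_maf_dist=(5e5, 5e5), seed=2
    )
    founders = simulate_founders(cfg)
    het = (founders.dosages == 1).mean().mean()
    assert abs(het - 0.5) < 0.02


def test_determinism_bit_identical():
    cfg = SimConfig(n_loci=120, samples_per_population=20, n_founders=20, seed=9)
    a = simulate_study(cfg, with_depths=True, with_alignments=True)
    b = simulate_study(cfg, with_depths=True, with_alignments=True)
    pd.testing.assert_frame_equal(a.genotypes.dosages, b.genotypes.dosages)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    pd.testing.assert_frame_equal(a.depths, b.depths)
    pd.testing.assert_frame_equal(a.alignments, b.alignments)


def test_huge_ne_freezes_frequencies():
    cfg = SimConfig(
        n_loci=500, ne_integrated=10**6, ne_segregated=10**6, ne_wild=10**6,
        samples_per_population=10, n_founders=50, seed=3,
    )
    founders = simulate_founders(cfg)
    pops = propagate_lines(founders, cfg)
    p0 = founders.freqs.to_numpy()
    for pop in pops:
        # binomial SE at Ne=1e6 per generation; 4 generations of drift.
        # ~4000 locus draws, so allow the expected handful of 3-SE exceedances
        se = np.sqrt(4 * p0 * (1 - p0) / (2e6)) + 1e-9
        dev = np.abs(pop.freqs.to_numpy() - p0)
        assert (dev < 3 * se + 1e-4).mean() > 0.99
        assert dev.max() < 0.01


def test_drift_variance_matches_wright_fisher():
    """Var(p_t - p_0) across neutral loci tracks the WF expectation."""
    ne = 80
    cfg = SimConfig(
        n_loci=800, ne_segregated=ne, ne_integrated=ne,
        samples_per_population=10, n_founders=50,
        founder_maf_dist=(8.0, 8.0), seed=4,
    )
    founders = simulate_founders(cfg)
    pops = propagate_lines(founders, cfg)
    p0 = founders.freqs.to_numpy()
    seg4 = [p for p in pops if p.line == "SEG" and p.generation == 4][0]
    d = seg4.freqs.to_numpy() - p0
    expected = np.mean(p0 * (1 - p0) * (1 - (1 - 1 / (2 * ne)) ** 4))
    observed = np.mean(d**2)
    assert abs(observed - expected) / expected < 0.15


def test_smaller_ne_drifts_more():
    cfg = SimConfig(
        n_loci=600, ne_segregated=40, ne_integrated=400, gene_flow_integrated=0.0,
        samples_per_population=10, n_founders=50, founder_maf_dist=(8.0, 8.0),
        seed=5,
    )
    founders = simulate_founders(cfg)
    pops = propagate_lines(founders, cfg)
    p0 = founders.freqs.to_numpy()
    var = {}
    for line in ("INT", "SEG"):
        p4 = [p for p in pops if p.line == line and p.generation == 4][0]
        var[line] = np.mean((p4.freqs.to_numpy() - p0) ** 2)
    assert var["SEG"] > var["INT"]


def test_selection_raises_frequency_in_segregated_line_only():
    up = 0
    for seed in range(8):
        cfg = SimConfig(
            n_loci=50, ne_segregated=100, ne_integrated=100,
            gene_flow_integrated=0.0, samples_per_population=10, n_founders=200,
            founder_maf_dist=(5e5, 5e5),  # start all loci near 0.5
            selected_loci=[(f"L{i:05d}", 0.5) for i in range(50)],
            seed=40 + seed,
        )
        founders = simulate_founders(cfg)
        pops = propagate_lines(founders, cfg)
        seg = [p for p in pops if p.line == "SEG" and p.generation == 4][0]
        integ = [p for p in pops if p.line == "INT" and p.generation == 4][0]
        up += seg.freqs.mean() > integ.freqs.mean()
    assert up >= 7


def test_heritability_realized_within_tolerance():
    arch = {t: TraitArchitecture(h2=0.0) for t in TRAITS}
    arch["length_cm"] = TraitArchitecture(n_causal=10, h2=0.5, effect_kind="standardized")
    cfg = SimConfig(
        n_loci=300, samples_per_population=50, n_founders=50,
        trait_architectures=arch, seed=6,
    )
    study = simulate_study(cfg)
    eff = study.causal_effects["length_cm"]
    dos = study.genotypes.dosages[eff.index].to_numpy()
    g = dos @ eff.to_numpy()
    y = study.phenotypes["length_cm"].to_numpy()
    # genetic values predict the trait with R^2 ~ h2 (scale-invariant)
    r2 = np.corrcoef(g, y)[0, 1] ** 2
    assert 0.45 <= r2 <= 0.55


def test_zero_heritability_gives_no_signal():
    arch = {t: TraitArchitecture(h2=0.0) for t in TRAITS}
    cfg = SimConfig(
        n_loci=200, samples_per_population=50, n_founders=50,
        trait_architectures=arch, seed=7,
    )
    study = simulate_study(cfg)
    eff = study.causal_effects["return_day"]
    dos = study.genotypes.dosages[eff.index].to_numpy()
    g = dos @ eff.to_numpy()
    y = study.phenotypes["return_day"].to_numpy()
    assert np.corrcoef(g, y)[0, 1] ** 2 < 0.05


def test_age_distribution_majority_age_four():
    cfg = SimConfig(n_loci=100, samples_per_population=120, n_founders=120, seed=8)
    study = simulate_study(cfg)
    frac4 = (study.phenotypes["age"] == 4).mean()
    assert 0.70 <= frac4 <= 0.80
    assert set(study.phenotypes["age"].unique()) <= {3, 4, 5}


# -- depths ------------------------------------------------------------------


def test_depths_zero_error_homozygotes_clean(small_study):
    cfg = SimConfig(
        n_loci=60, samples_per_population=20, n_founders=20,
        depth_model=DepthModel(mean_depth=30, dispersion=8, error_rate=0.0),
        seed=12,
    )
    study = simulate_study(cfg, with_depths=True)
    dep = study.depths.set_index(["individual", "locus"])
    dos = study.genotypes.dosages.stack()
    hom_ref = dos[dos == 0.0].index
    assert (dep.loc[hom_ref, "depth_a2"] == 0).all()
    hom_alt = dos[dos == 2.0].index
    assert (dep.loc[hom_alt, "depth_a1"] == 0).all()


def test_depth_tail_matches_closed_form(small_study):
    """P(both alleles >=2 and total > 10) for hets matches NB/binomial math."""
    dm = small_study.config.depth_model
    dep = small_study.depths.set_index(["individual", "locus"])
    dos = small_study.genotypes.dosages.stack()
    hets = dos[dos == 1.0].index
    d = dep.loc[hets]
    tot = (d["depth_a1"] + d["depth_a2"]).to_numpy()
    ok = (
        (d[["depth_a1", "depth_a2"]].min(axis=1) >= 2) & (tot > 10)
    ).to_numpy()

    # closed form: total ~ NB(k, k/(k+mu)); allele split Binomial(total, 1/2)
    k, mu = dm.dispersion, dm.mean_depth
    p_nb = k / (k + mu)
    tmax = 400
    t = np.arange(tmax)
    pt = stats.nbinom.pmf(t, k, p_nb)
    p_pass_given_t = np.where(
        t > 10,
        1.0 - stats.binom.cdf(1, t, 0.5) - stats.binom.sf(t - 2, t, 0.5),
        0.0,
    )
    expected = float((pt * np.clip(p_pass_given_t, 0, 1)).sum())
    assert ok.mean() == pytest.approx(expected, abs=0.02)
    assert expected > 0.99  # at mean depth 40 nearly all hets are callable


# -- phenote/genotype plumbing ----------------------------------------------


def test_combine_populations_labels(small_study):
    gm = small_study.genotypes
    assert gm.samples["population"].nunique() == 9  # P1 + 2 lines x 4 gens
    n = small_study.config.samples_per_population
    counts = gm.samples["population"].value_counts()
    assert (counts.drop("P1_F0") == n).all()


def test_alignment_truth_recoverability_rules(small_study):
    truth = small_study.alignment_truth
    assert ((truth["distance"] <= 100_000) & (truth["mapq"] >= 10)
            == truth["recoverable"]).all()


def test_domestication_scenario_pins_selection():
    study = domestication_scenario(seed=3, n_loci=200, samples_per_population=30,
                                   n_founders=30)
    sel = {l for l, _ in study.config.selected_loci}
    assert sel == set(study.causal_effects["spawn_day"].index)
    assert len(sel) == 10
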