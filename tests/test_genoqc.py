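"""Genotype caller, QC cascade filters, HWE exact test and imputation."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hatchscan import genoqc as gq
from hatchscan.containers import GenotypeMatrix, QcReport


def _gm(dosage_rows, populations, loci=None):
    """Build a GenotypeMatrix from a list of per-individual dosage lists."""
    n = len(dosage_rows)
    loci = loci or [f"L{j}" for j in range(len(dosage_rows[0]))]
    ids = [f"i{k}" for k in range(n)]
    lines = [p.split("_")[0] for p in populations]
    gens = [int(p.split("_F")[1]) for p in populations]
    dosages = pd.DataFrame(dosage_rows, index=ids, columns=loci, dtype=float)
    samples = pd.DataFrame(
        {"line": lines, "generation": gens, "sex": "F"}, index=ids
    )
    return GenotypeMatrix(dosages, samples)


# -- caller ------------------------------------------------------------------


@pytest.mark.parametrize(
    "d1,d2,expected",
    [
        (5, 6, 1.0),  # both alleles >=2 and total 11 > 10 -> het
        (0, 12, 2.0),  # single allele at depth >= 10 -> homozygote
        (12, 0, 0.0),
        (3, 7, np.nan),  # total 10 not >10; minority 3 denies homozygote
        (2, 9, 1.0),  # boundary: min 2, total 11
        (2, 8, np.nan),  # total exactly 10 fails the het rule
        (1, 9, 2.0),  # minority <=1, total 10 -> homozygote majority allele
        (9, 1, 0.0),
        (1, 10, 2.0),
        (0, 5, np.nan),  # too shallow for a confident homozygote
        (0, 0, np.nan),
    ],
)
def test_call_genotype_rule(d1, d2, expected):
    got = gq.call_genotype(d1, d2)
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == expected


def test_call_genotype_rejects_negative_depth():
    with pytest.raises(ValueError):
        gq.call_genotype(-1, 5)


def test_vectorized_caller_matches_scalar():
    rng = np.random.default_rng(0)
    d1 = rng.integers(0, 40, 300)
    d2 = rng.integers(0, 40, 300)
    depths = pd.DataFrame(
        {
            "individual": [f"i{k}" for k in range(300)],
            "locus": "L0",
            "depth_a1": d1,
            "depth_a2": d2,
        }
    )
    wide = gq.call_genotypes(depths)
    scalar = np.array([gq.call_genotype(a, b) for a, b in zip(d1, d2)])
    got = wide.loc[[f"i{k}" for k in range(300)], "L0"].to_numpy()
    assert np.array_equal(got, scalar, equal_nan=True)


# -- MAF / missingness filters ----------------------------------------------


def test_filter_maf_one_population_suffices():
    # per-population genotype counts (AA,Aa,aa) = (18,2,0), (20,0,0), (19,1,0)
    # -> MAFs 0.05, 0.0, 0.025 -> retained at threshold 0.05
    rows = []
    pops = []
    for counts, pop in [
        ((18, 2, 0), "INT_F1"),
        ((20, 0, 0), "INT_F2"),
        ((19, 1, 0), "SEG_F1"),
    ]:
        for dosage, k in zip((0.0, 1.0, 2.0), counts):
            rows += [[dosage]] * k
            pops += [pop] * k
    gm = _gm(rows, pops)
    kept = gq.filter_maf(gm, 0.05)
    assert list(kept.loci) == ["L0"]

    # monomorphic everywhere -> removed
    gm2 = _gm([[0.0]] * 60, pops)
    assert len(gq.filter_maf(gm2, 0.05).loci) == 0


def test_filter_maf_boundary_in_one_population():
    # MAF 0.04 in one population, 0.06 in the other -> retained
    rows, pops = [], []
    for dosage, k in [(0.0, 46), (1.0, 4)]:  # p = 4/100 = 0.04
        rows += [[dosage]] * k
        pops += ["INT_F1"] * k
    for dosage, k in [(0.0, 44), (1.0, 6)]:  # p = 0.06
        rows += [[dosage]] * k
        pops += ["SEG_F1"] * k
    gm = _gm(rows, pops)
    assert len(gq.filter_maf(gm, 0.05).loci) == 1


def test_filter_missing_individuals_boundary():
    # exactly 50% missing -> removed; 10 individuals, one over the line
    rng = np.random.default_rng(1)
    dos = rng.integers(0, 3, size=(10, 1000)).astype(float)
    dos[0, :500] = np.nan  # exactly 50%
    dos[1, :499] = np.nan  # just under
    gm = _gm(dos.tolist(), ["INT_F1"] * 10)
    kept = gq.filter_missing_individuals(gm)
    assert len(kept.individuals) == 9
    assert "i0" not in kept.individuals


def test_filter_missing_loci_every_population_counts():
    # locus 0 called in 5/10 and 6/10 -> retained (>=50% in each);
    # locus 1 called in 9/10 and 4/10 -> removed
    dos = np.ones((20, 2))
    dos[:5, 0] = np.nan  # pop A: 5/10 called
    dos[10:14, 0] = np.nan  # pop B: 6/10 called
    dos[0, 1] = np.nan  # pop A: 9/10
    dos[10:16, 1] = np.nan  # pop B: 4/10
    gm = _gm(dos.tolist(), ["INT_F1"] * 10 + ["SEG_F1"] * 10)
    kept = gq.filter_missing_loci(gm)
    assert list(kept.loci) == ["L0"]


# -- HWE exact test ----------------------------------------------------------


def hwe_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact-rational enumeration of Levene's conditional distribution."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    if min(n_A, n_a) == 0:
        return 1.0
    rare = min(n_A, n_a)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        aa = (rare - h) // 2
        AA = (max(n_A, n_a) - h) // 2
        # 2^h * n! / (AA! h! aa!) * nA! na! / (2n)!
        num = Fraction(2) ** h * Fraction(
            comb(n, AA) * comb(n - AA, h)
        )
        den = Fraction(comb(2 * n, n_A))
        probs[h] = num / den
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    p = sum(v / total for v in probs.values() if v / total <= obs)
    return float(p)


@pytest.mark.parametrize(
    "counts,check",
    [
        ((0, 100, 0), lambda p: p < 1e-10),  # all hets: extreme excess
        ((25, 50, 25), lambda p: p >= 0.5),  # modal configuration
        ((50, 0, 0), lambda p: p == 1.0),  # monomorphic
    ],
)
def test_hwe_landmarks(counts, check):
    assert check(gq.hwe_exact_test(*counts))


@given(
    st.integers(0, 25), st.integers(0, 25), st.integers(0, 25)
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hwe_matches_enumeration_oracle(a, h, b):
    if a + h + b == 0:
        return
    assert gq.hwe_exact_test(a, h, b) == pytest.approx(
        hwe_oracle(a, h, b), abs=1e-12
    )


def test_filter_hwe_two_population_rule():
    # a locus with extreme het excess in exactly one population is retained;
    # in two populations it is removed
    het_col = [1.0] * 30
    hwe_col = [0.0] * 8 + [1.0] * 14 + [2.0] * 8
    pops = ["P1_F0"] * 30 + ["INT_F1"] * 30 + ["SEG_F1"] * 30
    one = _gm(
        [[a, b] for a, b in zip(het_col + hwe_col + hwe_col, hwe_col * 3)],
        pops,
    )
    kept = gq.filter_hwe(one, alpha=0.05)
    assert list(kept.loci) == ["L0", "L1"]

    two = _gm(
        [[a, b] for a, b in zip(het_col + het_col + hwe_col, hwe_col * 3)],
        pops,
    )
    kept2 = gq.filter_hwe(two, alpha=0.05)
    assert list(kept2.loci) == ["L1"]


# -- imputation and F_IS -----------------------------------------------------


def test_impute_no_missing_is_identity(small_study):
    gm = small_study.genotypes
    out, r = gq.impute_missing(gm, seed=0)
    pd.testing.assert_frame_equal(out.dosages, gm.dosages)
    assert r == 1.0


def test_impute_preserves_allele_frequencies(small_study):
    rng = np.random.default_rng(5)
    gm = small_study.genotypes
    dos = gm.dosages.to_numpy().copy()
    mask = rng.random(dos.shape) < 0.05  # 5% MCAR
    dos[mask] = np.nan
    gm2 = GenotypeMatrix(
        pd.DataFrame(dos, index=gm.individuals, columns=gm.loci), gm.samples
    )
    out, r = gq.impute_missing(gm2, seed=1)
    assert not out.dosages.isna().any().any()
    assert r > 0.99
    # deterministic given the seed
    out2, _ = gq.impute_missing(gm2, seed=1)
    pd.testing.assert_frame_equal(out.dosages, out2.dosages)


def test_fis_extremes_and_null():
    # all heterozygotes at p=0.5 -> F_IS ~ -1 (maximal excess)
    gm = _gm([[1.0]] * 50, ["INT_F1"] * 50)
    fis = gq.compute_fis(gm)
    assert fis.loc["L0", "INT_F1"] == pytest.approx(-1.0, abs=0.05)
    # monomorphic -> undefined
    gm2 = _gm([[0.0]] * 50, ["INT_F1"] * 50)
    assert np.isnan(gq.compute_fis(gm2).loc["L0", "INT_F1"])


def test_fis_near_zero_under_hwe():
    rng = np.random.default_rng(2)
    p = rng.uniform(0.2, 0.8, 500)
    dos = rng.binomial(2, p, size=(200, 500)).astype(float)
    gm = _gm(dos.tolist(), ["INT_F1"] * 200, loci=[f"L{j}" for j in range(500)])
    fis = gq.compute_fis(gm)["INT_F1"]
    assert abs(float(fis.median())) < 0.05


# -- cascade bookkeeping -----------------------------------------------------


def test_qc_cascade_counts_reconcile(small_study):
    rng = np.random.default_rng(7)
    gm = small_study.genotypes
    dos = gm.dosages.to_numpy().copy()
    mask = rng.random(dos.shape) < 0.03
    dos[mask] = np.nan
    dos[0, :] = np.nan  # one individual fully missing
    gm2 = GenotypeMatrix(
        pd.DataFrame(dos, index=gm.individuals, columns=gm.loci), gm.samples
    )
    clean, rep = gq.run_qc(gm2)
    assert rep.loci_in == len(gm.loci)
    assert rep.loci_after_maf == rep.loci_in - rep.loci_removed_maf
    assert (
        rep.loci_out
        == rep.loci_after_maf - rep.loci_removed_missingness - rep.loci_removed_hwe
    )
    assert rep.individuals_removed == 1
    assert len(clean.individuals) == rep.individuals_in - 1
    assert not clean.dosages.isna().any().any()
    assert isinstance(rep.to_frame(), pd.DataFrame)
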