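"""Tests for the negative-binomial Wald differential-expression engine.

The engine is checked against independent oracles: brute-force
enumeration for the median-of-ratios factors and the BH step-up, and a
generic numeric NB maximum-likelihood fit (scipy optimizer plus
finite-difference information) for the Wald statistic.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from surfnom import diffexpr, simulate
from surfnom.errors import ValidationError

from conftest import make_counts


def two_group_design(n1, n2, g1="num", g2="den"):
    cols = [f"S{j}" for j in range(n1 + n2)]
    return pd.Series([g1] * n1 + [g2] * n2,
                     index=pd.Index(cols, name="sample_id"), name="group")


# ---------------------------------------------------------------------------
# size factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = make_counts([[5, 5], [9, 9], [2, 2]])
        np.testing.assert_allclose(diffexpr.estimate_size_factors(cm), 1.0)

    def test_doubled_column_doubles_ratio(self):
        cm = make_counts([[4, 8], [10, 20], [7, 14]])
        sf = diffexpr.estimate_size_factors(cm)
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_enumeration(self):
        cm = make_counts([[2, 8], [4, 4], [6, 6]])
        # brute force: geometric means per feature, then per-sample median ratio
        values = cm.to_numpy(float)
        geo = np.exp(np.log(values).mean(axis=1))
        expected = [np.median(values[:, j] / geo) for j in range(2)]
        np.testing.assert_allclose(
            diffexpr.estimate_size_factors(cm), expected
        )

    def test_feature_order_invariance(self):
        cm = make_counts([[2, 8], [4, 4], [6, 6]])
        shuffled = cm.iloc[[2, 0, 1]]
        np.testing.assert_allclose(
            diffexpr.estimate_size_factors(cm),
            diffexpr.estimate_size_factors(shuffled),
        )

    def test_no_all_nonzero_feature_is_hard_error(self):
        cm = make_counts([[0, 3], [5, 0]])
        with pytest.raises(ValidationError, match="pseudo-reference"):
            diffexpr.estimate_size_factors(cm)


# ---------------------------------------------------------------------------
# dispersions


class TestDispersions:
    def test_moment_formula_by_hand(self):
        # normalized counts [0, 20 | 0, 20]: pooled mean 10, within-group
        # SS = 400 over 2 df -> variance 200, alpha = (200 - 10) / 100 = 1.9
        cm = make_counts([[0, 20, 0, 20]])
        sf = pd.Series(1.0, index=cm.columns)
        design = two_group_design(2, 2)
        got = diffexpr.estimate_dispersions(cm, sf, design).iloc[0]
        assert got == pytest.approx(1.9)

    def test_poisson_like_data_hits_floor(self):
        rng = np.random.default_rng(0)
        cm = make_counts(rng.poisson(5.0, size=(200, 8)))
        sf = pd.Series(1.0, index=cm.columns)
        disp = diffexpr.estimate_dispersions(cm, sf, two_group_design(4, 4))
        # Poisson data: most moment estimates are at or near the floor
        assert np.median(disp) < 0.05

    def test_constant_feature_gets_floor(self):
        cm = make_counts([[7, 7, 7, 7]])
        sf = pd.Series(1.0, index=cm.columns)
        disp = diffexpr.estimate_dispersions(cm, sf, two_group_design(2, 2))
        assert disp.iloc[0] == diffexpr.DISPERSION_FLOOR

    def test_zero_feature_gets_floor(self):
        cm = make_counts([[0, 0, 0, 0], [5, 5, 5, 5]])
        sf = pd.Series(1.0, index=cm.columns)
        disp = diffexpr.estimate_dispersions(cm, sf, two_group_design(2, 2))
        assert disp.iloc[0] == diffexpr.DISPERSION_FLOOR


# ---------------------------------------------------------------------------
# Wald test


def run_wald(counts, design, num="num", den="den", sf=None, disp=None):
    sf = sf if sf is not None else diffexpr.estimate_size_factors(counts)
    disp = (
        disp
        if disp is not None
        else diffexpr.estimate_dispersions(counts, sf, design)
    )
    return diffexpr.nb_wald_test(counts, sf, disp, design, num, den)


class TestWald:
    def test_identical_groups_are_null(self):
        block = np.array([[10, 20, 30], [3, 1, 2]])
        cm = make_counts(np.hstack([block, block]))
        design = two_group_design(3, 3)
        res = run_wald(cm, design)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-8)
        np.testing.assert_allclose(res["wald_p"], 1.0, atol=1e-8)

    def test_swapping_groups_negates_lfc_preserves_p(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.poisson([[20], [80], [5]], size=(3, 8)))
        design = two_group_design(4, 4)
        a = run_wald(cm, design, "num", "den")
        b = run_wald(cm, design, "den", "num")
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-10)
        np.testing.assert_allclose(a["wald_p"], b["wald_p"], atol=1e-12)

    def test_both_groups_zero(self):
        cm = make_counts([[0, 0, 0, 0], [9, 9, 9, 9]])
        res = run_wald(
            cm, two_group_design(2, 2),
            sf=pd.Series(1.0, index=cm.columns),
            disp=pd.Series(0.1, index=cm.index),
        )
        assert res.loc["F0", "log2fc"] == 0.0
        assert res.loc["F0", "wald_p"] == 1.0
        assert res.loc["F0", "flag"] == "all_zero"

    def test_one_zero_group_is_capped_and_flagged(self):
        cm = make_counts([[40, 44, 0, 0]])
        res = run_wald(
            cm, two_group_design(2, 2),
            sf=pd.Series(1.0, index=cm.columns),
            disp=pd.Series(0.1, index=cm.index),
        )
        assert res.loc["F0", "log2fc"] == pytest.approx(diffexpr.LFC_CAP)
        assert res.loc["F0", "flag"] == "den_zero"
        assert res.loc["F0", "wald_p"] < 0.05

    def test_agrees_with_numeric_mle_oracle(self):
        """Wald z within 0.05 of a generic-optimizer NB MLE on 50 features."""
        rng = np.random.default_rng(7)
        F, n1, n2 = 50, 8, 6
        mu = rng.lognormal(np.log(500), 1, F)
        fc = rng.choice([1.0, 2.0, 0.5], F)
        k = np.hstack(
            [rng.poisson(np.tile(mu[:, None], (1, n1))),
             rng.poisson(np.tile((mu * fc)[:, None], (1, n2)))]
        )
        cm = make_counts(k)
        design = two_group_design(n1, n2)
        res = run_wald(
            cm, design,
            sf=pd.Series(1.0, index=cm.columns),
            disp=pd.Series(diffexpr.DISPERSION_FLOOR, index=cm.index),
        )
        z = (res["log2fc"] / res["se"]).to_numpy()
        for i, f in enumerate(cm.index):
            zo = _oracle_z(k[i, :n1], k[i, n1:], diffexpr.DISPERSION_FLOOR)
            assert abs(z[i] - zo) < 0.05

    def test_scale_invariance_of_results(self):
        cfg = simulate.SimConfig(
            seed=3, n_genes=300, group_sizes={"num": 8, "den": 8},
            n_true_targets=0, n_crpc_shared=0, n_nonsurface=0,
            n_broad_tissue=0, n_benign_leaky=0, n_isoform_switch=0,
        )
        co = simulate.simulate_cohort(cfg)
        a = run_wald(co.counts, co.design)
        scaled = co.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        b = run_wald(scaled, co.design)
        np.testing.assert_allclose(a["log2fc"], b["log2fc"], atol=0.01)
        za, zb = a["log2fc"] / a["se"], b["log2fc"] / b["se"]
        np.testing.assert_allclose(za, zb, atol=0.05)

    def test_padj_dominates_p_and_preserves_order(self, default_cohort):
        co = default_cohort
        sf = diffexpr.estimate_size_factors(co.counts)
        disp = diffexpr.estimate_dispersions(co.counts, sf, co.design)
        res = diffexpr.nb_wald_test(co.counts, sf, disp, co.design,
                                    "nepc", "benign")
        assert (res["padj"] >= res["wald_p"] - 1e-15).all()
        order = res.sort_values("wald_p")
        assert order["padj"].is_monotonic_increasing

    def test_cross_check_against_pydeseq2(self):
        """Rank correlation > 0.95 against an established NB-DE package."""
        pydeseq2 = pytest.importorskip("pydeseq2")  # noqa: F841
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(11)
        F, n = 400, 10
        mu = rng.lognormal(np.log(200), 1, F)
        fc = np.ones(F)
        de = rng.choice(F, 80, replace=False)
        fc[de] = rng.choice([4.0, 0.25], 80)
        r = 1 / 0.15
        k1 = rng.negative_binomial(r, r / (r + np.tile(mu[:, None], (1, n))))
        k2 = rng.negative_binomial(
            r, r / (r + np.tile((mu * fc)[:, None], (1, n)))
        )
        cm = make_counts(np.hstack([k1, k2]))
        design = two_group_design(n, n, "A", "B")
        mine = run_wald(cm, design, "B", "A")

        meta = pd.DataFrame({"condition": design.to_numpy()}, index=cm.columns)
        dds = DeseqDataSet(counts=cm.T, metadata=meta, design="~condition",
                           quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["condition", "B", "A"], quiet=True)
        ds.summary()
        theirs = ds.results_df.loc[mine.index, "pvalue"]
        rho = stats.spearmanr(mine["wald_p"], theirs).statistic
        assert rho > 0.95


def _oracle_z(k_num, k_den, alpha):
    """Independent z: scalar-optimizer MLE + finite-difference information."""

    def fit(k):
        r = 1.0 / alpha

        def nll(beta):
            m = np.exp(beta)
            return -stats.nbinom.logpmf(k, r, r / (r + m)).sum()

        center = np.log(max(k.mean(), 1e-3))
        b = optimize.minimize_scalar(
            nll, bounds=(center - 5, center + 5), method="bounded",
            options={"xatol": 1e-10},
        ).x
        h = 1e-4
        info = (nll(b + h) - 2 * nll(b) + nll(b - h)) / h**2
        return b, info

    b1, i1 = fit(np.asarray(k_num, float))
    b2, i2 = fit(np.asarray(k_den, float))
    lfc = (b1 - b2) / np.log(2)
    se = np.sqrt(1 / i1 + 1 / i2) / np.log(2)
    return lfc / se


# ---------------------------------------------------------------------------
# BH adjustment


def bh_brute_force(p):
    """Direct step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sp = p[order]
    q = np.empty(m)
    for i in range(m):
        q[i] = min(min(sp[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q
    return out


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.03]), [0.03])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(diffexpr.bh_adjust([0.2] * 5), [0.2] * 5)

    def test_worked_example(self):
        np.testing.assert_allclose(
            diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.5]),
            [0.04, 0.04, 0.04, 0.5],
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            diffexpr.bh_adjust([0.5, 1.5])

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40)
    )
    def test_identical_to_brute_force(self, p):
        np.testing.assert_allclose(
            diffexpr.bh_adjust(p), bh_brute_force(p), rtol=1e-12, atol=1e-12
        )

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(size=500)
        np.testing.assert_allclose(
            diffexpr.bh_adjust(p), sm.multipletests(p, method="fdr_bh")[1]
        )
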