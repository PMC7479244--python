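"""Dispersion shrinkage, the beta-binomial Wald test, the covariate-weighted
FDR adjustment, DMC thresholds, DMR chaining and set comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rrbsdiff.differential import (
    ComparisonSpec,
    DifferentialMethylation,
    _bh,
    call_dmcs,
    call_dmrs,
    compare_dmc_sets,
    estimate_dispersion_shrunk,
    ihw_adjust,
    volcano_table,
    wald_test,
)

from _oracles import brute_force_dmrs


def _counts(props, coverage):
    """(meth, total) arrays for one site from per-sample proportions."""
    total = np.full((1, len(props)), coverage, dtype=int)
    meth = np.round(np.asarray(props) * coverage).astype(int)[None, :]
    return meth, total


class TestDispersion:
    def test_identical_proportions_at_lower_clip(self):
        m1, t1 = _counts([0.5] * 6, 1000)
        m2, t2 = _counts([0.5] * 6, 1000)
        # a genome of such sites: prior mean collapses, estimate hits the clip
        phi = estimate_dispersion_shrunk(
            np.repeat(m1, 50, 0), np.repeat(t1, 50, 0), np.repeat(m2, 50, 0), np.repeat(t2, 50, 0)
        )
        assert (phi <= 2e-3).all()

    def test_parameter_recovery_on_beta_binomial(self):
        rng = np.random.default_rng(0)
        n_sites, phi_true, cov = 20_000, 0.1, 25
        s = 1 / phi_true - 1

        def draw(m):
            p = rng.beta(0.5 * s, 0.5 * s, size=(n_sites, m))
            return rng.binomial(cov, p), np.full((n_sites, m), cov)

        m1, t1 = draw(9)
        m2, t2 = draw(9)
        phi = estimate_dispersion_shrunk(m1, t1, m2, t2)
        assert 0.05 <= np.median(phi) <= 0.2

    def test_shrinkage_pulls_single_site_toward_prior(self):
        rng = np.random.default_rng(1)
        # background sites with moderate dispersion + one wild site
        bg_m = rng.binomial(25, 0.5, size=(500, 8))
        bg_t = np.full((500, 8), 25)
        wild_m = np.array([[0, 0, 0, 0, 25, 25, 25, 25]])
        wild_t = np.full((1, 8), 25)
        m1 = np.vstack([bg_m, wild_m])
        t1 = np.vstack([bg_t, wild_t])
        phi = estimate_dispersion_shrunk(m1, t1, m1, t1, prior_weight=50.0)
        # raw moment estimate at the wild site is ~1; shrunk is far below
        raw_wild = 1.0
        prior = np.median(phi[:-1])
        assert abs(phi[-1] - prior) < abs(phi[-1] - raw_wild)


class TestWald:
    def test_identical_groups_null(self):
        m, t = _counts([0.4] * 5, 20)
        diff, wald, p = wald_test(m, t, m, t, np.array([0.01]))
        assert diff[0] == 0 and wald[0] == 0 and p[0] == 1.0

    def test_extreme_separation(self):
        m1, t1 = _counts([1.0] * 4, 25)
        m2, t2 = _counts([0.0] * 4, 25)
        _, _, p = wald_test(m1, t1, m2, t2, np.array([1e-6]))
        assert p[0] < 1e-6

    def test_saturated_both_groups_p_one(self):
        m, t = _counts([1.0] * 4, 25)
        diff, wald, p = wald_test(m, t, m, t, np.array([1e-6]))
        assert p[0] == 1.0 and wald[0] == 0.0

    def test_orientation_group1_minus_group2(self):
        m1, t1 = _counts([0.8] * 4, 25)
        m2, t2 = _counts([0.2] * 4, 25)
        diff, _, _ = wald_test(m1, t1, m2, t2, np.array([0.01]))
        assert diff[0] == pytest.approx(60.0, abs=1e-9)


class TestIHW:
    def test_one_bin_equals_bh_spec_example(self):
        p = np.array([0.01, 0.02, 0.04, 0.8])
        w, padj = ihw_adjust(p, np.zeros(4), n_bins=1)
        np.testing.assert_allclose(w, 1.0)
        np.testing.assert_allclose(padj, [0.04, 0.04, 0.04 * 4 / 3, 0.8], atol=1e-12)

    def test_one_bin_matches_statsmodels_bh(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 300))
            _, padj = ihw_adjust(p, rng.normal(size=len(p)), n_bins=1)
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(padj, expected, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(2, 2000), st.integers(1, 8))
    def test_weights_average_one(self, seed, n, bins):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=n)
        w, _ = ihw_adjust(p, rng.normal(size=n), n_bins=bins)
        assert abs(w.mean() - 1.0) < 1e-9

    def test_informative_covariate_increases_power(self):
        rng = np.random.default_rng(4)
        n = 5000
        cov = rng.uniform(size=n)
        # signal concentrated in the low-covariate half
        is_signal = (cov < 0.3) & (rng.uniform(size=n) < 0.3)
        p = np.where(is_signal, rng.beta(0.08, 1, size=n), rng.uniform(size=n))
        _, padj_w = ihw_adjust(p, cov, n_bins=5)
        _, padj_u = ihw_adjust(p, cov, n_bins=1)
        assert (padj_w[is_signal] < 0.1).sum() >= (padj_u[is_signal] < 0.1).sum()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ihw_adjust([0.5], [0.1], n_bins=0)
        with pytest.raises(ValueError):
            ihw_adjust([0.5, 0.1], [np.nan, 0.0])


class TestCallDmcs:
    def _tests(self, **overrides):
        base = dict(
            chrom=["chr1"], pos=[100], n1=[5], n2=[5], mean1=[60.0], mean2=[40.0],
            diff=[20.0], phi=[0.01], wald=[3.0], p=[0.001], weight=[1.0], p_adj=[0.05],
        )
        base.update(overrides)
        return pd.DataFrame(base)

    @pytest.mark.parametrize(
        "padj,diff,n1,expected",
        [
            (0.1, 15.0, 5, 0),     # "weaker than 0.1" is strict
            (0.099, 10.0, 5, 1),   # boundary diff inclusive
            (0.001, 9.99, 5, 0),   # diff below threshold
            (0.05, 12.0, 3, 0),    # fewer than 4 bulls
        ],
    )
    def test_threshold_boundaries(self, padj, diff, n1, expected):
        spec = ComparisonSpec("HM15", "MM15")
        out = call_dmcs(self._tests(p_adj=[padj], diff=[diff], n1=[n1]), spec)
        assert len(out) == expected

    def test_direction_follows_sign(self):
        spec = ComparisonSpec("HM15", "MM15")
        out = call_dmcs(self._tests(diff=[-20.0]), spec)
        assert out["direction"].iloc[0] == "hypo_in_group1"

    def test_monotone_in_min_diff(self, small_matrix):
        res = DifferentialMethylation(small_matrix, ComparisonSpec("HM15", "MM15")).fit()
        loose = call_dmcs(res.tests, ComparisonSpec("HM15", "MM15", min_diff=5.0))
        strict = call_dmcs(res.tests, ComparisonSpec("HM15", "MM15", min_diff=10.0))
        strict_keys = set(zip(strict["chrom"], strict["pos"]))
        loose_keys = set(zip(loose["chrom"], loose["pos"]))
        assert strict_keys <= loose_keys


class TestCallDmrs:
    def _dmcs(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {
                "chrom": [chrom] * len(positions),
                "pos": positions,
                "diff": [15.0] * len(positions),
            }
        )

    def test_basic_chain(self):
        out = call_dmrs(self._dmcs([1000, 1050, 1140]))
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"], out.iloc[0]["n_dmcs"]) == (1000, 1140, 3)

    def test_gap_boundary(self):
        assert len(call_dmrs(self._dmcs([1000, 1050, 1151]))) == 0  # gap 101
        assert len(call_dmrs(self._dmcs([1000, 1050, 1150]))) == 1  # gap 100 joins

    def test_chromosomes_not_chained(self):
        d = pd.concat([self._dmcs([10, 50]), self._dmcs([60], chrom="chr2")])
        assert len(call_dmrs(d)) == 0

    def test_majority_direction(self):
        d = self._dmcs([10, 50, 90])
        d.loc[2, "diff"] = -20.0
        out = call_dmrs(d)
        assert out.iloc[0]["direction"] == "hyper_in_group1"

    def test_matches_brute_force_oracle_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(0, 50)
            pos = np.unique(rng.integers(0, 3000, size=n))
            out = call_dmrs(self._dmcs(list(pos)))
            expected = brute_force_dmrs(list(pos))
            got = [(r["start"], r["end"], r["n_dmcs"]) for _, r in out.iterrows()]
            assert got == expected


class TestCompareSets:
    def test_reported_set_arithmetic(self):
        a = pd.DataFrame(
            {"chrom": ["chr1"] * 491, "pos": range(491), "direction": ["hyper_in_group1"] * 491}
        )
        b = pd.DataFrame(
            {"chrom": ["chr1"] * 164, "pos": range(416, 580), "direction": ["hyper_in_group1"] * 164}
        )
        out = compare_dmc_sets(a, b)
        assert out["intersection"] == 75
        assert out["union"] == 580
        assert round(out["shared_pct"], 1) == 12.9

    def test_identical_and_disjoint(self):
        a = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [1, 2, 3], "direction": ["hyper_in_group1"] * 3})
        assert compare_dmc_sets(a, a)["shared_pct"] == 100.0
        b = pd.DataFrame({"chrom": ["chr1"] * 2, "pos": [9, 10], "direction": ["hypo_in_group1"] * 2})
        out = compare_dmc_sets(a, b)
        assert out["union"] == 5 and out["shared_pct"] == 0.0
        assert out["pct_hyper_group1_b"] == 0.0


class TestVolcano:
    def test_neglog10_and_flags_consistent(self, small_matrix):
        res = DifferentialMethylation(small_matrix, ComparisonSpec("HM15", "MM15")).fit()
        vt = res.volcano_table()
        np.testing.assert_allclose(
            vt["neg_log10_p"], -np.log10(np.maximum(res.tests["p"], 1e-300))
        )
        dmc_keys = set(zip(res.dmcs["chrom"], res.dmcs["pos"]))
        flagged = set(zip(vt.loc[vt["is_dmc"], "chrom"], vt.loc[vt["is_dmc"], "pos"]))
        assert flagged == dmc_keys

    def test_fail_reason_diff(self):
        tests = pd.DataFrame(
            dict(chrom=["chr1"], pos=[1], n1=[5], n2=[5], mean1=[52.0], mean2=[48.0],
                 diff=[4.0], phi=[0.01], wald=[5.0], p=[1e-7], weight=[1.0], p_adj=[1e-5])
        )
        vt = volcano_table(tests, ComparisonSpec("HM15", "MM15"))
        assert vt["fail_reason"].iloc[0] == "diff"


class TestModelInterface:
    def test_summary_mentions_counts(self, small_matrix):
        res = DifferentialMethylation(small_matrix, ComparisonSpec("HM15", "MM15")).fit()
        text = res.summary()
        assert "HM15 vs MM15" in text
        assert str(len(res.dmcs)) in text

    def test_all_emitted_dmcs_satisfy_thresholds(self, small_matrix):
        res = DifferentialMethylation(small_matrix, ComparisonSpec("HM15", "MM15")).fit()
        d = res.dmcs
        assert (d["p_adj"] < 0.1).all()
        assert (d["diff"].abs() >= 10).all()
        assert ((d["n1"] >= 4) & (d["n2"] >= 4)).all()

    def test_unknown_group_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            DifferentialMethylation(small_matrix, ComparisonSpec("HM15", "XX19"))

    def test_null_comparison_finds_nothing(self, small_matrix):
        # MM15 vs MM16 share identical truth: expect (almost) no DMCs
        res = DifferentialMethylation(small_matrix, ComparisonSpec("MM15", "MM16")).fit()
        assert len(res.dmcs) <= 2
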