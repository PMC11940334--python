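"""Group comparisons, FDR, Cohen's d maps, demographic tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import hemigrad as hg
from hemigrad.exceptions import DataError

from .oracles import bh_stepup_oracle


def _pheno(n, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    if groups is None:
        groups = np.r_[["HC"] * (n // 2), ["SZ"] * (n - n // 2)]
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": groups,
        "age": rng.normal(36, 11, n).clip(18, 65),
        "sex": np.where(rng.random(n) < 0.4, "F", "M"),
        "site": "site1",
        "mean_fd": np.exp(rng.normal(np.log(0.15), 0.3, n)),
    })


class TestFdrBH:
    def test_worked_example(self):
        q, rej = hg.fdr_bh([0.01, 0.02, 0.03, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])
        assert rej.sum() == 3

    def test_constant_and_single(self):
        q, _ = hg.fdr_bh([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)
        q, _ = hg.fdr_bh([0.123])
        assert q[0] == pytest.approx(0.123)

    def test_empty(self):
        q, rej = hg.fdr_bh([])
        assert q.size == 0 and rej.size == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            q, _ = hg.fdr_bh(p)
            assert np.allclose(q, bh_stepup_oracle(p), atol=1e-12)

    def test_invalid_pvalues(self):
        with pytest.raises(DataError):
            hg.fdr_bh([0.5, 1.2])


class TestGroupCompare:
    def test_matches_statsmodels_ols(self):
        pheno = _pheno(60, seed=1)
        rng = np.random.default_rng(2)
        feats = pd.DataFrame(rng.standard_normal((60, 4)),
                             index=pheno["subject_id"],
                             columns=[f"G1_intra_net_N{i}" for i in range(4)])
        res = hg.group_compare(feats, pheno, family="test")
        X = sm.add_constant(pd.DataFrame({
            "group": (pheno["group"] == "SZ").astype(float),
            "age": pheno["age"],
            "sex": (pheno["sex"] == "M").astype(float),
            "mean_fd": pheno["mean_fd"],
        })).to_numpy()
        for j, col in enumerate(feats.columns):
            fit = sm.OLS(feats[col].to_numpy(), X).fit()
            assert res.table.loc[j, "t"] == pytest.approx(fit.tvalues[1])
            assert res.table.loc[j, "p"] == pytest.approx(fit.pvalues[1])
            assert res.table.loc[j, "df"] == fit.df_resid

    def test_zero_noise_identical_groups(self):
        pheno = _pheno(40, seed=3)
        feats = pd.DataFrame(
            np.tile(np.linspace(0, 1, 40)[:, None], (1, 2)) * 0 + 0.5,
            index=pheno["subject_id"], columns=["G1_intra_net_A", "G1_intra_net_B"])
        # identical groups, no group signal: t is exactly 0 only with zero
        # residual correlation with group, so use a constant feature plus a
        # covariate-free check via permutation symmetry instead
        res = hg.group_compare(feats + 0.0, pheno, family="f",
                               covariates=())
        assert np.allclose(res.table["t"], 0.0)

    def test_covariate_rescaling_invariance(self):
        pheno = _pheno(50, seed=4)
        rng = np.random.default_rng(5)
        feats = pd.DataFrame(rng.standard_normal((50, 3)),
                             index=pheno["subject_id"],
                             columns=list("abc"))
        res1 = hg.group_compare(feats, pheno, family="f")
        pheno2 = pheno.copy()
        pheno2["age"] = pheno2["age"] * 12 + 7      # months, offset
        pheno2["mean_fd"] = pheno2["mean_fd"] * 1000  # microns
        res2 = hg.group_compare(feats, pheno2, family="f")
        assert np.allclose(res1.table["t"], res2.table["t"], atol=1e-8)

    def test_errors(self):
        pheno = _pheno(5, seed=6)
        feats = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 2)),
                             index=pheno["subject_id"], columns=["a", "b"])
        with pytest.raises(DataError):
            hg.group_compare(feats, pheno, family="f")  # n too small
        pheno1 = _pheno(30, seed=7, groups=np.array(["HC"] * 30))
        feats1 = pd.DataFrame(np.random.default_rng(1).standard_normal((30, 2)),
                              index=pheno1["subject_id"], columns=["a", "b"])
        with pytest.raises(DataError):
            hg.group_compare(feats1, pheno1, family="f")

    def test_null_rejections_controlled(self):
        """With permuted (null) labels the BH stage rarely rejects."""
        rejected = total = 0
        for seed in range(30):
            pheno = _pheno(60, seed=seed)
            rng = np.random.default_rng(100 + seed)
            feats = pd.DataFrame(rng.standard_normal((60, 10)),
                                 index=pheno["subject_id"],
                                 columns=[f"f{i}" for i in range(10)])
            res = hg.group_compare(feats, pheno, family="null")
            rejected += res.table["significant"].sum()
            total += len(res.table)
        assert rejected / total <= 0.05


class TestCohensD:
    def test_d_estimates_planted_mean(self):
        pheno = _pheno(200, seed=8)
        rng = np.random.default_rng(9)
        feats = pd.DataFrame(
            {"G1_intra_pair_0": rng.normal(0.5, 1.0, 200),
             "G1_intra_pair_1": rng.normal(0.0, 1.0, 200)},
            index=pheno["subject_id"])
        dmap = hg.cohens_d_map(feats, pheno)
        row = dmap.table[(dmap.table["group"] == "HC")
                         & (dmap.table["feature"] == "G1_intra_pair_0")].iloc[0]
        assert row["d"] == pytest.approx(0.5, abs=0.2)
        assert np.sign(row["d"]) == np.sign(row["mean"])

    def test_zero_sd_flagged(self):
        pheno = _pheno(20, seed=10)
        feats = pd.DataFrame({"G1_intra_pair_0": np.full(20, 0.3)},
                             index=pheno["subject_id"])
        dmap = hg.cohens_d_map(feats, pheno)
        assert dmap.table["flagged"].all()
        assert dmap.table["d"].isna().all()

    def test_sign_always_matches_mean(self):
        pheno = _pheno(50, seed=11)
        rng = np.random.default_rng(12)
        feats = pd.DataFrame(
            rng.normal(rng.normal(0, 1, 6), 1.0, (50, 6)),
            index=pheno["subject_id"],
            columns=[f"G{g}_intra_pair_{i}" for g in (1, 2) for i in range(3)])
        dmap = hg.cohens_d_map(feats, pheno)
        ok = dmap.table.dropna(subset=["d"])
        assert (np.sign(ok["d"]) == np.sign(ok["mean"])).all()


class TestDemographics:
    def test_printed_cohort_statistics(self):
        """Reproduce the published Yates chi-squared and Student's t."""
        chi2, p = hg.stats.chi2_sex_by_group(np.array([[65, 144], [91, 179]]))
        assert round(chi2, 2) == 0.25
        assert round(p, 2) == 0.61
        t, p = hg.stats.t_from_summary(36.50, 11.02, 209, 36.10, 10.67, 270)
        assert round(t, 2) == 0.40
        assert round(p, 2) == 0.69

    def test_identical_groups_give_zero(self):
        pheno = pd.concat([_pheno(20, seed=13, groups=np.array(["HC"] * 20)),
                           _pheno(20, seed=13, groups=np.array(["SZ"] * 20))],
                          ignore_index=True)
        out = hg.demographic_tests(pheno)
        assert out.loc[out["variable"] == "sex", "statistic"].iloc[0] == 0
        assert out.loc[out["variable"] == "age", "statistic"].iloc[0] == pytest.approx(0)

    def test_empty_group_errors(self):
        with pytest.raises(DataError):
            hg.demographic_tests(_pheno(10, groups=np.array(["HC"] * 10)))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_fdr_bh_property(pvals):
    """Adjusted values are monotone in p, within [0, 1], and >= p/ n-scaled."""
    q, rej = hg.fdr_bh(pvals)
    p = np.asarray(pvals)
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.allclose(q, bh_stepup_oracle(p), atol=1e-12)
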