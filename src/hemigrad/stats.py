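"""Mass-univariate group statistics on asymmetry features.

Per feature, AI is regressed on a group indicator plus age, sex and mean FD
(ordinary least squares); the group coefficient's t statistic is reported
with BH-FDR-adjusted q values across a declared test family.  Positive t
means higher AI in the SZ group.  One-sample Cohen's d maps per group, and
the cohort demographic tests (Yates chi-squared for sex, pooled-variance
Student's t for age and motion), complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .asymmetry import parse_feature_name
from .exceptions import DataError

DEFAULT_COVARIATES = ("age", "sex", "mean_fd")
DEFAULT_Q_LEVEL = 0.05


@dataclass
class ComparisonResult:
    """Tidy per-feature group-comparison table plus family metadata."""

    table: pd.DataFrame            # feature, estimate, t, df, p, q, significant
    family: str
    q_level: float = DEFAULT_Q_LEVEL

    @property
    def significant_features(self) -> list[str]:
        return self.table.loc[self.table["significant"], "feature"].tolist()

    def __len__(self) -> int:
        return len(self.table)


def fdr_bh(pvals, q_level: float = DEFAULT_Q_LEVEL) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q values and rejection mask.

    Rejection is ``q <= q_level``.  Empty input gives empty outputs.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, q <= q_level


def _ols_group_t(Y: np.ndarray, X: np.ndarray, group_col: int):
    """Vectorized OLS of each column of Y on X; t test of one coefficient."""
    n, p = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(X) < p:
        raise DataError("rank-deficient design matrix")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 * XtX_inv[group_col, group_col])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[group_col] / se, 0.0)
    pvals = 2 * sps.t.sf(np.abs(t), df)
    return beta[group_col], t, df, pvals


def group_compare(
    features: pd.DataFrame,
    phenotype: pd.DataFrame,
    family: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    q_level: float = DEFAULT_Q_LEVEL,
) -> ComparisonResult:
    """Mass-univariate SZ-vs-HC comparison with covariate adjustment.

    ``features`` rows must be indexed by subject_id and ``phenotype`` must
    contain group plus the covariate columns.  Per feature, OLS of AI on
    {intercept, group(SZ=1), covariates}; t and p for the group coefficient;
    BH adjustment across the whole declared family.
    """
    pheno = phenotype.set_index("subject_id").loc[features.index]
    if pheno[list(covariates) + ["group"]].isna().any().any():
        raise DataError("phenotype has missing group or covariate values")
    g = (pheno["group"] == "SZ").astype(float).to_numpy()
    if g.min() == g.max():
        raise DataError("both groups must be present")
    cols = [np.ones(len(pheno)), g]
    for c in covariates:
        v = pheno[c]
        cols.append((v == "M").astype(float).to_numpy() if c == "sex"
                    else v.astype(float).to_numpy())
    X = np.column_stack(cols)
    n, p = X.shape
    if n <= len(covariates) + 2:
        raise DataError(f"too few subjects (n={n}) for {len(covariates)} covariates")
    Y = features.to_numpy(dtype=float)
    est, t, df, pvals = _ols_group_t(Y, X, group_col=1)
    q, rej = fdr_bh(pvals, q_level)
    table = pd.DataFrame({
        "feature": features.columns,
        "estimate": est, "t": t, "df": df, "p": pvals, "q": q,
        "significant": rej,
    })
    return ComparisonResult(table=table, family=family, q_level=q_level)


@dataclass
class CohensDMap:
    """Per-(group, feature) one-sample effect sizes of AI against zero."""

    table: pd.DataFrame   # group, feature, n, mean, sd, d, t, p, q, flagged


def cohens_d_map(
    features: pd.DataFrame,
    phenotype: pd.DataFrame,
    q_level: float = DEFAULT_Q_LEVEL,
) -> CohensDMap:
    """One-sample Cohen's d of each AI feature within each group.

    d = mean / SD; one-sample t against 0; BH correction within each
    (gradient, type, group) family across regions/networks.  Zero-SD
    features are flagged with d undefined.
    """
    pheno = phenotype.set_index("subject_id").loc[features.index]
    rows = []
    for group in ("HC", "SZ"):
        sub = features.loc[(pheno["group"] == group).to_numpy()]
        n = len(sub)
        if n < 3:
            raise DataError(f"group {group} has fewer than 3 subjects")
        mean = sub.mean(axis=0).to_numpy()
        sd = sub.std(axis=0, ddof=1).to_numpy()
        flagged = sd <= 1e-12 * (np.abs(mean) + 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(flagged, np.nan, mean / sd)
            t = np.where(flagged, np.nan, mean / (sd / np.sqrt(n)))
        p = np.where(flagged, np.nan, 2 * sps.t.sf(np.abs(t), n - 1))
        for j, feat in enumerate(features.columns):
            rows.append({"group": group, "feature": feat, "n": n,
                         "mean": mean[j], "sd": sd[j], "d": d[j], "t": t[j],
                         "p": p[j], "flagged": bool(flagged[j])})
    table = pd.DataFrame(rows)

    def fam(row):
        g, kind, _, _ = parse_feature_name(row["feature"])
        return f"{row['group']}_G{g}_{kind}"

    table["fam"] = table.apply(fam, axis=1)
    table["q"] = np.nan
    for _, idx in table.groupby("fam").groups.items():
        ok = idx[~table.loc[idx, "p"].isna()]
        if len(ok):
            q, _ = fdr_bh(table.loc[ok, "p"].to_numpy(), q_level)
            table.loc[ok, "q"] = q
    return CohensDMap(table=table.drop(columns="fam"))


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------

def chi2_sex_by_group(table_2x2: np.ndarray) -> tuple[float, float]:
    """Yates-corrected chi-squared on a 2x2 sex-by-group contingency table."""
    chi2, p, _, _ = sps.chi2_contingency(np.asarray(table_2x2), correction=True)
    return float(chi2), float(p)


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample Student's t from printed summary statistics.

    Pooled-variance by default (Welch via ``equal_var=False``); this is the
    verification mode for reproducing published demographic comparisons.
    """
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                   equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def demographic_tests(phenotype: pd.DataFrame) -> pd.DataFrame:
    """Cohort demographic comparisons between SZ and HC.

    Sex: 2x2 chi-squared with Yates continuity correction.  Age and mean
    FD: pooled-variance two-sample Student's t (SZ first, so positive t
    means higher in SZ).
    """
    for col in ("group", "sex", "age", "mean_fd"):
        if col not in phenotype.columns:
            raise DataError(f"phenotype lacks column {col!r}")
    sz = phenotype[phenotype["group"] == "SZ"]
    hc = phenotype[phenotype["group"] == "HC"]
    if len(sz) == 0 or len(hc) == 0:
        raise DataError("both groups must be non-empty")
    table = np.array([
        [(sz["sex"] == "F").sum(), (sz["sex"] == "M").sum()],
        [(hc["sex"] == "F").sum(), (hc["sex"] == "M").sum()],
    ])
    chi2, p_sex = chi2_sex_by_group(table)
    rows = [{"variable": "sex", "test": "chi2_yates", "statistic": chi2, "p": p_sex}]
    for var in ("age", "mean_fd"):
        t, p = t_from_summary(sz[var].mean(), sz[var].std(ddof=1), len(sz),
                              hc[var].mean(), hc[var].std(ddof=1), len(hc))
        rows.append({"variable": var, "test": "student_t", "statistic": t, "p": p})
    return pd.DataFrame(rows)
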