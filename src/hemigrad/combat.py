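"""Parametric empirical-Bayes ComBat harmonization of multi-site features.

ComBat models each feature as a covariate-adjusted grand mean plus an
additive per-site location effect (gamma) and a multiplicative per-site
scale effect (delta), and shrinks the per-site estimates across features
with parametric empirical-Bayes priors (normal for location, inverse-gamma
for scale).  Harmonized data have the site effects removed while the
covariate structure (including, when present in the design, the group
effect of interest) is preserved.

Two usage protocols are distinguished by callers:

* ``pooled`` — fit on the whole cohort with group in the design (used
  before group statistics);
* ``split`` — fit separately within training and test sets during
  cross-validated prediction, group never in the test design.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

EB_TOL = 1e-4
EB_MAX_ITER = 200


@dataclass
class HarmonizationModel:
    """Fitted ComBat parameters.

    ``gamma_star`` / ``delta_star`` are the EB-shrunken standardized site
    location and scale estimates (one row per site, one column per feature);
    ``grand_mean`` and ``beta_cov`` reconstruct the covariate-predicted
    feature means, and ``var_pooled`` the pooled feature variances.
    """

    sites: list[str]
    grand_mean: np.ndarray            # (features,)
    beta_cov: np.ndarray              # (covariates, features)
    var_pooled: np.ndarray            # (features,)
    gamma_star: np.ndarray            # (sites, features)
    delta_star: np.ndarray            # (sites, features)
    n_per_site: np.ndarray
    identity: bool = False
    n_iterations: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "sites": self.sites,
            "grand_mean": self.grand_mean.tolist(),
            "beta_cov": self.beta_cov.tolist(),
            "var_pooled": self.var_pooled.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta_star": self.delta_star.tolist(),
            "n_per_site": self.n_per_site.tolist(),
            "identity": self.identity,
            "n_iterations": self.n_iterations,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "HarmonizationModel":
        d = json.loads(text)
        for k in ("grand_mean", "beta_cov", "var_pooled", "gamma_star",
                  "delta_star", "n_per_site"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


def _as_design(design) -> np.ndarray:
    if design is None:
        return np.empty((0, 0))
    if isinstance(design, pd.DataFrame):
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    return design


def fit_combat(
    features: np.ndarray | pd.DataFrame,
    site: np.ndarray | list,
    design: np.ndarray | pd.DataFrame | None = None,
    tol: float = EB_TOL,
    max_iter: int = EB_MAX_ITER,
) -> HarmonizationModel:
    """Fit the parametric EB ComBat model.

    ``features`` is subjects x features; ``design`` holds the covariates to
    preserve (numeric columns, NO intercept — the intercept is carried by
    the site indicators).  Requires >= 2 sites with >= 2 subjects each and a
    full-rank [site indicators | covariates] design.  With a single site a
    warning is emitted and an identity model returned.
    """
    Y = np.asarray(features, dtype=float)
    if Y.ndim != 2:
        raise DataError("features must be a 2-D subjects x features matrix")
    n, f = Y.shape
    site = np.asarray(site, dtype=object)
    if len(site) != n:
        raise DataError("site labels do not match feature rows")
    sd = Y.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DataError(f"zero-variance feature(s) at column(s) {dead.tolist()}")

    sites = sorted(set(site.tolist()))
    X_cov = _as_design(design)
    if X_cov.size and X_cov.shape[0] != n:
        raise DataError("design rows do not match feature rows")

    if len(sites) < 2:
        warnings.warn("single site: harmonization is the identity", stacklevel=2)
        p = X_cov.shape[1] if X_cov.size else 0
        return HarmonizationModel(
            sites=sites, grand_mean=np.zeros(f), beta_cov=np.zeros((p, f)),
            var_pooled=np.ones(f), gamma_star=np.zeros((1, f)),
            delta_star=np.ones((1, f)), n_per_site=np.array([n]), identity=True,
        )

    counts = np.array([(site == s).sum() for s in sites])
    if counts.min() < 2:
        small = [s for s, c in zip(sites, counts) if c < 2]
        raise DataError(f"site(s) {small} have fewer than 2 subjects")

    B = np.column_stack([(site == s).astype(float) for s in sites])
    X = np.column_stack([B, X_cov]) if X_cov.size else B
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DataError("design matrix [site | covariates] is rank deficient "
                        "(did you include an intercept or a site-confounded "
                        "covariate?)")

    n_site = len(sites)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    grand_mean = (counts / n) @ beta[:n_site]
    beta_cov = beta[n_site:]
    stand_mean = grand_mean[None, :] + (X_cov @ beta_cov if X_cov.size else 0.0)
    resid = Y - X @ beta
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled <= 0):
        bad = np.flatnonzero(var_pooled <= 0)
        raise DataError(f"degenerate feature(s) {bad.tolist()}: zero pooled variance")

    Z = (Y - stand_mean) / np.sqrt(var_pooled)

    gamma_star = np.empty((n_site, f))
    delta_star = np.empty((n_site, f))
    n_iterations = {}
    for i, s in enumerate(sites):
        idx = site == s
        zi = Z[idx]
        ni = counts[i]
        g_hat = zi.mean(axis=0)
        d_hat = zi.var(axis=0, ddof=1)
        g_bar = g_hat.mean()
        t2 = g_hat.var(ddof=1)
        m = d_hat.mean()
        s2 = d_hat.var(ddof=1)
        if f < 2 or s2 == 0 or t2 == 0:
            # too few features to estimate priors: no shrinkage
            gamma_star[i], delta_star[i] = g_hat, d_hat
            n_iterations[s] = 0
            continue
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        g_old, d_old = g_hat.copy(), d_hat.copy()
        change, it = np.inf, 0
        while change > tol and it < max_iter:
            g_new = (ni * t2 * g_hat + d_old * g_bar) / (ni * t2 + d_old)
            sum2 = ((zi - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + b_prior) / (ni / 2.0 + a_prior - 1.0)
            change = max(np.abs((g_new - g_old) / g_old).max(),
                         np.abs((d_new - d_old) / d_old).max())
            g_old, d_old = g_new, d_new
            it += 1
        gamma_star[i], delta_star[i] = g_old, d_old
        n_iterations[s] = it
    if np.any(delta_star <= 0):
        raise DataError("non-positive shrunken scale estimate; data degenerate")
    return HarmonizationModel(
        sites=sites, grand_mean=grand_mean, beta_cov=beta_cov,
        var_pooled=var_pooled, gamma_star=gamma_star, delta_star=delta_star,
        n_per_site=counts, n_iterations=n_iterations,
    )


def apply_combat(
    model: HarmonizationModel,
    features: np.ndarray | pd.DataFrame,
    site: np.ndarray | list,
    design: np.ndarray | pd.DataFrame | None = None,
) -> np.ndarray:
    """Harmonize features with a fitted model.

    Subtracts the (shrunken) site location, rescales by the site scale, and
    restores the covariate-predicted mean and pooled scale.  Sites unseen at
    fit time are an error — silent pass-through would leave them un-removed.
    """
    Y = np.asarray(features, dtype=float)
    site = np.asarray(site, dtype=object)
    if len(site) != Y.shape[0]:
        raise DataError("site labels do not match feature rows")
    if model.identity:
        return Y.copy()
    unseen = sorted(set(site.tolist()) - set(model.sites))
    if unseen:
        raise ParameterError(f"site(s) {unseen} were not present at fit time")
    X_cov = _as_design(design)
    if model.beta_cov.shape[0] and (not X_cov.size
                                    or X_cov.shape[1] != model.beta_cov.shape[0]):
        raise ParameterError("design covariates do not match the fitted model")
    stand_mean = model.grand_mean[None, :] + (
        X_cov @ model.beta_cov if model.beta_cov.shape[0] else 0.0
    )
    Z = (Y - stand_mean) / np.sqrt(model.var_pooled)
    site_idx = np.array([model.sites.index(s) for s in site])
    Z_adj = (Z - model.gamma_star[site_idx]) / np.sqrt(model.delta_star[site_idx])
    return Z_adj * np.sqrt(model.var_pooled) + stand_mean


def harmonize(
    features: np.ndarray | pd.DataFrame,
    site,
    design=None,
    **fit_kwargs,
) -> tuple[np.ndarray, HarmonizationModel]:
    """Fit-and-apply convenience wrapper (the pooled protocol)."""
    model = fit_combat(features, site, design, **fit_kwargs)
    return apply_combat(model, features, site, design), model


def make_design(
    phenotype: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "mean_fd"),
    include_group: bool = False,
) -> np.ndarray:
    """Numeric covariate design (no intercept) from a phenotype table.

    ``sex`` is coded M=1/F=0 and ``group`` SZ=1/HC=0.
    """
    cols = []
    for c in covariates:
        v = phenotype[c]
        if c == "sex":
            cols.append((v == "M").astype(float).to_numpy())
        else:
            cols.append(v.astype(float).to_numpy())
    if include_group:
        cols.insert(0, (phenotype["group"] == "SZ").astype(float).to_numpy())
    return np.column_stack(cols) if cols else None
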