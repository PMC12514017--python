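"""Empirical-Bayes location/scale harmonization of multi-site thickness.

Region-wise cortical thickness acquired on different scanners carries
additive and multiplicative site effects. The model standardizes each
region with a covariate fit (site indicators plus protected covariates:
group, age, sex), estimates per-site location (gamma) and scale (delta^2)
effects on the standardized residuals, shrinks them across regions with
parametric empirical Bayes (normal prior on gamma, inverse-gamma on
delta^2, moment-matched hyperpriors, fixed-point iteration), and removes
the shrunken effects while restoring the covariate signal.

Fitting and application are split so a model fitted on one cohort can be
audited (JSON dump) and applied to held-out data from the same sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: convergence tolerance and iteration cap of the EB fixed point
EB_TOL = 1e-6
EB_MAX_ITER = 500


@dataclass
class CombatModel:
    """Fitted harmonization model (all arrays are region-aligned)."""

    regions: np.ndarray            # region ids, in column order
    sites: list[str]               # site labels, in design order
    covariates: list[str]          # protected covariate names
    grand_mean: np.ndarray         # alpha_g, per region (mm)
    covariate_coefs: np.ndarray    # (n_cov, n_regions), design-aligned
    pooled_sd: np.ndarray          # sigma_g, per region (mm)
    gamma_star: np.ndarray         # (n_sites, n_regions), standardized units
    delta2_star: np.ndarray        # (n_sites, n_regions), variance ratios
    site_counts: np.ndarray        # subjects per site

    def to_json(self, path) -> None:
        payload = {
            "sites": self.sites,
            "covariates": self.covariates,
            "regions": self.regions.tolist(),
            "grand_mean": self.grand_mean.tolist(),
            "covariate_coefs": self.covariate_coefs.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "site_counts": self.site_counts.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CombatModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(regions=np.asarray(d["regions"]), sites=d["sites"],
                   covariates=d["covariates"],
                   grand_mean=np.asarray(d["grand_mean"]),
                   covariate_coefs=np.asarray(d["covariate_coefs"]),
                   pooled_sd=np.asarray(d["pooled_sd"]),
                   gamma_star=np.asarray(d["gamma_star"]),
                   delta2_star=np.asarray(d["delta2_star"]),
                   site_counts=np.asarray(d["site_counts"]))


def _covariate_design(participants: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Numeric design columns for the protected covariates (no intercept).

    'group' maps patient=1/control=0 and 'sex' maps F=1/M=0; other columns
    are taken as numeric.
    """
    cols = []
    for name in covariates:
        if name not in participants.columns:
            raise ValueError(f"covariate {name!r} missing from participant table")
        col = participants[name]
        if name == "group":
            cols.append((col == "patient").to_numpy(float))
        elif name == "sex":
            cols.append((col == "F").to_numpy(float))
        else:
            cols.append(col.to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(participants), 0))


def _aprior(delta2_hat: np.ndarray) -> float:
    m, v = delta2_hat.mean(), delta2_hat.var(ddof=1)
    return (2 * v + m ** 2) / v


def _bprior(delta2_hat: np.ndarray) -> float:
    m, v = delta2_hat.mean(), delta2_hat.var(ddof=1)
    return (m * v + m ** 3) / v


def combat_fit(thickness: pd.DataFrame, participants: pd.DataFrame,
               covariates: list[str] = ("group", "age", "sex")) -> CombatModel:
    """Fit the harmonization model on participants x regions thickness.

    Requires >= 2 participants per site and a full-rank design (site
    indicators plus covariates). Regions with zero residual variance raise.
    """
    covariates = list(covariates)
    participants = participants.loc[thickness.index]
    y = thickness.to_numpy(dtype=float)
    n, n_regions = y.shape

    sites = sorted(participants["site"].unique())
    site_idx = participants["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    counts = np.bincount(site_idx, minlength=len(sites))
    for s, c in zip(sites, counts):
        if c < 2:
            raise ValueError(f"site {s!r} has fewer than 2 participants")

    batch = np.zeros((n, len(sites)))
    batch[np.arange(n), site_idx] = 1.0
    cov = _covariate_design(participants, covariates)
    design = np.hstack([batch, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear site/covariates)")

    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    site_means = beta[: len(sites)]                  # per-site intercepts
    cov_coefs = beta[len(sites):]
    grand_mean = (counts / n) @ site_means           # weighted grand mean per region
    resid = y - design @ beta
    pooled_var = (resid ** 2).mean(axis=0)           # divisor n
    if (pooled_var <= 0).any():
        bad = thickness.columns[pooled_var <= 0][0]
        raise ValueError(f"region {bad!r} has zero residual variance")
    pooled_sd = np.sqrt(pooled_var)

    fitted_cov = cov @ cov_coefs if cov.size else 0.0
    z = (y - grand_mean - fitted_cov) / pooled_sd

    gamma_hat = np.vstack([z[site_idx == i].mean(axis=0) for i in range(len(sites))])
    delta2_hat = np.vstack([z[site_idx == i].var(axis=0) for i in range(len(sites))])

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i in range(len(sites)):
        g_hat, d2_hat = gamma_hat[i], delta2_hat[i]
        if g_hat.std() < 1e-12 and d2_hat.std() < 1e-12:
            # no spread across regions (e.g. single site): nothing to shrink
            gamma_star[i], delta2_star[i] = g_hat, d2_hat
            continue
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, b = _aprior(d2_hat), _bprior(d2_hat)
        ni = counts[i]
        zi = z[site_idx == i]
        g_new, d2_new = g_hat.copy(), d2_hat.copy()
        for _ in range(EB_MAX_ITER):
            g_old, d2_old = g_new, d2_new
            g_new = (ni * t2 * g_hat + d2_old * g_bar) / (ni * t2 + d2_old)
            sse = ((zi - g_new) ** 2).sum(axis=0)
            d2_new = (b + 0.5 * sse) / (ni / 2.0 + a - 1.0)
            change = max(np.abs(g_new - g_old).max() / (np.abs(g_old).max() + 1e-12),
                         np.abs(d2_new - d2_old).max() / d2_old.max())
            if change < EB_TOL:
                break
        gamma_star[i], delta2_star[i] = g_new, d2_new
    if (delta2_star <= 0).any():
        raise ValueError("non-positive shrunken variance ratio")

    return CombatModel(regions=thickness.columns.to_numpy(), sites=sites,
                       covariates=covariates, grand_mean=grand_mean,
                       covariate_coefs=cov_coefs, pooled_sd=pooled_sd,
                       gamma_star=gamma_star, delta2_star=delta2_star,
                       site_counts=counts)


def combat_apply(model: CombatModel, thickness: pd.DataFrame,
                 participants: pd.DataFrame) -> pd.DataFrame:
    """Remove the fitted site effects from (possibly new) data.

    Standardizes with the stored covariate fit, subtracts gamma*, divides by
    sqrt(delta2*), and back-transforms. Sites absent from the model raise.
    """
    participants = participants.loc[thickness.index]
    unknown = set(participants["site"]) - set(model.sites)
    if unknown:
        raise ValueError(f"unknown site label(s): {sorted(unknown)}")
    if not np.array_equal(thickness.columns.to_numpy(), model.regions):
        raise ValueError("region columns do not match the fitted model")
    y = thickness.to_numpy(dtype=float)
    site_idx = participants["site"].map({s: i for i, s in enumerate(model.sites)}).to_numpy()
    cov = _covariate_design(participants, model.covariates)
    fitted_cov = cov @ model.covariate_coefs if cov.size else 0.0
    z = (y - model.grand_mean - fitted_cov) / model.pooled_sd
    z_adj = (z - model.gamma_star[site_idx]) / np.sqrt(model.delta2_star[site_idx])
    y_adj = z_adj * model.pooled_sd + model.grand_mean + fitted_cov
    return pd.DataFrame(y_adj, index=thickness.index, columns=thickness.columns)


def harmonize(thickness: pd.DataFrame, participants: pd.DataFrame,
              covariates: list[str] = ("group", "age", "sex"),
              ) -> tuple[pd.DataFrame, CombatModel]:
    """Convenience: fit on the data and return (adjusted thickness, model)."""
    model = combat_fit(thickness, participants, covariates)
    return combat_apply(model, thickness, participants), model
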