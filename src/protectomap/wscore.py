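"""Control-referenced normative modeling (W-scores) and regional tests.

A per-region linear model (thickness ~ 1 + age + sex) is fitted on healthy
controls. For each patient, the W-score of a region is the observed minus
the model-predicted thickness, divided by the control residual SD: a
unitless deviation from age- and sex-matched controls, with negative values
indicating thinning. Per region, sex-interaction estimates regress patient
W-scores on a female indicator (beta > 0 means females are less atrophied
than males), and one-sample t-tests against zero quantify atrophy within a
sex stratum, with Benjamini-Hochberg FDR across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biostats import bh_fdr

#: sex coding used throughout: female = 1, male = 0, so a positive sex
#: coefficient / interaction estimate means "greater value in females"
SEX_CODING = {"F": 1.0, "M": 0.0}


@dataclass
class NormativeModel:
    """Per-region control regression: thickness ~ 1 + age + sex(F=1)."""

    regions: np.ndarray
    intercept: np.ndarray      # mm
    age_coef: np.ndarray       # mm / year
    sex_coef: np.ndarray       # mm (female - male)
    residual_sd: np.ndarray    # mm, denominator n - 3
    n_controls: int

    def predict(self, age: np.ndarray, sex_female: np.ndarray) -> np.ndarray:
        """Expected thickness for given ages and female indicators."""
        age = np.asarray(age, dtype=float)[:, None]
        sex = np.asarray(sex_female, dtype=float)[:, None]
        return self.intercept + age * self.age_coef + sex * self.sex_coef


def _design(covars: pd.DataFrame) -> np.ndarray:
    for col in ("age", "sex"):
        if col not in covars.columns:
            raise ValueError(f"covariate {col!r} missing")
    if covars[["age", "sex"]].isna().any().any():
        bad = covars.index[covars[["age", "sex"]].isna().any(axis=1)][0]
        raise ValueError(f"participant {bad!r} has a missing covariate")
    sex = covars["sex"].map(SEX_CODING)
    if sex.isna().any():
        bad = covars.index[sex.isna()][0]
        raise ValueError(f"participant {bad!r} has unrecognized sex label")
    return np.column_stack([np.ones(len(covars)),
                            covars["age"].to_numpy(float),
                            sex.to_numpy(float)])


def fit_normative(controls_thickness: pd.DataFrame,
                  controls_covars: pd.DataFrame) -> NormativeModel:
    """Fit the per-region control model. Requires >= 10 controls."""
    n = len(controls_thickness)
    if n < 10:
        raise ValueError(f"need >= 10 controls, got {n}")
    covars = controls_covars.loc[controls_thickness.index]
    x = _design(covars)
    y = controls_thickness.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - 3
    if dof <= 0:
        raise ValueError("too few controls for a 3-parameter model")
    rss = (resid ** 2).sum(axis=0)
    degenerate = rss <= n * 1e-18  # numerically zero residual variance
    if degenerate.any():
        bad = controls_thickness.columns[degenerate][0]
        raise ValueError(f"region {bad!r} has zero residual variance in controls")
    return NormativeModel(regions=controls_thickness.columns.to_numpy(),
                          intercept=beta[0], age_coef=beta[1], sex_coef=beta[2],
                          residual_sd=np.sqrt(rss / dof), n_controls=n)


def compute_wscores(patients_thickness: pd.DataFrame,
                    patients_covars: pd.DataFrame,
                    model: NormativeModel) -> pd.DataFrame:
    """W(i, r) = (observed - predicted(age_i, sex_i)) / residual_sd(r)."""
    if not np.array_equal(patients_thickness.columns.to_numpy(), model.regions):
        raise ValueError("region columns do not match the normative model")
    covars = patients_covars.loc[patients_thickness.index]
    x = _design(covars)  # validates covariates, names offenders
    pred = model.predict(x[:, 1], x[:, 2])
    w = (patients_thickness.to_numpy(dtype=float) - pred) / model.residual_sd
    if not np.isfinite(w).all():
        raise ValueError("non-finite W-scores")
    return pd.DataFrame(w, index=patients_thickness.index,
                        columns=patients_thickness.columns)


def sex_interaction_estimates(wscores: pd.DataFrame,
                              patient_sex: pd.Series) -> pd.DataFrame:
    """Per-region regression of W-scores on a female indicator.

    The estimate equals mean(W | female) - mean(W | male) exactly; t and p
    come from the homoskedastic OLS slope test (identical to a pooled
    two-sample t). Returns one row per region: beta, t, p, q (BH across
    regions), n_f, n_m.
    """
    sex = patient_sex.loc[wscores.index].map(SEX_CODING)
    if sex.isna().any():
        raise ValueError("unrecognized sex label among patients")
    f = sex.to_numpy(float)
    n_f, n_m = int(f.sum()), int((1 - f).sum())
    if n_f == 0 or n_m == 0:
        raise ValueError("both sexes must be present among patients")
    w = wscores.to_numpy(dtype=float)
    mean_f = w[f == 1].mean(axis=0)
    mean_m = w[f == 0].mean(axis=0)
    beta = mean_f - mean_m
    dof = n_f + n_m - 2
    ss_f = ((w[f == 1] - mean_f) ** 2).sum(axis=0)
    ss_m = ((w[f == 0] - mean_m) ** 2).sum(axis=0)
    pooled_var = (ss_f + ss_m) / dof
    se = np.sqrt(pooled_var * (1.0 / n_f + 1.0 / n_m))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"beta": beta, "t": t, "p": p, "q": bh_fdr(p),
                         "n_f": n_f, "n_m": n_m},
                        index=pd.Index(wscores.columns, name="region_id"))


def regional_atrophy_test(wscores: pd.DataFrame,
                          patient_sex: pd.Series | None = None,
                          subset: str = "all") -> pd.DataFrame:
    """Per-region one-sample t of W-scores against 0, with BH-FDR.

    ``subset`` selects 'F', 'M', or 'all' patients (sex labels required for
    a sex stratum). The result carries per-region t, p, q plus attrs with
    counts of significant regions at p < 0.05 and q < 0.05.
    """
    if subset not in ("all", "F", "M"):
        raise ValueError("subset must be 'all', 'F' or 'M'")
    w = wscores
    if subset != "all":
        if patient_sex is None:
            raise ValueError("patient_sex required for a sex-stratified test")
        w = wscores.loc[patient_sex.loc[wscores.index] == subset]
    if len(w) < 3:
        raise ValueError(f"subset {subset!r} has fewer than 3 patients")
    arr = w.to_numpy(dtype=float)
    res = stats.ttest_1samp(arr, 0.0, axis=0)
    t = np.asarray(res.statistic)
    p = np.asarray(res.pvalue)
    # a region with all-zero W-scores has zero variance: t = 0, p = 1
    degenerate = ~np.isfinite(t)
    t[degenerate] = 0.0
    p[degenerate] = 1.0
    q = bh_fdr(p)
    out = pd.DataFrame({"t": t, "p": p, "q": q},
                       index=pd.Index(w.columns, name="region_id"))
    out.attrs["subset"] = subset
    out.attrs["n_patients"] = len(w)
    out.attrs["n_sig_p"] = int((p < 0.05).sum())
    out.attrs["n_sig_q"] = int((q < 0.05).sum())
    out.attrs["prop_sig_p"] = float((p < 0.05).mean())
    out.attrs["prop_sig_q"] = float((q < 0.05).mean())
    return out
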