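"""Standardized multivariable linear models over facility profiles.

One ordinary-least-squares model is fit per outcome (ACS/34w rate, term/ACS
proportion, optimal-ACS/34w rate, ACS rate among all deliveries) on the full
set of facility-level factors; the ACS/34w rate additionally enters the other
three models as a covariate. Continuous covariates are standardized (sample
SD) so coefficient magnitudes are comparable — a coefficient is "percentage
points of outcome per 1 SD of the factor" — while binary covariates stay 0/1.
95% confidence intervals are t-based with n − p degrees of freedom; a
covariate is flagged significant when its CI excludes zero. Variance inflation
factors diagnose collinearity (all should stay below 3).

statsmodels provides the OLS and VIF machinery; this module owns the design
construction, standardization bookkeeping, and de-standardization back to
natural units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

OUTCOMES = ["acs34_rate", "term_acs_prop", "optimal34_rate", "acs_all_rate"]

BASE_COVARIATES = [
    "is_comprehensive", "in_designated_city",
    "n_total", "n_lt34",
    "tpl", "hdp", "pprom", "previa", "multiple", "fgr", "abruption",
    "transfer", "cesarean",
]
BINARY_COVARIATES = {"is_comprehensive", "in_designated_city"}


@dataclass
class ModelSpec:
    """Which outcome to model, over which covariates."""

    outcome: str
    covariates: list[str] = field(default_factory=list)
    standardize_continuous: bool = True
    sensitivity: bool = False

    def __post_init__(self):
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.covariates:
            self.covariates = list(BASE_COVARIATES)
            if self.outcome != "acs34_rate":
                self.covariates.append("acs34_rate")
        if self.outcome in self.covariates:
            raise ValueError(f"{self.outcome!r} cannot be both outcome and covariate")


class CollinearityError(ValueError):
    """The design matrix is rank-deficient."""


def standardize_design(
    profiles: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.Series, pd.DataFrame, pd.Series, pd.Series]:
    """Build (y, X, means, sds) for a model spec.

    Continuous covariates become mean-0 / sample-SD-1 columns; binary
    covariates are left as 0/1; a constant column ``const`` is appended.
    Rows with a missing outcome or covariate are dropped. A continuous
    covariate with zero SD raises, naming the column.
    """
    cols = [spec.outcome] + spec.covariates
    data = profiles[cols].dropna()
    if len(data) < len(spec.covariates) + 2:
        raise ValueError(
            f"need at least {len(spec.covariates) + 2} complete profiles, "
            f"got {len(data)}"
        )
    y = data[spec.outcome].astype(float)
    X = data[spec.covariates].astype(float).copy()
    means = pd.Series(0.0, index=spec.covariates)
    sds = pd.Series(1.0, index=spec.covariates)
    for c in spec.covariates:
        if c in BINARY_COVARIATES:
            continue
        mu, sd = X[c].mean(), X[c].std(ddof=1)
        if not np.isfinite(sd) or sd <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"covariate {c!r} has zero variance; cannot standardize")
        means[c], sds[c] = mu, sd
        if spec.standardize_continuous:
            X[c] = (X[c] - mu) / sd
    X["const"] = 1.0
    return y, X, means, sds


@dataclass
class ModelFit:
    """Coefficients, CIs, VIFs and standardization constants for one outcome."""

    outcome: str
    table: pd.DataFrame     # index: covariate; coef, ci_low, ci_high, vif, significant
    n: int
    df_resid: int
    resid_sd: float
    means: pd.Series
    sds: pd.Series
    r_squared: float


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate (the constant is not reported).

    VIF_j = 1 / (1 − R²_j) where R²_j regresses column j on the others (with
    intercept). Perfect collinearity yields an infinite VIF.
    """
    if "const" not in X.columns:
        X = X.copy()
        X["const"] = 1.0
    cov_cols = [c for c in X.columns if c != "const"]
    arr = X[cov_cols + ["const"]].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        vals = [variance_inflation_factor(arr, j) for j in range(len(cov_cols))]
    return pd.Series(vals, index=cov_cols)


def fit_linear_model(y: pd.Series, X: pd.DataFrame) -> ModelFit:
    """OLS with t-based 95% CIs (n − p df) and per-covariate VIFs.

    ``X`` must carry a ``const`` column (as produced by
    :func:`standardize_design`). A rank-deficient design raises
    :class:`CollinearityError` listing the columns involved.
    """
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        vifs = compute_vif(X)
        bad = list(vifs.index[~np.isfinite(vifs) | (vifs > 1e10)])
        raise CollinearityError(f"design is rank-deficient; collinear columns: {bad}")
    res = sm.OLS(y.to_numpy(dtype=float), arr).fit()
    ci = res.conf_int(alpha=0.05)
    cov_cols = [c for c in X.columns if c != "const"]
    idx = [list(X.columns).index(c) for c in cov_cols]
    table = pd.DataFrame(
        {
            "coef": res.params[idx],
            "ci_low": ci[idx, 0],
            "ci_high": ci[idx, 1],
        },
        index=pd.Index(cov_cols, name="covariate"),
    )
    table["vif"] = compute_vif(X)
    table["significant"] = (table["ci_low"] > 0) | (table["ci_high"] < 0)
    return ModelFit(
        outcome="",
        table=table,
        n=int(res.nobs),
        df_resid=int(res.df_resid),
        resid_sd=float(np.sqrt(res.mse_resid)),
        means=pd.Series(dtype=float),
        sds=pd.Series(dtype=float),
        r_squared=float(res.rsquared),
    )


def destandardize(fit: ModelFit, sds: pd.Series) -> pd.DataFrame:
    """Convert per-SD coefficients to per-natural-unit coefficients.

    ``slope_per_unit = slope_per_SD / SD`` for continuous covariates; binary
    covariates (SD recorded as 1) are unchanged. CIs scale the same way.
    """
    raw = fit.table[["coef", "ci_low", "ci_high"]].copy()
    scale = sds.reindex(raw.index).fillna(1.0)
    for c in raw.columns:
        raw[c] = raw[c] / scale
    raw.columns = ["raw_coef", "raw_ci_low", "raw_ci_high"]
    return raw


def fit_outcome_model(profiles: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """standardize → fit → destandardize, returning a complete ModelFit."""
    y, X, means, sds = standardize_design(profiles, spec)
    fit = fit_linear_model(y, X)
    fit.outcome = spec.outcome
    fit.means, fit.sds = means, sds
    if spec.standardize_continuous:
        fit.table = fit.table.join(destandardize(fit, sds))
    else:
        raw = fit.table[["coef", "ci_low", "ci_high"]].copy()
        raw.columns = ["raw_coef", "raw_ci_low", "raw_ci_high"]
        fit.table = fit.table.join(raw)
    return fit


def run_analysis_suite(
    profiles: pd.DataFrame,
    sensitivity: bool = False,
    records: pd.DataFrame | None = None,
    attributes: pd.DataFrame | None = None,
    pipeline_kwargs: dict | None = None,
    covariates: list[str] | None = None,
) -> dict[str, ModelFit]:
    """Fit all four outcome models on one cohort of profiles.

    For the sensitivity variant, patient-level ``records`` (already past the
    exclusion cascade) and ``attributes`` must be supplied: abruption and
    Grade-1-cesarean pregnancies are dropped and the *entire* metrics pipeline
    is rebuilt before refitting — the sensitivity analysis recomputes the
    metrics, it does not re-filter fitted values.
    """
    if sensitivity:
        if records is None or attributes is None:
            raise ValueError("sensitivity run needs patient-level records and attributes")
        from .pipeline import profiles_from_records
        from .registry import sensitivity_subset

        profiles, _ = profiles_from_records(
            sensitivity_subset(records), attributes, **(pipeline_kwargs or {})
        )
    # a covariate can become structurally constant (e.g. abruption prevalence
    # is zero everywhere after the sensitivity subset removes those records);
    # such columns cannot be standardized and are dropped from every model.
    candidates = list(covariates) if covariates is not None else list(BASE_COVARIATES)
    kept = []
    for c in candidates:
        if c in BINARY_COVARIATES:
            kept.append(c)
            continue
        sd = profiles[c].std(ddof=1)
        if np.isfinite(sd) and sd > 1e-12 * max(1.0, abs(profiles[c].mean())):
            kept.append(c)
    covariates = kept

    fits = {}
    for outcome in OUTCOMES:
        covs = [c for c in covariates if c != outcome]
        if outcome != "acs34_rate" and "acs34_rate" not in covs:
            covs.append("acs34_rate")
        spec = ModelSpec(outcome=outcome, covariates=covs, sensitivity=sensitivity)
        fits[outcome] = fit_outcome_model(profiles, spec)
    return fits


def suite_table(fits: dict[str, ModelFit]) -> pd.DataFrame:
    """Tidy long-format table across outcomes (forest-plot input)."""
    parts = []
    for outcome, fit in fits.items():
        t = fit.table.reset_index()
        t.insert(0, "outcome", outcome)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def forest_plot(fit: ModelFit, path=None):
    """Forest plot of standardized coefficients with 95% CIs for one outcome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = fit.table.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(t) + 1.2))
    ypos = np.arange(len(t))
    ax.errorbar(
        t["coef"], ypos,
        xerr=[t["coef"] - t["ci_low"], t["ci_high"] - t["coef"]],
        fmt="o", color="black", capsize=3, lw=1,
    )
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(t.index)
    ax.set_xlabel("coefficient (pp of outcome per 1 SD / level switch)")
    ax.set_title(fit.outcome)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
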