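"""Mode-function correlation, logistic risk models and ROC comparison.

The shape-based risk model regresses the binary adverse-event label
(aortic-valve repair/replacement) on the subject mode scores retained up to a
cumulative variance fraction (default 90%), combining the end-diastolic and
end-systolic models into one predictor vector.  It is compared against a
demographic baseline (age, sex, stroke volume) by the area under the ROC
curve.  AUC is reported both in-sample and by leave-one-out refitting; the
in-sample value mirrors the common single-cohort presentation, the
leave-one-out value guards against its optimism.

Logistic regression is fitted by iteratively reweighted least squares (IRLS,
i.e. Newton-Raphson on the log-likelihood).  Perfect separation, which drives
coefficients to infinity, is detected and the model refit with a small ridge
penalty, flagged as "penalized".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .shape_model import ShapeModel, n_modes_for_variance

_WALD_Z = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with two-sided t-test p-value.

    p is computed from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("at least 3 observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


@dataclass
class LogisticModel:
    """Maximum-likelihood (or ridge-penalised) logistic regression fit."""

    predictor_names: list[str]
    coefficients: np.ndarray          # intercept first
    standard_errors: np.ndarray
    wald_p_values: np.ndarray
    standardized_coefficients: np.ndarray  # beta_j * SD(x_j); 0 for intercept
    odds_ratios: np.ndarray           # exp(beta)
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    converged: bool
    status: str = "converged"         # converged / max_iter / penalized
    log_likelihood: float = np.nan
    n: int = 0

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        eta = np.clip(self.coefficients[0] + X @ self.coefficients[1:],
                      -500, 500)
        return 1.0 / (1.0 + np.exp(-eta))

    def table(self) -> pd.DataFrame:
        """Coefficient listing (Parameter, Coefficient, SE, SC, OR, OR CI)."""
        return pd.DataFrame({
            "parameter": ["constant"] + self.predictor_names,
            "coefficient": self.coefficients,
            "standard_error": self.standard_errors,
            "p_value": self.wald_p_values,
            "sc": self.standardized_coefficients,
            "or": self.odds_ratios,
            "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        })


def _irls(X: np.ndarray, y: np.ndarray, ridge: float,
          tol: float = 1e-8, max_iter: int = 100):
    """Newton-Raphson/IRLS for the logistic log-likelihood.

    Returns (beta, cov, log_likelihood, converged, separated).  The ridge
    penalty (not applied to the intercept) stabilises separated data.
    """
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, ridge)
    pen[0] = 0.0
    ll_old = -np.inf
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -500, 500)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - pen * beta
        hess = (X * w[:, None]).T @ X + np.diag(pen)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 50.0 or not np.all(np.isfinite(beta)):
            separated = True
            break
        mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -500, 500)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu)
                   - 0.5 * (pen * beta ** 2).sum())
        if abs(ll - ll_old) < tol and np.linalg.norm(grad) < 1e-6:
            converged = True
            ll_old = ll
            break
        ll_old = ll
    eta = np.clip(X @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X * w[:, None]).T @ X + np.diag(pen)
    cov = np.linalg.pinv(info)
    return beta, cov, ll_old, converged, separated


def fit_logistic(design_matrix, labels,
                 predictor_names: list[str] | None = None) -> LogisticModel:
    """Fit a logistic regression by IRLS with Wald inference.

    ``design_matrix`` holds the predictors only; the intercept is added
    internally.  Standardised coefficients are beta_j x SD(x_j); odds ratios
    are exp(beta_j) with 95% Wald confidence intervals.  Perfect separation
    (diverging |beta|) triggers a refit with ridge penalty 1e-4 and status
    "penalized".
    """
    X = np.asarray(design_matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, float).ravel()
    n, p = X.shape
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("labels must be binary with both classes present")
    if n <= p + 1:
        raise ValueError(f"n = {n} observations cannot support {p} predictors")
    if predictor_names is None:
        predictor_names = [f"x{j + 1}" for j in range(p)]
    if len(predictor_names) != p:
        raise ValueError("predictor_names length must match predictor count")

    Xd = np.column_stack([np.ones(n), X])
    beta, cov, ll, converged, separated = _irls(Xd, y, ridge=0.0)
    status = "converged" if converged else "max_iter"
    if separated:
        beta, cov, ll, converged, _ = _irls(Xd, y, ridge=1e-4)
        status = "penalized"

    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    sd_x = X.std(axis=0, ddof=1)
    sc = np.concatenate([[0.0], beta[1:] * sd_x])
    with np.errstate(over="ignore"):  # inf CI bound on near-separated data
        ors = np.exp(beta)
        ci_lo = np.exp(beta - _WALD_Z * se)
        ci_hi = np.exp(beta + _WALD_Z * se)
    return LogisticModel(
        predictor_names=list(predictor_names),
        coefficients=beta, standard_errors=se, wald_p_values=pvals,
        standardized_coefficients=sc, odds_ratios=ors,
        or_ci_low=ci_lo, or_ci_high=ci_hi,
        converged=converged, status=status, log_likelihood=ll, n=n,
    )


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray          # true-positive rate
    one_minus_specificity: np.ndarray  # false-positive rate
    auc: float


def roc_auc(scores, labels) -> ROCCurve:
    """Empirical ROC curve over all score thresholds, AUC by trapezoid rule.

    Tied scores are grouped, so the AUC equals the Mann-Whitney statistic
    P(score_1 > score_0) + 0.5 P(equal).
    """
    scores = np.asarray(scores, float).ravel()
    y = np.asarray(labels, float).ravel()
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, sensitivity=tpr,
                    one_minus_specificity=fpr, auc=auc)


def roc_to_frame(curve: ROCCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "threshold": curve.thresholds,
        "sensitivity": curve.sensitivity,
        "one_minus_specificity": curve.one_minus_specificity,
    })


def correlation_scan(scores: pd.DataFrame, cohort: pd.DataFrame,
                     variables: list[str], phase: str = "ED",
                     ) -> pd.DataFrame:
    """Pearson scan of every mode-score column against every functional
    variable, with a Benjamini-Hochberg adjusted-p column alongside raw p.

    Constant columns are skipped (their correlation is undefined).
    """
    merged = scores.merge(cohort, on="subject_id", how="inner")
    mode_cols = [c for c in scores.columns if c.startswith("mode")]
    rows = []
    for var in variables:
        if var not in merged.columns or np.ptp(merged[var].to_numpy(float)) == 0:
            continue
        for mc in mode_cols:
            res = pearson(merged[mc].to_numpy(float),
                          merged[var].to_numpy(float))
            rows.append({"phase": phase, "mode": int(mc[4:]), "variable": var,
                         "r": res.r, "p": res.p_value, "n": res.n})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def loo_auc(X: np.ndarray, y: np.ndarray,
            names: list[str] | None = None) -> float:
    """Leave-one-out AUC: each subject scored by a model fit without it."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = len(y)
    out = np.empty(n)
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            out[i] = 0.5
            continue
        model = fit_logistic(X[mask], y[mask], names)
        out[i] = model.predict_proba(X[i:i + 1])[0]
    return roc_auc(out, y).auc


@dataclass
class ModelComparison:
    shape_model: LogisticModel
    baseline_model: LogisticModel
    shape_roc: ROCCurve
    baseline_roc: ROCCurve
    shape_loo_auc: float
    baseline_loo_auc: float
    retained_modes: dict = field(default_factory=dict)
    excluded_covariates: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "auc_shape_in_sample": self.shape_roc.auc,
            "auc_baseline_in_sample": self.baseline_roc.auc,
            "auc_shape_loo": self.shape_loo_auc,
            "auc_baseline_loo": self.baseline_loo_auc,
            "retained_modes": self.retained_modes,
        }


def compare_prediction_models(cohort: pd.DataFrame,
                              ed_scores: pd.DataFrame,
                              es_scores: pd.DataFrame,
                              ed_model: ShapeModel, es_model: ShapeModel,
                              retained_fraction: float = 0.90,
                              compute_loo: bool = True) -> ModelComparison:
    """Shape-mode risk model vs demographic baseline.

    Model A regresses the event label on the concatenated ED+ES mode scores
    truncated at ``retained_fraction`` of each phase's variance; model B uses
    age, sex (F=0/M=1) and stroke volume.  Both are evaluated by in-sample
    ROC/AUC and, optionally, leave-one-out AUC.
    """
    if not 0 < retained_fraction <= 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    k_ed = n_modes_for_variance(ed_model, retained_fraction)
    k_es = n_modes_for_variance(es_model, retained_fraction)

    ed = ed_scores[["subject_id"] + [f"mode{k + 1}" for k in range(k_ed)]]
    ed = ed.rename(columns=lambda c: f"ed_{c}" if c != "subject_id" else c)
    es = es_scores[["subject_id"] + [f"mode{k + 1}" for k in range(k_es)]]
    es = es.rename(columns=lambda c: f"es_{c}" if c != "subject_id" else c)
    merged = cohort.merge(ed, on="subject_id").merge(es, on="subject_id")
    if len(merged) == 0:
        raise ValueError("no subjects shared between cohort and score tables")
    y = merged["event"].to_numpy(float)

    shape_cols = [c for c in merged.columns
                  if c.startswith("ed_mode") or c.startswith("es_mode")]
    X_shape = merged[shape_cols].to_numpy(float)

    excluded = []
    if "sv" not in merged.columns:
        merged = merged.assign(sv=merged["edv"] - merged["esv"])
    baseline_cols = []
    for col in ("age", "sex", "sv"):
        if col not in merged.columns or merged[col].isna().any():
            excluded.append(col)
        else:
            baseline_cols.append(col)
    if excluded:
        import warnings

        warnings.warn(f"baseline covariates excluded (missing): {excluded}",
                      stacklevel=2)
    base = merged[baseline_cols].copy()
    if "sex" in base.columns:
        base["sex"] = (base["sex"] == "M").astype(float)
    X_base = base.to_numpy(float)

    m_shape = fit_logistic(X_shape, y, shape_cols)
    m_base = fit_logistic(X_base, y, baseline_cols)
    roc_shape = roc_auc(m_shape.predict_proba(X_shape), y)
    roc_base = roc_auc(m_base.predict_proba(X_base), y)
    loo_shape = loo_auc(X_shape, y, shape_cols) if compute_loo else np.nan
    loo_base = loo_auc(X_base, y, baseline_cols) if compute_loo else np.nan
    return ModelComparison(
        shape_model=m_shape, baseline_model=m_base,
        shape_roc=roc_shape, baseline_roc=roc_base,
        shape_loo_auc=loo_shape, baseline_loo_auc=loo_base,
        retained_modes={"ED": k_ed, "ES": k_es},
        excluded_covariates=excluded,
    )
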