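"""Covariate-adjusted logistic genetic association.

The outcome model is an additive-model logistic regression of PONV
occurrence (or recurrence) on eight dichotomized clinical covariates plus
one genetic term (minor-allele dosage, a dominant/recessive recoding, or a
continuous enzyme-activity score):

    logit P(y=1) = b0 + b1*Gender + b2*Age + b3*PONVhistory + b4*Smoking
                 + b5*Cannabis + b6*Volatile + b7*HighOpioid + b8*Surgery
                 + b9*GeneticTerm

Fitting is maximum likelihood by iteratively reweighted least squares
(Newton scoring with step-halving, so the log-likelihood never decreases),
with Wald standard errors from the observed-information inverse and 95%
confidence intervals exp(beta +- 1.959964*SE).  Missing covariates or
genotypes are handled by listwise deletion.

Also here: the dichotomization rules for the raw clinical table, Bonferroni
correction, variance-inflation factors, and a marker-by-marker confounding
scan of the clinical coefficient estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .defaults import CLINICAL_COVARIATES
from .genotype_qc import GenotypeMatrix

__all__ = [
    "CLINICAL_COVARIATES",
    "FitResult",
    "AssociationResult",
    "dichotomize",
    "encode_genotype",
    "fit_logistic",
    "associate_marker",
    "associate_activity",
    "bonferroni",
    "vif",
    "confounding_scan",
    "association_table",
]

Z975 = 1.959964
MAX_ITER = 50
SCORE_TOL = 1e-8
DEVIANCE_TOL = 1e-10
SEPARATION_BETA = 15.0


# ---------------------------------------------------------------------------
# Cohort preparation
# ---------------------------------------------------------------------------

def dichotomize(raw: pd.DataFrame) -> pd.DataFrame:
    """Risk-code the raw clinical columns (1 = increased predicted risk).

    Age<50, female sex, non-smoking, no cannabis, previous PONV, visceral or
    gynecological surgery, volatile anesthetics, and opioid consumption above
    the 19 mg morphine-equivalent median are coded 1.  Rows with a missing
    raw field get missing codes and are excluded from model fits by listwise
    deletion downstream.
    """
    required = [
        "sex",
        "age_years",
        "smoker",
        "cannabis_user",
        "ponv_history",
        "surgery_type",
        "volatile",
        "opioid_mg",
    ]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw cohort table lacks columns: {missing_cols}")
    out = raw.copy()

    def code(series, fn):
        return series.map(lambda v: np.nan if pd.isna(v) else float(fn(v)))

    out["Gender"] = code(raw["sex"], lambda v: str(v).upper().startswith("F"))
    out["Age"] = code(raw["age_years"], lambda v: v < 50)
    out["Smoking"] = code(raw["smoker"], lambda v: not bool(v))
    out["Cannabis"] = code(raw["cannabis_user"], lambda v: not bool(v))
    out["PONVhistory"] = code(raw["ponv_history"], lambda v: bool(v))
    out["SurgeryType"] = code(
        raw["surgery_type"], lambda v: str(v).lower() in ("visceral", "gynecologic", "gynecological")
    )
    out["VolatileAnesthetics"] = code(raw["volatile"], lambda v: bool(v))
    out["HighOpioid"] = code(raw["opioid_mg"], lambda v: v > 19.0)
    out["complete_record"] = out[CLINICAL_COVARIATES].notna().all(axis=1).astype(np.int8)
    return out


def encode_genotype(dosage: pd.Series, encoding: str = "additive") -> pd.Series:
    """Recode a minor-allele dosage column under a genetic model.

    additive -> 0/1/2 copies; dominant -> carrier flag; recessive ->
    minor-homozygote flag.  Missing dosages stay missing (listwise deletion).
    """
    d = dosage.astype(float)
    if encoding == "additive":
        return d
    if encoding == "dominant":
        return d.map(lambda v: np.nan if pd.isna(v) else float(v > 0))
    if encoding == "recessive":
        return d.map(lambda v: np.nan if pd.isna(v) else float(v == 2))
    raise ValueError(f"unknown genetic encoding {encoding!r}")


# ---------------------------------------------------------------------------
# IRLS logistic regression
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood logistic fit with Wald inference."""

    columns: list[str]
    beta: np.ndarray
    se: np.ndarray
    or_: np.ndarray
    ci95: np.ndarray          # shape (p, 2), on the OR scale
    p: np.ndarray
    converged: bool
    n_used: int
    loglik: float
    n_iter: int
    separated: bool = False
    vcov: np.ndarray | None = None

    def coef(self, name: str) -> float:
        return float(self.beta[self.columns.index(name)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "OR": self.or_,
                "ci_low": self.ci95[:, 0],
                "ci_high": self.ci95[:, 1],
                "p": self.p,
            },
            index=self.columns,
        )


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name an aliased column via pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [columns[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; aliased column(s): {bad or columns}")


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    add_intercept: bool = True,
) -> FitResult:
    """Fit a logistic regression by IRLS with listwise deletion.

    Convergence when the maximum absolute score drops below 1e-8 or the
    relative deviance change below 1e-10, within 50 iterations.  Diverging
    coefficients (|beta| > 15) flag (quasi-)separation and the result is
    marked non-converged rather than silently returned.
    """
    cols = list(covariates)
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate covariates")
    frame = data[[outcome] + cols].apply(pd.to_numeric, errors="coerce").dropna()
    y = frame[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} is not binary")
    X = frame[cols].to_numpy(dtype=float)
    names = cols
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["Intercept"] + cols
    n, p = X.shape
    if n <= p:
        raise ValueError(f"too few complete rows ({n}) for {p} parameters")
    _check_rank(X, names)

    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    separated = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving keeps the log-likelihood non-decreasing
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
        eta = X @ beta
        rel_dev = abs(ll_new - ll) / (abs(ll) + 1e-12)
        ll = ll_new
        if np.max(np.abs(beta)) > SEPARATION_BETA:
            separated = True
            warnings.warn("possible separation: |beta| exceeds 15; fit flagged non-converged", stacklevel=2)
            break
        if np.max(np.abs(score)) < SCORE_TOL or rel_dev < DEVIANCE_TOL:
            converged = True
            break

    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = (X * w[:, None]).T @ X
    vcov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    zs = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(zs))
    ci = np.exp(np.column_stack([beta - Z975 * se, beta + Z975 * se]))
    return FitResult(
        columns=list(names),
        beta=beta,
        se=se,
        or_=np.exp(beta),
        ci95=ci,
        p=pvals,
        converged=converged and not separated,
        n_used=n,
        loglik=ll,
        n_iter=it,
        separated=separated,
        vcov=vcov,
    )


# ---------------------------------------------------------------------------
# Marker / activity association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    """One marker (or activity score) under one encoding, adjusted for the eight clinical covariates."""

    term: str
    outcome: str
    encoding: str
    or_: float
    ci95: tuple[float, float]
    p: float
    beta: float
    se: float
    n_used: int
    converged: bool
    fit: FitResult = field(repr=False, default=None)


def _marker_result(fit: FitResult, term: str, outcome: str, encoding: str) -> AssociationResult:
    j = fit.columns.index(term)
    return AssociationResult(
        term=term,
        outcome=outcome,
        encoding=encoding,
        or_=float(fit.or_[j]),
        ci95=(float(fit.ci95[j, 0]), float(fit.ci95[j, 1])),
        p=float(fit.p[j]),
        beta=float(fit.beta[j]),
        se=float(fit.se[j]),
        n_used=fit.n_used,
        converged=fit.converged,
        fit=fit,
    )


def associate_marker(
    marker_id: str,
    outcome: str,
    data: pd.DataFrame,
    genotypes: GenotypeMatrix,
    encoding: str = "additive",
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Clinical-covariate-adjusted logistic fit with one genetic marker term.

    ``outcome='ponv_occurrence'`` uses the full cohort;
    ``'ponv_recurrence'`` is automatically restricted to followed cases
    (missing recurrence flags drop by listwise deletion).
    """
    covariates = list(CLINICAL_COVARIATES) if covariates is None else list(covariates)
    dosage = genotypes.dosage(marker_id).reindex(data.index)
    d = dosage.dropna()
    if d.nunique() < 2:
        raise ValueError(f"marker {marker_id!r} is monomorphic in the analysis sample")
    work = data.copy()
    work[marker_id] = encode_genotype(dosage, encoding)
    fit = fit_logistic(work, outcome, covariates + [marker_id])
    return _marker_result(fit, marker_id, outcome, encoding)


def associate_activity(
    score_column: str,
    outcome: str,
    data: pd.DataFrame,
    covariates: list[str] | None = None,
) -> AssociationResult:
    """Clinical-covariate-adjusted logistic fit with a continuous enzyme-activity score term."""
    covariates = list(CLINICAL_COVARIATES) if covariates is None else list(covariates)
    if data[score_column].dropna().nunique() < 2:
        raise np.linalg.LinAlgError(f"activity score {score_column!r} is constant (aliased with intercept)")
    fit = fit_logistic(data, outcome, covariates + [score_column])
    return _marker_result(fit, score_column, outcome, "continuous_score")


def association_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Marker/OR/CI/p summary frame (one row per association result)."""
    rows = []
    for r in results:
        rows.append(
            {
                "term": r.term,
                "outcome": r.outcome,
                "encoding": r.encoding,
                "OR": r.or_,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p": r.p,
                "n": r.n_used,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Multiple testing / diagnostics
# ---------------------------------------------------------------------------

def bonferroni(p_values, m: int | None = None, alpha: float = 0.05):
    """Bonferroni-corrected threshold and significance flags.

    Returns (threshold, flags) with flag = p < alpha/m.
    """
    p = np.asarray(list(p_values), dtype=float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    threshold = alpha / m
    return threshold, p < threshold


def vif(data: pd.DataFrame, covariates: list[str]) -> pd.Series:
    """Variance inflation factors: 1/(1-R^2) regressing each covariate on the
    rest (with intercept).  Aliased columns report inf.
    """
    if len(covariates) < 2:
        raise ValueError("VIF needs at least two covariates")
    frame = data[covariates].apply(pd.to_numeric, errors="coerce").dropna()
    out = {}
    for j, name in enumerate(covariates):
        others = [c for c in covariates if c != name]
        X = np.column_stack([np.ones(len(frame)), frame[others].to_numpy(float)])
        yj = frame[name].to_numpy(float)
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[name] = np.inf
            continue
        coef, *_ = np.linalg.lstsq(X, yj, rcond=None)
        ssr = float(np.sum((yj - X @ coef) ** 2))
        r2 = 1.0 - ssr / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def confounding_scan(
    marker_ids: list[str],
    outcome: str,
    data: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: list[str] | None = None,
    change_threshold: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Relative change of significant clinical coefficients when each marker
    enters the model; |change| > 10% is flagged as (weak) confounding.
    """
    covariates = list(CLINICAL_COVARIATES) if covariates is None else list(covariates)
    base = fit_logistic(data, outcome, covariates)
    if not base.converged:
        raise RuntimeError("base clinical model did not converge")
    significant = [
        c for c in covariates if base.p[base.columns.index(c)] < alpha
    ]
    rows = []
    for marker in marker_ids:
        work = data.copy()
        work[marker] = encode_genotype(genotypes.dosage(marker).reindex(data.index), "additive")
        fit = fit_logistic(work, outcome, covariates + [marker])
        for cov in significant:
            b0 = base.coef(cov)
            b1 = fit.coef(cov)
            change = np.nan if b0 == 0 else (b1 - b0) / abs(b0)
            rows.append(
                {
                    "marker": marker,
                    "covariate": cov,
                    "beta_without": b0,
                    "beta_with": b1,
                    "relative_change": change,
                    "flagged": bool(abs(change) > change_threshold) if np.isfinite(change) else False,
                }
            )
    return pd.DataFrame(rows)
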