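"""Genotype-adjusted Apfel risk scoring and its clinical evaluation.

The simplified Apfel score counts four factors — female sex, non-smoking,
previous PONV (or motion-sickness) history, and postoperative opioid use —
giving risk categories 0-4.  Medium-risk (category 2) women are the
population where a serotonin-receptor genotype is most informative, so two
genotyping policies are evaluated:

* Model 1: genotype category-2 women younger than 50;
* Model 2: genotype all category-2 women.

The genetic risk flag at the rs3782025 locus is 1 for G/G, 0 for A/A, and
age-dependent for A/G (1 below 50 years, 0 above).  Evaluation metrics are
closed-form: sensitivity/specificity/accuracy of the flag against observed
PONV in the genotyped group, the number needed to treat
NNT = 1/(risk difference), and the number needed to genotype
NNG = NNT / (flagged- or unflagged-group frequency), rounded to the nearest
integer.  ROC/AUC uses the Mann-Whitney pair statistic (ties counted 1/2)
with DeLong or bootstrap confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_qc import GenotypeMatrix

__all__ = [
    "apfel_score",
    "genetic_risk_flag",
    "select_genotyping_population",
    "ClassificationMetrics",
    "metrics_from_groups",
    "adjusted_category",
    "ROCCurve",
    "roc_auc",
    "evaluate_model",
]


# ---------------------------------------------------------------------------
# Scores and flags
# ---------------------------------------------------------------------------

def apfel_score(data: pd.DataFrame) -> pd.Series:
    """Simplified Apfel category (0-4) per patient.

    One point each for female sex (``Gender``), non-smoking (``Smoking``),
    PONV history (``PONVhistory``) and postoperative opioid use
    (``postop_opioid``).  Rows with any missing factor get a missing score.
    """
    needed = ["Gender", "Smoking", "PONVhistory", "postop_opioid"]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise ValueError(f"Apfel factors missing from table: {missing}")
    factors = data[needed].apply(pd.to_numeric, errors="coerce")
    score = factors.sum(axis=1, skipna=False)
    return score


def genetic_risk_flag(genotype_dosage: float, age_years: float) -> float:
    """rs3782025 risk flag: G/G (dosage 2) -> 1, A/A (0) -> 0; heterozygotes
    are high-risk below 50 years and low-risk above.  Missing -> NaN.
    """
    if pd.isna(genotype_dosage):
        return np.nan
    d = int(genotype_dosage)
    if d == 2:
        return 1.0
    if d == 0:
        return 0.0
    return 1.0 if age_years < 50 else 0.0


def select_genotyping_population(data: pd.DataFrame, model: int) -> pd.Series:
    """Boolean mask of patients genotyped under Model 1 or 2.

    Model 1: women in Apfel category 2 below 50 years; Model 2: all women in
    Apfel category 2.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    apfel = data["apfel"] if "apfel" in data.columns else apfel_score(data)
    mask = (data["Gender"] == 1) & (apfel == 2)
    if model == 1:
        mask &= data["age_years"] < 50
    return mask.fillna(False)


def adjusted_category(data: pd.DataFrame, model: int, marker: str = "rs3782025") -> pd.DataFrame:
    """Per-patient genotype-adjusted Apfel categories.

    Within the genotyped subset the category shifts by +1 (flag=1) or -1
    (flag=0); everyone else keeps the plain Apfel category.  Returns a frame
    with apfel, genotyped flag, genetic risk flag, and adjusted category.
    """
    apfel = data["apfel"] if "apfel" in data.columns else apfel_score(data)
    genotyped = select_genotyping_population(data.assign(apfel=apfel), model)
    flags = pd.Series(np.nan, index=data.index)
    if marker in data.columns:
        flags[genotyped] = [
            genetic_risk_flag(d, a)
            for d, a in zip(data.loc[genotyped, marker], data.loc[genotyped, "age_years"])
        ]
    adjusted = apfel.astype(float).copy()
    adjusted[genotyped & (flags == 1)] += 1
    adjusted[genotyped & (flags == 0)] -= 1
    return pd.DataFrame(
        {
            "apfel": apfel,
            "genotyped": genotyped.astype(int),
            "genetic_risk": flags,
            "adjusted_category": adjusted,
        }
    )


# ---------------------------------------------------------------------------
# Closed-form group metrics
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class ClassificationMetrics:
    """Prediction-model parameters for a genotyped group split by the flag."""

    n_genotyped: int
    n_risk_flagged: int
    pct_ponv_overall: float
    pct_ponv_risk: float
    pct_ponv_norisk: float
    sensitivity: float
    specificity: float
    accuracy: float
    nnt: float
    nng_increased: int
    nng_decreased: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def metrics_from_groups(
    n_risk: int, n_norisk: int, p_risk: float, p_norisk: float
) -> ClassificationMetrics:
    """Exact arithmetic evaluation of a binary risk flag from group sizes and
    group PONV proportions.

    cases = n_risk*p_risk + n_norisk*p_norisk;
    sensitivity = flagged cases / cases;
    specificity = unflagged non-cases / non-cases;
    NNT = 1/(p_risk - p_norisk);
    NNG(increased) = NNT / (n_risk/total), NNG(decreased) = NNT /
    (n_norisk/total), both rounded to the nearest integer.
    """
    if n_risk < 1 or n_norisk < 1:
        raise ValueError("group sizes must be >= 1")
    for name, p in (("p_risk", p_risk), ("p_norisk", p_norisk)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    total = n_risk + n_norisk
    cases = n_risk * p_risk + n_norisk * p_norisk
    noncases = total - cases
    flags: list[str] = []
    sens = n_risk * p_risk / cases if cases > 0 else np.nan
    spec = n_norisk * (1.0 - p_norisk) / noncases if noncases > 0 else np.nan
    if cases == 0:
        flags.append("no cases: sensitivity undefined")
    if noncases == 0:
        flags.append("no non-cases: specificity undefined")
    accuracy = (n_risk * p_risk + n_norisk * (1.0 - p_norisk)) / total
    if p_risk == p_norisk:
        flags.append("equal group risks: NNT/NNG undefined")
        nnt = np.nan
        nng_inc = nng_dec = -1
    else:
        nnt = 1.0 / (p_risk - p_norisk)
        nng_inc = _round_half_up(nnt / (n_risk / total))
        nng_dec = _round_half_up(nnt / (n_norisk / total))
    return ClassificationMetrics(
        n_genotyped=total,
        n_risk_flagged=n_risk,
        pct_ponv_overall=100.0 * cases / total,
        pct_ponv_risk=100.0 * p_risk,
        pct_ponv_norisk=100.0 * p_norisk,
        sensitivity=sens,
        specificity=spec,
        accuracy=accuracy,
        nnt=nnt,
        nng_increased=nng_inc,
        nng_decreased=nng_dec,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: tuple[float, float]
    ci_method: str


def _auc_mann_whitney(scores: np.ndarray, outcomes: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair statistic with ties counted 1/2."""
    ranks = stats.rankdata(scores)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    r1 = ranks[outcomes == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _delong_ci(scores: np.ndarray, outcomes: np.ndarray, auc: float) -> tuple[float, float]:
    cases = scores[outcomes == 1]
    controls = scores[outcomes == 0]
    m, n = len(cases), len(controls)

    def psi(x, y):
        return np.where(x > y, 1.0, np.where(x == y, 0.5, 0.0))

    v10 = np.array([psi(x, controls).mean() for x in cases])
    v01 = np.array([psi(cases, y).mean() for y in controls])
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    half = 1.959964 * math.sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_auc(
    scores,
    outcomes,
    ci_method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
) -> ROCCurve:
    """ROC curve and AUC for a (possibly ordinal) score against a binary
    outcome.  Degenerate classes (no case or no control) are an error.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(y))
    s, y = s[keep], y[keep]
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs at least one case and one control")
    auc = _auc_mann_whitney(s, y)

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(s[y == 0] >= t).mean() for t in thresholds])

    if ci_method == "delong":
        ci = _delong_ci(s, y, auc)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx1 = np.where(y == 1)[0]
        idx0 = np.where(y == 0)[0]
        samples = []
        for _ in range(n_boot):
            b = np.concatenate([rng.choice(idx1, n1), rng.choice(idx0, n0)])
            samples.append(_auc_mann_whitney(s[b], y[b]))
        ci = tuple(np.quantile(samples, [0.025, 0.975]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, ci95=(float(ci[0]), float(ci[1])), ci_method=ci_method)


# ---------------------------------------------------------------------------
# Cohort-level evaluation
# ---------------------------------------------------------------------------

def evaluate_model(
    data: pd.DataFrame,
    genotypes: GenotypeMatrix,
    model: int,
    marker: str = "rs3782025",
    outcome: str = "ponv_occurrence",
) -> dict:
    """Apply a genotyping policy to a cohort and evaluate it.

    Returns the per-patient risk table, the closed-form group metrics, the
    subgroup ROC (genetic flag as score, genotyped patients only) and the
    whole-cohort ROC (adjusted category as ordinal score).
    """
    work = data.copy()
    work[marker] = genotypes.dosage(marker).reindex(data.index)
    risk = adjusted_category(work, model, marker=marker)
    risk[outcome] = work[outcome]
    sub = risk[(risk["genotyped"] == 1) & risk["genetic_risk"].notna() & risk[outcome].notna()]
    flagged = sub[sub["genetic_risk"] == 1]
    unflagged = sub[sub["genetic_risk"] == 0]
    metrics = None
    if len(flagged) and len(unflagged):
        metrics = metrics_from_groups(
            len(flagged), len(unflagged), flagged[outcome].mean(), unflagged[outcome].mean()
        )
    roc_sub = None
    if len(sub) and sub[outcome].nunique() == 2:
        roc_sub = roc_auc(sub["genetic_risk"], sub[outcome])
    full = risk[risk[outcome].notna()]
    roc_full = roc_auc(full["adjusted_category"], full[outcome])
    roc_apfel = roc_auc(full["apfel"], full[outcome])
    return {
        "risk_table": risk,
        "metrics": metrics,
        "roc_genotyped_subgroup": roc_sub,
        "roc_whole_cohort": roc_full,
        "roc_apfel": roc_apfel,
    }
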