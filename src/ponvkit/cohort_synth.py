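"""Synthetic surgical-cohort generator.

Emulates the statistical structure of a 601-patient anesthesia cohort
followed 24 h for postoperative nausea and vomiting (PONV): dichotomized
clinical risk covariates with optional pairwise odds-ratio couplings,
biallelic/triallelic genotypes under Hardy-Weinberg or block haplotype
structure, and occurrence/recurrence outcomes drawn from an additive-model
logistic regression on the coded covariates plus per-allele marker effects.

The generator's defaults (see :mod:`ponvkit.defaults`) are calibrated to the
published cohort: covariate prevalences, marker allele and haplotype
frequencies, odds ratios, and an intercept solved so the implied PONV
prevalence is 43.9% (68.6% recurrence among followed cases).

Covariate couplings use a sequential-conditional Bernoulli scheme: variables
are drawn in a fixed order and a coupled variable is drawn from the two
conditional probabilities implied by its marginal prevalence, the parent's
marginal, and the requested odds ratio (closed-form 2x2 solve).  This
preserves all marginals exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .genotype_qc import GenotypeMatrix, VariantDef

__all__ = [
    "CovariateSpec",
    "LocusSpec",
    "OutcomeModelSpec",
    "RecurrenceModelSpec",
    "SyntheticCohort",
    "solve_2x2_joint",
    "generate_covariates",
    "covariate_joint_probs",
    "generate_genotypes",
    "inject_missingness",
    "generate_outcomes",
    "decorate_raw_columns",
    "generate_cohort",
    "write_cohort_tsv",
    "read_cohort_tsv",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """One dichotomized risk covariate.

    ``prevalence`` is the marginal probability of the risk-coded level (1).
    ``given``/``given_or`` optionally couple the covariate to one previously
    drawn covariate with the stated odds ratio; marginals are preserved.
    """

    name: str
    prevalence: float
    given: str | None = None
    given_or: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"covariate {self.name!r}: prevalence {self.prevalence} not in [0, 1]")
        if self.given_or <= 0:
            raise ValueError(f"covariate {self.name!r}: coupling odds ratio must be > 0")


@dataclass(frozen=True)
class LocusSpec:
    """One biallelic (or triallelic) marker locus.

    Unblocked loci are drawn under Hardy-Weinberg (two independent allele
    draws at ``maf``).  Loci sharing a ``block_id`` are drawn jointly as two
    independent haplotypes from ``haplotype_freqs`` (keys are tuples of
    allele strings, one per locus in block order) and collapsed to unphased
    genotypes.  A triallelic locus carries an ``extra_allele`` drawn by a
    nested biallelic scheme so both minor-allele frequencies match exactly.
    """

    variant_id: str
    maf: float
    chrom: str = "."
    major_allele: str = "A"
    minor_allele: str = "G"
    block_id: str | None = None
    haplotype_freqs: dict | None = None
    extra_allele: str | None = None
    extra_allele_freq: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"locus {self.variant_id!r}: maf {self.maf} not in (0, 0.5]")
        if self.extra_allele is not None and not 0.0 < self.extra_allele_freq < self.maf:
            raise ValueError(f"locus {self.variant_id!r}: extra allele frequency must be in (0, maf)")

    def to_variant_def(self) -> VariantDef:
        return VariantDef(
            variant_id=self.variant_id,
            chrom=self.chrom,
            major_allele=self.major_allele,
            minor_allele=self.minor_allele,
            extra_allele=self.extra_allele,
        )


@dataclass(frozen=True)
class RecurrenceModelSpec:
    """Logistic model for a second PONV episode among followed cases."""

    intercept: float
    covariate_betas: dict = field(default_factory=dict)
    marker_betas: dict = field(default_factory=dict)
    extra_terms: dict = field(default_factory=dict)
    followed_rate: float = 1.0


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Additive-model logistic outcome generator.

    ``covariate_betas`` are log-odds per risk-coded covariate,
    ``marker_betas`` log-odds per minor-allele copy at the named loci, and
    ``extra_terms`` log-odds per unit of arbitrary numeric cohort columns
    (used e.g. for continuous enzyme-activity effects).
    """

    intercept: float
    covariate_betas: dict = field(default_factory=dict)
    marker_betas: dict = field(default_factory=dict)
    extra_terms: dict = field(default_factory=dict)
    recurrence_model: RecurrenceModelSpec | None = None

    def __post_init__(self) -> None:
        for name, beta in {**self.covariate_betas, **self.marker_betas, **self.extra_terms}.items():
            if not math.isfinite(beta):
                raise ValueError(f"non-finite coefficient for {name!r}")
        if not math.isfinite(self.intercept):
            raise ValueError("non-finite intercept")


@dataclass
class SyntheticCohort:
    """Generated cohort table + genotypes + the generating truth."""

    cohort_table: pd.DataFrame
    genotype_matrix: GenotypeMatrix
    truth: dict


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def solve_2x2_joint(p_x: float, p_y: float, odds_ratio: float) -> float:
    """P(X=1, Y=1) for a 2x2 table with margins ``p_x``, ``p_y`` and the
    given odds ratio.  Unique root of the margin-constrained quadratic.
    """
    if not (0.0 <= p_x <= 1.0 and 0.0 <= p_y <= 1.0):
        raise ValueError("margins must be probabilities")
    lo = max(0.0, p_x + p_y - 1.0)
    hi = min(p_x, p_y)
    if odds_ratio == 1.0 or p_x in (0.0, 1.0) or p_y in (0.0, 1.0):
        return p_x * p_y
    a = 1.0 - odds_ratio
    b = 1.0 + (odds_ratio - 1.0) * (p_x + p_y)
    c = -odds_ratio * p_x * p_y
    if abs(a) < 1e-12:
        return -c / b
    disc = math.sqrt(b * b - 4 * a * c)
    for root in ((-b + disc) / (2 * a), (-b - disc) / (2 * a)):
        if lo - 1e-9 <= root <= hi + 1e-9:
            return min(hi, max(lo, root))
    raise ArithmeticError("no admissible joint probability")  # pragma: no cover


def _conditional_probs(spec: CovariateSpec, parent_prev: float) -> tuple[float, float]:
    """(P(Y=1 | parent=0), P(Y=1 | parent=1)) preserving the Y marginal."""
    p11 = solve_2x2_joint(parent_prev, spec.prevalence, spec.given_or)
    p_given1 = p11 / parent_prev if parent_prev > 0 else spec.prevalence
    p_given0 = (spec.prevalence - p11) / (1 - parent_prev) if parent_prev < 1 else spec.prevalence
    return p_given0, p_given1


def generate_covariates(specs: list[CovariateSpec], n: int, seed: int) -> pd.DataFrame:
    """Draw `n` rows of dichotomized covariates under the sequential scheme."""
    if n < 1:
        raise ValueError("n must be >= 1")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate covariate names")
    rng = np.random.default_rng(seed)
    out = {}
    prev_by_name = {s.name: s.prevalence for s in specs}
    for spec in specs:
        u = rng.random(n)
        if spec.given is None or spec.given_or == 1.0:
            col = (u < spec.prevalence).astype(np.int8)
        else:
            if spec.given not in out:
                raise ValueError(f"covariate {spec.name!r} coupled to {spec.given!r} which is not drawn yet")
            p0, p1 = _conditional_probs(spec, prev_by_name[spec.given])
            p = np.where(out[spec.given] == 1, p1, p0)
            col = (u < p).astype(np.int8)
        out[spec.name] = col
    df = pd.DataFrame(out)
    df.index.name = "sample_id"
    return df


def covariate_joint_probs(specs: list[CovariateSpec]) -> tuple[np.ndarray, np.ndarray]:
    """Exact joint distribution over all 2^k covariate patterns.

    Returns (patterns, probs) with patterns of shape (2^k, k) in the spec
    order.  Used to solve outcome-model intercepts without Monte Carlo.
    """
    k = len(specs)
    patterns = np.array([[(i >> j) & 1 for j in range(k)] for i in range(2 ** k)], dtype=np.int8)
    probs = np.ones(len(patterns))
    idx = {s.name: j for j, s in enumerate(specs)}
    prev_by_name = {s.name: s.prevalence for s in specs}
    for j, spec in enumerate(specs):
        x = patterns[:, j]
        if spec.given is None or spec.given_or == 1.0:
            p = np.full(len(patterns), spec.prevalence)
        else:
            p0, p1 = _conditional_probs(spec, prev_by_name[spec.given])
            p = np.where(patterns[:, idx[spec.given]] == 1, p1, p0)
        probs *= np.where(x == 1, p, 1.0 - p)
    return patterns, probs


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _validate_block(block_id: str, loci: list[LocusSpec]) -> list[tuple]:
    freqs = loci[0].haplotype_freqs
    for locus in loci:
        if locus.haplotype_freqs != freqs:
            raise ValueError(f"block {block_id!r}: loci disagree on haplotype_freqs")
    if freqs is None:
        raise ValueError(f"block {block_id!r}: haplotype_freqs required for blocked loci")
    haps = list(freqs)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"block {block_id!r}: haplotype frequencies sum to {total}, not 1")
    for i, locus in enumerate(loci):
        margin = sum(f for h, f in freqs.items() if h[i] == locus.minor_allele)
        if abs(margin - locus.maf) > 1e-6:
            raise ValueError(
                f"block {block_id!r}: haplotype margin {margin:.4f} at {locus.variant_id} "
                f"inconsistent with maf {locus.maf}"
            )
        for h in haps:
            if len(h) != len(loci):
                raise ValueError(f"block {block_id!r}: haplotype {h} has wrong length")
            if h[i] not in (locus.major_allele, locus.minor_allele):
                raise ValueError(f"block {block_id!r}: haplotype allele {h[i]!r} undeclared at {locus.variant_id}")
    return haps


def generate_genotypes(
    loci: list[LocusSpec], n: int, seed: int
) -> tuple[GenotypeMatrix, dict]:
    """Draw genotypes for `n` samples; returns (matrix, truth).

    ``truth`` maps block ids to the drawn per-sample haplotype index pairs
    (for oracle tests against the retained phase) and ``"dosage"`` to the
    complete minor-allele dosage frame (before any missingness injection).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    truth: dict = {"blocks": {}}

    # group blocked loci, preserving overall locus order for output
    blocks: dict[str, list[LocusSpec]] = {}
    for locus in loci:
        if locus.block_id is not None:
            blocks.setdefault(locus.block_id, []).append(locus)

    done: set[str] = set()
    for locus in loci:
        if locus.variant_id in done:
            continue
        if locus.block_id is None:
            if locus.extra_allele is None:
                a1 = np.where(rng.random(n) < locus.maf, locus.minor_allele, locus.major_allele)
                a2 = np.where(rng.random(n) < locus.maf, locus.minor_allele, locus.major_allele)
            else:
                # nested draws: major vs non-major, then extra within non-major
                p_nonmajor = locus.maf + locus.extra_allele_freq
                p_extra = locus.extra_allele_freq / p_nonmajor

                def draw(size):
                    nonmajor = rng.random(size) < p_nonmajor
                    extra = rng.random(size) < p_extra
                    return np.where(
                        nonmajor,
                        np.where(extra, locus.extra_allele, locus.minor_allele),
                        locus.major_allele,
                    )

                a1, a2 = draw(n), draw(n)
            columns[locus.variant_id] = _pair_calls(a1, a2, locus)
            done.add(locus.variant_id)
        else:
            block_loci = blocks[locus.block_id]
            haps = _validate_block(locus.block_id, block_loci)
            freqs = np.array([block_loci[0].haplotype_freqs[h] for h in haps])
            h1 = rng.choice(len(haps), size=n, p=freqs)
            h2 = rng.choice(len(haps), size=n, p=freqs)
            truth["blocks"][locus.block_id] = {
                "haplotypes": [tuple(h) for h in haps],
                "h1": h1,
                "h2": h2,
            }
            for i, bl in enumerate(block_loci):
                a1 = np.array([haps[j][i] for j in h1])
                a2 = np.array([haps[j][i] for j in h2])
                columns[bl.variant_id] = _pair_calls(a1, a2, bl)
                done.add(bl.variant_id)

    index = pd.Index([f"S{i:06d}" for i in range(n)], name="sample_id")
    calls = pd.DataFrame({l.variant_id: columns[l.variant_id] for l in loci}, index=index, dtype=object)
    gm = GenotypeMatrix(calls, [l.to_variant_def() for l in loci])
    dosage = pd.DataFrame({l.variant_id: gm.dosage(l.variant_id) for l in loci})
    truth["dosage"] = dosage
    return gm, truth


def _pair_calls(a1: np.ndarray, a2: np.ndarray, locus: LocusSpec) -> np.ndarray:
    """Collapse two phased allele draws into unphased call strings.

    The major allele is written first for readability; the call is unphased.
    """
    order = {locus.major_allele: 0, locus.minor_allele: 1}
    if locus.extra_allele is not None:
        order[locus.extra_allele] = 2
    first = np.where([order[x] <= order[y] for x, y in zip(a1, a2)], a1, a2)
    second = np.where([order[x] <= order[y] for x, y in zip(a1, a2)], a2, a1)
    return np.char.add(np.char.add(first.astype(str), "/"), second.astype(str))


def inject_missingness(gm: GenotypeMatrix, rate: float = 0.006, seed: int = 0) -> GenotypeMatrix:
    """Set a random `rate` fraction of calls to missing (QC-path exercise)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    mask = rng.random(calls.shape) < rate
    calls = calls.mask(pd.DataFrame(mask, index=calls.index, columns=calls.columns))
    return GenotypeMatrix(calls, gm.variants, gm.cyp2d6_copy_number)


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def _linear_predictor(
    intercept: float,
    covariate_betas: dict,
    marker_betas: dict,
    extra_terms: dict,
    cohort: pd.DataFrame,
    dosage: pd.DataFrame | None,
) -> np.ndarray:
    eta = np.full(len(cohort), intercept, dtype=float)
    for name, beta in covariate_betas.items():
        if name not in cohort.columns:
            raise ValueError(f"outcome model references missing covariate {name!r}")
        eta += beta * cohort[name].to_numpy(dtype=float)
    for vid, beta in marker_betas.items():
        if dosage is None or vid not in dosage.columns:
            raise ValueError(f"outcome model references missing marker {vid!r}")
        d = dosage[vid].to_numpy(dtype=float)
        if np.isnan(d).any():
            raise ValueError(f"marker {vid!r} has missing dosages; generate outcomes before missingness injection")
        eta += beta * d
    for name, beta in extra_terms.items():
        if name not in cohort.columns:
            raise ValueError(f"outcome model references missing column {name!r}")
        eta += beta * cohort[name].to_numpy(dtype=float)
    return eta


def generate_outcomes(
    cohort: pd.DataFrame,
    genotypes: GenotypeMatrix | None,
    model: OutcomeModelSpec,
    seed: int,
    dosage: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw occurrence (and recurrence, if modelled) flags onto the cohort.

    Recurrence is drawn only for occurring cases that are followed up
    (Bernoulli ``followed_rate``); non-followed and non-case rows get missing
    recurrence.  Dosages come from ``dosage`` (complete truth) when given,
    else from the genotype matrix.
    """
    if dosage is None and genotypes is not None:
        dosage = pd.DataFrame({vid: genotypes.dosage(vid) for vid in genotypes.variant_ids})
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    eta = _linear_predictor(
        model.intercept, model.covariate_betas, model.marker_betas, model.extra_terms, out, dosage
    )
    occurrence = (rng.random(len(out)) < expit(eta)).astype(np.int8)
    out["ponv_occurrence"] = occurrence

    rec = model.recurrence_model
    if rec is not None:
        followed = np.zeros(len(out), dtype=np.int8)
        followed[occurrence == 1] = (
            rng.random(int(occurrence.sum())) < rec.followed_rate
        ).astype(np.int8)
        out["followed_flag"] = followed
        eta_rec = _linear_predictor(
            rec.intercept, rec.covariate_betas, rec.marker_betas, rec.extra_terms, out, dosage
        )
        recurrence = np.where(rng.random(len(out)) < expit(eta_rec), 1.0, 0.0)
        recurrence[followed == 0] = np.nan
        out["ponv_recurrence"] = recurrence
    return out


# ---------------------------------------------------------------------------
# Raw (undichotomized) columns
# ---------------------------------------------------------------------------

_SURGERY_RISK = ("visceral", "gynecologic")
_SURGERY_OTHER = ("orthopedic", "ENT", "neurologic", "plastic")

# opioid morphine-equivalent distribution: lognormal matched to the cohort's
# median 19 mg and IQR 6-46 mg
_OPIOID_MU = math.log(19.0)
_OPIOID_SIGMA = (math.log(46.0) - math.log(6.0)) / (2 * 0.6745)


def decorate_raw_columns(
    coded: pd.DataFrame,
    seed: int,
    postop_opioid_prevalence: float = 0.80,
    tramadol_prevalence: float = 0.083,
) -> pd.DataFrame:
    """Synthesize raw clinical columns consistent with the coded risk flags.

    Dichotomizing the produced raw columns reproduces the coded flags exactly
    (a generator/analysis round-trip property).  The postoperative-opioid and
    tramadol flags are drawn independently at the stated prevalences.
    """
    rng = np.random.default_rng(seed)
    n = len(coded)
    out = coded.copy()
    out["sex"] = np.where(coded["Gender"] == 1, "F", "M")
    out["age_years"] = np.where(
        coded["Age"] == 1, rng.uniform(18, 49.99, n), rng.uniform(50, 90, n)
    ).round(1)
    out["smoker"] = (coded["Smoking"] == 0).astype(np.int8)
    out["cannabis_user"] = (coded["Cannabis"] == 0).astype(np.int8)
    out["ponv_history"] = coded["PONVhistory"].astype(np.int8)
    risk_surgery = rng.choice(_SURGERY_RISK, size=n)
    # gynecologic surgery only for female patients
    risk_surgery = np.where(
        (out["sex"] == "M") & (risk_surgery == "gynecologic"), "visceral", risk_surgery
    )
    out["surgery_type"] = np.where(
        coded["SurgeryType"] == 1, risk_surgery, rng.choice(_SURGERY_OTHER, size=n)
    )
    out["volatile"] = coded["VolatileAnesthetics"].astype(np.int8)
    # draw from the lognormal conditioned on the correct side of the median
    u = rng.uniform(0, 0.5, n) + np.where(coded["HighOpioid"] == 1, 0.5, 0.0)
    from scipy.stats import norm

    out["opioid_mg"] = np.exp(_OPIOID_MU + _OPIOID_SIGMA * norm.ppf(u)).round(1)
    out.loc[out["HighOpioid"] == 0, "opioid_mg"] = out.loc[out["HighOpioid"] == 0, "opioid_mg"].clip(upper=19.0)
    out["postop_opioid"] = (rng.random(n) < postop_opioid_prevalence).astype(np.int8)
    out["tramadol_flag"] = (rng.random(n) < tramadol_prevalence).astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# Pipeline + I/O
# ---------------------------------------------------------------------------

def generate_cohort(
    covariate_specs: list[CovariateSpec],
    loci: list[LocusSpec],
    model: OutcomeModelSpec,
    n: int,
    seed: int,
    missing_rate: float = 0.006,
    raw_columns: bool = True,
) -> SyntheticCohort:
    """Full pipeline: covariates -> genotypes -> outcomes -> missingness.

    Outcomes are generated from the complete (pre-missingness) dosages so the
    injected missingness only exercises QC/listwise-deletion paths.
    """
    ss = np.random.SeedSequence(seed)
    s_cov, s_geno, s_out, s_miss, s_raw = (int(x.generate_state(1)[0] % (2**31)) for x in ss.spawn(5))
    cohort = generate_covariates(covariate_specs, n, s_cov)
    gm, truth = generate_genotypes(loci, n, s_geno)
    cohort.index = gm.calls.index
    truth["dosage"].index = gm.calls.index
    if raw_columns:
        cohort = decorate_raw_columns(cohort, s_raw)
    cohort = generate_outcomes(cohort, gm, model, s_out, dosage=truth["dosage"])
    if missing_rate > 0:
        gm = inject_missingness(gm, rate=missing_rate, seed=s_miss)
    truth["seed"] = seed
    truth["model"] = model
    truth["covariate_specs"] = covariate_specs
    truth["loci"] = loci
    return SyntheticCohort(cohort_table=cohort, genotype_matrix=gm, truth=truth)


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=True, na_rep="NA")


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])


def write_spec_json(covariate_specs, loci, model, path) -> None:
    """Serialize a generating specification (the cohort 'truth') to JSON."""

    def hap_key(freqs):
        return {"|".join(h): f for h, f in freqs.items()} if freqs else None

    payload = {
        "covariates": [vars(s).copy() for s in covariate_specs],
        "loci": [
            {**{k: v for k, v in vars(l).items() if k != "haplotype_freqs"},
             "haplotype_freqs": hap_key(l.haplotype_freqs)}
            for l in loci
        ],
        "model": {
            "intercept": model.intercept,
            "covariate_betas": model.covariate_betas,
            "marker_betas": model.marker_betas,
            "extra_terms": model.extra_terms,
            "recurrence_model": None
            if model.recurrence_model is None
            else {
                "intercept": model.recurrence_model.intercept,
                "covariate_betas": model.recurrence_model.covariate_betas,
                "marker_betas": model.recurrence_model.marker_betas,
                "extra_terms": model.recurrence_model.extra_terms,
                "followed_rate": model.recurrence_model.followed_rate,
            },
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
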