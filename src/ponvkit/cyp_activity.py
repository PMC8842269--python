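"""Star-allele diplotype assignment and CYP activity scoring.

Each pharmacogene is described by an allele-definition table: a set of star
alleles, each defined by required variant alleles, with a per-allele
activity value and a deterministic matching priority.  Diplotypes are
assigned by exhaustive enumeration of allele pairs whose joint requirements
exactly explain the observed allele dosages at every defining variant of
the gene.

Scoring follows the activity-score convention: the gene score is the sum of
the two per-allele values.  CYP2D6 is copy-number aware (extra copies add
the higher-activity allele's value); CYP2C9 counts reduced-function
alleles; CYP3A is scored as a metabolizer group (PM=0, IM=1, EM=2) from the
CYP3A4/CYP3A5 functional-allele combination with a one-group increment for
CYP3A7*1C carriers; CYP1A2 can be induction-adjusted (x1.5) for smokers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix

__all__ = [
    "StarAllele",
    "GeneDef",
    "AlleleDefinitionTable",
    "load_allele_definitions",
    "Diplotype",
    "ActivityProfile",
    "assign_diplotype",
    "score_additive_gene",
    "score_cyp2d6",
    "score_cyp3a",
    "score_cyp2c9",
    "adjust_cyp1a2_smoking",
    "activity_profiles",
]

GROUP_SCORE = {"PM": 0.0, "IM": 1.0, "EM": 2.0}
SCORE_GROUP = {0.0: "PM", 1.0: "IM", 2.0: "EM"}


@dataclass(frozen=True)
class StarAllele:
    name: str
    requirements: tuple          # ((variant_id, required_allele), ...)
    score: float

    def required_dosage(self, variant_id: str) -> int:
        return sum(1 for v, _ in self.requirements if v == variant_id)


@dataclass
class GeneDef:
    gene: str
    alleles: list[StarAllele]    # in priority order; default (no-requirement) allele first

    @property
    def default_allele(self) -> StarAllele:
        for a in self.alleles:
            if not a.requirements:
                return a
        raise ValueError(f"{self.gene}: no default allele defined")

    @property
    def defining_variants(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.alleles:
            for v, _ in a.requirements:
                seen.setdefault(v)
        return list(seen)

    def required_allele(self, variant_id: str) -> str:
        for a in self.alleles:
            for v, req in a.requirements:
                if v == variant_id:
                    return req
        raise KeyError(variant_id)


class AlleleDefinitionTable:
    """Per-gene star-allele definitions with scores and matching priority."""

    def __init__(self, genes: dict[str, GeneDef]):
        self.genes = genes
        for gene_def in genes.values():
            gene_def.default_allele  # raises if absent
            for a in gene_def.alleles:
                if a.score < 0:
                    raise ValueError(f"{gene_def.gene}{a.name}: negative score")

    def __getitem__(self, gene: str) -> GeneDef:
        return self.genes[gene]

    def score(self, gene: str, star: str) -> float:
        for a in self.genes[gene].alleles:
            if a.name == star:
                return a.score
        raise KeyError(f"no score defined for {gene}{star}")

    @classmethod
    def from_tsv(cls, path_or_buf) -> "AlleleDefinitionTable":
        df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
        genes: dict[str, GeneDef] = {}
        for gene, sub in df.groupby("gene", sort=False):
            alleles: dict[str, dict] = {}
            for _, row in sub.iterrows():
                entry = alleles.setdefault(row["star_allele"], {"reqs": [], "score": float(row["score"])})
                if row["variant_id"] != ".":
                    entry["reqs"].append((row["variant_id"], row["required_allele"]))
            genes[gene] = GeneDef(
                gene,
                [StarAllele(name, tuple(e["reqs"]), e["score"]) for name, e in alleles.items()],
            )
        return cls(genes)


def load_allele_definitions(path=None) -> AlleleDefinitionTable:
    """Load the shipped default table, or a user override TSV."""
    if path is not None:
        return AlleleDefinitionTable.from_tsv(path)
    ref = resources.files("ponvkit.data").joinpath("allele_definitions.tsv")
    with ref.open() as fh:
        return AlleleDefinitionTable.from_tsv(fh)


# ---------------------------------------------------------------------------
# Diplotype assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diplotype:
    gene: str
    alleles: tuple[str, str] | None   # None = no-call
    ambiguous: bool = False
    no_call: bool = False
    used_default: bool = False

    def __str__(self) -> str:
        if self.alleles is None:
            return f"{self.gene} no-call"
        return f"{self.gene} {self.alleles[0]}/{self.alleles[1]}"


def _dosage_columns(gm: GenotypeMatrix, gene_def: GeneDef) -> dict[str, pd.Series | None]:
    """Per-variant required-allele dosage columns (None = absent from panel)."""
    out: dict[str, pd.Series | None] = {}
    for vid in gene_def.defining_variants:
        if vid not in gm.calls.columns:
            out[vid] = None
        else:
            out[vid] = gm.allele_counts(vid, gene_def.required_allele(vid))
    return out


def _observed_dosages(gm: GenotypeMatrix, sample, gene_def: GeneDef) -> dict[str, float | None]:
    cols = _dosage_columns(gm, gene_def)
    return {
        vid: (None if col is None or pd.isna(col.get(sample, np.nan)) else float(col[sample]))
        for vid, col in cols.items()
    }


def _assign_from_doses(gene: str, gene_def: GeneDef, observed: dict[str, float | None]) -> Diplotype:
    candidates = []
    for a, b in itertools.combinations_with_replacement(gene_def.alleles, 2):
        ok = True
        for vid, dose in observed.items():
            if dose is None:
                continue
            if a.required_dosage(vid) + b.required_dosage(vid) != dose:
                ok = False
                break
        if ok:
            candidates.append((a.name, b.name))
    if not candidates:
        return Diplotype(gene, None, no_call=True)
    has_wildcard = any(d is None for d in observed.values())
    return Diplotype(
        gene,
        candidates[0],
        ambiguous=len(candidates) > 1 and has_wildcard,
        used_default=has_wildcard and any(
            n == gene_def.default_allele.name for n in candidates[0]
        ),
    )


def assign_diplotype(gm: GenotypeMatrix, sample, gene: str, table: AlleleDefinitionTable) -> Diplotype:
    """Deterministic star-allele pair assignment by exhaustive enumeration.

    A candidate pair is admissible when, at every defining variant of the
    gene, the joint required dosage of the two alleles equals the observed
    dosage.  Missing calls act as wildcards (any requirement matches) and
    mark the result ambiguous when more than one pair remains; ties resolve
    by the table's priority order.  Calls inconsistent with every pair give
    a no-call.
    """
    gene_def = table[gene]
    return _assign_from_doses(gene, gene_def, _observed_dosages(gm, sample, gene_def))


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

@dataclass
class ActivityProfile:
    """Per-gene star-allele diplotype with its numeric activity score."""

    gene: str
    diplotype: tuple[str, str] | None
    activity_score: float
    copy_number: int | None = None
    activity_group: str | None = None
    smoking_adjusted: bool = False
    flags: list[str] = field(default_factory=list)


def score_additive_gene(diplotype: tuple[str, str], gene: str, table: AlleleDefinitionTable) -> float:
    """Gene activity score = sum of the two per-allele values."""
    return table.score(gene, diplotype[0]) + table.score(gene, diplotype[1])


def score_cyp2d6(
    diplotype: tuple[str, str],
    copy_number: int,
    table: AlleleDefinitionTable,
) -> ActivityProfile:
    """Copy-number-aware CYP2D6 activity score.

    copy_number > 2: the extra copies duplicate the higher-activity allele
    (standard convention when the duplicated allele is not resolved).
    copy_number == 1: only the lower-activity allele is counted
    (conservative).  copy_number == 0 with non-null alleles is flagged
    inconsistent and scores 0.
    """
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    s = sorted((table.score("CYP2D6", a) for a in diplotype))
    flags: list[str] = []
    if copy_number == 0:
        score = 0.0
        if any(v > 0 for v in s):
            flags.append("copy number 0 inconsistent with non-deleted alleles")
    elif copy_number == 1:
        score = s[0]
        flags.append("single gene copy: lower-activity allele counted")
    else:
        score = sum(s) + (copy_number - 2) * s[1]
    return ActivityProfile(
        gene="CYP2D6",
        diplotype=tuple(diplotype),
        activity_score=float(score),
        copy_number=copy_number,
        flags=flags,
    )


def score_cyp3a(
    cyp3a4_diplotype: tuple[str, str] | None,
    cyp3a5_diplotype: tuple[str, str] | None,
    cyp3a7_diplotype: tuple[str, str] | None,
    table: AlleleDefinitionTable,
) -> ActivityProfile:
    """Combined CYP3A metabolizer group and score.

    Base group from functional-allele status: CYP3A5 expressor (any *1) and
    fully functional CYP3A4 (no *22) -> EM; exactly one of the two -> IM;
    neither -> PM.  CYP3A7*1C carriers move one group up, capped at EM.
    Scores map PM/IM/EM -> 0/1/2.
    """
    if cyp3a4_diplotype is None or cyp3a5_diplotype is None:
        return ActivityProfile("CYP3A", None, np.nan, flags=["no-call"])
    a4_functional = all(table.score("CYP3A4", a) > 0 for a in cyp3a4_diplotype)
    a5_expressor = any(table.score("CYP3A5", a) > 0 for a in cyp3a5_diplotype)
    group = {2: "EM", 1: "IM", 0: "PM"}[int(a4_functional) + int(a5_expressor)]
    flags = []
    if cyp3a7_diplotype is not None and any(table.score("CYP3A7", a) > 0 for a in cyp3a7_diplotype):
        group = {"PM": "IM", "IM": "EM", "EM": "EM"}[group]
        flags.append("CYP3A7*1C increment")
    return ActivityProfile(
        gene="CYP3A",
        diplotype=None,
        activity_score=GROUP_SCORE[group],
        activity_group=group,
        flags=flags,
    )


def score_cyp2c9(diplotype: tuple[str, str], table: AlleleDefinitionTable) -> float:
    """Number of reduced-activity CYP2C9 alleles (0-2)."""
    return float(sum(1 for a in diplotype if table.score("CYP2C9", a) > 0))


def adjust_cyp1a2_smoking(profile: ActivityProfile, smoker: bool) -> ActivityProfile:
    """Induction adjustment: multiply the CYP1A2 score by 1.5 for smokers.

    Applying the adjustment twice is an error; the returned profile carries
    the ``smoking_adjusted`` flag either way.
    """
    if profile.smoking_adjusted:
        raise ValueError("smoking adjustment already applied")
    factor = 1.5 if smoker else 1.0
    return replace(
        profile,
        activity_score=profile.activity_score * factor,
        smoking_adjusted=True,
    )


# ---------------------------------------------------------------------------
# Cohort-level convenience
# ---------------------------------------------------------------------------

_ADDITIVE_GENES = ("CYP1A2", "CYP2B6", "CYP2C19")


def activity_profiles(
    gm: GenotypeMatrix,
    table: AlleleDefinitionTable | None = None,
    smokers: pd.Series | None = None,
    genes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-sample activity scores for every scorable gene in the panel.

    Returns a sample x gene DataFrame; genes whose defining variants are all
    absent from the panel are skipped.  ``smokers`` (boolean per sample)
    triggers the CYP1A2 induction adjustment, reported as the extra column
    ``CYP1A2_smoking_adjusted``.
    """
    table = table if table is not None else load_allele_definitions()
    panel = set(gm.calls.columns)

    def panel_has(gene: str) -> bool:
        return gene in table.genes and any(v in panel for v in table[gene].defining_variants)

    wanted = set(genes) if genes is not None else set(table.genes) | {"CYP3A"}
    # precompute required-allele dosage columns once per gene (cheap across
    # the whole cohort, where per-sample lookups would be quadratic)
    dose_cols = {g: _dosage_columns(gm, table[g]) for g in table.genes}

    def diplo(gene: str, sample) -> Diplotype:
        observed = {
            vid: (None if col is None or pd.isna(col.get(sample, np.nan)) else float(col[sample]))
            for vid, col in dose_cols[gene].items()
        }
        return _assign_from_doses(gene, table[gene], observed)

    out: dict = {}
    cyp3a_wanted = ("CYP3A" in wanted or "CYP3A4" in wanted) and (panel_has("CYP3A4") or panel_has("CYP3A5"))
    for sample in gm.samples:
        row: dict[str, float] = {}
        for gene in _ADDITIVE_GENES:
            if gene in wanted and panel_has(gene):
                d = diplo(gene, sample)
                row[gene] = np.nan if d.alleles is None else score_additive_gene(d.alleles, gene, table)
        if "CYP2C9" in wanted and panel_has("CYP2C9"):
            d = diplo("CYP2C9", sample)
            row["CYP2C9"] = np.nan if d.alleles is None else score_cyp2c9(d.alleles, table)
        if "CYP2D6" in wanted and panel_has("CYP2D6"):
            d = diplo("CYP2D6", sample)
            row["CYP2D6"] = (
                np.nan
                if d.alleles is None
                else score_cyp2d6(d.alleles, int(gm.cyp2d6_copy_number.get(sample, 2)), table).activity_score
            )
        if cyp3a_wanted:
            prof = score_cyp3a(
                diplo("CYP3A4", sample).alleles,
                diplo("CYP3A5", sample).alleles,
                diplo("CYP3A7", sample).alleles if "CYP3A7" in table.genes else None,
                table,
            )
            row["CYP3A"] = prof.activity_score
        if "CYP1A2" in row and smokers is not None:
            base = ActivityProfile("CYP1A2", None, row["CYP1A2"])
            row["CYP1A2_smoking_adjusted"] = adjust_cyp1a2_smoking(
                base, bool(smokers.get(sample, False))
            ).activity_score
        out[sample] = row
    return pd.DataFrame.from_dict(out, orient="index").reindex(gm.calls.index)
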