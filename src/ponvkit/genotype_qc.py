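"""Genotype data containers, I/O, and quality control.

This module reads unphased biallelic (or triallelic, handled on a primary
allele pair) genotype calls for a small fixed pharmacogenetic panel,
normalizes allele orientation, and computes the usual panel QC: per-sample
and per-variant call rates, minor-allele frequencies, and Hardy-Weinberg
equilibrium tests (1-df chi-square and the exact conditional test on the
heterozygote count).

Alleles are taken from the variant table as declared; there is no
genome-build liftover or strand flipping.  Indels are treated as biallelic
presence/absence symbols (e.g. ``CA`` / ``-``).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

MISSING = "."

__all__ = [
    "VariantDef",
    "GenotypeMatrix",
    "QCSummary",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "normalize_orientation",
    "compute_qc",
    "hwe_test",
    "hwe_exact_enumeration",
    "filter_variants",
]


@dataclass(frozen=True)
class VariantDef:
    """Declared alleles for one panel variant.

    ``major_allele`` / ``minor_allele`` give the declared orientation; QC may
    swap them if the data disagree (ties keep the declaration).  At most one
    ``extra_allele`` (third allele) is supported; calls carrying it are
    excluded from the primary-pair dosage and its frequency is reported
    separately.
    """

    variant_id: str
    chrom: str = "."
    major_allele: str = "A"
    minor_allele: str = "G"
    extra_allele: str | None = None

    def __post_init__(self) -> None:
        alleles = [self.major_allele, self.minor_allele]
        if self.extra_allele is not None:
            alleles.append(self.extra_allele)
        if any(not a for a in alleles):
            raise ValueError(f"{self.variant_id}: empty allele string")
        if len(set(alleles)) != len(alleles):
            raise ValueError(f"{self.variant_id}: alleles must be distinct")

    @property
    def alleles(self) -> tuple[str, ...]:
        if self.extra_allele is None:
            return (self.major_allele, self.minor_allele)
        return (self.major_allele, self.minor_allele, self.extra_allele)


class GenotypeMatrix:
    """Sample x variant matrix of unphased allele-pair calls.

    ``calls`` is a pandas DataFrame indexed by sample id with one column per
    variant id; each cell is ``"A1/A2"`` or NaN for a missing call.
    ``cyp2d6_copy_number`` is a per-sample integer series (default 2).
    """

    def __init__(
        self,
        calls: pd.DataFrame,
        variants: list[VariantDef],
        cyp2d6_copy_number: pd.Series | None = None,
    ):
        vids = [v.variant_id for v in variants]
        if len(set(vids)) != len(vids):
            raise ValueError("duplicate variant ids")
        if list(calls.columns) != vids:
            missing = set(vids) ^ set(calls.columns)
            raise ValueError(f"calls columns do not match variant defs: {missing}")
        self.calls = calls
        self.variants = list(variants)
        self._by_id = {v.variant_id: v for v in variants}
        if cyp2d6_copy_number is None:
            cyp2d6_copy_number = pd.Series(2, index=calls.index, dtype=int)
        self.cyp2d6_copy_number = cyp2d6_copy_number.reindex(calls.index).fillna(2).astype(int)
        self._validate_calls()

    # -- basic accessors ---------------------------------------------------
    @property
    def samples(self) -> list:
        return list(self.calls.index)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def variant(self, variant_id: str) -> VariantDef:
        return self._by_id[variant_id]

    @property
    def n_samples(self) -> int:
        return len(self.calls.index)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def _validate_calls(self) -> None:
        bad: list[str] = []
        for v in self.variants:
            allowed = set(v.alleles)
            col = self.calls[v.variant_id]
            for sample, call in col.dropna().items():
                for a in str(call).split("/"):
                    if a not in allowed:
                        bad.append(f"{sample}@{v.variant_id}: allele {a!r} not declared")
        if bad:
            raise ValueError("undeclared alleles:\n" + "\n".join(bad[:20]))

    # -- dosage ------------------------------------------------------------
    def allele_counts(self, variant_id: str, allele: str) -> pd.Series:
        """Per-sample count of `allele` (0/1/2), NaN where the call is missing."""
        col = self.calls[variant_id]

        def _count(call):
            if pd.isna(call):
                return np.nan
            return float(sum(a == allele for a in str(call).split("/")))

        return col.map(_count).astype(float)

    def dosage(self, variant_id: str) -> pd.Series:
        """Minor-allele dosage on the primary allele pair.

        Calls containing the extra (third) allele are set to NaN so downstream
        association runs on the primary pair only.
        """
        v = self.variant(variant_id)
        col = self.calls[variant_id]

        def _dose(call):
            if pd.isna(call):
                return np.nan
            alleles = str(call).split("/")
            if v.extra_allele is not None and v.extra_allele in alleles:
                return np.nan
            return float(sum(a == v.minor_allele for a in alleles))

        return col.map(_dose).astype(float)

    def genotype_counts(self, variant_id: str) -> tuple[int, int, int]:
        """(n hom-major, n het, n hom-minor) on the primary allele pair."""
        d = self.dosage(variant_id).dropna()
        return (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))

    def subset(self, samples=None, variant_ids=None) -> "GenotypeMatrix":
        calls = self.calls
        variants = self.variants
        if variant_ids is not None:
            variants = [self._by_id[v] for v in variant_ids]
            calls = calls[list(variant_ids)]
        if samples is not None:
            calls = calls.loc[list(samples)]
        return GenotypeMatrix(calls.copy(), variants, self.cyp2d6_copy_number.loc[calls.index])

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.calls.equals(other.calls)
            and self.cyp2d6_copy_number.equals(other.cyp2d6_copy_number)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    """Long-format TSV: one row per (sample, variant); missing written as '.'.

    Variant declarations ride along as ``##variant=`` header lines so a
    round-trip preserves orientation and extra alleles; CYP2D6 copy numbers
    as ``##cn=`` lines.
    """
    with open(path, "w") as fh:
        for v in gm.variants:
            extra = v.extra_allele if v.extra_allele is not None else "."
            fh.write(
                f"##variant=id:{v.variant_id},chrom:{v.chrom},"
                f"major:{v.major_allele},minor:{v.minor_allele},extra:{extra}\n"
            )
        for sample, cn in gm.cyp2d6_copy_number.items():
            if cn != 2:
                fh.write(f"##cn=sample:{sample},copies:{cn}\n")
        fh.write("sample_id\tvariant_id\tallele1\tallele2\n")
        for sample in gm.samples:
            for vid in gm.variant_ids:
                call = gm.calls.at[sample, vid]
                if pd.isna(call):
                    a1 = a2 = MISSING
                else:
                    a1, a2 = str(call).split("/")
                fh.write(f"{sample}\t{vid}\t{a1}\t{a2}\n")


def _read_tsv(path) -> GenotypeMatrix:
    variants: list[VariantDef] = []
    cn: dict[str, int] = {}
    rows: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##variant="):
                kv = dict(item.split(":", 1) for item in line[len("##variant="):].split(","))
                variants.append(
                    VariantDef(
                        variant_id=kv["id"],
                        chrom=kv.get("chrom", "."),
                        major_allele=kv["major"],
                        minor_allele=kv["minor"],
                        extra_allele=None if kv.get("extra", ".") == "." else kv["extra"],
                    )
                )
                continue
            if line.startswith("##cn="):
                kv = dict(item.split(":", 1) for item in line[len("##cn="):].split(","))
                cn[kv["sample"]] = int(kv["copies"])
                continue
            if line.startswith("##"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[:4] != ["sample_id", "variant_id", "allele1", "allele2"]:
                    raise ValueError(f"malformed genotype TSV header: {parts[:4]}")
                header_seen = True
                continue
            rows.append(tuple(parts[:4]))
    if not header_seen:
        raise ValueError("genotype TSV has no header line")
    df = pd.DataFrame(rows, columns=["sample_id", "variant_id", "allele1", "allele2"])
    if not variants:
        # no declarations: infer biallelic defs from observed alleles
        for vid, sub in df.groupby("variant_id", sort=False):
            obs = [a for a in pd.concat([sub.allele1, sub.allele2]).unique() if a != MISSING]
            if len(obs) == 1:
                obs.append("N")
            variants.append(VariantDef(vid, major_allele=obs[0], minor_allele=obs[1]))
    vids = [v.variant_id for v in variants]
    samples = list(dict.fromkeys(df.sample_id))
    calls = pd.DataFrame(np.nan, index=pd.Index(samples, name="sample_id"), columns=vids, dtype=object)
    errors = []
    by_id = {v.variant_id: v for v in variants}
    for sample_id, vid, a1, a2 in rows:
        if vid not in by_id:
            errors.append(f"{sample_id}@{vid}: undeclared variant")
            continue
        if a1 == MISSING or a2 == MISSING:
            continue
        allowed = set(by_id[vid].alleles)
        if a1 not in allowed or a2 not in allowed:
            errors.append(f"{sample_id}@{vid}: undeclared allele {a1}/{a2}")
            continue
        calls.at[sample_id, vid] = f"{a1}/{a2}"
    if errors:
        raise ValueError("genotype record errors:\n" + "\n".join(errors))
    cn_series = pd.Series({s: cn.get(s, 2) for s in samples})
    return GenotypeMatrix(calls, variants, cn_series)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with GT-only FORMAT.

    Positions are synthetic (panel order); REF is the declared major allele,
    ALT the minor (and extra, if any).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(v.chrom if v.chrom != "." else "0" for v in gm.variants)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in gm.samples) + "\n")
        for pos, v in enumerate(gm.variants, start=1):
            # VCF alleles cannot be '-'; represent indel deletion with 'N' anchor
            def enc(a: str) -> str:
                return a if a != "-" else "N"

            alts = [enc(v.minor_allele)] + ([enc(v.extra_allele)] if v.extra_allele else [])
            allele_index = {v.major_allele: 0, v.minor_allele: 1}
            if v.extra_allele:
                allele_index[v.extra_allele] = 2
            gts = []
            for sample in gm.samples:
                call = gm.calls.at[sample, v.variant_id]
                if pd.isna(call):
                    gts.append("./.")
                else:
                    a1, a2 = str(call).split("/")
                    gts.append(f"{allele_index[a1]}/{allele_index[a2]}")
            chrom = v.chrom if v.chrom != "." else "0"
            fh.write(
                f"{chrom}\t{pos}\t{v.variant_id}\t{enc(v.major_allele)}\t"
                f"{','.join(alts)}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantDef] = []
    columns: dict[str, list] = {}
    for rec in vcf:
        def dec(a: str) -> str:
            return a if a != "N" else "-"

        alts = [dec(a) for a in rec.ALT]
        vd = VariantDef(
            variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
            chrom=str(rec.CHROM),
            major_allele=dec(rec.REF),
            minor_allele=alts[0] if alts else "N",
            extra_allele=alts[1] if len(alts) > 1 else None,
        )
        variants.append(vd)
        alleles = (vd.major_allele, vd.minor_allele) + ((vd.extra_allele,) if vd.extra_allele else ())
        col = []
        for g in rec.genotypes:
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                col.append(np.nan)
            else:
                col.append(f"{alleles[a1]}/{alleles[a2]}")
        columns[vd.variant_id] = col
    calls = pd.DataFrame(columns, index=pd.Index(samples, name="sample_id"), dtype=object)
    calls = calls[[v.variant_id for v in variants]]
    return GenotypeMatrix(calls, variants)


def read_genotypes(path, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` (long format) or ``vcf``."""
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def normalize_orientation(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, list[str]]:
    """Ensure the declared minor allele is the less frequent one in the data.

    Returns the (possibly new) matrix and the list of swapped variant ids.
    Ties keep the declared orientation, so the operation is idempotent.
    """
    swapped: list[str] = []
    new_variants: list[VariantDef] = []
    for v in gm.variants:
        n_minor = gm.allele_counts(v.variant_id, v.minor_allele).sum()
        n_major = gm.allele_counts(v.variant_id, v.major_allele).sum()
        if n_minor > n_major:
            swapped.append(v.variant_id)
            new_variants.append(replace(v, major_allele=v.minor_allele, minor_allele=v.major_allele))
        else:
            new_variants.append(v)
    if not swapped:
        return gm, []
    return GenotypeMatrix(gm.calls.copy(), new_variants, gm.cyp2d6_copy_number), swapped


def hwe_chi2(n_hom_major: int, n_het: int, n_hom_minor: int) -> tuple[float, float]:
    """1-df Pearson chi-square test against Hardy-Weinberg proportions.

    Returns (statistic, p).  Monomorphic input gives (0, 1) with a warning.
    """
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_minor = n_het + 2 * n_hom_minor
    n_major = n_het + 2 * n_hom_major
    if n_minor == 0 or n_major == 0:
        warnings.warn("monomorphic variant: HWE p set to 1", stacklevel=2)
        return 0.0, 1.0
    p = n_minor / (2 * n)
    q = 1.0 - p
    expected = np.array([q * q * n, 2 * p * q * n, p * p * n])
    observed = np.array([n_hom_major, n_het, n_hom_minor], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def _log_hwe_prob(n_het: int, n_samples: int, n_minor: int) -> float:
    """Log probability of `n_het` heterozygotes conditional on allele counts."""
    n_hom_minor = (n_minor - n_het) // 2
    n_hom_major = n_samples - n_het - n_hom_minor
    n_major = 2 * n_samples - n_minor
    return (
        gammaln(n_samples + 1)
        - gammaln(n_hom_major + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_minor + 1)
        + n_het * math.log(2)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n_samples + 1)
    )


def hwe_exact_enumeration(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional HWE test by full enumeration of heterozygote counts.

    Sums the probabilities of all heterozygote counts (same parity as the
    minor-allele total) whose conditional probability does not exceed that of
    the observed configuration.
    """
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    n_minor = n_het + 2 * n_hom_minor
    n_major = n_het + 2 * n_hom_major
    if n_minor == 0 or n_major == 0:
        warnings.warn("monomorphic variant: HWE p set to 1", stacklevel=2)
        return 1.0
    # condition on the rarer allele count; symmetric in the allele labels
    rare = min(n_minor, n_major)
    h_values = list(range(rare % 2, rare + 1, 2))
    logs = np.array([_log_hwe_prob(h, n, rare) for h in h_values])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[h_values.index(n_het)]
    pval = float(probs[probs <= p_obs * (1 + 1e-12)].sum())
    return min(1.0, pval)


def hwe_test(genotype_counts: tuple[int, int, int], method: str = "auto") -> float:
    """HWE p-value for (n hom-major, n het, n hom-minor).

    ``method='chi2'`` uses the 1-df Pearson test, ``'exact'`` the full
    enumeration conditional test, and ``'auto'`` (default) picks exact when
    the minor-allele count is below 100 (small-sample practice), chi-square
    otherwise.
    """
    n_hom_major, n_het, n_hom_minor = (int(c) for c in genotype_counts)
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    if method == "auto":
        n_minor = n_het + 2 * n_hom_minor
        method = "exact" if n_minor < 100 else "chi2"
    if method == "chi2":
        return hwe_chi2(n_hom_major, n_het, n_hom_minor)[1]
    if method == "exact":
        return hwe_exact_enumeration(n_hom_major, n_het, n_hom_minor)
    raise ValueError(f"unknown HWE method {method!r}")


@dataclass
class QCSummary:
    """Per-sample and per-variant QC metrics for a genotype matrix."""

    sample_call_rate: pd.Series
    variant_call_rate: pd.Series
    maf: pd.Series
    extra_allele_freq: pd.Series
    hwe_p_chi2: pd.Series
    hwe_p_exact: pd.Series
    hwe_p: pd.Series
    hwe_p_by_stratum: pd.DataFrame | None = None
    undefined_maf: list[str] = field(default_factory=list)
    swapped_orientation: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "call_rate": self.variant_call_rate,
                "maf": self.maf,
                "extra_allele_freq": self.extra_allele_freq,
                "hwe_p_chi2": self.hwe_p_chi2,
                "hwe_p_exact": self.hwe_p_exact,
                "hwe_p": self.hwe_p,
            }
        )

    def write(self, tsv_path=None, json_path=None) -> None:
        frame = self.to_frame()
        if tsv_path is not None:
            frame.to_csv(tsv_path, sep="\t", index_label="variant_id")
        if json_path is not None:
            payload = {
                "variants": frame.reset_index().rename(columns={"index": "variant_id"}).to_dict("records"),
                "sample_call_rate": {str(k): v for k, v in self.sample_call_rate.items()},
                "undefined_maf": self.undefined_maf,
                "swapped_orientation": self.swapped_orientation,
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=1, default=float)


def compute_qc(gm: GenotypeMatrix, case_labels: pd.Series | None = None) -> QCSummary:
    """Call rates, MAF, and HWE tests for every variant.

    Allele orientation is normalized first (minor = less frequent in data).
    If ``case_labels`` (binary series over samples) is given, HWE is also
    evaluated within cases and within controls, mirroring QC workflows that
    annotate departures by stratum.
    """
    if gm.n_samples == 0 or gm.n_variants == 0:
        raise ValueError("empty genotype matrix")
    gm, swapped = normalize_orientation(gm)
    present = gm.calls.notna()
    sample_cr = present.mean(axis=1)
    variant_cr = present.mean(axis=0)

    maf = {}
    extra_freq = {}
    p_chi2 = {}
    p_exact = {}
    p_auto = {}
    undefined = []
    strata_rows = {}
    for v in gm.variants:
        vid = v.variant_id
        col = gm.calls[vid].dropna()
        if len(col) == 0:
            undefined.append(vid)
            maf[vid] = np.nan
            extra_freq[vid] = np.nan
            p_chi2[vid] = np.nan
            p_exact[vid] = np.nan
            p_auto[vid] = np.nan
            continue
        if v.extra_allele is not None:
            n_extra = gm.allele_counts(vid, v.extra_allele).sum()
            extra_freq[vid] = float(n_extra / (2 * len(col)))
        else:
            extra_freq[vid] = 0.0
        d = gm.dosage(vid).dropna()
        maf[vid] = float(d.sum() / (2 * len(d))) if len(d) else np.nan
        counts = gm.genotype_counts(vid)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_chi2[vid] = hwe_chi2(*counts)[1]
            p_exact[vid] = hwe_exact_enumeration(*counts)
            p_auto[vid] = hwe_test(counts, method="auto")
            if case_labels is not None:
                labels = case_labels.reindex(gm.calls.index)
                row = {}
                for name, mask in (("cases", labels == 1), ("controls", labels == 0)):
                    sub = gm.subset(samples=gm.calls.index[mask.fillna(False)])
                    row[name] = hwe_test(sub.genotype_counts(vid), method="auto")
                strata_rows[vid] = row
    idx = gm.variant_ids
    return QCSummary(
        sample_call_rate=sample_cr,
        variant_call_rate=variant_cr,
        maf=pd.Series(maf).reindex(idx),
        extra_allele_freq=pd.Series(extra_freq).reindex(idx),
        hwe_p_chi2=pd.Series(p_chi2).reindex(idx),
        hwe_p_exact=pd.Series(p_exact).reindex(idx),
        hwe_p=pd.Series(p_auto).reindex(idx),
        hwe_p_by_stratum=pd.DataFrame(strata_rows).T if strata_rows else None,
        undefined_maf=undefined,
        swapped_orientation=swapped,
    )


def filter_variants(
    gm: GenotypeMatrix,
    qc: QCSummary,
    min_call_rate: float = 0.9,
    min_sample_call_rate: float | None = None,
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop variants (and optionally samples) below the call-rate threshold.

    Returns the filtered matrix and a log of drop reasons.  Dropping every
    variant is fatal.
    """
    if not 0.0 <= min_call_rate <= 1.0:
        raise ValueError("min_call_rate must be in [0, 1]")
    log: list[str] = []
    keep_variants = []
    for vid in gm.variant_ids:
        cr = qc.variant_call_rate.get(vid, np.nan)
        if cr < min_call_rate:
            log.append(f"variant {vid}: call rate {cr:.4f} < {min_call_rate}")
        else:
            keep_variants.append(vid)
    if not keep_variants:
        raise ValueError(f"all {gm.n_variants} variants dropped at threshold {min_call_rate}; " + "; ".join(log))
    keep_samples = gm.samples
    if min_sample_call_rate is not None:
        if not 0.0 <= min_sample_call_rate <= 1.0:
            raise ValueError("min_sample_call_rate must be in [0, 1]")
        keep_samples = []
        for s in gm.samples:
            cr = qc.sample_call_rate.get(s, np.nan)
            if cr < min_sample_call_rate:
                log.append(f"sample {s}: call rate {cr:.4f} < {min_sample_call_rate}")
            else:
                keep_samples.append(s)
        if not keep_samples:
            raise ValueError("all samples dropped")
    return gm.subset(samples=keep_samples, variant_ids=keep_variants), log
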