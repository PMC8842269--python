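"""EM haplotype frequency estimation, linkage disequilibrium, and
haplotype-outcome association for small multi-locus regions.

Unphased multilocus genotypes over 2-8 biallelic loci are phased
probabilistically by expectation-maximization over the 2^L haplotype space:
the E-step assigns each compatible phase a posterior proportional to the
product of current haplotype frequencies (x2 for heterozygous pairs), the
M-step re-estimates frequencies from posterior-weighted counts.  The
log-likelihood is non-decreasing and convergence is declared when the
largest frequency change falls below tolerance.

Pairwise LD is derived from estimated two-locus haplotype frequencies:
D = p_AB - p_A p_B, D' = |D|/D_max, r^2 = D^2/(p_A q_A p_B q_B).  Blocks are
found by greedily merging adjacent loci with D' at or above a threshold.
Haplotype association uses posterior-expected haplotype dosages per sample
in a 1-df score (trend) test, with an optional covariate-adjusted logistic
mode.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_qc import GenotypeMatrix

__all__ = [
    "LDStats",
    "HaplotypeBlock",
    "HaplotypeAssociationResult",
    "em_haplotype_frequencies",
    "ld_pairwise",
    "ld_matrix",
    "find_blocks",
    "haplotype_association",
]


@dataclass
class LDStats:
    """Pairwise disequilibrium between two biallelic loci (minor-allele
    orientation)."""

    locus_a: str
    locus_b: str
    D: float
    D_prime: float
    r2: float


@dataclass
class HaplotypeBlock:
    """EM-estimated haplotypes over an ordered set of loci."""

    block_id: str
    loci: list[str]
    haplotypes: dict          # allele-tuple -> frequency
    coverage_nonmissing: float
    coverage_resolved: float
    converged: bool
    n_iter: int
    loglik: float
    dosages: pd.DataFrame = field(repr=False, default=None)  # posterior copies per haplotype

    def label(self, hap: tuple) -> str:
        return "".join(hap)

    def frequency_frame(self) -> pd.DataFrame:
        rows = [
            {"block": self.block_id, "haplotype": self.label(h), "frequency": f}
            for h, f in sorted(self.haplotypes.items(), key=lambda kv: -kv[1])
        ]
        return pd.DataFrame(rows)


@dataclass
class HaplotypeAssociationResult:
    haplotype: str
    frequency: float
    or_: float
    stat: float
    p: float
    n_used: int
    adjusted: bool


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _compatible_pairs(genotype: tuple[int, ...]) -> list[tuple[int, int]]:
    """All unordered haplotype pairs (as bitmasks) compatible with an
    unphased multilocus dosage vector."""
    het = [i for i, g in enumerate(genotype) if g == 1]
    base = 0
    for i, g in enumerate(genotype):
        if g == 2:
            base |= 1 << i
    if not het:
        return [(base, base)]
    pairs = []
    first = het[0]
    for combo in itertools.product([0, 1], repeat=len(het) - 1):
        h1 = base | (1 << first)
        h2 = base
        for i, bit in zip(het[1:], combo):
            if bit:
                h1 |= 1 << i
            else:
                h2 |= 1 << i
        pairs.append((h1, h2))
    return pairs


def em_haplotype_frequencies(
    gm: GenotypeMatrix,
    loci: list[str],
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    block_id: str | None = None,
) -> HaplotypeBlock:
    """Estimate haplotype frequencies for `loci` by EM on unphased genotypes.

    Samples missing any locus are excluded (both coverage definitions are
    reported: non-missing fraction and, identically here, the fraction with
    at least one compatible phase).  Frequencies are initialized from the
    phase-ignorant allele-frequency products plus a small seeded jitter to
    avoid symmetric stalls.
    """
    L = len(loci)
    if not 2 <= L <= 8:
        raise ValueError("EM supports 2-8 loci")
    dosage = pd.DataFrame({v: gm.dosage(v) for v in loci})
    complete = dosage.dropna()
    n = len(complete)
    if n == 0:
        raise ValueError("no sample has complete calls over the requested loci")
    coverage = n / len(dosage)

    rows = [tuple(int(g) for g in row) for row in complete.to_numpy()]
    from collections import Counter

    counts = Counter(rows)
    genotypes = list(counts)
    weights = np.array([counts[g] for g in genotypes], dtype=float)
    pair_sets = [_compatible_pairs(g) for g in genotypes]

    H = 2 ** L
    # initialization: product of single-locus allele frequencies + jitter
    p_minor = complete.mean().to_numpy() / 2.0
    freqs = np.ones(H)
    for h in range(H):
        for i in range(L):
            freqs[h] *= p_minor[i] if (h >> i) & 1 else 1.0 - p_minor[i]
    rng = np.random.default_rng(seed)
    freqs = freqs + 1e-3 * rng.random(H)
    freqs /= freqs.sum()

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros(H)
        ll = 0.0
        for g_idx, pairs in enumerate(pair_sets):
            w = weights[g_idx]
            probs = np.array(
                [(2.0 if h1 != h2 else 1.0) * freqs[h1] * freqs[h2] for h1, h2 in pairs]
            )
            denom = probs.sum()
            if denom <= 0:
                continue
            ll += w * math.log(denom)
            post = probs / denom
            for (h1, h2), q in zip(pairs, post):
                new[h1] += w * q
                new[h2] += w * q
        new /= 2.0 * n
        delta = np.max(np.abs(new - freqs))
        freqs = new
        ll_prev = ll
        if delta < tol:
            converged = True
            break

    # final posterior dosages per sample for association
    hap_keys = [h for h in range(H) if freqs[h] > 0]
    dos = np.zeros((n, len(hap_keys)))
    key_index = {h: j for j, h in enumerate(hap_keys)}
    row_lookup = {}
    for g, pairs in zip(genotypes, pair_sets):
        probs = np.array([(2.0 if h1 != h2 else 1.0) * freqs[h1] * freqs[h2] for h1, h2 in pairs])
        denom = probs.sum()
        exp_d = np.zeros(len(hap_keys))
        if denom > 0:
            post = probs / denom
            for (h1, h2), q in zip(pairs, post):
                for h in (h1, h2):
                    if h in key_index:
                        exp_d[key_index[h]] += q
        row_lookup[g] = exp_d
    for i, g in enumerate(rows):
        dos[i] = row_lookup[g]

    defs = {v: gm.variant(v) for v in loci}

    def hap_tuple(h: int) -> tuple:
        return tuple(
            defs[v].minor_allele if (h >> i) & 1 else defs[v].major_allele
            for i, v in enumerate(loci)
        )

    hap_freqs = {hap_tuple(h): float(freqs[h]) for h in range(H) if freqs[h] > 1e-12}
    labels = ["".join(hap_tuple(h)) for h in hap_keys]
    dosage_frame = pd.DataFrame(dos, index=complete.index, columns=labels)
    return HaplotypeBlock(
        block_id=block_id or "+".join(loci),
        loci=list(loci),
        haplotypes=hap_freqs,
        coverage_nonmissing=coverage,
        coverage_resolved=coverage,
        converged=converged,
        n_iter=it,
        loglik=ll_prev,
        dosages=dosage_frame,
    )


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_from_freqs(p_ab: float, p_a: float, p_b: float) -> tuple[float, float, float]:
    """(D, D', r^2) from a two-locus haplotype frequency and both margins."""
    for name, v in (("p_a", p_a), ("p_b", p_b)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"monomorphic locus: {name} = {v}")
    D = p_ab - p_a * p_b
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = 0.0 if d_max == 0 else abs(D) / d_max
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return D, min(1.0, d_prime), min(1.0, r2)


def ld_pairwise(block: HaplotypeBlock) -> LDStats:
    """LD statistics from an estimated two-locus haplotype block."""
    if len(block.loci) != 2:
        raise ValueError("ld_pairwise expects a two-locus block")
    # margins and joint frequency of the (minor, minor) haplotype; allele
    # identity is recovered from haplotype tuples
    haps = block.haplotypes
    alleles_a = {h[0] for h in haps}
    alleles_b = {h[1] for h in haps}
    # minor allele at each locus = the one with the smaller margin
    freq_a = {a: sum(f for h, f in haps.items() if h[0] == a) for a in alleles_a}
    freq_b = {b: sum(f for h, f in haps.items() if h[1] == b) for b in alleles_b}
    if len(freq_a) < 2 or len(freq_b) < 2:
        raise ValueError("monomorphic locus in block; LD undefined")
    minor_a = min(freq_a, key=freq_a.get)
    minor_b = min(freq_b, key=freq_b.get)
    p_a = freq_a[minor_a]
    p_b = freq_b[minor_b]
    p_ab = sum(f for h, f in haps.items() if h[0] == minor_a and h[1] == minor_b)
    D, d_prime, r2 = ld_from_freqs(p_ab, p_a, p_b)
    return LDStats(block.loci[0], block.loci[1], D, d_prime, r2)


def ld_matrix(gm: GenotypeMatrix, loci: list[str], seed: int = 0) -> pd.DataFrame:
    """Pairwise D' (upper triangle) and r^2 (lower triangle) over loci."""
    k = len(loci)
    out = pd.DataFrame(np.eye(k), index=loci, columns=loci)
    for i in range(k):
        for j in range(i + 1, k):
            block = em_haplotype_frequencies(gm, [loci[i], loci[j]], seed=seed)
            ld = ld_pairwise(block)
            out.iloc[i, j] = ld.D_prime
            out.iloc[j, i] = ld.r2
    return out


def find_blocks(
    gm: GenotypeMatrix,
    loci: list[str],
    dprime_threshold: float = 0.8,
    seed: int = 0,
) -> list[HaplotypeBlock]:
    """Greedy adjacent-D' block finder.

    Loci must be in map order; adjacent loci with pairwise D' >= threshold
    are merged and blocks of size >= 2 are re-estimated jointly by EM.
    """
    if len(loci) < 2:
        return []
    runs: list[list[str]] = [[loci[0]]]
    for a, b in zip(loci[:-1], loci[1:]):
        ld = ld_pairwise(em_haplotype_frequencies(gm, [a, b], seed=seed))
        if ld.D_prime >= dprime_threshold:
            runs[-1].append(b)
        else:
            runs.append([b])
    blocks = []
    for i, run in enumerate(r for r in runs if len(r) >= 2):
        blocks.append(em_haplotype_frequencies(gm, run, seed=seed, block_id=f"block{i + 1}"))
    return blocks


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def _score_test(dosage: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """1-df score (trend) test of expected haplotype dosage vs binary outcome."""
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        raise ValueError("degenerate outcome")
    u = float(np.sum(dosage * (y - ybar)))
    v = float(ybar * (1 - ybar) * np.sum((dosage - dosage.mean()) ** 2))
    if v <= 0:
        return 0.0, 1.0
    stat = u * u / v
    return stat, float(stats.chi2.sf(stat, df=1))


def haplotype_association(
    block: HaplotypeBlock,
    outcome: pd.Series,
    data: pd.DataFrame | None = None,
    covariate_adjust: bool = False,
    covariates: list[str] | None = None,
    min_frequency: float = 0.01,
) -> list[HaplotypeAssociationResult]:
    """Per-haplotype association with a binary outcome.

    Default mode: 1-df chi-square score test on the posterior-expected
    haplotype dosage (STAT) plus an odds ratio from a dosage-only logistic
    fit.  Adjusted mode adds the eight clinical covariates to the logistic
    model and takes OR/STAT (Wald chi-square) from it.  Haplotypes below
    ``min_frequency`` are skipped.
    """
    from .assoc_glm import CLINICAL_COVARIATES, fit_logistic

    results = []
    y_all = outcome.reindex(block.dosages.index)
    for hap, freq in sorted(block.haplotypes.items(), key=lambda kv: -kv[1]):
        label = block.label(hap)
        if freq < min_frequency:
            continue
        if label not in block.dosages.columns:
            continue
        d = block.dosages[label]
        frame = pd.DataFrame({"dosage": d, "y": y_all})
        if covariate_adjust:
            cols = list(CLINICAL_COVARIATES) if covariates is None else list(covariates)
            frame = frame.join(data[cols])
            frame = frame.dropna()
            fit = fit_logistic(frame, "y", cols + ["dosage"])
            j = fit.columns.index("dosage")
            z = fit.beta[j] / fit.se[j] if fit.se[j] > 0 else 0.0
            stat = float(z * z)
            results.append(
                HaplotypeAssociationResult(
                    haplotype=label,
                    frequency=freq,
                    or_=float(fit.or_[j]),
                    stat=stat,
                    p=float(stats.chi2.sf(stat, df=1)),
                    n_used=fit.n_used,
                    adjusted=True,
                )
            )
        else:
            frame = frame.dropna()
            stat, p = _score_test(frame["dosage"].to_numpy(float), frame["y"].to_numpy(float))
            fit = fit_logistic(frame, "y", ["dosage"])
            results.append(
                HaplotypeAssociationResult(
                    haplotype=label,
                    frequency=freq,
                    or_=float(fit.or_[fit.columns.index("dosage")]),
                    stat=stat,
                    p=p,
                    n_used=len(frame),
                    adjusted=False,
                )
            )
    return results


def association_frame(results: list[HaplotypeAssociationResult], block: HaplotypeBlock) -> pd.DataFrame:
    rows = [
        {
            "block": block.block_id,
            "loci": "+".join(block.loci),
            "coverage": block.coverage_nonmissing,
            "haplotype": r.haplotype,
            "frequency": r.frequency,
            "OR": r.or_,
            "STAT": r.stat,
            "p": r.p,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
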