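"""EM haplotype frequencies, LD statistics, block finding, association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ponvkit.cohort_synth import LocusSpec, generate_genotypes
from ponvkit.defaults import default_loci
from ponvkit.genotype_qc import GenotypeMatrix, VariantDef
from ponvkit.haplotype import (
    em_haplotype_frequencies,
    find_blocks,
    haplotype_association,
    ld_from_freqs,
    ld_pairwise,
)

TWO_LOCI = [VariantDef("L1", "1", "A", "a"), VariantDef("L2", "1", "B", "b")]


def _gm(col1, col2):
    idx = pd.Index([f"s{i}" for i in range(len(col1))], name="sample_id")
    return GenotypeMatrix(
        pd.DataFrame({"L1": col1, "L2": col2}, index=idx, dtype=object), TWO_LOCI
    )


# ---------------------------------------------------------------------------
# Grid-search oracle for two-locus EM (exhaustive over the 3-simplex)
# ---------------------------------------------------------------------------

def grid_oracle_two_locus(dosage_rows, coarse=0.005, fine=0.001):
    """Maximize the multinomial phase-summed likelihood over the 4-haplotype
    simplex by grid search (coarse pass + 1e-3 local refinement)."""
    hap_bits = [(0, 0), (1, 0), (0, 1), (1, 1)]  # (minor at L1, minor at L2)

    def pair_terms(genotype):
        het = [i for i in range(2) if genotype[i] == 1]
        base = [1 if genotype[i] == 2 else 0 for i in range(2)]
        if not het:
            h = hap_bits.index(tuple(base))
            return [(h, h)]
        if len(het) == 1:
            h1b, h2b = list(base), list(base)
            h1b[het[0]] = 1
            return [(hap_bits.index(tuple(h1b)), hap_bits.index(tuple(h2b)))]
        return [(hap_bits.index((1, 0)), hap_bits.index((0, 1))),
                (hap_bits.index((1, 1)), hap_bits.index((0, 0)))]

    terms = [pair_terms(g) for g in dosage_rows]

    def loglik(freqs):
        ll = 0.0
        for pairs in terms:
            p = sum((2.0 if h1 != h2 else 1.0) * freqs[h1] * freqs[h2] for h1, h2 in pairs)
            if p <= 0:
                return -np.inf
            ll += np.log(p)
        return ll

    def search(lo, hi, step):
        best, best_ll = None, -np.inf
        ticks = np.arange(lo[0], hi[0] + step / 2, step)
        ticks2 = np.arange(lo[1], hi[1] + step / 2, step)
        ticks3 = np.arange(lo[2], hi[2] + step / 2, step)
        for f1 in ticks:
            for f2 in ticks2:
                if f1 + f2 > 1:
                    break
                for f3 in ticks3:
                    f4 = 1.0 - f1 - f2 - f3
                    if f4 < -1e-12:
                        break
                    ll = loglik((f1, f2, f3, max(f4, 0.0)))
                    if ll > best_ll:
                        best, best_ll = (f1, f2, f3, max(f4, 0.0)), ll
        return best

    c = search((0, 0, 0), (1, 1, 1), coarse)
    lo = tuple(max(0.0, x - 2 * coarse) for x in c[:3])
    hi = tuple(min(1.0, x + 2 * coarse) for x in c[:3])
    return search(lo, hi, fine)


def test_unambiguous_homozygotes_give_single_haplotype():
    gm = _gm(["A/A"] * 4, ["B/B"] * 4)
    block = em_haplotype_frequencies(gm, ["L1", "L2"])
    assert block.haplotypes[("A", "B")] == pytest.approx(1.0, abs=1e-9)
    assert block.converged


@pytest.mark.parametrize(
    "col1,col2",
    [
        (["A/a", "A/A", "a/a"], ["B/b", "B/B", "b/b"]),          # one double-het
        (["A/a", "A/a", "A/A", "a/a"], ["B/b", "B/b", "B/b", "B/B"]),
        (["A/a"] * 3 + ["A/A"], ["B/b"] * 3 + ["b/b"]),
    ],
)
def test_em_matches_exhaustive_grid_oracle(col1, col2):
    gm = _gm(col1, col2)
    block = em_haplotype_frequencies(gm, ["L1", "L2"], tol=1e-10)
    dosage_rows = [
        tuple(int(gm.dosage(l)[s]) for l in ("L1", "L2")) for s in gm.samples
    ]
    oracle = grid_oracle_two_locus(dosage_rows)
    # oracle haplotype order: (major,major), (minor,major), (major,minor), (minor,minor)
    hap_order = [("A", "B"), ("a", "B"), ("A", "b"), ("a", "b")]
    est = [block.haplotypes.get(h, 0.0) for h in hap_order]
    for e, o in zip(est, oracle):
        assert e == pytest.approx(o, abs=1.5e-3)


def test_em_frequencies_sum_to_one_and_loglik_finite(default_cohort):
    gm = default_cohort.genotype_matrix
    block = em_haplotype_frequencies(gm, ["rs76124337", "rs3782025"], seed=1)
    assert sum(block.haplotypes.values()) == pytest.approx(1.0, abs=1e-6)
    assert np.isfinite(block.loglik)
    assert block.converged


def test_em_recovers_generating_block_frequency():
    haps = {("-", "G"): 0.33, ("CA", "G"): 0.11, ("CA", "A"): 0.56}
    loci = [
        LocusSpec("v1", 0.33, major_allele="CA", minor_allele="-", block_id="b", haplotype_freqs=haps),
        LocusSpec("v2", 0.44, major_allele="A", minor_allele="G", block_id="b", haplotype_freqs=haps),
    ]
    gm, truth = generate_genotypes(loci, 100_000, seed=13)
    block = em_haplotype_frequencies(gm, ["v1", "v2"], seed=0)
    assert block.haplotypes[("-", "G")] == pytest.approx(0.33, abs=0.01)
    # EM agrees with the retained phased truth
    blk = truth["blocks"]["b"]
    idx = blk["haplotypes"].index(("-", "G"))
    truth_freq = (np.concatenate([blk["h1"], blk["h2"]]) == idx).mean()
    assert block.haplotypes[("-", "G")] == pytest.approx(truth_freq, abs=0.005)


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------

def test_ld_hand_computed_example():
    D, d_prime, r2 = ld_from_freqs(0.4, 0.5, 0.6)
    assert D == pytest.approx(0.1)
    assert d_prime == pytest.approx(0.1 / 0.2)
    assert r2 == pytest.approx(0.01 / (0.25 * 0.24))


def test_perfect_ld_two_haplotypes():
    gm = _gm(["A/A", "a/a", "A/a", "a/a"], ["B/B", "b/b", "B/b", "b/b"])
    block = em_haplotype_frequencies(gm, ["L1", "L2"], tol=1e-10)
    ld = ld_pairwise(block)
    assert ld.D_prime == pytest.approx(1.0, abs=1e-6)
    assert ld.r2 == pytest.approx(1.0, abs=1e-6)


def test_independent_loci_have_near_zero_ld():
    gm1, _ = generate_genotypes(
        [LocusSpec("L1", 0.4, major_allele="A", minor_allele="a"),
         LocusSpec("L2", 0.3, major_allele="B", minor_allele="b")],
        20_000, seed=14,
    )
    block = em_haplotype_frequencies(gm1, ["L1", "L2"], seed=0)
    ld = ld_pairwise(block)
    assert abs(ld.D) < 0.01
    assert ld.r2 < 0.01


def test_dprime_is_one_when_a_haplotype_class_is_absent():
    # generating block lacks the '-'+'A' haplotype entirely
    haps = {("-", "G"): 0.33, ("CA", "G"): 0.11, ("CA", "A"): 0.56}
    loci = [
        LocusSpec("v1", 0.33, major_allele="CA", minor_allele="-", block_id="b", haplotype_freqs=haps),
        LocusSpec("v2", 0.44, major_allele="A", minor_allele="G", block_id="b", haplotype_freqs=haps),
    ]
    gm, _ = generate_genotypes(loci, 5_000, seed=15)
    ld = ld_pairwise(em_haplotype_frequencies(gm, ["v1", "v2"], seed=0))
    assert ld.D_prime > 0.95


def test_r2_invariant_to_allele_label_swap():
    gm, _ = generate_genotypes(
        [LocusSpec("L1", 0.4, major_allele="A", minor_allele="a"),
         LocusSpec("L2", 0.3, major_allele="B", minor_allele="b")],
        3_000, seed=16,
    )
    block = em_haplotype_frequencies(gm, ["L1", "L2"], seed=0)
    r2 = ld_pairwise(block).r2
    # relabel L1 alleles (swap major/minor symbols in the calls)
    swapped_calls = gm.calls.copy()
    swapped_calls["L1"] = swapped_calls["L1"].map(
        lambda c: c if pd.isna(c) else "/".join(sorted(("a" if x == "A" else "A") for x in c.split("/")))
    )
    gm_swapped = GenotypeMatrix(
        swapped_calls, [VariantDef("L1", "1", "a", "A"), VariantDef("L2", "1", "B", "b")]
    )
    block2 = em_haplotype_frequencies(gm_swapped, ["L1", "L2"], seed=0)
    assert ld_pairwise(block2).r2 == pytest.approx(r2, abs=1e-6)


def test_monomorphic_locus_ld_flagged():
    gm = _gm(["A/A"] * 5, ["B/b", "B/B", "b/b", "B/b", "B/B"])
    block = em_haplotype_frequencies(gm, ["L1", "L2"])
    with pytest.raises(ValueError, match="monomorphic"):
        ld_pairwise(block)


# ---------------------------------------------------------------------------
# Block detection
# ---------------------------------------------------------------------------

def test_three_blocks_recovered_from_default_structure():
    loci = [l for l in default_loci() if l.block_id is not None]
    gm, _ = generate_genotypes(loci, 1_000, seed=17)
    blocks = find_blocks(gm, [l.variant_id for l in loci], dprime_threshold=0.8)
    pairs = [tuple(b.loci) for b in blocks]
    assert pairs == [
        ("rs3758987", "rs45460698"),
        ("rs76124337", "rs3782025"),
        ("rs10160548", "rs1176713"),
    ]


def test_independent_loci_yield_no_blocks():
    gm, _ = generate_genotypes(
        [LocusSpec(f"L{i}", 0.3, major_allele="A", minor_allele="G") for i in range(4)],
        3_000, seed=18,
    )
    assert find_blocks(gm, [f"L{i}" for i in range(4)], dprime_threshold=0.8) == []


def test_threshold_zero_merges_everything():
    gm, _ = generate_genotypes(
        [LocusSpec(f"L{i}", 0.3, major_allele="A", minor_allele="G") for i in range(4)],
        500, seed=19,
    )
    blocks = find_blocks(gm, [f"L{i}" for i in range(4)], dprime_threshold=0.0)
    assert len(blocks) == 1
    assert blocks[0].loci == [f"L{i}" for i in range(4)]


# ---------------------------------------------------------------------------
# Association
# ---------------------------------------------------------------------------

def test_null_haplotype_stat_is_chi_square_one_df():
    rng = np.random.default_rng(20)
    stats_seen = []
    haps = {("-", "G"): 0.33, ("CA", "G"): 0.11, ("CA", "A"): 0.56}
    loci = [
        LocusSpec("v1", 0.33, major_allele="CA", minor_allele="-", block_id="b", haplotype_freqs=haps),
        LocusSpec("v2", 0.44, major_allele="A", minor_allele="G", block_id="b", haplotype_freqs=haps),
    ]
    for rep in range(60):
        gm, _ = generate_genotypes(loci, 800, seed=100 + rep)
        y = pd.Series(rng.integers(0, 2, 800), index=gm.calls.index)
        block = em_haplotype_frequencies(gm, ["v1", "v2"], seed=0)
        res = haplotype_association(block, y)
        stats_seen.extend(r.stat for r in res)
    assert np.mean(stats_seen) == pytest.approx(1.0, abs=0.25)


def test_unambiguous_phase_reduces_to_contingency_trend_test():
    """With no double heterozygotes, posterior dosages are exact counts and
    the STAT equals the Cochran-Armitage-style trend statistic computed from
    the 2x3 contingency table (independent oracle)."""
    col1 = ["A/A", "A/a", "a/a", "A/A", "A/a", "A/A", "a/a", "A/A"]
    col2 = ["B/B"] * 8  # second locus monomorphic -> phase always resolved
    y = pd.Series([1, 1, 1, 0, 0, 1, 0, 0])
    gm = _gm(col1, col2)
    y.index = gm.calls.index
    block = em_haplotype_frequencies(gm, ["L1", "L2"], tol=1e-12)
    res = {r.haplotype: r for r in haplotype_association(block, y)}
    # oracle for the 'aB' haplotype: dosage = minor-allele count at L1
    d = gm.dosage("L1").to_numpy()
    yv = y.to_numpy(float)
    u = np.sum(d * (yv - yv.mean()))
    v = yv.mean() * (1 - yv.mean()) * np.sum((d - d.mean()) ** 2)
    stat_oracle = u * u / v
    assert res["aB"].stat == pytest.approx(stat_oracle, abs=1e-6)
    assert res["aB"].p == pytest.approx(float(stats.chi2.sf(stat_oracle, 1)), abs=1e-9)


def test_rare_haplotypes_are_skipped():
    gm, _ = generate_genotypes(
        [LocusSpec("L1", 0.5, major_allele="A", minor_allele="a"),
         LocusSpec("L2", 0.5, major_allele="B", minor_allele="b")],
        2_000, seed=21,
    )
    rng = np.random.default_rng(21)
    y = pd.Series(rng.integers(0, 2, 2_000), index=gm.calls.index)
    block = em_haplotype_frequencies(gm, ["L1", "L2"], seed=0)
    res = haplotype_association(block, y, min_frequency=0.3)
    assert all(r.frequency >= 0.3 for r in res)
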