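"""HWE exact test, EM haplotype estimation, LD permutation, Bonferroni,
and synteny annotation."""

import numpy as np
import pytest

from _oracles import grid_search_ml, hwe_oracle
from iisnp.equilibrium import (
    _em_loglik,
    _em_run,
    annotate_synteny,
    bonferroni,
    em_haplotypes,
    hwe_exact,
    ld_permutation_test,
    tabulate_pair,
)
from iisnp.panel_io import ValidationError


# ---------------------------------------------------------------------------
# HWE exact test


def test_hwe_tiny_enumeration_examples():
    """n = 2 with one A-hom and one a-hom: only configs (1,0,1) w.p. 1/3 and
    (0,2,0) w.p. 2/3 exist."""
    assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3)
    assert hwe_exact(0, 2, 0) == pytest.approx(1.0)
    assert hwe_exact(50, 0, 0) == 1.0  # monomorphic


def test_hwe_matches_rational_oracle_small_n():
    """All genotype configurations with n <= 12 agree with the exact
    rational-arithmetic oracle (the acceptance run extends to n <= 30)."""
    for n in range(1, 13):
        for n_aa in range(n + 1):
            for n_het in range(n - n_aa + 1):
                n_bb = n - n_aa - n_het
                expected = float(hwe_oracle(n_aa, n_het, n_bb))
                assert hwe_exact(n_aa, n_het, n_bb) == pytest.approx(expected, rel=1e-9), (
                    n_aa, n_het, n_bb)


def test_hwe_rejects_negative_or_empty():
    with pytest.raises(ValidationError):
        hwe_exact(-1, 2, 3)
    with pytest.raises(ValidationError):
        hwe_exact(0, 0, 0)


def test_hwe_type_one_error_at_most_nominal():
    """Exact-test p-values under HWE are conservative: rejection rate at
    alpha = 0.05 stays within 3 SE above 0.05 over many simulated loci."""
    rng = np.random.default_rng(17)
    n_loci, n = 400, 120
    rejections = 0
    for _ in range(n_loci):
        p = rng.uniform(0.2, 0.8)
        g = rng.binomial(2, p, size=n)
        if hwe_exact(int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())) < 0.05:
            rejections += 1
    se = np.sqrt(0.05 * 0.95 / n_loci)
    assert rejections / n_loci <= 0.05 + 3 * se


# ---------------------------------------------------------------------------
# EM haplotype frequencies


def test_em_without_double_hets_equals_direct_counting():
    """With no phase ambiguity, haplotypes are countable directly."""
    # genotype pairs avoiding (1,1): e.g. (0,0) x4, (1,0) x2, (2,2) x2, (0,1) x2
    g1 = np.array([0, 0, 0, 0, 1, 1, 2, 2, 0, 0])
    g2 = np.array([0, 0, 0, 0, 0, 0, 2, 2, 1, 1])
    h, ll = em_haplotypes(g1, g2)
    # unambiguous gamete decomposition by hand (20 gametes):
    # (0,0)x4 -> 8 of 00; (1,0)x2 -> 00+10 each; (2,2)x2 -> 11+11 each; (0,1)x2 -> 00+01 each
    counts = np.array([12, 2, 2, 4], dtype=float)
    assert h == pytest.approx(counts / 20, abs=1e-9)


def test_em_symmetric_double_het():
    """All double heterozygotes: two mirror-image maxima with equal
    likelihood; the best-of-inits answer attains that likelihood."""
    g = np.ones(12, dtype=int)
    h, ll = em_haplotypes(g, g)
    mirror = h[[3, 2, 1, 0]]
    ll_mirror = _em_loglik(mirror[None], tabulate_pair(g, g)[None].astype(float))[0]
    assert ll == pytest.approx(ll_mirror, abs=1e-9)
    assert h.sum() == pytest.approx(1.0)


def test_em_matches_grid_search_oracle():
    """EM frequencies land within 1e-4 of the grid-search ML optimum on
    random 50-sample instances (acceptance runs 50 replicates)."""
    rng = np.random.default_rng(23)
    for _ in range(5):
        hap_p = rng.dirichlet(np.ones(4) * 2)
        haps = rng.choice(4, size=(50, 2), p=hap_p)
        g1 = (haps // 2).sum(axis=1)
        g2 = (haps % 2).sum(axis=1)
        h_em, ll_em = em_haplotypes(g1, g2)
        h_grid = grid_search_ml(tabulate_pair(g1, g2))
        assert np.abs(h_em - h_grid).max() < 1e-4


def test_em_loglik_nondecreasing_over_iterations():
    rng = np.random.default_rng(31)
    g1 = rng.binomial(2, 0.4, size=60)
    g2 = rng.binomial(2, 0.5, size=60)
    table = tabulate_pair(g1, g2)[None].astype(float)
    h0 = np.full((1, 4), 0.25)
    lls = []
    for k in range(1, 25):
        h = _em_run(table, h0, tol=0.0, max_iter=k)
        lls.append(_em_loglik(h, table)[0])
    assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))


# ---------------------------------------------------------------------------
# LD permutation test


def test_complete_ld_hits_permutation_floor():
    """D' = 1 with common alleles: the observed LR beats every permutation."""
    rng = np.random.default_rng(5)
    hap = rng.binomial(1, 0.5, size=(200, 2))
    g1 = hap.sum(axis=1)
    g2 = g1.copy()  # same haplotypes at both loci: complete LD
    res = ld_permutation_test(g1, g2, n_permutations=999, seed=11)
    assert res.p_value == pytest.approx(1 / 1000)
    assert res.lr_statistic > 0


def test_monomorphic_locus_gives_p_one():
    g1 = np.zeros(50, dtype=int)
    g2 = np.random.default_rng(0).binomial(2, 0.5, size=50)
    res = ld_permutation_test(g1, g2, n_permutations=100, seed=1)
    assert res.p_value == 1.0
    assert res.lr_statistic == 0.0
    assert res.monomorphic


def test_permutation_p_invariant_to_allele_relabeling():
    """Swapping which allele is 'ref' at a locus (dosage g -> 2 - g) leaves
    the LR and the permutation p-value unchanged."""
    rng = np.random.default_rng(9)
    g1 = rng.binomial(2, 0.35, size=120)
    g2 = rng.binomial(2, 0.6, size=120)
    a = ld_permutation_test(g1, g2, n_permutations=500, seed=77)
    b = ld_permutation_test(2 - g1, g2, n_permutations=500, seed=77)
    c = ld_permutation_test(g1, 2 - g2, n_permutations=500, seed=77)
    assert a.lr_statistic == pytest.approx(b.lr_statistic, abs=1e-8)
    assert a.lr_statistic == pytest.approx(c.lr_statistic, abs=1e-8)
    assert a.p_value == b.p_value == c.p_value


def test_independent_loci_p_values_roughly_uniform():
    """Under independence the p-value distribution is flat: the rejection
    rate at 0.05 stays near nominal (full-scale check in acceptance)."""
    rng = np.random.default_rng(13)
    ps = []
    for i in range(100):
        g1 = rng.binomial(2, 0.4, size=100)
        g2 = rng.binomial(2, 0.5, size=100)
        ps.append(ld_permutation_test(g1, g2, n_permutations=199, seed=1000 + i).p_value)
    frac = np.mean(np.asarray(ps) < 0.05)
    se = np.sqrt(0.05 * 0.95 / 100)
    assert frac <= 0.05 + 3 * se


# ---------------------------------------------------------------------------
# Bonferroni and synteny


def test_bonferroni_single_test_is_raw_threshold():
    assert bonferroni([0.04]).tolist() == [True]
    assert bonferroni([0.06]).tolist() == [False]


def test_bonferroni_study_scale_arithmetic():
    """p = 1e-4 does not survive correction over 4371 pairwise tests."""
    ps = np.full(4371, 0.5)
    ps[0] = 1e-4
    assert bonferroni(ps).sum() == 0  # 1e-4 > 0.05/4371
    ps[0] = 1e-5
    assert bool(bonferroni(ps)[0])  # 1e-5 < 0.05/4371


def test_bonferroni_uniform_p_values_rarely_survive():
    rng = np.random.default_rng(3)
    survivors = bonferroni(rng.uniform(size=100)).sum()
    assert survivors <= 1


def test_annotate_synteny():
    from iisnp.panel_io import SnpLocus

    loci = [
        SnpLocus("rs1355366", "chr3", 10_000_000, "A", "G", "forward", "AAAAA", 0),
        SnpLocus("rs1357617", "chr3", 200_000_000, "C", "T", "forward", "CCCCC", 0),
        SnpLocus("rs938283", "chr17", 5_000_000, "G", "A", "forward", "GGGGG", 0),
    ]
    syntenic, dist = annotate_synteny(("rs1355366", "rs1357617"), loci)
    assert syntenic and dist == 190_000_000  # the 190 Mb chr3 pair
    syntenic, dist = annotate_synteny(("rs1355366", "rs938283"), loci)
    assert not syntenic and dist is None
    with pytest.raises(ValidationError):
        annotate_synteny(("rs1355366", "rs1355366"), loci)
    with pytest.raises(KeyError):
        annotate_synteny(("rs1355366", "rsNOPE"), loci)
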