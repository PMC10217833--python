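"""Hardy-Weinberg and linkage-disequilibrium testing for biallelic loci.

HWE uses the exact conditional test: given the allele counts, the probability
of observing ``n_Aa`` heterozygotes under random mating is

    P(n_Aa | n, n_A) = 2^{n_Aa} n! n_A! n_a! / (n_AA! n_Aa! n_aa! (2n)!)

and the two-sided p-value sums the probabilities of all heterozygote counts
no more probable than the observed one.  For biallelic loci this enumeration
is tractable and deterministic, so no Markov-chain approximation is needed.

LD between two loci is tested with a likelihood-ratio statistic
``LR = 2 [lnL(EM haplotype frequencies) - lnL(allele-frequency product)]``
whose null distribution is built by permuting one locus's genotypes across
individuals, breaking any gametic association while preserving both marginal
genotype distributions.  Haplotype frequencies come from an EM algorithm over
the double-heterozygote phase ambiguity, run from multiple starts (uniform
and linkage-equilibrium product) and keeping the best likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from iisnp.panel_io import SnpLocus, ValidationError

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000
_TINY = 1e-300


@dataclass
class HweResult:
    rsid: str
    population: str
    n_aa_hom: int  # n_AA
    n_het: int     # n_Aa
    n_bb_hom: int  # n_aa
    p_value: float
    monomorphic: bool = False


@dataclass
class LdResult:
    rsid1: str
    rsid2: str
    population: str
    lr_statistic: float
    p_value: float
    n_permutations: int
    monomorphic: bool = False
    syntenic: bool | None = None
    distance_bp: int | None = None


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _hwe_log_probs(n_a: int, n_b: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-probabilities of every heterozygote count compatible with the
    allele counts (n_a, n_b); returns (het counts, log probs)."""
    n = (n_a + n_b) // 2
    hets = np.arange(n_a % 2, min(n_a, n_b) + 1, 2)
    n_aa = (n_a - hets) // 2
    n_bb = (n_b - hets) // 2
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1) + gammaln(n_a + 1) + gammaln(n_b + 1)
        - gammaln(n_aa + 1) - gammaln(hets + 1) - gammaln(n_bb + 1) - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact two-sided HWE p-value from the three genotype counts.

    Conditions on the observed allele counts; a monomorphic locus returns 1.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValidationError("hwe_exact needs at least one genotype")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    if n_a == 0 or n_b == 0:
        return 1.0
    hets, logp = _hwe_log_probs(n_a, n_b)
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(min(probs[probs <= observed * (1 + 1e-12)].sum(), 1.0))


def hwe_scan(calls: pd.DataFrame, grouping: str = "population") -> pd.DataFrame:
    """HWE exact test per locus (per population or pooled)."""
    called = calls[calls["status"] == "called"].copy()
    if grouping == "overall":
        called["population"] = "Overall"
    rows = []
    for (rsid, population), sub in called.groupby(["rsid", "population"], sort=True):
        alleles = sorted(set(sub["allele1"]) | set(sub["allele2"]))
        a = alleles[0]
        dosage = (sub["allele1"] == a).astype(int) + (sub["allele2"] == a).astype(int)
        n_aa_hom = int((dosage == 2).sum())
        n_het = int((dosage == 1).sum())
        n_bb_hom = int((dosage == 0).sum())
        rows.append(
            {
                "rsid": rsid, "population": population,
                "n_AA": n_aa_hom, "n_Aa": n_het, "n_aa": n_bb_hom,
                "p_value": hwe_exact(n_aa_hom, n_het, n_bb_hom),
                "monomorphic": len(alleles) < 2,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation (vectorized over batches of 3x3 tables)


def tabulate_pair(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype (alt-dosage) counts for one locus pair."""
    codes = 3 * g1 + g2
    return np.bincount(codes, minlength=9).reshape(3, 3)


def _em_loglik(h: np.ndarray, tables: np.ndarray) -> np.ndarray:
    """Log-likelihood of batched tables (B,3,3) under haplotype freqs (B,4)."""
    h00, h01, h10, h11 = h[:, 0], h[:, 1], h[:, 2], h[:, 3]
    p = np.empty((h.shape[0], 9))
    p[:, 0] = h00 ** 2            # (0,0)
    p[:, 1] = 2 * h00 * h01       # (0,1)
    p[:, 2] = h01 ** 2            # (0,2)
    p[:, 3] = 2 * h00 * h10       # (1,0)
    p[:, 4] = 2 * h00 * h11 + 2 * h01 * h10  # (1,1) both phases
    p[:, 5] = 2 * h01 * h11       # (1,2)
    p[:, 6] = h10 ** 2            # (2,0)
    p[:, 7] = 2 * h10 * h11      # (2,1)
    p[:, 8] = h11 ** 2            # (2,2)
    n = tables.reshape(-1, 9)
    return np.where(n > 0, n * np.log(np.maximum(p, _TINY)), 0.0).sum(axis=1)


def _em_run(tables: np.ndarray, h0: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """EM iterations from one start; returns converged frequencies (B,4)."""
    n = tables.reshape(-1, 9).astype(float)
    two_n = n.sum(axis=1) * 2.0
    h = h0.copy()
    for _ in range(max_iter):
        h00, h01, h10, h11 = h[:, 0], h[:, 1], h[:, 2], h[:, 3]
        denom = np.maximum(h00 * h11 + h01 * h10, _TINY)
        alpha = (h00 * h11) / denom  # P(phase 00/11 | double het)
        c00 = 2 * n[:, 0] + n[:, 1] + n[:, 3] + alpha * n[:, 4]
        c01 = n[:, 1] + 2 * n[:, 2] + n[:, 5] + (1 - alpha) * n[:, 4]
        c10 = n[:, 3] + 2 * n[:, 6] + n[:, 7] + (1 - alpha) * n[:, 4]
        c11 = n[:, 5] + n[:, 7] + 2 * n[:, 8] + alpha * n[:, 4]
        h_new = np.stack([c00, c01, c10, c11], axis=1) / two_n[:, None]
        delta = np.abs(h_new - h).max()
        h = h_new
        if delta < tol:
            break
    return h


def _allele_freqs(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alt-allele frequencies (p1, p2) per batched table."""
    n = tables.reshape(-1, 9).astype(float)
    two_n = n.sum(axis=1) * 2.0
    g1 = np.repeat(np.arange(3), 3)[None, :]
    g2 = np.tile(np.arange(3), 3)[None, :]
    p1 = (n * g1).sum(axis=1) / two_n
    p2 = (n * g2).sum(axis=1) / two_n
    return p1, p2


def _em_batch(tables: np.ndarray, n_inits: int = 2, tol: float = _EM_TOL,
              max_iter: int = _EM_MAX_ITER) -> tuple[np.ndarray, np.ndarray]:
    """Best-of-initializations EM over a batch of 3x3 tables.

    Returns (haplotype freqs (B,4) in order 00,01,10,11 of alt dosage,
    log-likelihoods (B,)).
    """
    B = tables.reshape(-1, 9).shape[0]
    p1, p2 = _allele_freqs(tables)
    inits = [np.full((B, 4), 0.25)]
    if n_inits >= 2:
        le = np.stack([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2], axis=1)
        inits.append(np.clip(le, 1e-6, None) / np.clip(le, 1e-6, None).sum(axis=1, keepdims=True))
    best_h, best_ll = None, None
    for h0 in inits[:max(n_inits, 1)]:
        h = _em_run(tables, h0, tol, max_iter)
        ll = _em_loglik(h, tables)
        if best_ll is None:
            best_h, best_ll = h, ll
        else:
            better = ll > best_ll
            best_h = np.where(better[:, None], h, best_h)
            best_ll = np.maximum(ll, best_ll)
    return best_h, best_ll


def em_haplotypes(g1: np.ndarray, g2: np.ndarray, n_inits: int = 2) -> tuple[np.ndarray, float]:
    """Two-locus haplotype frequencies by EM from unphased genotypes.

    ``g1``/``g2`` are alt-allele dosages (0/1/2) per individual; entries
    negative or NaN in either vector are dropped.  Returns the haplotype
    frequency vector (order: ref-ref, ref-alt, alt-ref, alt-alt) and the
    log-likelihood at the best of ``n_inits`` starts.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValidationError("genotype vectors must have equal length")
    keep = ~(np.isnan(g1) | np.isnan(g2) | (g1 < 0) | (g2 < 0))
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    if g1.size == 0:
        raise KeyError("em_haplotypes: no sample with both loci called")
    table = tabulate_pair(g1, g2)[None, :, :]
    h, ll = _em_batch(table, n_inits=n_inits)
    return h[0], float(ll[0])


def _lr_statistics(tables: np.ndarray, n_inits: int = 2) -> np.ndarray:
    """Batched LR = 2 (lnL_EM - lnL_independence), clipped at 0."""
    _, ll_em = _em_batch(tables, n_inits=n_inits)
    p1, p2 = _allele_freqs(tables)
    h0 = np.stack([(1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2], axis=1)
    ll0 = _em_loglik(h0, tables)
    return np.maximum(2.0 * (ll_em - ll0), 0.0)


def ld_permutation_test(
    g1: np.ndarray,
    g2: np.ndarray,
    n_permutations: int = 10000,
    seed: int | None = None,
    rsid1: str = "",
    rsid2: str = "",
    population: str = "",
    n_inits: int = 2,
) -> LdResult:
    """Permutation LR test of gametic association between two loci.

    One locus's genotype column is permuted across individuals to build the
    null; ``p = (1 + #{perm LR >= observed}) / (n_permutations + 1)``, so the
    smallest attainable p-value is 1/(n_permutations + 1).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    keep = ~(np.isnan(g1) | np.isnan(g2) | (g1 < 0) | (g2 < 0))
    g1, g2 = g1[keep].astype(int), g2[keep].astype(int)
    if g1.size == 0:
        raise KeyError("ld_permutation_test: no sample with both loci called")
    if len(np.unique(g1)) == 1 and g1[0] in (0, 2) or len(np.unique(g2)) == 1 and g2[0] in (0, 2):
        return LdResult(rsid1, rsid2, population, 0.0, 1.0, n_permutations, monomorphic=True)

    observed = float(_lr_statistics(tabulate_pair(g1, g2)[None])[0])

    rng = np.random.default_rng(seed)
    n = g1.size
    perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
    codes = 3 * g1[None, :] + g2[perm_idx]
    offsets = 9 * np.arange(n_permutations)[:, None]
    tables = np.bincount((codes + offsets).ravel(), minlength=9 * n_permutations).reshape(n_permutations, 3, 3)
    null = _lr_statistics(tables, n_inits=n_inits)
    p = (1.0 + float(np.sum(null >= observed - 1e-12))) / (n_permutations + 1.0)
    return LdResult(rsid1, rsid2, population, observed, p, n_permutations)


# ---------------------------------------------------------------------------
# Multiple testing and synteny


def bonferroni(p_values: "np.ndarray | list[float]", alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of tests significant after Bonferroni correction.

    ``m`` is the number of tests actually performed in the batch, i.e.
    ``len(p_values)``; a test survives iff ``p < alpha / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValidationError("bonferroni requires at least one p-value")
    return p < alpha / p.size


def annotate_synteny(pair: tuple[str, str], panel: "list[SnpLocus]") -> tuple[bool, int | None]:
    """Whether two panel loci share a chromosome, and their distance if so."""
    rsid1, rsid2 = pair
    if rsid1 == rsid2:
        raise ValidationError(f"self-pair {rsid1} is not a valid locus pair")
    by_rsid = {l.rsid: l for l in panel}
    try:
        l1, l2 = by_rsid[rsid1], by_rsid[rsid2]
    except KeyError as exc:
        raise KeyError(f"rsid {exc} not in panel") from exc
    if l1.chrom != l2.chrom:
        return False, None
    return True, abs(l1.pos - l2.pos)


def dosage_matrix(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Samples x loci alt-dosage matrix from a genotype table.

    The "reference" allele per locus is the lexicographically smallest
    observed allele (the test statistics are invariant to this choice).
    No-calls become NaN.  Returns (matrix, reference allele per locus).
    """
    called = calls[calls["status"] == "called"]
    ref_allele = {
        rsid: sorted(set(sub["allele1"]) | set(sub["allele2"]))[0]
        for rsid, sub in called.groupby("rsid")
    }
    dosage = called.apply(
        lambda r: (r["allele1"] != ref_allele[r["rsid"]]) + (r["allele2"] != ref_allele[r["rsid"]]),
        axis=1,
    )
    mat = (
        called.assign(dosage=dosage)
        .pivot_table(index="sample_id", columns="rsid", values="dosage", aggfunc="first")
    )
    return mat, ref_allele


def ld_scan(
    calls: pd.DataFrame,
    panel: "list[SnpLocus]",
    n_permutations: int = 10000,
    seed: int | None = None,
    grouping: str = "population",
) -> pd.DataFrame:
    """All-pairs LD permutation tests, per population, with synteny annotation."""
    work = calls.copy()
    if grouping == "overall":
        work["population"] = "Overall"
    rng = np.random.default_rng(seed)
    rows = []
    for population, sub in work.groupby("population", sort=True):
        mat, _ = dosage_matrix(sub)
        loci = sorted(mat.columns)
        for i, r1 in enumerate(loci):
            for r2 in loci[i + 1:]:
                res = ld_permutation_test(
                    mat[r1].to_numpy(), mat[r2].to_numpy(),
                    n_permutations=n_permutations,
                    seed=int(rng.integers(2**31)),
                    rsid1=r1, rsid2=r2, population=population,
                )
                syntenic, dist = annotate_synteny((r1, r2), panel)
                rows.append(
                    {
                        "rsid1": r1, "rsid2": r2, "population": population,
                        "lr_statistic": res.lr_statistic, "p_value": res.p_value,
                        "n_permutations": res.n_permutations,
                        "syntenic": syntenic, "distance_bp": dist if dist is not None else "",
                    }
                )
    return pd.DataFrame(rows)
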