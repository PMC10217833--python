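"""Independent oracles shared between unit and acceptance tests.

These deliberately avoid the code paths they check: the HWE oracle works in
exact rational arithmetic from combinatorial counts, and the EM oracle is a
nested grid search over the haplotype simplex.
"""

import itertools
from fractions import Fraction
from math import comb

import numpy as np

from iisnp.equilibrium import _em_loglik


def hwe_oracle(n_aa_hom, n_het, n_bb_hom):
    """Exact two-sided HWE p-value by full enumeration with Fractions.

    P(config | allele counts) = C(n, nAA) C(n - nAA, nAa) 2^{nAa} / C(2n, nA).
    """
    n = n_aa_hom + n_het + n_bb_hom
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    if n_a == 0 or n_b == 0:
        return Fraction(1)

    def prob(het):
        aa = (n_a - het) // 2
        ways = Fraction(comb(n, aa) * comb(n - aa, het)) * 2 ** het
        return ways / comb(2 * n, n_a)

    probs = {h: prob(h) for h in range(n_a % 2, min(n_a, n_b) + 1, 2)}
    observed = probs[n_het]
    return sum(p for p in probs.values() if p <= observed)


def grid_search_ml(table, coarse=0.02):
    """ML haplotype frequencies by coarse-to-fine grid search on the simplex."""

    def loglik_many(h):
        return _em_loglik(h, np.broadcast_to(table.astype(float), (h.shape[0], 3, 3)))

    def search(center, width, step):
        axes = [
            np.arange(max(c - width, 0.0), min(c + width, 1.0) + step / 2, step)
            for c in center[:3]
        ]
        pts = np.array([p for p in itertools.product(*axes) if sum(p) <= 1.0 + 1e-12])
        h = np.column_stack([pts, np.clip(1.0 - pts.sum(axis=1), 0.0, 1.0)])
        ll = loglik_many(h)
        return h[int(np.argmax(ll))]

    best = search((0.5, 0.5, 0.5), 0.5, coarse)
    for step in (coarse / 10, coarse / 100, coarse / 2000):
        best = search(best, step * 12, step)
    return best
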