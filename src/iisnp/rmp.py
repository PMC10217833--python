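"""Random-match probabilities under the product rule.

The RMP of a multi-locus profile is the product of per-locus genotype
frequencies (``p^2`` for a homozygote, ``2pq`` for a heterozygote) assuming
independence between markers.  At ~94 loci the product reaches ~1e-38, so all
accumulation is in log10 space; linear-scale summaries use stable log-space
aggregation.  No-call loci are skipped from the product and counted.
No theta/subpopulation correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from iisnp.panel_io import ValidationError


@dataclass
class RmpProfile:
    sample_id: str
    marker_set: str
    log10_rmp: float
    n_loci_used: int
    n_loci_skipped: int

    @property
    def rmp(self) -> float:
        return 10.0 ** self.log10_rmp


def profile_rmp(
    profile: pd.DataFrame,
    freqs: pd.DataFrame,
    marker_set: str = "iiSNPs",
    population: str | None = None,
) -> RmpProfile:
    """RMP for one sample's genotype calls against a frequency table.

    ``profile`` is a genotype table restricted to one sample; ``freqs`` has
    columns rsid, population, allele, frequency.  ``population`` selects the
    frequency stratum (defaults to the single stratum present).  A called
    allele missing from the table, or carrying zero frequency, is an error:
    no minimum-allele-frequency substitution is applied.
    """
    samples = profile["sample_id"].unique()
    if len(samples) != 1:
        raise ValidationError(f"profile_rmp expects one sample, got {len(samples)}")
    ftab = freqs
    if population is not None:
        ftab = freqs[freqs["population"] == population]
    elif freqs["population"].nunique() > 1:
        raise ValidationError("frequency table has multiple populations; pass population=")
    lookup = {(r.rsid, r.allele): r.frequency for r in ftab.itertuples(index=False)}

    log10_rmp = 0.0
    used = skipped = 0
    for row in profile.itertuples(index=False):
        if row.status != "called":
            skipped += 1
            continue
        try:
            p = lookup[(row.rsid, row.allele1)]
            q = lookup[(row.rsid, row.allele2)]
        except KeyError as exc:
            raise KeyError(f"no frequency for allele {exc} at locus {row.rsid}") from exc
        if p <= 0 or q <= 0:
            raise ValidationError(f"zero frequency at locus {row.rsid}")
        g = p * p if row.allele1 == row.allele2 else 2.0 * p * q
        log10_rmp += math.log10(g)
        used += 1
    return RmpProfile(
        sample_id=samples[0], marker_set=marker_set,
        log10_rmp=log10_rmp, n_loci_used=used, n_loci_skipped=skipped,
    )


def rmp_table(
    calls: pd.DataFrame,
    freqs: pd.DataFrame,
    marker_set: str = "iiSNPs",
    population: str | None = None,
) -> pd.DataFrame:
    """Per-sample RMP table for a whole call set."""
    rows = []
    for sample_id, sub in calls.groupby("sample_id", sort=True):
        prof = profile_rmp(sub, freqs, marker_set=marker_set, population=population)
        rows.append(
            {
                "sample_id": sample_id, "marker_set": marker_set,
                "log10_rmp": prof.log10_rmp, "rmp": prof.rmp,
                "n_loci_used": prof.n_loci_used, "n_loci_skipped": prof.n_loci_skipped,
            }
        )
    return pd.DataFrame(rows)


def summarize_rmp(log10_rmps: "np.ndarray | list[float] | list[RmpProfile]") -> dict[str, float]:
    """Linear-scale mean, SD, and five-number summary from log10 RMPs.

    Mean and SD are computed on the linear scale via log-space aggregation so
    values near 1e-38 do not underflow intermediate sums.
    """
    if len(log10_rmps) == 0:
        raise ValidationError("summarize_rmp requires at least one profile")
    if isinstance(log10_rmps[0], RmpProfile):
        log10_rmps = [p.log10_rmp for p in log10_rmps]
    lg = np.asarray(log10_rmps, dtype=float) * math.log(10.0)  # natural log
    n = lg.size
    log_mean = logsumexp(lg) - math.log(n)
    mean = math.exp(log_mean)
    if n > 1:
        log_e2 = logsumexp(2 * lg) - math.log(n)  # E[x^2]
        var = math.exp(log_e2) - mean * mean
        # sample variance with Bessel correction
        var = max(var * n / (n - 1), 0.0)
        sd = math.sqrt(var)
    else:
        sd = 0.0
    q1, med, q3 = np.percentile(np.asarray(log10_rmps, dtype=float), [25, 50, 75])
    return {
        "mean": mean,
        "sd": sd,
        "min": 10.0 ** float(np.min(log10_rmps)),
        "max": 10.0 ** float(np.max(log10_rmps)),
        "median": 10.0 ** float(med),
        "q1": 10.0 ** float(q1),
        "q3": 10.0 ** float(q3),
        "n": float(n),
    }


def compare_marker_sets(summaries: "list[tuple[str, float]]") -> pd.DataFrame:
    """Pairwise orders-of-magnitude gaps between marker-set mean RMPs.

    For each ordered pair, ``delta_orders = round(log10(mean_A / mean_B))``:
    positive when A's mean RMP is larger (less discriminating) than B's.
    """
    for label, mean in summaries:
        if mean <= 0:
            raise ValidationError(f"marker set {label!r} has non-positive mean RMP")
    rows = []
    for label_a, mean_a in summaries:
        for label_b, mean_b in summaries:
            if label_a == label_b:
                continue
            rows.append(
                {
                    "marker_set_a": label_a,
                    "marker_set_b": label_b,
                    "log10_ratio": math.log10(mean_a / mean_b),
                    "delta_orders": int(round(math.log10(mean_a / mean_b))),
                }
            )
    return pd.DataFrame(rows)
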