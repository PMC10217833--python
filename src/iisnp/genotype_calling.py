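"""Threshold-based genotype calling from per-allele read counts.

The calling rule mirrors sequence-based HID practice.  With ``c1 >= c2`` the
two largest per-allele read counts at a locus:

* heterozygous iff ``c2 > het_min_reads_per_allele`` and ``c2/c1 > acr_min``;
* otherwise homozygous for the top allele iff ``c1 > hom_min_reads`` and the
  minor-signal fraction ``c2/(c1+c2) <= noise_max_fraction``;
* otherwise a no-call carrying an explanatory flag.

All threshold comparisons are strict inequalities.  The region between
"noise" (minor signal ignorable) and a credible second allele yields a
conservative no-call rather than a forced homozygote.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from iisnp.panel_io import CallingThresholds, GenotypeCall, ValidationError


@dataclass
class LocusPerformance:
    """Per-locus call-rate, coverage, and heterozygote-balance summary."""

    rsid: str
    n_samples: int
    n_called: int
    dropout_rate: float
    mean_coverage: float
    sd_coverage: float
    median_coverage: float
    mean_acr: float | None
    sd_acr: float | None
    allele_coverage: dict[str, tuple[float, float]]  # allele -> (mean, sd) reads


def compute_acr(c_low: float, c_high: float) -> float:
    """Allele coverage ratio: lower-coverage reads over higher-coverage reads.

    Accepts the pair in either order and returns ``min/max`` in [0, 1].
    """
    if c_low < 0 or c_high < 0:
        raise ValidationError("read counts must be non-negative")
    if c_low == 0 and c_high == 0:
        raise ValidationError("ACR undefined when both allele counts are zero")
    lo, hi = sorted((c_low, c_high))
    return lo / hi


def call_genotype(
    counts: "AlleleCountsLike",
    thresholds: CallingThresholds = CallingThresholds(),
) -> GenotypeCall:
    """Call one sample-locus genotype from per-allele read counts.

    ``counts`` may be an :class:`~iisnp.panel_io.AlleleCounts` record or any
    mapping/sequence of ``(allele, reads)`` pairs; identical allele strings
    are aggregated first.  Alleles beyond the top two are treated as noise;
    if their summed read fraction exceeds ``acr_min`` the call is still
    attempted from the top two but flagged ``high_noise``.
    """
    sample_id, population, rsid = "", "", ""
    if hasattr(counts, "observations"):
        sample_id, population, rsid = counts.sample_id, counts.population, counts.rsid
        obs = counts.observations
    elif isinstance(counts, Mapping):
        obs = list(counts.items())
    else:
        obs = list(counts)
    if not obs:
        raise ValidationError("call_genotype requires at least one observation")

    pooled: dict[str, int] = {}
    for allele, reads in obs:
        if reads < 0:
            raise ValidationError(f"negative read count {reads} for allele {allele!r}")
        pooled[allele] = pooled.get(allele, 0) + int(reads)

    ranked = sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    (a1, c1) = ranked[0]
    (a2, c2) = ranked[1] if len(ranked) > 1 else (None, 0)
    total = sum(pooled.values())
    coverage = total

    flags: set[str] = set()
    rest = total - c1 - c2
    if total > 0 and rest / total > thresholds.acr_min:
        flags.add("high_noise")

    t = thresholds
    # Heterozygote: both alleles credibly observed and balanced.
    if c2 > t.het_min_reads_per_allele and c2 / c1 > t.acr_min:
        lo, hi = sorted((a1, a2))
        return GenotypeCall(
            sample_id=sample_id, rsid=rsid, population=population, status="called",
            allele1=lo, allele2=hi, coverage=coverage, acr=c2 / c1, flags=frozenset(flags),
        )
    # Homozygote: enough major-allele reads and negligible minor signal.
    if c1 > t.hom_min_reads and c2 / (c1 + c2) <= t.noise_max_fraction:
        return GenotypeCall(
            sample_id=sample_id, rsid=rsid, population=population, status="called",
            allele1=a1, allele2=a1, coverage=coverage, flags=frozenset(flags),
        )
    # No-call: pick the flag that explains the failure.
    if c2 > t.het_min_reads_per_allele and c2 / c1 <= t.acr_min:
        flags.add("imbalanced")
    elif c1 > t.hom_min_reads and c2 / (c1 + c2) > t.noise_max_fraction:
        flags.add("high_noise")
    else:
        flags.add("low_coverage")
    return GenotypeCall(
        sample_id=sample_id, rsid=rsid, population=population, status="no_call",
        coverage=coverage, flags=frozenset(flags),
    )


def call_table(
    counts: Sequence["AlleleCountsLike"],
    thresholds: CallingThresholds = CallingThresholds(),
) -> list[GenotypeCall]:
    """Call genotypes for a batch of per-sample-locus count records."""
    return [call_genotype(c, thresholds) for c in counts]


def summarize_locus(calls: pd.DataFrame, counts: pd.DataFrame | None = None) -> LocusPerformance:
    """Summarize dropout, coverage, and ACR for the calls at a single locus.

    ``calls`` is a genotype table restricted to one rsid.  If a raw counts
    table (sample_id, rsid, sequence/allele, reads) is given, per-allele mean
    coverage is computed over the samples carrying each called allele.
    """
    if len(calls) == 0:
        raise KeyError("summarize_locus: empty call table")
    rsids = calls["rsid"].unique()
    if len(rsids) != 1:
        raise ValidationError(f"summarize_locus expects a single locus, got {list(rsids)}")
    rsid = rsids[0]

    n = len(calls)
    called = calls[calls["status"] == "called"]
    n_called = len(called)
    cov = calls["coverage"].to_numpy(dtype=float)
    acr = pd.to_numeric(calls["acr"], errors="coerce").dropna().to_numpy(dtype=float)

    allele_cov: dict[str, tuple[float, float]] = {}
    if counts is not None:
        sub = counts[counts["rsid"] == rsid]
        col = "allele" if "allele" in sub.columns else "sequence"
        for allele, grp in sub.groupby(col):
            reads = grp["reads"].to_numpy(dtype=float)
            allele_cov[allele] = (float(reads.mean()), float(reads.std(ddof=1)) if len(reads) > 1 else 0.0)

    return LocusPerformance(
        rsid=rsid,
        n_samples=n,
        n_called=n_called,
        dropout_rate=1.0 - n_called / n,
        mean_coverage=float(cov.mean()),
        sd_coverage=float(cov.std(ddof=1)) if n > 1 else 0.0,
        median_coverage=float(np.median(cov)),
        mean_acr=float(acr.mean()) if len(acr) else None,
        sd_acr=(float(acr.std(ddof=1)) if len(acr) > 1 else 0.0) if len(acr) else None,
        allele_coverage=allele_cov,
    )


def performance_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-locus performance summaries for a whole genotype table."""
    rows = []
    for rsid, grp in calls.groupby("rsid", sort=True):
        perf = summarize_locus(grp)
        rows.append(
            {
                "rsid": rsid,
                "n_samples": perf.n_samples,
                "n_called": perf.n_called,
                "dropout_rate": perf.dropout_rate,
                "mean_coverage": perf.mean_coverage,
                "sd_coverage": perf.sd_coverage,
                "median_coverage": perf.median_coverage,
                "mean_acr": perf.mean_acr,
                "sd_acr": perf.sd_acr,
            }
        )
    return pd.DataFrame(rows)
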