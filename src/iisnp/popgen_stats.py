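"""Allele frequencies and the forensic-statistics battery.

Per locus and population the module reports, in the conventional forensic
definitions:

* unbiased gene diversity ``GD = n/(n-1) * (1 - sum p_i^2)`` with ``n`` the
  number of successfully typed gene copies;
* polymorphism information content
  ``PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2``;
* probability of matching ``PM = sum_g f_g^2`` over *observed* genotype
  proportions ``f_g``, and power of discrimination ``PD = 1 - PM``;
* power of exclusion ``PE = h^2 (1 - 2 h H^2)`` and typical paternity index
  ``TPI = 1/(2H)``, with ``h`` the observed heterozygosity and ``H = 1 - h``;
* effective number of alleles ``A_e = 1/(p^2 + q^2)`` for a biallelic locus.

Each called sample contributes two gene copies; no-calls leave the
denominator, so ``n`` can differ across loci.  All arithmetic is at full
precision; rounding happens only when tables are written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from iisnp.panel_io import OVERALL, ValidationError


@dataclass
class LocusStats:
    rsid: str
    population: str
    n_alleles: int
    gd: float
    hobs: float
    pic: float
    pm: float
    pd: float
    pe: float
    tpi: float
    ae: float


def allele_frequencies(calls: pd.DataFrame, grouping: str = "population") -> pd.DataFrame:
    """Allele frequencies per locus from a genotype table.

    ``grouping`` is ``"population"`` for per-group tables or ``"overall"``
    for the pooled sample.  Output columns: rsid, population, allele,
    frequency, n_alleles.
    """
    called = calls[calls["status"] == "called"]
    if len(called) == 0:
        raise KeyError("allele_frequencies: no called genotypes")
    if grouping == "overall":
        called = called.assign(population=OVERALL)
    elif grouping != "population":
        raise ValueError(f"unknown grouping {grouping!r}")

    melted = pd.concat(
        [
            called[["rsid", "population", "allele1"]].rename(columns={"allele1": "allele"}),
            called[["rsid", "population", "allele2"]].rename(columns={"allele2": "allele"}),
        ]
    )
    counts = melted.groupby(["rsid", "population", "allele"], sort=True).size().rename("count").reset_index()
    totals = counts.groupby(["rsid", "population"])["count"].transform("sum")
    counts["frequency"] = counts["count"] / totals
    counts["n_alleles"] = totals
    return counts[["rsid", "population", "allele", "frequency", "n_alleles"]]


def gene_diversity(freqs: np.ndarray, n: int) -> float:
    """Nei's unbiased gene diversity, n = typed gene copies."""
    if n < 2:
        raise ValidationError("gene diversity needs at least 2 gene copies")
    return (n / (n - 1)) * (1.0 - float(np.sum(np.square(freqs))))


def pic_value(freqs: np.ndarray) -> float:
    """Botstein's polymorphism information content."""
    p2 = np.square(freqs)
    cross = np.sum(np.outer(p2, p2)) - np.sum(p2 * p2)  # 2 * sum_{i<j} p_i^2 p_j^2
    return 1.0 - float(np.sum(p2)) - float(cross)


def match_probability(genotype_props: np.ndarray) -> float:
    """Probability of matching: sum of squared observed genotype proportions."""
    if abs(genotype_props.sum() - 1.0) > 1e-9:
        raise ValidationError("genotype proportions must sum to 1")
    return float(np.sum(np.square(genotype_props)))


def power_of_exclusion(hobs: float) -> float:
    """Fisher's PE from observed heterozygosity."""
    h, H = hobs, 1.0 - hobs
    return h * h * (1.0 - 2.0 * h * H * H)


def paternity_index(hobs: float) -> float:
    """Typical paternity index 1/(2H); infinite when no homozygotes observed."""
    H = 1.0 - hobs
    if H == 0:
        return math.inf
    return 1.0 / (2.0 * H)


def effective_alleles(p: float) -> float:
    """Effective number of alleles A_e = 1/(p^2 + q^2) for a biallelic locus."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"frequency {p} outside [0, 1]")
    q = 1.0 - p
    return 1.0 / (p * p + q * q)


def forensic_stats(
    freqs: pd.DataFrame,
    genotype_props: pd.Series | dict,
    hobs: float,
    rsid: str = "",
    population: str = "",
) -> LocusStats:
    """Compute the statistics battery for one locus in one population.

    ``freqs`` is the frequency table restricted to that locus/population;
    ``genotype_props`` maps unordered genotype labels to observed proportions.
    """
    p = freqs["frequency"].to_numpy(dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"{rsid}/{population}: allele frequencies sum to {p.sum():.6f}")
    n = int(freqs["n_alleles"].iloc[0])
    props = np.asarray(list(genotype_props.values()) if isinstance(genotype_props, dict) else genotype_props, dtype=float)
    pm = match_probability(props)
    if len(p) == 2:
        ae = effective_alleles(float(p[0]))
    else:
        ae = 1.0 / float(np.sum(np.square(p)))  # general-allele form, used for MH encodings
    return LocusStats(
        rsid=rsid,
        population=population,
        n_alleles=n,
        gd=gene_diversity(p, n),
        hobs=hobs,
        pic=pic_value(p),
        pm=pm,
        pd=1.0 - pm,
        pe=power_of_exclusion(hobs),
        tpi=paternity_index(hobs),
        ae=ae,
    )


def locus_statistics(calls: pd.DataFrame, grouping: str = "population") -> pd.DataFrame:
    """The full statistics table: one row per locus x population (STRAF-like).

    Uses observed genotype proportions among called samples for PM/PD and
    observed heterozygosity for H_obs, PE and TPI.
    """
    freq_table = allele_frequencies(calls, grouping)
    called = calls[calls["status"] == "called"]
    if grouping == "overall":
        called = called.assign(population=OVERALL)
    rows = []
    for (rsid, population), freqs in freq_table.groupby(["rsid", "population"], sort=True):
        sub = called[(called["rsid"] == rsid) & (called["population"] == population)]
        geno = sub.apply(lambda r: "/".join(sorted((r["allele1"], r["allele2"]))), axis=1)
        props = geno.value_counts(normalize=True)
        hobs = float((sub["allele1"] != sub["allele2"]).mean())
        stats = forensic_stats(freqs, props, hobs, rsid=rsid, population=population)
        rows.append(
            {
                "rsid": rsid, "population": population, "n_alleles": stats.n_alleles,
                "GD": stats.gd, "Hobs": stats.hobs, "PIC": stats.pic, "PM": stats.pm,
                "PD": stats.pd, "PE": stats.pe, "TPI": stats.tpi, "Ae": stats.ae,
            }
        )
    return pd.DataFrame(rows)


def ae_outlier_line(ae_values: "list[float] | np.ndarray") -> float:
    """Reference line Q1 - 1.5 * IQR over a collection of A_e values.

    Quartiles use linear interpolation between order statistics.  Loci with
    any population value below the line are low-A_e outliers.
    """
    vals = np.asarray(ae_values, dtype=float)
    if vals.size < 4:
        raise KeyError("ae_outlier_line requires at least 4 values")
    q1, q3 = np.percentile(vals, [25, 75])
    return float(q1 - 1.5 * (q3 - q1))


def ae_outliers(stats: pd.DataFrame) -> tuple[float, list[str]]:
    """Apply the reference line to a statistics table; returns (line, loci
    with any population's A_e below it)."""
    line = ae_outlier_line(stats["Ae"].to_numpy())
    low = stats.loc[stats["Ae"] < line, "rsid"].unique().tolist()
    return line, sorted(low)
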