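"""Dual-pipeline concordance accounting for genotype call sets.

Two call sets over the same sample x locus grid are compared cell by cell.
A cell is concordant when both pipelines called the same unordered genotype,
or when *both* failed calling thresholds (a dual no-call carries no evidence
of disagreement).  A cell where exactly one pipeline failed is discordant,
with a reason code recording which side dropped out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REASONS = ("b_no_call", "a_no_call", "genotype_mismatch")


@dataclass
class ConcordanceReport:
    n_possible: int
    n_called_a: int
    n_failed_a: int
    n_concordant: int
    n_discordant: int
    per_locus_dropouts: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, int] = field(default_factory=lambda: {r: 0 for r in REASONS})
    discordant_cells: list[tuple[str, str, str]] = field(default_factory=list)  # (sample, rsid, reason)

    @property
    def call_rate(self) -> float:
        return self.n_called_a / self.n_possible

    @property
    def concordance_rate(self) -> float:
        return self.n_concordant / self.n_possible


def _genotype_key(row) -> frozenset | None:
    if row.status != "called":
        return None
    return frozenset((row.allele1, row.allele2))


def compare_callsets(a: pd.DataFrame, b: pd.DataFrame) -> ConcordanceReport:
    """Compare genotype tables from two pipelines over an identical grid.

    Raises ``KeyError`` listing missing cells if the (sample, locus) grids
    differ.  Genotypes compare as unordered allele pairs.
    """
    key_a = {(r.sample_id, r.rsid): _genotype_key(r) for r in a.itertuples(index=False)}
    key_b = {(r.sample_id, r.rsid): _genotype_key(r) for r in b.itertuples(index=False)}
    only_a = set(key_a) - set(key_b)
    only_b = set(key_b) - set(key_a)
    if only_a or only_b:
        raise KeyError(
            f"sample/locus grids differ: {len(only_a)} cells only in A "
            f"(e.g. {sorted(only_a)[:3]}), {len(only_b)} only in B (e.g. {sorted(only_b)[:3]})"
        )

    report = ConcordanceReport(
        n_possible=len(key_a),
        n_called_a=sum(g is not None for g in key_a.values()),
        n_failed_a=sum(g is None for g in key_a.values()),
        n_concordant=0,
        n_discordant=0,
    )
    dropouts: dict[str, int] = {}
    for (sample, rsid), ga in key_a.items():
        gb = key_b[(sample, rsid)]
        if ga is None:
            dropouts[rsid] = dropouts.get(rsid, 0) + 1
        if ga == gb:  # equal genotypes, or dual no-call (None == None)
            report.n_concordant += 1
            continue
        report.n_discordant += 1
        reason = "b_no_call" if gb is None else "a_no_call" if ga is None else "genotype_mismatch"
        report.reasons[reason] += 1
        report.discordant_cells.append((sample, rsid, reason))
    report.per_locus_dropouts = dropouts
    return report


def possible_genotypes(n_samples: int, n_loci: int) -> int:
    """Size of the full sample x locus call grid."""
    if n_samples < 0 or n_loci < 0:
        raise ValueError("sample and locus counts must be non-negative")
    return n_samples * n_loci


def call_rate_accounting(a: pd.DataFrame) -> tuple[int, int, int, float]:
    """Accounting for one call set: (n_possible, n_called, n_failed, call_rate).

    ``n_possible`` is the full sample x locus grid of the table.
    """
    n_samples = a["sample_id"].nunique()
    n_loci = a["rsid"].nunique()
    n_possible = n_samples * n_loci
    n_called = int((a["status"] == "called").sum())
    return n_possible, n_called, n_possible - n_called, n_called / n_possible


def attribute_dropouts(a: pd.DataFrame, loci: list[str] | set[str]) -> int:
    """Count no-call cells restricted to a subset of panel loci."""
    unknown = set(loci) - set(a["rsid"].unique())
    if unknown:
        raise KeyError(f"loci not present in call set: {sorted(unknown)}")
    sub = a[a["rsid"].isin(set(loci))]
    return int((sub["status"] == "no_call").sum())


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Presentation-rounding helper: 100 * numerator/denominator to n digits."""
    return round(100.0 * numerator / denominator, ndigits)


def report_text(report: ConcordanceReport) -> str:
    """Human-readable accounting summary."""
    lines = [
        f"possible genotypes:  {report.n_possible}",
        f"called by A:         {report.n_called_a} ({percent(report.n_called_a, report.n_possible)}%)",
        f"failed by A:         {report.n_failed_a}",
        f"concordant:          {report.n_concordant} ({percent(report.n_concordant, report.n_possible)}%)",
        f"discordant:          {report.n_discordant}",
    ]
    for reason in REASONS:
        lines.append(f"  {reason}: {report.reasons[reason]}")
    return "\n".join(lines)
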