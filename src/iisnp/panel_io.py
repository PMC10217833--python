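"""Domain types and file I/O for the iiSNP pipeline.

All tabular formats are plain TSV/CSV so files diff cleanly:

* panel TSV: ``rsid  chrom  pos  ref  alt  reporting_strand  amplicon_ref  target_offset``
* counts TSV: ``sample_id  population  rsid  sequence  reads``
* genotype TSV: ``sample_id  population  rsid  status  allele1  allele2  coverage  acr  flags``
* frequency CSV: ``rsid,population,allele,frequency,n_alleles``

Alleles, amplicon sequences and frequencies are stored in the panel's
*reporting-strand* orientation (the orientation the upstream analysis software
reports, which for some loci is the GRCh38 reverse strand); only VCF export
converts to the forward strand.  Panel positions are 1-based GRCh38
coordinates; offsets inside amplicon strings are 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam


class FormatError(ValueError):
    """A file does not conform to its expected schema."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


DNA_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: The four population labels of the study design, used as defaults everywhere.
DEFAULT_POPULATIONS = ("African American", "Asian American", "Caucasian", "Hispanic")

PANEL_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "reporting_strand", "amplicon_ref", "target_offset"]
COUNTS_COLUMNS = ["sample_id", "population", "rsid", "sequence", "reads"]
GENOTYPE_COLUMNS = ["sample_id", "population", "rsid", "status", "allele1", "allele2", "coverage", "acr", "flags"]
FREQUENCY_COLUMNS = ["rsid", "population", "allele", "frequency", "n_alleles"]

#: Pseudo-population label for statistics pooled over all groups.
OVERALL = "Overall"


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (an involution)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    """Complement a DNA string without reversing (for single-base alleles)."""
    return base.translate(DNA_COMPLEMENT)


@dataclass(frozen=True)
class SnpLocus:
    """One biallelic target SNP with its sequenced amplicon.

    ``ref_allele``/``alt_allele`` and ``amplicon_ref`` are in reporting-strand
    orientation; ``pos`` is the 1-based GRCh38 forward-strand coordinate of the
    target SNP; ``target_offset`` is the 0-based index of the target base
    within ``amplicon_ref``.
    """

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    reporting_strand: str  # "forward" | "reverse"
    amplicon_ref: str
    target_offset: int

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.rsid}: ref and alt alleles are identical ({self.ref_allele})")
        if self.reporting_strand not in ("forward", "reverse"):
            raise ValidationError(f"{self.rsid}: reporting_strand must be 'forward' or 'reverse'")
        if not (0 <= self.target_offset < len(self.amplicon_ref)):
            raise ValidationError(
                f"{self.rsid}: target_offset {self.target_offset} outside amplicon of length {len(self.amplicon_ref)}"
            )
        if self.amplicon_ref[self.target_offset] != self.ref_allele:
            raise ValidationError(
                f"{self.rsid}: amplicon base {self.amplicon_ref[self.target_offset]!r} at offset "
                f"{self.target_offset} does not match ref allele {self.ref_allele!r}"
            )

    @property
    def forward_ref(self) -> str:
        """Reference allele on the GRCh38 forward strand."""
        return self.ref_allele if self.reporting_strand == "forward" else complement(self.ref_allele)

    @property
    def forward_alt(self) -> str:
        return self.alt_allele if self.reporting_strand == "forward" else complement(self.alt_allele)

    def to_forward(self, allele: str) -> str:
        """Convert a reported single-base allele to forward-strand orientation."""
        return allele if self.reporting_strand == "forward" else complement(allele)

    def to_reported(self, allele: str) -> str:
        """Convert a forward-strand single-base allele to reporting orientation."""
        return allele if self.reporting_strand == "forward" else complement(allele)


@dataclass
class AlleleCounts:
    """Observed sequence alleles with read counts for one sample at one locus."""

    sample_id: str
    population: str
    rsid: str
    observations: list[tuple[str, int]]

    def __post_init__(self) -> None:
        for seq, reads in self.observations:
            if not seq:
                raise ValidationError(f"{self.sample_id}/{self.rsid}: empty sequence string")
            if reads < 0 or int(reads) != reads:
                raise ValidationError(f"{self.sample_id}/{self.rsid}: read count {reads} is not a non-negative integer")


@dataclass
class GenotypeCall:
    """A called or no-call genotype with its QC metrics.

    ``acr`` (allele coverage ratio: reads of the lower-coverage allele divided
    by reads of the higher-coverage allele) is present iff heterozygous.
    """

    sample_id: str
    rsid: str
    status: str  # "called" | "no_call"
    allele1: str | None = None
    allele2: str | None = None
    coverage: int = 0
    acr: float | None = None
    flags: frozenset[str] = frozenset()
    population: str = ""

    VALID_FLAGS = frozenset({"low_coverage", "imbalanced", "high_noise", "deletion_artifact"})

    def __post_init__(self) -> None:
        unknown = set(self.flags) - self.VALID_FLAGS
        if unknown:
            raise ValidationError(f"{self.sample_id}/{self.rsid}: unknown flags {sorted(unknown)}")
        if self.status == "called":
            if self.allele1 is None or self.allele2 is None:
                raise ValidationError(f"{self.sample_id}/{self.rsid}: called genotype missing alleles")
            het = self.allele1 != self.allele2
            if het and self.acr is None:
                raise ValidationError(f"{self.sample_id}/{self.rsid}: heterozygote without ACR")
            if not het and self.acr is not None:
                raise ValidationError(f"{self.sample_id}/{self.rsid}: homozygote with ACR")
            if self.acr is not None and not (0 < self.acr <= 1):
                raise ValidationError(f"{self.sample_id}/{self.rsid}: ACR {self.acr} outside (0, 1]")

    @property
    def is_het(self) -> bool:
        return self.status == "called" and self.allele1 != self.allele2

    @property
    def genotype(self) -> frozenset[str] | None:
        """Unordered allele pair, or None for a no-call."""
        if self.status != "called":
            return None
        return frozenset((self.allele1, self.allele2))


@dataclass(frozen=True)
class CallingThresholds:
    """Analytical/stochastic genotype-calling thresholds.

    All comparisons are strict ("greater than"): a homozygote needs more than
    ``hom_min_reads`` total; a heterozygote needs more than
    ``het_min_reads_per_allele`` for each allele and an ACR strictly above
    ``acr_min``.  ``noise_max_fraction`` bounds the minor-signal fraction
    tolerated by a homozygous call, and ``deletion_flag_fraction`` is the
    read fraction above which a deletion-artifact flag is raised.
    """

    hom_min_reads: int = 30
    het_min_reads_per_allele: int = 10
    acr_min: float = 0.20
    noise_max_fraction: float = 0.10
    deletion_flag_fraction: float = 0.50

    def __post_init__(self) -> None:
        for name in ("hom_min_reads", "het_min_reads_per_allele", "acr_min", "noise_max_fraction", "deletion_flag_fraction"):
            if getattr(self, name) < 0:
                raise ValidationError(f"threshold {name} must be >= 0")
        if self.acr_min >= 1:
            raise ValidationError("acr_min must be < 1")


# ---------------------------------------------------------------------------
# Panel I/O


def read_panel(path: str | Path) -> list[SnpLocus]:
    """Read a panel definition TSV into validated :class:`SnpLocus` records.

    Raises :class:`FormatError` for missing columns and
    :class:`ValidationError` for duplicate rsIDs or rows whose amplicon does
    not carry the reference allele at the stated offset.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel file {path}: missing column(s) {missing}")
    loci: list[SnpLocus] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.rsid in seen:
            raise ValidationError(f"panel file {path}: duplicate rsid {row.rsid}")
        seen.add(row.rsid)
        loci.append(
            SnpLocus(
                rsid=row.rsid,
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                reporting_strand=row.reporting_strand,
                amplicon_ref=row.amplicon_ref,
                target_offset=int(row.target_offset),
            )
        )
    return loci


def write_panel(loci: Sequence[SnpLocus], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "rsid": [l.rsid for l in loci],
            "chrom": [l.chrom for l in loci],
            "pos": [l.pos for l in loci],
            "ref": [l.ref_allele for l in loci],
            "alt": [l.alt_allele for l in loci],
            "reporting_strand": [l.reporting_strand for l in loci],
            "amplicon_ref": [l.amplicon_ref for l in loci],
            "target_offset": [l.target_offset for l in loci],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Counts I/O


def read_counts(path: str | Path) -> list[AlleleCounts]:
    """Read a per-read-sequence counts TSV, grouping rows by (sample, locus)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str, "rsid": str, "sequence": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts file {path}: missing column(s) {missing}")
    if not pd.api.types.is_integer_dtype(df["reads"]):
        raise FormatError(f"counts file {path}: 'reads' column must be integer")
    out: list[AlleleCounts] = []
    for (sample_id, population, rsid), grp in df.groupby(["sample_id", "population", "rsid"], sort=False):
        out.append(
            AlleleCounts(
                sample_id=sample_id,
                population=population,
                rsid=rsid,
                observations=list(zip(grp["sequence"], grp["reads"].astype(int))),
            )
        )
    return out


def write_counts(counts: Iterable[AlleleCounts], path: str | Path) -> None:
    rows = [
        (c.sample_id, c.population, c.rsid, seq, reads)
        for c in counts
        for seq, reads in c.observations
    ]
    pd.DataFrame(rows, columns=COUNTS_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotype table I/O

def calls_to_table(calls: Iterable[GenotypeCall]) -> pd.DataFrame:
    """Assemble :class:`GenotypeCall` records into the tabular genotype layout."""
    rows = []
    for c in calls:
        rows.append(
            {
                "sample_id": c.sample_id,
                "population": c.population,
                "rsid": c.rsid,
                "status": c.status,
                "allele1": c.allele1 if c.allele1 is not None else "",
                "allele2": c.allele2 if c.allele2 is not None else "",
                "coverage": c.coverage,
                "acr": c.acr if c.acr is not None else "",
                "flags": ";".join(sorted(c.flags)),
            }
        )
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)


def table_to_calls(table: pd.DataFrame) -> list[GenotypeCall]:
    calls = []
    for row in table.itertuples(index=False):
        acr = getattr(row, "acr", "")
        acr = None if acr in ("", None) or pd.isna(acr) else float(acr)
        flags = getattr(row, "flags", "")
        flags = frozenset() if flags in ("", None) or pd.isna(flags) else frozenset(str(flags).split(";"))
        called = row.status == "called"
        calls.append(
            GenotypeCall(
                sample_id=row.sample_id,
                rsid=row.rsid,
                status=row.status,
                allele1=(row.allele1 or None) if called else None,
                allele2=(row.allele2 or None) if called else None,
                coverage=int(row.coverage),
                acr=acr,
                flags=flags,
                population=getattr(row, "population", ""),
            )
        )
    return calls


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV, validating schema and per-row invariants."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"genotype file {path}: missing column(s) {missing}")
    bad = df.loc[~df["status"].isin(["called", "no_call"]), "status"].unique()
    if len(bad):
        raise FormatError(f"genotype file {path}: unknown status value(s) {list(bad)}")
    df["coverage"] = df["coverage"].astype(int)
    df["acr"] = pd.to_numeric(df["acr"].replace("", None), errors="raise")
    table_to_calls(df)  # full invariant check, row by row
    return df


def write_genotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Frequency table I/O


def read_frequencies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"rsid": str, "population": str, "allele": str})
    missing = [c for c in FREQUENCY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"frequency file {path}: missing column(s) {missing}")
    sums = df.groupby(["rsid", "population"])["frequency"].sum()
    off = sums[(sums - 1.0).abs() > 1e-6]
    if len(off):
        key = off.index[0]
        raise ValidationError(f"frequency file {path}: frequencies for {key} sum to {off.iloc[0]:.6f}, not 1")
    return df


def write_frequencies(freqs: pd.DataFrame, path: str | Path) -> None:
    out = freqs.copy()
    out["frequency"] = out["frequency"].round(4)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# VCF export


def write_vcf(calls: pd.DataFrame, panel: Sequence[SnpLocus], path: str | Path) -> None:
    """Export target-SNP genotype calls to VCF 4.2 on the GRCh38 forward strand.

    Reverse-reported loci have their alleles complemented so that REF/ALT
    match the forward strand; no-calls are written as ``./.``.
    """
    by_rsid = {l.rsid: l for l in panel}
    unknown = set(calls["rsid"]) - set(by_rsid)
    if unknown:
        raise KeyError(f"rsid(s) not in panel: {sorted(unknown)}")

    samples = sorted(calls["sample_id"].unique())
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(l.chrom for l in panel):  # insertion order, deduplicated
        header.contigs.add(chrom)
    for s in samples:
        header.add_sample(s)

    loci = sorted((l for l in panel if l.rsid in set(calls["rsid"])), key=lambda l: (l.chrom, l.pos))
    cells = {(r.sample_id, r.rsid): r for r in calls.itertuples(index=False)}

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus in loci:
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos,
                alleles=(locus.forward_ref, locus.forward_alt),
                id=locus.rsid,
            )
            allele_index = {locus.forward_ref: 0, locus.forward_alt: 1}
            for s in samples:
                row = cells.get((s, locus.rsid))
                if row is None or row.status != "called":
                    rec.samples[s]["GT"] = (None, None)
                    continue
                try:
                    gt = tuple(sorted(allele_index[locus.to_forward(a)] for a in (row.allele1, row.allele2)))
                except KeyError as exc:
                    raise ValidationError(f"{s}/{locus.rsid}: allele {exc} not among panel ref/alt") from exc
                rec.samples[s]["GT"] = gt
            vcf.write(rec)


def read_vcf(path: str | Path, panel: Sequence[SnpLocus]) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a genotype table.

    Alleles are converted back to reporting-strand orientation, so a write
    followed by a read round-trips the genotype matrix (QC columns excluded).
    """
    by_rsid = {l.rsid: l for l in panel}
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            locus = by_rsid.get(rec.id)
            if locus is None:
                raise KeyError(f"VCF record {rec.id} not in panel")
            for sample, call in rec.samples.items():
                gt = call["GT"]
                if gt is None or any(a is None for a in gt):
                    rows.append({"sample_id": sample, "population": "", "rsid": rec.id, "status": "no_call",
                                 "allele1": "", "allele2": "", "coverage": 0, "acr": "", "flags": ""})
                else:
                    a1, a2 = (locus.to_reported(rec.alleles[i]) for i in gt)
                    rows.append({"sample_id": sample, "population": "", "rsid": rec.id, "status": "called",
                                 "allele1": a1, "allele2": a2, "coverage": 0,
                                 "acr": "" if a1 == a2 else 1.0, "flags": ""})
    return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
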