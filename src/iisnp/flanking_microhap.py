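"""Flanking-region microhaplotype extraction from amplicon sequences.

A microhaplotype (MH) is the phased combination of the target SNP allele with
any flanking-sequence variants observed in the same short read.  Observed
amplicon sequences are globally aligned to the amplicon reference
(match +1, mismatch -1, linear gap -2); differences become
:class:`FlankingVariant` records, indels inside homopolymer runs are
left-aligned to the first base of the run, and the base at the target offset
is carried separately as the target allele.

Carrying the target base separately is what rescues the classic alignment
artifact at a target SNP adjacent to a homopolymer: a read carrying the
alternate target base plus a one-base homopolymer deletion is interpreted as
(alt target, deletion in the flank) rather than as a deletion of the target
itself.  A call where more than half the reads carry a deletion at or next to
the target is flagged ``deletion_artifact`` for reviewer attention.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from iisnp.genotype_calling import call_genotype
from iisnp.panel_io import (
    AlleleCounts,
    CallingThresholds,
    GenotypeCall,
    SnpLocus,
    ValidationError,
    calls_to_table,
)

logger = logging.getLogger(__name__)

#: Reads needing more than this many edits against the reference are treated
#: as noise for the sample-locus (mirrors pipelines that drop error-laden reads).
MAX_READ_EDITS = 4


@dataclass(frozen=True)
class FlankingVariant:
    """A single difference from the amplicon reference, 0-based offset."""

    offset: int
    kind: str  # "snv" | "deletion" | "insertion"
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind == "snv" and not (len(self.ref) == 1 and len(self.alt) == 1):
            raise ValidationError(f"snv at {self.offset} must have length-1 ref and alt")
        if self.kind == "deletion" and (self.alt != "" or self.ref == ""):
            raise ValidationError(f"deletion at {self.offset} must have empty alt and non-empty ref")
        if self.kind == "insertion" and (self.ref != "" or self.alt == ""):
            raise ValidationError(f"insertion at {self.offset} must have empty ref and non-empty alt")

    @property
    def n_edits(self) -> int:
        return max(len(self.ref), len(self.alt))

    @property
    def span(self) -> tuple[int, int]:
        """Half-open interval of reference positions the variant touches."""
        if self.kind == "insertion":
            return (self.offset, self.offset)
        return (self.offset, self.offset + len(self.ref))


@dataclass(frozen=True)
class MicrohapAllele:
    """A target SNP allele plus its phased flanking variants, as one allele."""

    rsid: str
    target_allele: str
    variants: tuple[FlankingVariant, ...]
    allele_string: str
    novel: bool = False


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def _left_align(ref: str, variants: list[FlankingVariant]) -> list[FlankingVariant]:
    """Shift indels left while the flanking context allows (homopolymer rule)."""
    out = []
    for v in variants:
        if v.kind == "deletion":
            k, L = v.offset, len(v.ref)
            while k > 0 and ref[k - 1] == ref[k + L - 1]:
                k -= 1
            v = FlankingVariant(k, "deletion", ref[k:k + L], "")
        elif v.kind == "insertion":
            k, ins = v.offset, v.alt
            while k > 0 and ref[k - 1] == ins[-1]:
                ins = ins[-1] + ins[:-1]
                k -= 1
            v = FlankingVariant(k, "insertion", "", ins)
        out.append(v)
    return sorted(out, key=lambda v: (v.offset, v.kind))


# distinct read sequences recur heavily (clean haplotypes across samples,
# single-substitution error patterns within a locus), so alignments are memoized
_align_cache: dict[tuple[str, str], tuple[FlankingVariant, ...]] = {}
_ALIGN_CACHE_MAX = 500_000


def align_read(seq: str, ref: str) -> list[FlankingVariant]:
    """Globally align an observed sequence to the amplicon reference and
    return the differences as left-aligned variants (empty list if identical)."""
    if not seq or not ref:
        raise ValidationError("align_read requires non-empty sequences")
    if seq == ref:
        return []
    cached = _align_cache.get((seq, ref))
    if cached is not None:
        return list(cached)
    aln = _aligner.align(ref, seq)[0]
    gapped_ref, gapped_seq = str(aln[0]), str(aln[1])

    variants: list[FlankingVariant] = []
    ref_pos = 0
    i = 0
    n = len(gapped_ref)
    while i < n:
        r, s = gapped_ref[i], gapped_seq[i]
        if r != "-" and s != "-":
            if r != s:
                variants.append(FlankingVariant(ref_pos, "snv", r, s))
            ref_pos += 1
            i += 1
        elif s == "-":  # run of deleted reference bases
            start = ref_pos
            deleted = []
            while i < n and gapped_seq[i] == "-" and gapped_ref[i] != "-":
                deleted.append(gapped_ref[i])
                ref_pos += 1
                i += 1
            variants.append(FlankingVariant(start, "deletion", "".join(deleted), ""))
        else:  # run of inserted read bases
            inserted = []
            while i < n and gapped_ref[i] == "-" and gapped_seq[i] != "-":
                inserted.append(gapped_seq[i])
                i += 1
            variants.append(FlankingVariant(ref_pos, "insertion", "", "".join(inserted)))
    result = _left_align(ref, variants)
    if len(_align_cache) >= _ALIGN_CACHE_MAX:
        _align_cache.clear()
    _align_cache[(seq, ref)] = tuple(result)
    return result


def _variant_token(v: FlankingVariant) -> str:
    ref = v.ref if v.ref else "-"
    alt = v.alt if v.alt else "-"
    return f"{v.offset}:{ref}>{alt}"


def build_microhap(
    target_allele: str,
    variants: Iterable[FlankingVariant],
    rsid: str = "",
    target_offset: int | None = None,
) -> MicrohapAllele:
    """Compose a canonical microhaplotype allele string.

    Variants are sorted by offset, so any ordering of the same set yields an
    identical string.  The bare target allele is its own string when no
    flanking variation exists.  A variant overlapping the target offset is
    rejected: the target base is carried separately.
    """
    vs = tuple(sorted(variants, key=lambda v: (v.offset, v.kind, v.ref, v.alt)))
    if target_offset is not None:
        for v in vs:
            lo, hi = v.span
            touches = (v.kind == "snv" and lo == target_offset) or (
                v.kind == "deletion" and lo <= target_offset < hi
            )  # an insertion lands *before* its offset and never alters the target base
            if touches:
                raise ValidationError(f"variant {_variant_token(v)} overlaps the target offset {target_offset}")
    allele_string = target_allele if not vs else ";".join([target_allele] + [_variant_token(v) for v in vs])
    return MicrohapAllele(rsid=rsid, target_allele=target_allele, variants=vs, allele_string=allele_string)


def flag_deletion_artifact(reads_with_target_deletion: int, total_reads: int, threshold: float = 0.5) -> bool:
    """True when the fraction of reads carrying a deletion at/next to the
    target SNP strictly exceeds ``threshold`` (exactly the threshold is not
    flagged)."""
    if total_reads <= 0:
        raise ValidationError("flag_deletion_artifact requires total_reads > 0")
    if reads_with_target_deletion > total_reads or reads_with_target_deletion < 0:
        raise ValidationError(
            f"deletion read count {reads_with_target_deletion} outside [0, {total_reads}]"
        )
    return reads_with_target_deletion / total_reads > threshold


def read_registry(path: str | Path) -> dict[str, set[str]]:
    """Load a known-allele registry (TSV: rsid, allele_string) keyed by rsid."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    registry: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        registry.setdefault(row.rsid, set()).add(row.allele_string)
    return registry


def label_novel(mh: MicrohapAllele, registry: Mapping[str, set[str]]) -> MicrohapAllele:
    """Mark an MH allele novel when absent from the known-allele registry.

    A locus missing entirely from the registry is treated as all-novel, with
    a warning.
    """
    known = registry.get(mh.rsid)
    if known is None:
        logger.warning("rsid %s absent from registry; treating all alleles as novel", mh.rsid)
        return dataclasses.replace(mh, novel=True)
    return dataclasses.replace(mh, novel=mh.allele_string not in known)


def _resolve_against(seq: str, ref: str, target_offset: int) -> tuple[str, tuple[FlankingVariant, ...], int] | None:
    """Align and split into (target allele, flanking variants, flanking edits).

    Returns None when a deletion removes the target base, which makes the
    target allele unresolvable against this reference.
    """
    variants = align_read(seq, ref)
    target_allele = ref[target_offset]
    flanking: list[FlankingVariant] = []
    for v in variants:
        lo, hi = v.span
        if v.kind == "snv" and lo == target_offset:
            target_allele = v.alt
        elif v.kind == "deletion" and lo <= target_offset < hi:
            shifted = _shift_deletion_off_target(v, ref, target_offset)
            if shifted is None:
                return None
            flanking.append(shifted)
        else:
            flanking.append(v)
    return target_allele, tuple(flanking), sum(v.n_edits for v in flanking)


def _shift_deletion_off_target(v: FlankingVariant, ref: str, target_offset: int) -> FlankingVariant | None:
    """Re-place a left-aligned homopolymer deletion just after the target.

    When the target base heads a homopolymer run, a run deletion left-aligns
    onto the target even though the read still carries a copy of the run
    base there.  If the run continues far enough for the deletion to sit
    entirely after the target, the equivalent placement at ``target+1`` is
    returned; otherwise the target really is deleted and None is returned.
    """
    L = len(v.ref)
    base = ref[target_offset]
    if set(v.ref) != {base}:
        return None
    new_lo = target_offset + 1
    if ref[new_lo: new_lo + L] != base * L:
        return None
    return FlankingVariant(new_lo, "deletion", base * L, "")


def classify_read(
    seq: str, locus: SnpLocus, max_edits: int = MAX_READ_EDITS
) -> tuple[str, tuple[FlankingVariant, ...]] | None:
    """Resolve one read into (target allele, flanking variants).

    Returns ``None`` when the read is noise: more than ``max_edits`` edits
    against the reference, or a deletion that truly removes the target base.

    When the target SNP heads a homopolymer run, a read carrying the
    alternate target base plus a one-base run deletion aligns ambiguously:
    left-alignment can drag the deletion onto the target itself.  Because the
    target base is carried separately, such reads are re-aligned against the
    reference with each possible base substituted at the target; the
    interpretation with the fewest flanking edits wins, recovering the
    (alt target, deletion in the flank) reading.
    """
    ref = locus.amplicon_ref
    t = locus.target_offset
    resolved = _resolve_against(seq, ref, t)
    if resolved is None:
        # deletion covered the target: retry with every candidate target base
        candidates = []
        order = {locus.ref_allele: 0, locus.alt_allele: 1}
        for a in sorted("ACGT", key=lambda b: (order.get(b, 2), b)):
            ref_a = ref if a == ref[t] else ref[:t] + a + ref[t + 1:]
            alt_resolved = _resolve_against(seq, ref_a, t)
            if alt_resolved is None:
                continue
            target_allele, flanking, n_edits = alt_resolved
            if target_allele != a:  # read does not actually carry base `a`
                continue
            candidates.append((n_edits, target_allele, flanking))
        if not candidates:
            return None
        candidates.sort(key=lambda c: c[0])
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            return None  # irreducibly ambiguous read
        _, target_allele, flanking = candidates[0]
    else:
        target_allele, flanking, _ = resolved
    if sum(v.n_edits for v in flanking) + (target_allele != ref[t]) > max_edits:
        return None
    return target_allele, tuple(flanking)


def _deletion_near_target(variants: Sequence[FlankingVariant], target_offset: int) -> bool:
    """Deletion touching the target base or the base on either side of it."""
    for v in variants:
        if v.kind != "deletion":
            continue
        lo, hi = v.span
        if lo <= target_offset + 1 and hi >= target_offset:
            return True
    return False


@dataclass
class MicrohapCallResult:
    """Per-sample-locus outcome of microhaplotype extraction."""

    mh_call: GenotypeCall
    target_call: GenotypeCall
    mh_alleles: dict[str, int]  # allele_string -> reads
    noise_reads: int
    deletion_reads: int
    total_reads: int


def call_sample_locus(
    counts: AlleleCounts,
    locus: SnpLocus,
    thresholds: CallingThresholds = CallingThresholds(),
    max_edits: int = MAX_READ_EDITS,
) -> MicrohapCallResult:
    """Extract MH alleles for one sample-locus and call both encodings.

    The same calling thresholds are applied to MH-allele read counts and to
    the counts collapsed onto the target base.
    """
    mh_counts: dict[str, int] = {}
    target_counts: dict[str, int] = {}
    noise = 0
    deletion_reads = 0
    total = 0
    for seq, reads in counts.observations:
        total += reads
        resolved = classify_read(seq, locus, max_edits=max_edits)
        if resolved is None:
            noise += reads
            # a deletion call that removed the target base still counts toward
            # the artifact indicator
            variants = align_read(seq, locus.amplicon_ref)
            if _deletion_near_target(variants, locus.target_offset):
                deletion_reads += reads
            continue
        target_allele, variants = resolved
        if _deletion_near_target(variants, locus.target_offset):
            deletion_reads += reads
        mh = build_microhap(target_allele, variants, rsid=locus.rsid, target_offset=locus.target_offset)
        mh_counts[mh.allele_string] = mh_counts.get(mh.allele_string, 0) + reads
        target_counts[target_allele] = target_counts.get(target_allele, 0) + reads

    def _call(pool: dict[str, int]) -> GenotypeCall:
        if not pool:
            return GenotypeCall(
                sample_id=counts.sample_id, rsid=counts.rsid, population=counts.population,
                status="no_call", coverage=total, flags=frozenset({"low_coverage"}),
            )
        call = call_genotype(
            AlleleCounts(counts.sample_id, counts.population, counts.rsid, list(pool.items())),
            thresholds,
        )
        if total > 0 and flag_deletion_artifact(deletion_reads, total, thresholds.deletion_flag_fraction):
            call = dataclasses.replace(call, flags=call.flags | {"deletion_artifact"})
        return call

    return MicrohapCallResult(
        mh_call=_call(mh_counts),
        target_call=_call(target_counts),
        mh_alleles=mh_counts,
        noise_reads=noise,
        deletion_reads=deletion_reads,
        total_reads=total,
    )


def call_microhaps(
    counts: Sequence[AlleleCounts],
    panel: Sequence[SnpLocus],
    thresholds: CallingThresholds = CallingThresholds(),
    registry: Mapping[str, set[str]] | None = None,
    max_edits: int = MAX_READ_EDITS,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run MH extraction over a counts table.

    Returns (mh genotype table, target-SNP genotype table, allele table).
    The allele table lists each distinct MH allele string seen in called
    genotypes with its carrier count and, when a registry is given, a novelty
    flag.
    """
    by_rsid = {l.rsid: l for l in panel}
    mh_calls: list[GenotypeCall] = []
    target_calls: list[GenotypeCall] = []
    allele_carriers: dict[tuple[str, str], int] = {}
    for rec in counts:
        locus = by_rsid.get(rec.rsid)
        if locus is None:
            raise KeyError(f"counts reference rsid {rec.rsid} absent from panel")
        res = call_sample_locus(rec, locus, thresholds, max_edits)
        mh_calls.append(res.mh_call)
        target_calls.append(res.target_call)
        if res.mh_call.status == "called":
            for allele in {res.mh_call.allele1, res.mh_call.allele2}:
                allele_carriers[(rec.rsid, allele)] = allele_carriers.get((rec.rsid, allele), 0) + 1

    rows = []
    for (rsid, allele_string), carriers in sorted(allele_carriers.items()):
        novel = ""
        if registry is not None:
            mh = MicrohapAllele(rsid=rsid, target_allele=allele_string.split(";")[0],
                                variants=(), allele_string=allele_string)
            novel = label_novel(mh, registry).novel
        rows.append({
            "rsid": rsid,
            "allele_string": allele_string,
            "n_carriers": carriers,
            "has_flanking_variants": ";" in allele_string,
            "novel": novel,
        })
    allele_table = pd.DataFrame(rows, columns=["rsid", "allele_string", "n_carriers", "has_flanking_variants", "novel"])
    return calls_to_table(mh_calls), calls_to_table(target_calls), allele_table


@dataclass
class HobsGain:
    """Observed-heterozygosity gain of the MH encoding over the target SNP."""

    rsid: str
    hobs_target: float
    hobs_mh: float
    delta: float
    n_extra_alleles: int
    category: str  # "high" >= 0.15 | "moderate" [0.05, 0.15) | "low" < 0.05


def _categorize(delta: float) -> str:
    if delta >= 0.15:
        return "high"
    if delta >= 0.05:
        return "moderate"
    return "low"


def hobs_gain(target_calls: pd.DataFrame, mh_calls: pd.DataFrame) -> list[HobsGain]:
    """Per-locus observed heterozygosity under both encodings.

    H_obs is the fraction of heterozygous samples among those called under
    *both* encodings, so the two proportions share a denominator; refining
    alleles can then only increase H_obs.
    """
    out: list[HobsGain] = []
    t_by = dict(tuple(target_calls.groupby("rsid", sort=True)))
    m_by = dict(tuple(mh_calls.groupby("rsid", sort=True)))
    for rsid in sorted(set(t_by) | set(m_by)):
        t = t_by.get(rsid)
        m = m_by.get(rsid)
        if t is None or m is None:
            raise KeyError(f"locus {rsid} present in only one encoding")
        t_called = t[t["status"] == "called"].set_index("sample_id")
        m_called = m[m["status"] == "called"].set_index("sample_id")
        shared = t_called.index.intersection(m_called.index)
        if len(shared) == 0:
            raise KeyError(f"locus {rsid}: no sample called under both encodings")
        t_sub, m_sub = t_called.loc[shared], m_called.loc[shared]
        hobs_t = float((t_sub["allele1"] != t_sub["allele2"]).mean())
        hobs_m = float((m_sub["allele1"] != m_sub["allele2"]).mean())
        n_alleles = pd.concat([m_sub["allele1"], m_sub["allele2"]]).nunique()
        out.append(
            HobsGain(
                rsid=rsid,
                hobs_target=hobs_t,
                hobs_mh=hobs_m,
                delta=hobs_m - hobs_t,
                n_extra_alleles=int(n_alleles - 2),
                category=_categorize(hobs_m - hobs_t),
            )
        )
    return out


def hobs_gain_table(target_calls: pd.DataFrame, mh_calls: pd.DataFrame) -> pd.DataFrame:
    gains = hobs_gain(target_calls, mh_calls)
    return pd.DataFrame([dataclasses.asdict(g) for g in gains])
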