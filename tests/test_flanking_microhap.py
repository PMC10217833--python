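"""Alignment, microhaplotype composition, artifact flagging, novelty, and
heterozygosity gain."""

import itertools

import numpy as np
import pandas as pd
import pytest

from iisnp.flanking_microhap import (
    FlankingVariant,
    align_read,
    build_microhap,
    classify_read,
    flag_deletion_artifact,
    hobs_gain,
    label_novel,
)
from iisnp.panel_io import SnpLocus, ValidationError

REF = "ACGCATTTTGACGTA"  # target T at offset 5 heads a TTTT homopolymer
HPOLY_LOCUS = SnpLocus("rs10", "chr8", 100, "T", "C", "forward", REF, 5)


def test_identity_and_single_substitution():
    assert align_read(REF, REF) == []
    mutated = REF[:7] + "G" + REF[8:]
    assert align_read(mutated, REF) == [FlankingVariant(7, "snv", "T", "G")]


def test_homopolymer_deletion_with_alt_target():
    """A read carrying the alternate target base plus one deleted run base is
    interpreted as (alt target, deletion in the flank), not a deleted target."""
    read = REF[:5] + "C" + "TT" + REF[9:]
    target, variants = classify_read(read, HPOLY_LOCUS)
    assert target == "C"
    assert variants == (FlankingVariant(6, "deletion", "T", ""),)


def test_homopolymer_deletion_with_ref_target():
    """A pure run deletion keeps the reference target base."""
    read = REF[:5] + "TTT" + REF[9:]
    target, variants = classify_read(read, HPOLY_LOCUS)
    assert target == "T"
    assert variants == (FlankingVariant(6, "deletion", "T", ""),)


def test_noise_read_rejected():
    scrambled = "GGGGGGGGGGGGGGG"
    assert classify_read(scrambled, HPOLY_LOCUS) is None


# ---------------------------------------------------------------------------
# Brute-force edit-enumeration oracle


def _apply(ref: str, variants) -> str:
    """Independent variant application (descending offsets keep indices valid)."""
    seq = list(ref)
    for v in sorted(variants, key=lambda v: -v.offset):
        if v.kind == "snv":
            seq[v.offset] = v.alt
        elif v.kind == "deletion":
            del seq[v.offset: v.offset + len(v.ref)]
        else:
            seq[v.offset: v.offset] = list(v.alt)
    return "".join(seq)


def _single_edits(ref):
    edits = []
    for i, b in enumerate(ref):
        edits.extend(FlankingVariant(i, "snv", b, c) for c in "ACGT" if c != b)
        edits.append(FlankingVariant(i, "deletion", b, ""))
    for i in range(len(ref) + 1):
        edits.extend(FlankingVariant(i, "insertion", "", c) for c in "ACGT")
    return edits


def _min_edit_sets(ref, seq, max_edits=2):
    """All minimal variant sets (size <= max_edits) reproducing seq from ref."""
    singles = _single_edits(ref)
    hits = []
    for v in singles:
        if _apply(ref, [v]) == seq:
            hits.append((v,))
    if hits:
        return 1, hits
    for pair in itertools.combinations(singles, 2):
        if pair[0].offset == pair[1].offset and {pair[0].kind, pair[1].kind} != {"snv"}:
            pass  # same-offset mixes are still applicable; keep them
        try:
            if _apply(ref, pair) == seq:
                hits.append(pair)
        except IndexError:
            continue
    return (2, hits) if hits else (None, [])


def test_alignment_recovers_planted_edits_against_enumeration_oracle():
    """On randomly mutated amplicons with <= 2 edits, align_read reproduces
    the sequence with the brute-force minimal number of edits, and recovers
    planted substitutions exactly."""
    rng = np.random.default_rng(42)
    for case in range(12):
        ref = "".join(rng.choice(list("ACGT"), size=22))
        singles = _single_edits(ref)
        k = int(rng.integers(1, 3))
        planted = [singles[i] for i in rng.choice(len(singles), size=k, replace=False)]
        if len({v.offset for v in planted}) < k:
            continue
        seq = _apply(ref, planted)
        if seq == ref or not seq:
            continue
        got = align_read(seq, ref)
        assert _apply(ref, got) == seq  # faithful reconstruction
        min_edits, min_sets = _min_edit_sets(ref, seq)
        assert min_edits is not None
        assert sum(v.n_edits for v in got) == min_edits  # minimality
        if all(v.kind == "snv" for v in planted) and min_edits == k:
            assert sorted(got, key=lambda v: v.offset) == sorted(planted, key=lambda v: v.offset)


# ---------------------------------------------------------------------------
# Microhaplotype composition


def test_build_microhap_bare_and_composite():
    assert build_microhap("T", []).allele_string == "T"
    mh = build_microhap("C", [FlankingVariant(6, "deletion", "T", "")], rsid="rs10", target_offset=5)
    assert mh.allele_string == "C;6:T>-"
    assert mh.allele_string != "C"


def test_build_microhap_canonical_ordering():
    v1 = FlankingVariant(3, "snv", "A", "G")
    v2 = FlankingVariant(9, "snv", "G", "T")
    assert build_microhap("T", [v1, v2]).allele_string == build_microhap("T", [v2, v1]).allele_string


def test_build_microhap_rejects_variant_on_target():
    with pytest.raises(ValidationError):
        build_microhap("C", [FlankingVariant(5, "snv", "T", "C")], target_offset=5)
    with pytest.raises(ValidationError):
        build_microhap("C", [FlankingVariant(4, "deletion", "AT", "")], target_offset=5)


def test_deletion_artifact_threshold():
    assert flag_deletion_artifact(109, 196) is True  # 0.556 > 0.5
    assert flag_deletion_artifact(0, 196) is False
    assert flag_deletion_artifact(98, 196) is False  # exactly 0.5 is not flagged
    with pytest.raises(ValidationError):
        flag_deletion_artifact(200, 196)


def test_label_novel_set_difference():
    registry = {"rs10": {"T", "C", "C;6:T>-"}}
    known = build_microhap("C", [FlankingVariant(6, "deletion", "T", "")], rsid="rs10")
    assert label_novel(known, registry).novel is False
    observed = [
        build_microhap("T", [], rsid="rs10"),
        build_microhap("C", [], rsid="rs10"),
        build_microhap("C", [FlankingVariant(6, "deletion", "T", "")], rsid="rs10"),
        build_microhap("T", [FlankingVariant(2, "snv", "G", "A")], rsid="rs10"),
        build_microhap("C", [FlankingVariant(12, "snv", "G", "T")], rsid="rs10"),
    ]
    novel = [m for m in observed if label_novel(m, registry).novel]
    assert len(novel) == 2  # 5 observed minus 3 known
    # locus absent from registry: everything is novel (with a warning)
    assert label_novel(build_microhap("A", [], rsid="rsX"), registry).novel is True


# ---------------------------------------------------------------------------
# Heterozygosity gain


def _call_table(genotypes, rsid="rs1"):
    rows = []
    for i, (a1, a2) in enumerate(genotypes):
        rows.append(
            {
                "sample_id": f"s{i}", "population": "X", "rsid": rsid, "status": "called",
                "allele1": a1, "allele2": a2, "coverage": 100,
                "acr": 0.9 if a1 != a2 else "", "flags": "",
            }
        )
    return pd.DataFrame(rows)


def test_hobs_gain_no_flanking_variation():
    target = _call_table([("A", "A"), ("A", "G"), ("G", "G"), ("A", "G")])
    gains = hobs_gain(target, target.copy())
    assert gains[0].delta == 0.0
    assert gains[0].category == "low"


def test_hobs_gain_matches_hand_count():
    target = _call_table([("A", "A"), ("A", "A"), ("A", "G"), ("A", "G")])
    mh = _call_table([("A", "A;7:C>T"), ("A", "A"), ("A;7:C>T", "G"), ("A", "G")])
    (g,) = hobs_gain(target, mh)
    assert g.hobs_target == 0.5
    assert g.hobs_mh == 0.75
    assert g.delta == pytest.approx(0.25)
    assert g.category == "high"
    assert g.n_extra_alleles == 1  # alleles {A, G, A;7:C>T} minus 2


def test_singleton_allele_moves_hobs_at_most_one_over_n():
    n = 10
    target = _call_table([("A", "A")] * n)
    mh_genotypes = [("A", "A")] * (n - 1) + [("A", "A;3:G>C")]
    (g,) = hobs_gain(target, _call_table(mh_genotypes))
    assert 0 < g.delta <= 1 / n + 1e-12


def test_hobs_mh_never_below_target_on_simulated_data(sim):
    """Refining alleles with phased flanking variants cannot merge
    heterozygotes: H_obs(MH) >= H_obs(target) at every simulated locus."""
    gains = hobs_gain(sim.target_calls, sim.mh_calls)
    assert len(gains) == sim.config.n_loci
    for g in gains:
        assert g.hobs_mh >= g.hobs_target - 1e-12


def test_planted_haplotype_gain_recovered_within_3_se():
    """A flanking SNV riding one target haplotype raises H_obs by the
    analytically expected amount."""
    from iisnp.synthetic_data import (
        FlankSpec, SimConfig, expected_hobs_gain, make_panel, simulate_genotypes,
    )

    base_cfg = dict(
        populations=(("Caucasian", 500),), n_loci=2, fst=0.0, freq_range=(0.5, 0.5),
    )
    probe = make_panel(SimConfig(**base_cfg, flank_specs={}), 3)
    ref_base = probe.loci[1].amplicon_ref[40]
    alt_base = "A" if ref_base != "A" else "G"
    spec = FlankSpec(offset=40, kind="snv", alt_base=alt_base, attached_to="ref", freq=0.4)
    cfg = SimConfig(**base_cfg, flank_specs={1: (spec,)})
    panel = make_panel(cfg, 3)
    truth = simulate_genotypes(panel, cfg, 3)
    rsid = panel.loci[1].rsid
    # build call tables straight from the phased truth
    t = truth.haplotypes[truth.haplotypes["rsid"] == rsid]
    target = _call_table(
        [(r.hap1.split(";")[0], r.hap2.split(";")[0]) for r in t.itertuples(index=False)], rsid
    )
    mh = _call_table([(r.hap1, r.hap2) for r in t.itertuples(index=False)], rsid)
    (g,) = hobs_gain(target, mh)
    exp_t, exp_m = expected_hobs_gain(panel, truth.target_freqs, rsid, "Caucasian")
    n = 500
    se = (exp_t * (1 - exp_t) / n) ** 0.5 + (exp_m * (1 - exp_m) / n) ** 0.5
    assert g.delta == pytest.approx(exp_m - exp_t, abs=3 * se)
    assert g.delta > 0
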