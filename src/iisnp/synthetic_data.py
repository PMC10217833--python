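"""Synthetic data generator with known ground truth.

Emulates the statistical structure of a four-population, 94-locus identity
SNP study: Balding-Nichols divergence of population allele frequencies
around balanced base frequencies, HWE genotypes within populations, a
lognormal per-locus coverage scale spanning roughly two orders of magnitude
around a 553x median, negative-binomial per-sample depth, beta-binomial
heterozygote allele imbalance with configurable skewed loci, iid sequencing
errors sprinkled over reads, phased flanking variants riding on specific
target alleles, and a rare one-base deletion in a homopolymer adjacent to
the first locus's target SNP.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so panel, genotypes, and reads are
independently regenerable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from iisnp.flanking_microhap import FlankingVariant, build_microhap
from iisnp.panel_io import (
    DEFAULT_POPULATIONS,
    AlleleCounts,
    SnpLocus,
    write_counts,
    write_frequencies,
    write_panel,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class FlankSpec:
    """A planted flanking variant phased to one target allele.

    ``freq`` is the conditional frequency of the variant given a haplotype
    carrying ``attached_to`` ("ref" or "alt") at the target SNP.
    """

    offset: int
    kind: str  # "snv" | "deletion"
    alt_base: str  # substituted base for snv, "" for deletion
    attached_to: str  # "ref" | "alt"
    freq: float


@dataclass
class SimConfig:
    """Study-design knobs; defaults reproduce the study conditions."""

    populations: tuple[tuple[str, int], ...] = (
        (DEFAULT_POPULATIONS[0], 342),
        (DEFAULT_POPULATIONS[1], 97),
        (DEFAULT_POPULATIONS[2], 361),
        (DEFAULT_POPULATIONS[3], 236),
    )
    n_loci: int = 94
    freq_range: tuple[float, float] = (0.2, 0.8)  # base alt-allele frequency
    fst: float = 0.05
    coverage_median: float = 553.0
    coverage_log_sigma: float = 1.0  # lognormal sd of per-locus scale (ln units)
    nb_dispersion: float = 8.0  # negative-binomial size for per-sample depth
    allele_bias: float = 0.5  # expected alt-allele read fraction in hets
    bias_concentration: float = 150.0  # beta concentration of the het split
    skewed_loci: dict[int, float] = field(default_factory=lambda: {1: 0.30, 2: 0.35})
    error_rate: float = 0.003  # per-base iid error rate
    amplicon_length: int = 60
    # fraction of loci carrying a common / a rare phased flanking SNV
    p_flank_common: float = 0.13
    p_flank_rare: float = 0.5
    common_flank_freq: tuple[float, float] = (0.25, 0.5)
    rare_flank_freq: tuple[float, float] = (0.005, 0.05)
    rare_indel_freq: float = 1e-4  # homopolymer deletion at locus 0
    flank_specs: dict[int, tuple[FlankSpec, ...]] | None = None  # explicit override

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.populations)


def fixture_config(**overrides) -> SimConfig:
    """Test-sized configuration: 4 populations x 20 loci x 50 samples."""
    defaults = dict(
        populations=(
            (DEFAULT_POPULATIONS[0], 17),
            (DEFAULT_POPULATIONS[1], 5),
            (DEFAULT_POPULATIONS[2], 16),
            (DEFAULT_POPULATIONS[3], 12),
        ),
        n_loci=20,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class SimPanel:
    """Generated panel plus the planted flanking-variant specs per locus."""

    loci: list[SnpLocus]
    flank_specs: dict[str, tuple[FlankSpec, ...]]  # rsid -> specs


@dataclass
class SimTruth:
    """Ground truth: per-sample haplotype pairs and true allele frequencies."""

    haplotypes: pd.DataFrame  # sample_id, population, rsid, hap1, hap2
    target_freqs: pd.DataFrame  # rsid, population, allele, frequency (truth)
    hap_catalog: dict[tuple[str, str], tuple[str, str]]  # (rsid, hap) -> (sequence, target allele)


def _spawn(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def make_panel(config: SimConfig, seed: int) -> SimPanel:
    """Generate a synthetic locus panel with planted flanking-variant specs.

    Locus 0 is built with a four-base homopolymer starting at the target SNP
    (reference T, alternate C) and carries the rare one-base homopolymer
    deletion phased to the alternate allele, mirroring the alignment-artifact
    scenario.  Chromosomes cycle through 1..22 so some pairs are syntenic.
    """
    (rng,) = _spawn(np.random.SeedSequence(entropy=seed, spawn_key=(0,)), 1)
    L = config.amplicon_length
    t = L // 2
    loci: list[SnpLocus] = []
    specs: dict[str, tuple[FlankSpec, ...]] = {}
    pos_used: dict[str, int] = {}
    for i in range(config.n_loci):
        rsid = f"rs9{i:06d}"
        chrom = f"chr{(i % 22) + 1}"
        pos = pos_used.get(chrom, 0) + int(rng.integers(1_000_000, 60_000_000))
        pos_used[chrom] = pos
        seq = "".join(rng.choice(list(_BASES), size=L))
        if i == 0:
            # homopolymer-artifact locus: target T heads a TTTT run; flanks free of T runs
            seq = seq[: t - 1] + "A" + "TTTT" + "G" + seq[t + 5:]
            ref, alt = "T", "C"
        else:
            ref = seq[t]
            alt = rng.choice([b for b in _BASES if b != ref])
            # avoid homopolymer ambiguity around the target at ordinary loci
            while seq[t - 1] == ref or seq[t + 1] == ref:
                seq = seq[: t - 1] + "".join(rng.choice(list(_BASES), size=3)) + seq[t + 2:]
                ref = seq[t]
                alt = rng.choice([b for b in _BASES if b != ref])
        strand = "reverse" if i % 5 == 4 else "forward"
        loci.append(
            SnpLocus(
                rsid=rsid, chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                reporting_strand=strand, amplicon_ref=seq, target_offset=t,
            )
        )

        if config.flank_specs is not None:
            specs[rsid] = config.flank_specs.get(i, ())
            continue
        planted: list[FlankSpec] = []
        if i == 0 and config.rare_indel_freq > 0:
            planted.append(FlankSpec(offset=t + 1, kind="deletion", alt_base="",
                                     attached_to="alt", freq=config.rare_indel_freq))
        if rng.random() < config.p_flank_common:
            planted.append(_random_snv_spec(rng, seq, t, config.common_flank_freq))
        if rng.random() < config.p_flank_rare:
            planted.append(_random_snv_spec(rng, seq, t, config.rare_flank_freq))
        specs[rsid] = tuple(planted)
    return SimPanel(loci=loci, flank_specs=specs)


def _random_snv_spec(rng: np.random.Generator, seq: str, t: int, freq_range: tuple[float, float]) -> FlankSpec:
    offset = int(rng.integers(5, len(seq) - 5))
    while abs(offset - t) < 3:
        offset = int(rng.integers(5, len(seq) - 5))
    alt = rng.choice([b for b in _BASES if b != seq[offset]])
    return FlankSpec(
        offset=offset, kind="snv", alt_base=str(alt),
        attached_to=str(rng.choice(["ref", "alt"])),
        freq=float(rng.uniform(*freq_range)),
    )


def _hap_variants(spec_hits: tuple[FlankSpec, ...], locus: SnpLocus) -> tuple[FlankingVariant, ...]:
    out = []
    for s in spec_hits:
        if s.kind == "snv":
            out.append(FlankingVariant(s.offset, "snv", locus.amplicon_ref[s.offset], s.alt_base))
        else:
            out.append(FlankingVariant(s.offset, "deletion", locus.amplicon_ref[s.offset], ""))
    return tuple(out)


def _hap_sequence(locus: SnpLocus, target_allele: str, variants: tuple[FlankingVariant, ...]) -> str:
    seq = list(locus.amplicon_ref)
    seq[locus.target_offset] = target_allele
    for v in sorted(variants, key=lambda v: -v.offset):
        if v.kind == "snv":
            seq[v.offset] = v.alt
        elif v.kind == "deletion":
            del seq[v.offset: v.offset + len(v.ref)]
        else:
            seq[v.offset: v.offset] = list(v.alt)
    return "".join(seq)


def simulate_genotypes(panel: SimPanel, config: SimConfig, seed: int) -> SimTruth:
    """Draw population allele frequencies and phased diploid genotypes.

    Per population and locus the alt-allele frequency follows a
    Balding-Nichols Beta around the base frequency with divergence
    ``fst`` (``fst = 0`` collapses to the base frequency exactly);
    genotypes are drawn under HWE, and each haplotype independently
    acquires its phased flanking variants at their conditional frequencies.
    """
    (rng,) = _spawn(np.random.SeedSequence(entropy=seed, spawn_key=(1,)), 1)
    base = rng.uniform(*config.freq_range, size=config.n_loci)

    freq_rows = []
    hap_catalog: dict[tuple[str, str], tuple[str, str]] = {}
    records: list[dict] = []
    for pop, n_pop in config.populations:
        if config.fst > 0:
            a = base * (1 - config.fst) / config.fst
            b = (1 - base) * (1 - config.fst) / config.fst
            p_alt = rng.beta(a, b)
        else:
            p_alt = base.copy()
        for j, locus in enumerate(panel.loci):
            freq_rows.append({"rsid": locus.rsid, "population": pop, "allele": locus.alt_allele,
                              "frequency": float(p_alt[j])})
            freq_rows.append({"rsid": locus.rsid, "population": pop, "allele": locus.ref_allele,
                              "frequency": float(1 - p_alt[j])})
        sample_ids = [f"{pop.replace(' ', '')}_{k:04d}" for k in range(n_pop)]
        for j, locus in enumerate(panel.loci):
            specs = panel.flank_specs.get(locus.rsid, ())
            # 2 gametes per sample: target allele then flank variants per spec
            is_alt = rng.random((n_pop, 2)) < p_alt[j]
            spec_draws = rng.random((n_pop, 2, max(len(specs), 1)))
            for k, sid in enumerate(sample_ids):
                haps = []
                for g in range(2):
                    target = locus.alt_allele if is_alt[k, g] else locus.ref_allele
                    attached = "alt" if is_alt[k, g] else "ref"
                    hits = tuple(
                        s for m, s in enumerate(specs)
                        if s.attached_to == attached and spec_draws[k, g, m] < s.freq
                    )
                    variants = _hap_variants(hits, locus)
                    mh = build_microhap(target, variants, rsid=locus.rsid,
                                        target_offset=locus.target_offset)
                    key = (locus.rsid, mh.allele_string)
                    if key not in hap_catalog:
                        hap_catalog[key] = (_hap_sequence(locus, target, variants), target)
                    haps.append(mh.allele_string)
                records.append({"sample_id": sid, "population": pop, "rsid": locus.rsid,
                                "hap1": haps[0], "hap2": haps[1]})
    truth = pd.DataFrame(records, columns=["sample_id", "population", "rsid", "hap1", "hap2"])
    freqs = pd.DataFrame(freq_rows)
    return SimTruth(haplotypes=truth, target_freqs=freqs, hap_catalog=hap_catalog)


def simulate_reads(
    truth: SimTruth,
    panel: SimPanel,
    config: SimConfig,
    seed: int,
    deterministic_depth: float | None = None,
) -> list[AlleleCounts]:
    """Generate per-sample per-locus sequence read counts from the truth.

    Depth per cell is negative-binomial around a lognormal per-locus scale
    (or fixed to ``deterministic_depth`` for noiseless-limit experiments);
    heterozygote reads split beta-binomially with the locus's allele bias;
    each read independently carries a sequencing error with probability
    ``1 - (1 - error_rate)^L``, realized as one random substitution.
    """
    (rng,) = _spawn(np.random.SeedSequence(entropy=seed, spawn_key=(2,)), 1)
    rsid_order = [l.rsid for l in panel.loci]
    locus_by = {l.rsid: l for l in panel.loci}
    if deterministic_depth is None:
        scale = np.exp(rng.normal(np.log(config.coverage_median), config.coverage_log_sigma,
                                  size=len(rsid_order)))
    else:
        scale = np.full(len(rsid_order), float(deterministic_depth))
    locus_scale = dict(zip(rsid_order, scale))
    locus_index = {r: i for i, r in enumerate(rsid_order)}

    out: list[AlleleCounts] = []
    for row in truth.haplotypes.itertuples(index=False):
        locus = locus_by[row.rsid]
        mu = locus_scale[row.rsid]
        if deterministic_depth is not None:
            depth = int(mu)
        else:
            k = config.nb_dispersion
            depth = int(rng.negative_binomial(k, k / (k + mu)))
        if depth == 0:
            out.append(AlleleCounts(row.sample_id, row.population, row.rsid,
                                    [(locus.amplicon_ref, 0)]))
            continue
        seq1, t1 = truth.hap_catalog[(row.rsid, row.hap1)]
        seq2, t2 = truth.hap_catalog[(row.rsid, row.hap2)]
        if t1 != t2:
            b = config.skewed_loci.get(locus_index[row.rsid], config.allele_bias)
            kappa = config.bias_concentration
            frac_alt = rng.beta(b * kappa, (1 - b) * kappa)
            n_alt = rng.binomial(depth, frac_alt)
            d1 = n_alt if t1 == locus.alt_allele else depth - n_alt
        else:
            d1 = rng.binomial(depth, 0.5)
        d2 = depth - d1

        pooled: dict[str, int] = {}
        for seq, d in ((seq1, d1), (seq2, d2)):
            if d == 0:
                continue
            if config.error_rate > 0:
                p_err = 1.0 - (1.0 - config.error_rate) ** len(seq)
                n_err = rng.binomial(d, p_err)
            else:
                n_err = 0
            pooled[seq] = pooled.get(seq, 0) + (d - n_err)
            if n_err:
                positions = rng.integers(len(seq), size=n_err)
                subs = rng.integers(3, size=n_err)
                codes, counts_ = np.unique(positions * 3 + subs, return_counts=True)
                for code, cnt in zip(codes, counts_):
                    pos, sub = divmod(int(code), 3)
                    base = [b for b in _BASES if b != seq[pos]][sub]
                    err_seq = seq[:pos] + base + seq[pos + 1:]
                    pooled[err_seq] = pooled.get(err_seq, 0) + int(cnt)
        obs = [(s, c) for s, c in pooled.items() if c > 0]
        if not obs:
            obs = [(locus.amplicon_ref, 0)]
        out.append(AlleleCounts(row.sample_id, row.population, row.rsid, obs))
    return out


def expected_hobs_gain(panel: SimPanel, target_freqs: pd.DataFrame, rsid: str, population: str) -> tuple[float, float]:
    """Analytic expected (H_obs target, H_obs MH) from the planted truth.

    Under HWE the expected observed heterozygosity equals the expected
    heterozygosity: ``1 - sum f_h^2`` over haplotype (allele) frequencies.
    """
    locus = next(l for l in panel.loci if l.rsid == rsid)
    specs = panel.flank_specs.get(rsid, ())
    sub = target_freqs[(target_freqs["rsid"] == rsid) & (target_freqs["population"] == population)]
    p = {r.allele: r.frequency for r in sub.itertuples(index=False)}
    hobs_target = 1.0 - sum(f * f for f in p.values())

    hap_freqs: list[float] = []
    for allele, attached in ((locus.ref_allele, "ref"), (locus.alt_allele, "alt")):
        attached_specs = [s for s in specs if s.attached_to == attached]
        for hits in product([False, True], repeat=len(attached_specs)):
            f = p[allele]
            for hit, s in zip(hits, attached_specs):
                f *= s.freq if hit else (1.0 - s.freq)
            hap_freqs.append(f)
    hobs_mh = 1.0 - sum(f * f for f in hap_freqs)
    return hobs_target, hobs_mh


def make_fixture_suite(out_dir: str | Path, seed: int, config: SimConfig | None = None) -> dict[str, Path]:
    """Write a complete, mutually consistent input file set for tests.

    Emits panel TSV, counts TSV, haplotype truth TSV, a known-allele registry
    (haplotypes carried by at least two samples; rarer ones surface as
    novel), and the true target-allele frequency CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = config or fixture_config()
    panel = make_panel(config, seed)
    truth = simulate_genotypes(panel, config, seed)
    counts = simulate_reads(truth, panel, config, seed)

    paths = {
        "panel": out_dir / "panel.tsv",
        "counts": out_dir / "counts.tsv",
        "truth": out_dir / "truth.tsv",
        "registry": out_dir / "registry.tsv",
        "frequencies": out_dir / "frequencies.csv",
    }
    write_panel(panel.loci, paths["panel"])
    write_counts(counts, paths["counts"])
    truth.haplotypes.to_csv(paths["truth"], sep="\t", index=False)

    carriers = (
        pd.concat([
            truth.haplotypes[["rsid", "hap1"]].rename(columns={"hap1": "allele_string"}),
            truth.haplotypes[["rsid", "hap2"]].rename(columns={"hap2": "allele_string"}),
        ])
        .groupby(["rsid", "allele_string"]).size().rename("n").reset_index()
    )
    registry = carriers[carriers["n"] >= 2][["rsid", "allele_string"]].sort_values(["rsid", "allele_string"])
    registry.to_csv(paths["registry"], sep="\t", index=False)

    freqs = truth.target_freqs.copy()
    counts_per_pop = dict(config.populations)
    freqs["n_alleles"] = freqs["population"].map(lambda p: 2 * counts_per_pop[p])
    write_frequencies(freqs.sort_values(["rsid", "population", "allele"]), paths["frequencies"])
    return paths
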