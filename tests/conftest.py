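"""Shared fixtures: one session-scoped synthetic dataset used across modules."""

from dataclasses import dataclass

import pandas as pd
import pytest
from hypothesis import settings

from iisnp.flanking_microhap import call_microhaps
from iisnp.synthetic_data import (
    SimConfig,
    SimPanel,
    SimTruth,
    fixture_config,
    make_panel,
    simulate_genotypes,
    simulate_reads,
)

SEED = 20230512

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@dataclass
class SimBundle:
    config: SimConfig
    panel: SimPanel
    truth: SimTruth
    counts: list
    mh_calls: pd.DataFrame
    target_calls: pd.DataFrame
    allele_table: pd.DataFrame


@pytest.fixture(scope="session")
def sim() -> SimBundle:
    """Default test-sized dataset (4 populations, 20 loci, 50 samples),
    simulated once and fully called under default thresholds."""
    config = fixture_config()
    panel = make_panel(config, SEED)
    truth = simulate_genotypes(panel, config, SEED)
    counts = simulate_reads(truth, panel, config, SEED)
    mh_calls, target_calls, allele_table = call_microhaps(counts, panel.loci)
    return SimBundle(config, panel, truth, counts, mh_calls, target_calls, allele_table)


@pytest.fixture(scope="session")
def true_genotypes(sim: SimBundle) -> pd.DataFrame:
    """Ground-truth target-SNP genotype table derived from the haplotype truth."""
    t = sim.truth.haplotypes
    rows = []
    for r in t.itertuples(index=False):
        a1, a2 = sorted((r.hap1.split(";")[0], r.hap2.split(";")[0]))
        rows.append(
            {
                "sample_id": r.sample_id, "population": r.population, "rsid": r.rsid,
                "status": "called", "allele1": a1, "allele2": a2,
                "coverage": 1000, "acr": 1.0 if a1 != a2 else "", "flags": "",
            }
        )
    return pd.DataFrame(rows)
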