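import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from pulsechase import (Genotype, IPSimConfig, PeptideQuantRecord,
                        TurnoverSimConfig, simulate_ip, simulate_turnover)


def make_record(peptide="ACDEFGHIK", protein="P1", heavy=100.0, light=10.0,
                t=0.0, genotype="MUT", replicate=1):
    return PeptideQuantRecord(peptide=peptide, protein=protein, heavy_area=heavy,
                              light_area=light, chase_time=t, genotype=genotype,
                              replicate=replicate)


@pytest.fixture
def small_peptide_records():
    """Two proteins, two genotypes, anchors plus one later time."""
    rows = []
    for genotype in ("MUT", "CTRL"):
        for prot, areas0, areas5 in (("P1", (100.0, 200.0), (50.0, 90.0)),
                                     ("P2", (80.0,), (20.0,))):
            for j, a in enumerate(areas0):
                rows.append(make_record(peptide=f"{prot}PEP{j}K", protein=prot,
                                        heavy=a, light=10.0, t=0.0, genotype=genotype))
            for j, a in enumerate(areas5):
                rows.append(make_record(peptide=f"{prot}PEP{j}K", protein=prot,
                                        heavy=a, light=120.0, t=5.0, genotype=genotype))
    return rows


@pytest.fixture
def noiseless_config():
    return TurnoverSimConfig(n_proteins=40, peptides_per_protein=(3, 6),
                             noise_cv=0.0, dropout_midpoint=0.0, seed=123)


@pytest.fixture
def default_turnover_sim():
    cfg = TurnoverSimConfig(n_proteins=80, seed=42)
    records, truth = simulate_turnover(cfg)
    return cfg, records, truth


@pytest.fixture
def default_ip_sim():
    cfg = IPSimConfig(seed=42)
    records, truth = simulate_ip(cfg)
    return cfg, records, truth
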