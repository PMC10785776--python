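"""Synthetic post-search tables with known ground truth.

Two generators emulate the statistical structure of the study's two
experiments so every downstream stage has a parameter-recovery surface:

``simulate_turnover``
    SILAC pulse-chase peptide quantification. Cultures are labeled to a
    heavy fraction E (``label_efficiency``) by the end of the pulse, then
    chased; pre-existing (heavy) protein decays first-order with a
    per-protein rate k while newly made (light) protein replaces it. The
    cells are postmitotic, so the total pool is assumed stationary
    (synthesis balances degradation): for protein p, peptide j, chase time
    t and genotype g the expected areas are

        heavy = A_p * ion_j * E * exp(-k_{p,g} * t)
        light = A_p * ion_j * (1 - E * exp(-k_{p,g} * t))

    where A_p is protein abundance and ion_j a peptide ionization factor
    drawn once and shared across every run. A fraction of proteins is
    "slowed" in the mutant genotype (k_mut = rate_factor * k_ctrl).
    Observed areas carry multiplicative lognormal noise (mean 1, CV
    ``noise_cv``); whole peptide x run observations drop out with a
    logistic probability decreasing in the expected total (heavy+light)
    intensity, which under the stationary-pool assumption is constant over
    the chase.

``simulate_ip``
    Crosslink-IP spectral counts. Each genotype x replicate contributes a
    bait (VCP) run and an IgG control run. True interactors co-precipitate
    with the bait (counts Poisson, proportional to the bait count) and leak
    only weakly into the IgG run; background proteins appear with
    comparable expected counts in both runs; a configurable fraction of
    true interactors is exclusive to one genotype.

Draw order is fixed and documented on each function, and each generator
consumes a single ``numpy.random.default_rng(seed)`` stream, so a given
config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .records import Bait, Genotype, PeptideQuantRecord, SpectralCountRecord

_AMINO_ACIDS = np.array(list("ACDEFGHILMNPQSTVWY"))  # tryptic interior (no K/R)

BAIT_ACCESSION = "VCP"


@dataclass
class TurnoverSimConfig:
    """Study conditions for the pulse-chase generator.

    Defaults mirror the experimental design: chase sampling at 0/1/5/21
    days after a pulse reaching ~90% labeling, two genotypes, and a
    lognormal spread of degradation rates (median 0.15/day, i.e. half-life
    ~4.6 days, 0.45 decades SD) under which roughly half of the heavy
    signal is gone by day 5 and ~15% remains at day 21. A fifth of
    proteins are slowed to half their control rate in the mutant.
    """

    n_proteins: int = 300
    peptides_per_protein: tuple[int, int] = (3, 8)
    chase_times: tuple[float, ...] = (0.0, 1.0, 5.0, 21.0)
    k_log10_mean: float = -0.8239  # log10(0.15 / day)
    k_log10_sd: float = 0.45
    frac_slowed: float = 0.2
    rate_factor: float = 0.5
    label_efficiency: float = 0.9
    noise_cv: float = 0.2
    dropout_midpoint: float = 3e3  # intensity at 50% dropout; <=0 disables
    dropout_steepness: float = 1.5  # logistic slope per decade of intensity
    abundance_log10_mean: float = 5.0
    abundance_log10_sd: float = 0.5
    ion_log_sd: float = 0.5  # lognormal sigma of peptide ionization factors
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ConfigError("peptides_per_protein must satisfy 1 <= min <= max")
        times = tuple(float(t) for t in self.chase_times)
        if sorted(times) != list(times) or len(set(times)) != len(times):
            raise ConfigError("chase_times must be strictly ascending")
        if not times or times[0] != 0.0:
            raise ConfigError("chase_times must start at 0 (the pulse-end anchor)")
        if any(t < 0 for t in times):
            raise ConfigError("chase_times must be nonnegative")
        if not 0.0 <= self.frac_slowed <= 1.0:
            raise ConfigError("frac_slowed must be in [0, 1]")
        if not 0.0 < self.rate_factor <= 1.0:
            raise ConfigError("rate_factor must be in (0, 1]")
        if not 0.0 < self.label_efficiency <= 1.0:
            raise ConfigError("label_efficiency must be in (0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated pulse-chase table."""

    proteins: pd.DataFrame  # protein, abundance, k_ctrl, k_mut, slowed
    peptides: pd.DataFrame  # protein, peptide, ion_factor

    def rate(self, protein: str, genotype: Genotype | str) -> float:
        col = "k_mut" if Genotype(str(genotype).upper()) is Genotype.MUT else "k_ctrl"
        row = self.proteins.loc[self.proteins["protein"] == protein, col]
        return float(row.iloc[0])


@dataclass
class IPSimConfig:
    """Study conditions for the crosslink-IP spectral-count generator.

    Three IP replicates per genotype, each paired with an IgG control run,
    matching the triple-replicate design of the interactome experiment.
    """

    n_true_interactors: int = 60
    n_background: int = 40
    bait_count_mean: float = 60.0
    interactor_ratio_range: tuple[float, float] = (0.05, 0.5)
    igg_leak_range: tuple[float, float] = (0.0, 0.15)
    frac_mut_exclusive: float = 0.2
    frac_ctrl_exclusive: float = 0.2
    background_count_range: tuple[float, float] = (1.0, 20.0)
    n_replicates: int = 3
    count_noise: str = "poisson"
    seed: int = 0

    def validate(self) -> None:
        if self.n_true_interactors < 1:
            raise ConfigError("n_true_interactors must be >= 1")
        if self.n_background < 0:
            raise ConfigError("n_background must be >= 0")
        if self.bait_count_mean <= 0:
            raise ConfigError("bait_count_mean must be > 0")
        for name in ("interactor_ratio_range", "igg_leak_range", "background_count_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigError(f"{name} must be (low, high) with low <= high")
        if self.interactor_ratio_range[0] <= 0:
            raise ConfigError("interactor_ratio_range must be positive")
        if not (0 <= self.igg_leak_range[0] and self.igg_leak_range[1] <= 1):
            raise ConfigError("igg_leak_range must lie in [0, 1]")
        if not 0 <= self.frac_mut_exclusive <= 1 or not 0 <= self.frac_ctrl_exclusive <= 1:
            raise ConfigError("exclusivity fractions must lie in [0, 1]")
        if self.frac_mut_exclusive + self.frac_ctrl_exclusive > 1:
            raise ConfigError("exclusivity fractions must sum to <= 1 "
                              "(the remainder are shared interactors)")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.count_noise != "poisson":
            raise ConfigError(f"unsupported count_noise {self.count_noise!r}")


def _noise_factor(z: np.ndarray, cv: float) -> np.ndarray:
    """Mean-one lognormal multiplier with coefficient of variation cv."""
    if cv == 0:
        return np.ones_like(z)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def _dropout_prob(total_intensity: np.ndarray, midpoint: float, steepness: float) -> np.ndarray:
    """Logistic missingness, decreasing in log10 expected total intensity."""
    if midpoint <= 0:
        return np.zeros_like(total_intensity)
    x = np.log10(total_intensity) - np.log10(midpoint)
    return 1.0 / (1.0 + np.exp(np.log(10.0) * steepness * x))


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    """Unique tryptic-looking sequences (random interior, K/R terminus)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(7, 20))
        body = "".join(rng.choice(_AMINO_ACIDS, size=length))
        term = "K" if rng.random() < 0.5 else "R"
        seq = body + term
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out


def simulate_turnover(config: TurnoverSimConfig
                      ) -> tuple[list[PeptideQuantRecord], SimulationTruth]:
    """Generate a pulse-chase peptide table plus its ground truth.

    Draw order (single RNG stream): protein abundances; control rates;
    slowed flags; peptides-per-protein counts; peptide sequences;
    ionization factors; then per genotype (MUT first, CTRL second) one
    block each of heavy-noise normals, light-noise normals and dropout
    uniforms, shaped (peptide, chase_time). Records are emitted ordered by
    genotype (MUT, CTRL), then chase time, then protein, then peptide.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    times = np.array([float(t) for t in config.chase_times])
    E = config.label_efficiency

    abundance = 10.0 ** rng.normal(config.abundance_log10_mean, config.abundance_log10_sd, n)
    k_ctrl = 10.0 ** rng.normal(config.k_log10_mean, config.k_log10_sd, n)
    slowed = rng.random(n) < config.frac_slowed
    k_mut = np.where(slowed, k_ctrl * config.rate_factor, k_ctrl)
    lo, hi = config.peptides_per_protein
    n_pep = rng.integers(lo, hi + 1, size=n)

    total_pep = int(n_pep.sum())
    pep_protein_idx = np.repeat(np.arange(n), n_pep)
    sequences = _peptide_sequences(rng, total_pep)
    ion = rng.lognormal(mean=0.0, sigma=config.ion_log_sd, size=total_pep)

    protein_names = [f"P{i + 1:05d}" for i in range(n)]
    truth = SimulationTruth(
        proteins=pd.DataFrame({
            "protein": protein_names,
            "abundance": abundance,
            "k_ctrl": k_ctrl,
            "k_mut": k_mut,
            "slowed": slowed,
        }),
        peptides=pd.DataFrame({
            "protein": [protein_names[i] for i in pep_protein_idx],
            "peptide": sequences,
            "ion_factor": ion,
        }),
    )

    base = abundance[pep_protein_idx] * ion  # expected total intensity, constant in t
    records: list[PeptideQuantRecord] = []
    for genotype, k in ((Genotype.MUT, k_mut), (Genotype.CTRL, k_ctrl)):
        decay = np.exp(-np.outer(k[pep_protein_idx], times))  # (pep, time)
        mu_heavy = base[:, None] * E * decay
        mu_light = base[:, None] * (1.0 - E * decay)
        z_heavy = rng.standard_normal(mu_heavy.shape)
        z_light = rng.standard_normal(mu_heavy.shape)
        u_drop = rng.random(mu_heavy.shape)
        heavy = mu_heavy * _noise_factor(z_heavy, config.noise_cv)
        light = mu_light * _noise_factor(z_light, config.noise_cv)
        p_drop = _dropout_prob(np.broadcast_to(base[:, None], mu_heavy.shape),
                               config.dropout_midpoint, config.dropout_steepness)
        keep = u_drop >= p_drop
        for ti in range(len(times)):
            for j in range(total_pep):
                if not keep[j, ti]:
                    continue
                records.append(PeptideQuantRecord(
                    peptide=sequences[j],
                    protein=protein_names[pep_protein_idx[j]],
                    heavy_area=float(heavy[j, ti]),
                    light_area=float(light[j, ti]),
                    chase_time=float(times[ti]),
                    genotype=genotype,
                    replicate=1,
                ))
    return records, truth


def simulate_ip(config: IPSimConfig
                ) -> tuple[list[SpectralCountRecord], pd.DataFrame]:
    """Generate IP spectral-count runs plus a per-genotype truth table.

    The first ``round(frac_mut_exclusive * n_true)`` interactors are
    mutant-exclusive, the next ``round(frac_ctrl_exclusive * n_true)``
    control-exclusive, the remainder shared (deterministic assignment by
    index). Draw order: interactor bait-proportionality ratios; interactor
    IgG leak fractions; background expected counts; then per genotype
    (MUT, CTRL) and replicate (1..R): the bait count (redrawn until
    positive), interactor VCP counts, background VCP counts, interactor
    IgG leak counts, background IgG counts. Rows with zero counts are not
    emitted (absence from a run is meaningful downstream).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_true = config.n_true_interactors
    n_mut_excl = int(round(config.frac_mut_exclusive * n_true))
    n_ctrl_excl = int(round(config.frac_ctrl_exclusive * n_true))
    if n_mut_excl + n_ctrl_excl > n_true:
        raise ConfigError("rounded exclusive counts exceed n_true_interactors")

    interactors = [f"INT{i + 1:04d}" for i in range(n_true)]
    background = [f"BKG{i + 1:04d}" for i in range(config.n_background)]
    in_mut = np.ones(n_true, dtype=bool)
    in_ctrl = np.ones(n_true, dtype=bool)
    in_ctrl[:n_mut_excl] = False
    in_mut[n_mut_excl:n_mut_excl + n_ctrl_excl] = False
    member = {Genotype.MUT: in_mut, Genotype.CTRL: in_ctrl}

    r_lo, r_hi = config.interactor_ratio_range
    ratios = rng.uniform(r_lo, r_hi, size=n_true)
    l_lo, l_hi = config.igg_leak_range
    leaks = rng.uniform(l_lo, l_hi, size=n_true)
    b_lo, b_hi = config.background_count_range
    bg_lambda = rng.uniform(b_lo, b_hi, size=config.n_background)

    records: list[SpectralCountRecord] = []

    def emit(protein: str, bait: Bait, genotype: Genotype, replicate: int, count: int):
        if count > 0:
            records.append(SpectralCountRecord(
                protein=protein, bait=bait, genotype=genotype,
                replicate=replicate, spec_count=int(count)))

    for genotype in (Genotype.MUT, Genotype.CTRL):
        active = member[genotype]
        for rep in range(1, config.n_replicates + 1):
            bait_count = 0
            while bait_count < 1:
                bait_count = int(rng.poisson(config.bait_count_mean))
            emit(BAIT_ACCESSION, Bait.VCP, genotype, rep, bait_count)
            vcp_counts = rng.poisson(ratios * bait_count)
            for i, prot in enumerate(interactors):
                if active[i]:
                    emit(prot, Bait.VCP, genotype, rep, int(vcp_counts[i]))
            bg_vcp = rng.poisson(bg_lambda) if config.n_background else np.array([], dtype=int)
            for i, prot in enumerate(background):
                emit(prot, Bait.VCP, genotype, rep, int(bg_vcp[i]))
            igg_counts = rng.poisson(leaks * ratios * config.bait_count_mean)
            for i, prot in enumerate(interactors):
                if active[i]:
                    emit(prot, Bait.IGG, genotype, rep, int(igg_counts[i]))
            bg_igg = rng.poisson(bg_lambda) if config.n_background else np.array([], dtype=int)
            for i, prot in enumerate(background):
                emit(prot, Bait.IGG, genotype, rep, int(bg_igg[i]))

    truth = pd.DataFrame({
        "protein": [BAIT_ACCESSION] + interactors + background,
        "role": (["bait"]
                 + ["interactor_mut_only"] * n_mut_excl
                 + ["interactor_ctrl_only"] * n_ctrl_excl
                 + ["interactor_shared"] * (n_true - n_mut_excl - n_ctrl_excl)
                 + ["background"] * config.n_background),
        "interactor_mut": ([False] + list(in_mut) + [False] * config.n_background),
        "interactor_ctrl": ([False] + list(in_ctrl) + [False] * config.n_background),
    })
    return records, truth
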