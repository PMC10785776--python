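"""Protein-level turnover ratios, persistence calls and comparisons.

The pulse-chase readout for one protein is its day-30-anchored heavy ratio

    R(t) = mean heavy area over peptides at chase time t
           / mean heavy area over peptides at chase time 0

computed per genotype. Rollup averages peptide heavy areas arithmetically,
singletons included, without requiring matched peptide sets across times.
Filtering follows three rules: a protein needs a chase-time-0 anchor and at
least one later time point; any individual R(t) >= 1 is discarded (heavy
signal cannot grow in a chase, so such ratios are measurement artifacts);
and a protein with no surviving ratio is dropped.

A protein "persists" at time t when it is quantified in both genotypes at t
and its mutant ratio strictly exceeds the control ratio (ties do not
count). Cross-genotype statistics mirror the study's tests: a paired
two-tailed t-test of per-protein normalized intensities at one time point,
and an unpaired t-test on per-peptide self-normalized values for a single
protein (each peptide's heavy area at t divided by the same peptide's heavy
area at time 0, so ionization efficiency cancels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .records import Genotype, PeptideQuantRecord
from .tables_io import peptide_records_to_frame


@dataclass
class ProteinTurnoverProfile:
    """Per protein x genotype: anchor heavy abundance and later ratios."""

    protein: str
    genotype: Genotype
    anchor_heavy: float                 # mean heavy area at chase time 0
    ratios: dict[float, float]          # chase_time > 0 -> R in (0, 1)
    n_peptides: dict[float, int]        # contributing peptides per time (incl. 0)


@dataclass
class TimePointCall:
    common: bool
    mut_ratio: float | None
    ctrl_ratio: float | None
    persists: bool


@dataclass
class PersistenceCall:
    protein: str
    by_time: dict[float, TimePointCall]
    persists_all: bool


@dataclass
class PersistenceResult:
    calls: list[PersistenceCall]
    fractions: dict[float, float]       # persisting / common per time (nan if none common)
    common_counts: dict[float, int]
    venn: dict[tuple[float, ...], list[str]]  # persist-time combination -> proteins
    all_times_set: list[str]            # proteins persisting at every requested time


def _zero_variance_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float] | None:
    """Degenerate t-test handling: identical constant samples => no evidence."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.size and b.size and a.flat[0] == b.flat[0]:
            return 0.0, 1.0
        return math.inf, 0.0
    return None


def rollup_protein_heavy(records: Iterable[PeptideQuantRecord], protein: str,
                         chase_time: float, genotype: Genotype | str) -> float | None:
    """Arithmetic mean heavy area over matching quantified peptides.

    Singletons (single-peptide proteins) are included. Records with zero
    heavy area carry no heavy quantification and do not contribute.
    Returns None when nothing matches (absent value, not zero).
    """
    genotype = Genotype(str(genotype).upper()) if not isinstance(genotype, Genotype) else genotype
    areas = [r.heavy_area for r in records
             if r.protein == protein and r.chase_time == chase_time
             and r.genotype is genotype and r.heavy_area > 0]
    if not areas:
        return None
    return float(np.mean(areas))


def _heavy_frame(records: Iterable[PeptideQuantRecord]) -> pd.DataFrame:
    df = peptide_records_to_frame(records)
    return df[df["heavy_area"] > 0]


def turnover_profiles(records: Iterable[PeptideQuantRecord]) -> list[ProteinTurnoverProfile]:
    """Roll peptides up to per-protein x genotype turnover profiles.

    Applies the anchor, ratio-below-1 and nonempty-profile rules described
    in the module docstring.
    """
    df = _heavy_frame(records)
    if df.empty or not (df["chase_time"] == 0.0).any():
        raise ValidationError("input table has no quantified chase_time-0 (anchor) records")
    agg = (df.groupby(["protein", "genotype", "chase_time"])["heavy_area"]
             .agg(["mean", "size"]).reset_index())
    profiles: list[ProteinTurnoverProfile] = []
    for (protein, genotype), sub in agg.groupby(["protein", "genotype"], sort=True):
        means = dict(zip(sub["chase_time"], sub["mean"]))
        sizes = dict(zip(sub["chase_time"], sub["size"]))
        anchor = means.get(0.0)
        if anchor is None:
            continue
        ratios = {}
        n_peptides = {0.0: int(sizes[0.0])}
        for t, m in means.items():
            if t == 0.0:
                continue
            r = m / anchor
            if r < 1.0:
                ratios[float(t)] = float(r)
                n_peptides[float(t)] = int(sizes[t])
        if not ratios:
            continue
        profiles.append(ProteinTurnoverProfile(
            protein=protein, genotype=Genotype(genotype),
            anchor_heavy=float(anchor), ratios=ratios, n_peptides=n_peptides))
    return profiles


def split_profiles(profiles: Iterable[ProteinTurnoverProfile]
                   ) -> tuple[dict[str, ProteinTurnoverProfile], dict[str, ProteinTurnoverProfile]]:
    """Index profiles by protein, split into (mutant, control) maps."""
    mut: dict[str, ProteinTurnoverProfile] = {}
    ctrl: dict[str, ProteinTurnoverProfile] = {}
    for p in profiles:
        (mut if p.genotype is Genotype.MUT else ctrl)[p.protein] = p
    return mut, ctrl


def common_proteins(profiles_mut: Mapping[str, ProteinTurnoverProfile],
                    profiles_ctrl: Mapping[str, ProteinTurnoverProfile],
                    chase_time: float) -> set[str]:
    """Proteins holding a ratio at `chase_time` in both genotypes."""
    return {p for p, prof in profiles_mut.items() if chase_time in prof.ratios
            and p in profiles_ctrl and chase_time in profiles_ctrl[p].ratios}


def persistence_calls(profiles_mut: Mapping[str, ProteinTurnoverProfile],
                      profiles_ctrl: Mapping[str, ProteinTurnoverProfile],
                      chase_times: Sequence[float]) -> PersistenceResult:
    """Call persisting proteins (mutant R strictly above control) per time.

    Also reports, per time, the persisting fraction of common proteins, the
    Venn partition of persister sets across times, and the proteins that
    are common and persisting at every requested time.
    """
    chase_times = [float(t) for t in chase_times]
    calls: list[PersistenceCall] = []
    per_time_common = {t: common_proteins(profiles_mut, profiles_ctrl, t) for t in chase_times}
    if not any(per_time_common.values()):
        warnings.warn("no common proteins at any requested chase time", stacklevel=2)
    proteins = sorted(set().union(*per_time_common.values()))
    fractions: dict[float, float] = {}
    persisters: dict[float, set[str]] = {t: set() for t in chase_times}
    for t in chase_times:
        for prot in per_time_common[t]:
            if profiles_mut[prot].ratios[t] > profiles_ctrl[prot].ratios[t]:
                persisters[t].add(prot)
        n_common = len(per_time_common[t])
        fractions[t] = len(persisters[t]) / n_common if n_common else math.nan
    for prot in proteins:
        by_time: dict[float, TimePointCall] = {}
        for t in chase_times:
            common = prot in per_time_common[t]
            by_time[t] = TimePointCall(
                common=common,
                mut_ratio=profiles_mut[prot].ratios.get(t) if prot in profiles_mut else None,
                ctrl_ratio=profiles_ctrl[prot].ratios.get(t) if prot in profiles_ctrl else None,
                persists=prot in persisters[t],
            )
        persists_all = all(by_time[t].common and by_time[t].persists for t in chase_times)
        calls.append(PersistenceCall(protein=prot, by_time=by_time, persists_all=persists_all))
    venn: dict[tuple[float, ...], list[str]] = {}
    for call in calls:
        key = tuple(t for t in chase_times if call.by_time[t].persists)
        if key:
            venn.setdefault(key, []).append(call.protein)
    all_times = sorted(c.protein for c in calls if c.persists_all)
    return PersistenceResult(calls=calls, fractions=fractions,
                             common_counts={t: len(per_time_common[t]) for t in chase_times},
                             venn=venn, all_times_set=all_times)


def compare_mean_normalized_intensity(profiles_mut: Mapping[str, ProteinTurnoverProfile],
                                      profiles_ctrl: Mapping[str, ProteinTurnoverProfile],
                                      chase_time: float) -> dict:
    """Paired two-tailed t-test of mutant vs control R(t) over common proteins."""
    chase_time = float(chase_time)
    commons = sorted(common_proteins(profiles_mut, profiles_ctrl, chase_time))
    if len(commons) < 2:
        raise InsufficientDataError(
            f"need >= 2 common proteins at t={chase_time} for a paired test, "
            f"found {len(commons)}")
    mut = np.array([profiles_mut[p].ratios[chase_time] for p in commons])
    ctrl = np.array([profiles_ctrl[p].ratios[chase_time] for p in commons])
    diffs = mut - ctrl
    if np.ptp(diffs) == 0:
        t_stat, p = (0.0, 1.0) if diffs[0] == 0 else (math.inf, 0.0)
    else:
        t_stat, p = stats.ttest_rel(mut, ctrl)
    return {
        "chase_time": chase_time,
        "n": len(commons),
        "mean_mut": float(mut.mean()),
        "mean_ctrl": float(ctrl.mean()),
        "t_stat": float(t_stat),
        "p_paired": float(p),
    }


def peptide_level_comparison(records: Iterable[PeptideQuantRecord], protein: str,
                             chase_time: float, equal_var: bool = False) -> dict:
    """Unpaired t-test on per-peptide self-normalized heavy values.

    Within each genotype, every peptide quantified at both time 0 and
    `chase_time` contributes heavy(t)/heavy(0); multiple replicates of the
    same peptide are averaged per time first. Welch's test by default
    (``equal_var=True`` gives the classical pooled-variance form).
    """
    chase_time = float(chase_time)
    df = _heavy_frame(records)
    df = df[df["protein"] == protein]
    values: dict[Genotype, np.ndarray] = {}
    for genotype in (Genotype.MUT, Genotype.CTRL):
        sub = df[df["genotype"] == genotype.value]
        piv = (sub.groupby(["peptide", "chase_time"])["heavy_area"].mean()
                  .unstack("chase_time"))
        if 0.0 not in piv.columns or chase_time not in piv.columns:
            values[genotype] = np.array([])
            continue
        both = piv[[0.0, chase_time]].dropna()
        values[genotype] = (both[chase_time] / both[0.0]).to_numpy()
    mut, ctrl = values[Genotype.MUT], values[Genotype.CTRL]
    if len(mut) < 2 or len(ctrl) < 2:
        raise InsufficientDataError(
            f"protein {protein!r}: need >= 2 peptides matched across t=0 and "
            f"t={chase_time} in each genotype (got {len(mut)} MUT, {len(ctrl)} CTRL)")
    degenerate = _zero_variance_ttest(mut, ctrl)
    if degenerate is not None:
        t_stat, p = degenerate
    else:
        t_stat, p = stats.ttest_ind(mut, ctrl, equal_var=equal_var)
    return {
        "protein": protein,
        "chase_time": chase_time,
        "mut_values": mut,
        "ctrl_values": ctrl,
        "t_stat": float(t_stat),
        "p_unpaired": float(p),
    }


def profiles_to_frame(profiles: Iterable[ProteinTurnoverProfile]) -> pd.DataFrame:
    """Long-format view of profiles (one row per protein x genotype x time)."""
    rows = []
    for prof in profiles:
        for t in sorted(prof.ratios):
            rows.append({
                "protein": prof.protein,
                "genotype": prof.genotype.value,
                "chase_time": t,
                "ratio": prof.ratios[t],
                "anchor_heavy": prof.anchor_heavy,
                "n_peptides_t": prof.n_peptides[t],
                "n_peptides_anchor": prof.n_peptides[0.0],
            })
    cols = ["protein", "genotype", "chase_time", "ratio", "anchor_heavy",
            "n_peptides_t", "n_peptides_anchor"]
    return pd.DataFrame(rows, columns=cols)


def profiles_from_frame(df: pd.DataFrame) -> list[ProteinTurnoverProfile]:
    """Inverse of :func:`profiles_to_frame` (for the kinetics CLI stage)."""
    profiles = []
    for (protein, genotype), sub in df.groupby(["protein", "genotype"], sort=True):
        ratios = dict(zip(sub["chase_time"].astype(float), sub["ratio"].astype(float)))
        n_pep = dict(zip(sub["chase_time"].astype(float), sub["n_peptides_t"].astype(int)))
        n_pep[0.0] = int(sub["n_peptides_anchor"].iloc[0])
        profiles.append(ProteinTurnoverProfile(
            protein=protein, genotype=Genotype(genotype),
            anchor_heavy=float(sub["anchor_heavy"].iloc[0]),
            ratios=ratios, n_peptides=n_pep))
    return profiles
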