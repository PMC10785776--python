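"""IP-MS interactor filtering, genotype partition and enrichment.

Each IP experiment yields, per genotype and replicate, a bait (VCP) run and
a paired nonspecific-IgG control run of spectral counts. The filter applies
four rules per genotype:

1. bait normalization: every protein's count in a VCP run is expressed
   relative to the bait's own count in that run (the bait maps to 1);
2. IgG exclusivity / ratio: a protein seen in the VCP run but absent from
   the paired IgG run (count at or below a configurable floor, default 0)
   passes as EXCLUSIVE; a protein seen in both passes only when its raw
   VCP-over-IgG count ratio is strictly greater than the threshold
   (default 3) -- a ratio of exactly 3 FAILS;
3. replicate concordance: a protein is a genuine interactor only when it
   passes (either route) in every replicate (default: all of them);
4. genotype partition: interactor sets are split into mutant-only,
   control-only and common.

For common interactors, per-protein two-tailed unpaired t-tests on
replicate-level bait-normalized ratios flag genotype-enriched interactors
at alpha (default 0.05, no multiple-testing correction by default, matching
the per-comparison convention of the source procedure; Benjamini-Hochberg
is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BaitMissingError, InsufficientDataError, ValidationError
from .records import Bait, Genotype, SpectralCountRecord

BAIT_ACCESSION = "VCP"


class Route(str, Enum):
    EXCLUSIVE = "EXCLUSIVE"
    RATIO_PASS = "RATIO_PASS"
    FAIL = "FAIL"


class Partition(str, Enum):
    MUT_ONLY = "MUT_ONLY"
    CTRL_ONLY = "CTRL_ONLY"
    COMMON = "COMMON"
    NONE = "NONE"


class EnrichedIn(str, Enum):
    MUT = "MUT"
    CTRL = "CTRL"
    NEITHER = "NEITHER"


@dataclass
class EnrichmentResult:
    protein: str
    mean_ratio_mut: float
    mean_ratio_ctrl: float
    p_value: float  # nan when replicate support is insufficient
    enriched_in: EnrichedIn


@dataclass
class InteractomeResult:
    """Full output of the filtering pipeline on one spectral-count table."""

    replicate_calls: dict[Genotype, dict[int, dict[str, Route]]]
    bait_ratios: dict[Genotype, dict[int, dict[str, float]]]
    interactors: dict[Genotype, set[str]]
    partition: dict[Partition, set[str]]
    enrichment: list[EnrichmentResult]


def split_runs(records: Iterable[SpectralCountRecord]
               ) -> dict[tuple[Bait, Genotype, int], dict[str, int]]:
    """Group records into per-run protein -> count maps."""
    runs: dict[tuple[Bait, Genotype, int], dict[str, int]] = {}
    for r in records:
        run = runs.setdefault((r.bait, r.genotype, r.replicate), {})
        if r.protein in run:
            raise ValidationError(
                f"duplicate protein {r.protein!r} in run {(r.bait, r.genotype, r.replicate)}")
        run[r.protein] = r.spec_count
    return runs


def bait_normalize(run: Mapping[str, int], bait: str = BAIT_ACCESSION) -> dict[str, float]:
    """Spectral counts of one VCP run relative to the bait's own count."""
    bait_count = run.get(bait, 0)
    if bait_count <= 0:
        raise BaitMissingError(
            f"bait {bait!r} absent or zero in this run; run is unusable")
    return {protein: count / bait_count for protein, count in run.items()}


def call_replicate(vcp_run: Mapping[str, int], igg_run: Mapping[str, int],
                   threshold: float = 3.0, igg_floor: int = 0,
                   bait: str = BAIT_ACCESSION) -> dict[str, Route]:
    """Route every non-bait protein of one VCP/IgG run pair.

    EXCLUSIVE when the IgG count is at or below ``igg_floor`` (default:
    absent); otherwise RATIO_PASS iff raw VCP/IgG count ratio is strictly
    greater than ``threshold``, else FAIL.
    """
    if vcp_run.get(bait, 0) <= 0:
        raise BaitMissingError(f"bait {bait!r} absent or zero in VCP run")
    routes: dict[str, Route] = {}
    for protein, vcp_count in vcp_run.items():
        if protein == bait or vcp_count <= 0:
            continue
        igg_count = igg_run.get(protein, 0)
        if igg_count <= igg_floor:
            routes[protein] = Route.EXCLUSIVE
        elif vcp_count / igg_count > threshold:
            routes[protein] = Route.RATIO_PASS
        else:
            routes[protein] = Route.FAIL
    return routes


def concordant_interactors(replicate_routes: Sequence[Mapping[str, Route]],
                           n_required: int | None = None) -> set[str]:
    """Proteins passing (either route) in at least ``n_required`` replicates.

    The default requires every replicate; a protein absent from a
    replicate's VCP run has no route there and counts as a failure.
    """
    if not replicate_routes:
        return set()
    if n_required is None:
        n_required = len(replicate_routes)
    if n_required > len(replicate_routes):
        raise ValidationError(
            f"n_required={n_required} exceeds the {len(replicate_routes)} replicates")
    candidates: set[str] = set().union(*[set(r) for r in replicate_routes])
    out = set()
    for protein in candidates:
        passes = sum(1 for routes in replicate_routes
                     if routes.get(protein, Route.FAIL) is not Route.FAIL)
        if passes >= n_required:
            out.add(protein)
    return out


def genotype_partition(interactors_mut: set[str], interactors_ctrl: set[str]
                       ) -> dict[Partition, set[str]]:
    return {
        Partition.MUT_ONLY: interactors_mut - interactors_ctrl,
        Partition.CTRL_ONLY: interactors_ctrl - interactors_mut,
        Partition.COMMON: interactors_mut & interactors_ctrl,
    }


def common_enrichment(common: Iterable[str],
                      bait_ratios: Mapping[Genotype, Mapping[int, Mapping[str, float]]],
                      alpha: float = 0.05, equal_var: bool = False,
                      bh_correct: bool = False) -> list[EnrichmentResult]:
    """Per-protein unpaired t-tests on replicate-level bait-normalized ratios.

    A protein absent from a replicate's VCP run contributes no ratio there
    (absence informs the presence calls, not the magnitudes). Proteins with
    fewer than two ratios on either side are reported with p = nan and
    NEITHER.
    """
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for protein in sorted(common):
        sides = {}
        for genotype in (Genotype.MUT, Genotype.CTRL):
            reps = bait_ratios.get(genotype, {})
            vals = [reps[rep][protein] for rep in reps if protein in reps[rep]]
            sides[genotype] = np.asarray(vals, dtype=float)
        mut, ctrl = sides[Genotype.MUT], sides[Genotype.CTRL]
        mean_mut = float(mut.mean()) if mut.size else math.nan
        mean_ctrl = float(ctrl.mean()) if ctrl.size else math.nan
        if mut.size < 2 or ctrl.size < 2:
            p = math.nan
        elif np.ptp(mut) == 0 and np.ptp(ctrl) == 0:
            p = 1.0 if mut[0] == ctrl[0] else 0.0
        else:
            _, p = stats.ttest_ind(mut, ctrl, equal_var=equal_var)
            p = float(p)
        results.append(EnrichmentResult(protein, mean_mut, mean_ctrl, p, EnrichedIn.NEITHER))
        pvals.append(p)
    adjusted = list(pvals)
    if bh_correct:
        order = sorted((p, i) for i, p in enumerate(pvals) if not math.isnan(p))
        m = len(order)
        running = math.inf
        for rank in range(m, 0, -1):
            p, i = order[rank - 1]
            running = min(running, p * m / rank)
            adjusted[i] = running
    for res, p_adj in zip(results, adjusted):
        if not math.isnan(p_adj) and p_adj < alpha:
            if res.mean_ratio_mut > res.mean_ratio_ctrl:
                res.enriched_in = EnrichedIn.MUT
            elif res.mean_ratio_mut < res.mean_ratio_ctrl:
                res.enriched_in = EnrichedIn.CTRL
    return results


def analyze_interactome(records: Iterable[SpectralCountRecord],
                        bait: str = BAIT_ACCESSION, threshold: float = 3.0,
                        alpha: float = 0.05, igg_floor: int = 0,
                        equal_var: bool = False, bh_correct: bool = False,
                        n_required: int | None = None) -> InteractomeResult:
    """Run the four filtering rules plus enrichment on one table."""
    runs = split_runs(records)
    genotypes = sorted({g for (_, g, _) in runs}, key=lambda g: g.value)
    replicate_calls: dict[Genotype, dict[int, dict[str, Route]]] = {}
    bait_ratios: dict[Genotype, dict[int, dict[str, float]]] = {}
    interactors: dict[Genotype, set[str]] = {}
    for genotype in genotypes:
        reps = sorted({rep for (b, g, rep) in runs if g == genotype and b is Bait.VCP})
        if not reps:
            raise InsufficientDataError(f"no VCP runs for genotype {genotype.value}")
        replicate_calls[genotype] = {}
        bait_ratios[genotype] = {}
        for rep in reps:
            vcp_run = runs[(Bait.VCP, genotype, rep)]
            igg_run = runs.get((Bait.IGG, genotype, rep), {})
            replicate_calls[genotype][rep] = call_replicate(
                vcp_run, igg_run, threshold=threshold, igg_floor=igg_floor, bait=bait)
            ratios = bait_normalize(vcp_run, bait=bait)
            ratios.pop(bait, None)
            bait_ratios[genotype][rep] = ratios
        interactors[genotype] = concordant_interactors(
            list(replicate_calls[genotype].values()), n_required=n_required)
    partition = genotype_partition(interactors.get(Genotype.MUT, set()),
                                   interactors.get(Genotype.CTRL, set()))
    enrichment = common_enrichment(partition[Partition.COMMON], bait_ratios,
                                   alpha=alpha, equal_var=equal_var, bh_correct=bh_correct)
    return InteractomeResult(replicate_calls=replicate_calls, bait_ratios=bait_ratios,
                             interactors=interactors, partition=partition,
                             enrichment=enrichment)


def result_frames(result: InteractomeResult) -> dict[str, pd.DataFrame]:
    """Flatten an InteractomeResult into volcano-ready DataFrames."""
    call_rows = []
    for genotype, reps in result.replicate_calls.items():
        for rep, routes in reps.items():
            ratios = result.bait_ratios[genotype][rep]
            for protein, route in routes.items():
                call_rows.append({
                    "genotype": genotype.value, "replicate": rep, "protein": protein,
                    "route": route.value, "vcp_ratio": ratios.get(protein, math.nan),
                })
    partition_rows = [{"protein": p, "partition": part.value}
                      for part, prots in result.partition.items() for p in sorted(prots)]
    enrich_rows = [{
        "protein": e.protein, "mean_ratio_mut": e.mean_ratio_mut,
        "mean_ratio_ctrl": e.mean_ratio_ctrl, "p_value": e.p_value,
        "enriched_in": e.enriched_in.value,
    } for e in result.enrichment]
    return {
        "interactome_calls": pd.DataFrame(
            call_rows, columns=["genotype", "replicate", "protein", "route", "vcp_ratio"]),
        "interactome_partition": pd.DataFrame(partition_rows, columns=["protein", "partition"]),
        "interactome_enrichment": pd.DataFrame(
            enrich_rows, columns=["protein", "mean_ratio_mut", "mean_ratio_ctrl",
                                  "p_value", "enriched_in"]),
    }
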