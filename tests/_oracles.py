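"""Independent brute-force implementations of the filtering rules.

Deliberately naive (plain dicts, explicit loops, no pandas, no imports from
the package's analysis code) so they can serve as oracles for the vectorized
implementations. They re-state the rules directly:

Turnover: average heavy areas per (protein, genotype, time) over peptides
with heavy signal; keep proteins quantified at time 0 plus >= 1 later time;
ratio to time 0; discard ratios >= 1; a protein persists at t when both
genotypes hold a ratio there and mutant > control strictly.

Interactome: per replicate, a protein in the VCP run is EXCLUSIVE if absent
from (or zero in) the IgG run, RATIO_PASS if raw VCP/IgG > threshold,
otherwise FAIL; interactors must pass in all replicates; genotype sets are
partitioned by set algebra.
"""

from collections import defaultdict


def brute_turnover(records, chase_times):
    """Return (profiles, persistence) per the Methods rules.

    profiles: {(protein, genotype): {t: ratio}}
    persistence: {t: {"common": set, "persist": set, "fraction": float|None}}
    """
    sums = defaultdict(lambda: [0.0, 0])
    for r in records:
        if r.heavy_area > 0:
            key = (r.protein, str(r.genotype.value), float(r.chase_time))
            sums[key][0] += r.heavy_area
            sums[key][1] += 1
    means = {k: s / n for k, (s, n) in sums.items()}

    profiles = {}
    groups = {(p, g) for (p, g, _t) in means}
    for (p, g) in groups:
        anchor = means.get((p, g, 0.0))
        if anchor is None:
            continue
        ratios = {}
        for (p2, g2, t) in means:
            if p2 == p and g2 == g and t > 0:
                r = means[(p2, g2, t)] / anchor
                if r < 1.0:
                    ratios[t] = r
        if ratios:
            profiles[(p, g)] = ratios

    persistence = {}
    for t in chase_times:
        t = float(t)
        common = {p for (p, g) in profiles
                  if g == "MUT" and t in profiles[(p, "MUT")]
                  and (p, "CTRL") in profiles and t in profiles[(p, "CTRL")]}
        persist = {p for p in common
                   if profiles[(p, "MUT")][t] > profiles[(p, "CTRL")][t]}
        persistence[t] = {
            "common": common,
            "persist": persist,
            "fraction": len(persist) / len(common) if common else None,
        }
    return profiles, persistence


def brute_all_times_persisters(persistence, chase_times):
    sets = [persistence[float(t)]["persist"] for t in chase_times]
    out = set.intersection(*sets) if sets else set()
    commons = [persistence[float(t)]["common"] for t in chase_times]
    return out & set.intersection(*commons) if commons else out


def brute_interactome(records, threshold=3.0, bait="VCP"):
    """Return (per-genotype interactor sets, partition dict)."""
    runs = defaultdict(dict)
    for r in records:
        runs[(str(r.bait.value), str(r.genotype.value), r.replicate)][r.protein] = r.spec_count

    interactors = {}
    for genotype in ("MUT", "CTRL"):
        reps = sorted({rep for (b, g, rep) in runs if b == "VCP" and g == genotype})
        passing_per_rep = []
        for rep in reps:
            vcp = runs[("VCP", genotype, rep)]
            igg = runs.get(("IGG", genotype, rep), {})
            ok = set()
            for protein, count in vcp.items():
                if protein == bait or count <= 0:
                    continue
                igg_count = igg.get(protein, 0)
                if igg_count == 0:
                    ok.add(protein)          # exclusively with VCP
                elif count / igg_count > threshold:
                    ok.add(protein)          # ratio strictly above threshold
            passing_per_rep.append(ok)
        interactors[genotype] = set.intersection(*passing_per_rep) if passing_per_rep else set()

    partition = {
        "MUT_ONLY": interactors["MUT"] - interactors["CTRL"],
        "CTRL_ONLY": interactors["CTRL"] - interactors["MUT"],
        "COMMON": interactors["MUT"] & interactors["CTRL"],
    }
    return interactors, partition
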