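"""Random small-table generators for oracle-equivalence tests.

Independent of the package's synthetic_data module: tables are drawn from
small value grids so that edge cases occur often -- missing anchors, ratios
at or above 1, exact mutant/control ties, VCP/IgG count ratios of exactly
the threshold, proteins absent from single replicates.
"""

import numpy as np

from pulsechase import PeptideQuantRecord, SpectralCountRecord

_AREA_GRID = [5.0, 10.0, 20.0, 40.0, 80.0, 120.0]


def random_peptide_table(rng: np.random.Generator, max_proteins: int = 10,
                         chase_times=(0.0, 1.0, 5.0, 21.0)):
    n_prot = int(rng.integers(1, max_proteins + 1))
    records = []
    tie_pool = {}  # (protein, t) -> areas copied from MUT to force ties
    for p in range(n_prot):
        protein = f"Q{p:03d}"
        for genotype in ("MUT", "CTRL"):
            for t in chase_times:
                if rng.random() < 0.25:  # drop the whole protein x time cell
                    continue
                n_pep = int(rng.integers(1, 4))
                if genotype == "CTRL" and rng.random() < 0.3 and (protein, t) in tie_pool:
                    areas = tie_pool[(protein, t)]  # exact tie with MUT
                else:
                    areas = [float(rng.choice(_AREA_GRID)) for _ in range(n_pep)]
                if genotype == "MUT":
                    tie_pool[(protein, t)] = areas
                for j, area in enumerate(areas):
                    records.append(PeptideQuantRecord(
                        peptide=f"{protein}PEP{j}K", protein=protein,
                        heavy_area=area, light_area=float(rng.choice(_AREA_GRID)),
                        chase_time=float(t), genotype=genotype, replicate=1))
    return records


def random_speccount_table(rng: np.random.Generator, max_proteins: int = 20,
                           n_replicates: int = 3, bait: str = "VCP"):
    n_prot = int(rng.integers(1, max_proteins + 1))
    proteins = [f"R{p:03d}" for p in range(n_prot)]
    records = []
    for genotype in ("MUT", "CTRL"):
        for rep in range(1, n_replicates + 1):
            records.append(SpectralCountRecord(
                protein=bait, bait="VCP", genotype=genotype,
                replicate=rep, spec_count=int(rng.integers(20, 80))))
            for protein in proteins:
                vcp = int(rng.integers(0, 13))
                if vcp > 0:
                    records.append(SpectralCountRecord(
                        protein=protein, bait="VCP", genotype=genotype,
                        replicate=rep, spec_count=vcp))
                # IgG counts drawn small so exact-threshold ratios (e.g. 9/3)
                # and igg-only proteins both occur
                igg = int(rng.integers(0, 5))
                if igg > 0:
                    records.append(SpectralCountRecord(
                        protein=protein, bait="IGG", genotype=genotype,
                        replicate=rep, spec_count=igg))
    return records
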