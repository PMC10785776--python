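#!/usr/bin/env python
"""Generate the study-condition datasets every later step analyzes.

Writes a pulse-chase peptide table (500 proteins, chase days 0/1/5/21, two
genotypes, 20% of proteins slowed to half rate in the mutant) and a
crosslink-IP spectral-count table (60 true interactors, 40 background
proteins, 3 replicates per genotype with paired IgG controls) under
results/data/, together with their ground-truth tables.
"""

from pathlib import Path

from pulsechase import (IPSimConfig, TurnoverSimConfig, simulate_ip,
                        simulate_turnover, write_peptide_table, write_results,
                        write_speccount_table)

OUT = Path("results/data")
SEED = 20240901


def main() -> None:
    turnover_cfg = TurnoverSimConfig(n_proteins=500, seed=SEED)
    peptides, truth = simulate_turnover(turnover_cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_peptide_table(peptides, OUT / "peptides.tsv")

    ip_cfg = IPSimConfig(seed=SEED + 1)
    counts, ip_truth = simulate_ip(ip_cfg)
    write_speccount_table(counts, OUT / "speccounts.tsv")

    manifest = write_results({"turnover_truth": truth.proteins,
                              "peptide_truth": truth.peptides,
                              "ip_truth": ip_truth}, OUT)
    print(f"peptide rows:        {len(peptides):>7d}  (proteins: {turnover_cfg.n_proteins})")
    print(f"spectral-count rows: {len(counts):>7d}  (replicates: {ip_cfg.n_replicates} per genotype)")
    print(f"truth tables:        {[f['name'] for f in manifest['files']]}")


if __name__ == "__main__":
    main()
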