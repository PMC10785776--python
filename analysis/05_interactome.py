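#!/usr/bin/env python
"""Filter the IP spectral counts into bait interactor sets.

Applies IgG exclusivity, the strict VCP/IgG > 3 count-ratio rule and
all-replicates concordance per genotype, partitions interactors into
mutant-only / control-only / common, tests common interactors for genotype
enrichment, and scores everything against the generator's truth labels.
"""

from pathlib import Path

import pandas as pd

from pulsechase import (Genotype, Partition, analyze_interactome,
                        read_speccount_table, write_results)
from pulsechase.interactome import EnrichedIn, result_frames

DATA = Path("results/data")
OUT = Path("results/interactome")


def main() -> None:
    records = read_speccount_table(DATA / "speccounts.tsv")
    result = analyze_interactome(records, threshold=3.0, alpha=0.05)
    write_results(result_frames(result), OUT)

    truth = pd.read_csv(DATA / "ip_truth.tsv", sep="\t")
    truth_mut = set(truth.loc[truth.interactor_mut, "protein"])
    truth_ctrl = set(truth.loc[truth.interactor_ctrl, "protein"])
    background = set(truth.loc[truth.role == "background", "protein"])
    union = result.interactors[Genotype.MUT] | result.interactors[Genotype.CTRL]

    print(f"interactors called:  MUT {len(result.interactors[Genotype.MUT])}, "
          f"CTRL {len(result.interactors[Genotype.CTRL])}, union {len(union)}")
    print(f"partition:           mut-only {len(result.partition[Partition.MUT_ONLY])}, "
          f"ctrl-only {len(result.partition[Partition.CTRL_ONLY])}, "
          f"common {len(result.partition[Partition.COMMON])}")
    recalled = (len(result.interactors[Genotype.MUT] & truth_mut)
                + len(result.interactors[Genotype.CTRL] & truth_ctrl))
    print(f"recall vs truth:     {recalled}/{len(truth_mut) + len(truth_ctrl)} "
          f"({100 * recalled / (len(truth_mut) + len(truth_ctrl)):.1f}%)")
    print(f"background called:   {len(union & background)}/{len(background)}")
    n_mut = sum(e.enriched_in is EnrichedIn.MUT for e in result.enrichment)
    n_ctrl = sum(e.enriched_in is EnrichedIn.CTRL for e in result.enrichment)
    print(f"enriched (p<0.05):   {n_mut} in MUT, {n_ctrl} in CTRL "
          f"of {len(result.enrichment)} common")


if __name__ == "__main__":
    main()
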