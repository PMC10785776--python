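#!/usr/bin/env python
"""Protein turnover ratios, persistence calls and paired statistics.

Rolls peptide heavy areas up to day-0-anchored per-protein ratios R(t),
applies the anchor / ratio-below-1 filters, calls proteins persisting in
the mutant (strictly higher R than control), and runs the paired t-test of
normalized intensities at each chase time.
"""

from pathlib import Path

import pandas as pd

from pulsechase import (compare_mean_normalized_intensity, persistence_calls,
                        read_peptide_table, split_profiles, turnover_profiles,
                        write_results)
from pulsechase.turnover import profiles_to_frame

DATA = Path("results/data/peptides.tsv")
OUT = Path("results/turnover")
CHASE_TIMES = (1.0, 5.0, 21.0)


def main() -> None:
    records = read_peptide_table(DATA)
    profiles = turnover_profiles(records)
    mut, ctrl = split_profiles(profiles)
    persistence = persistence_calls(mut, ctrl, CHASE_TIMES)
    stats_rows = [compare_mean_normalized_intensity(mut, ctrl, t) for t in CHASE_TIMES]

    write_results({
        "profiles": profiles_to_frame(profiles),
        "persistence": pd.DataFrame(
            [{"protein": c.protein, "chase_time": t, "common": tp.common,
              "mut_ratio": tp.mut_ratio, "ctrl_ratio": tp.ctrl_ratio,
              "persists": tp.persists, "persists_all": c.persists_all}
             for c in persistence.calls for t, tp in c.by_time.items()]),
        "venn": pd.DataFrame(
            [{"persist_times": "|".join(f"{t:g}" for t in key),
              "n_proteins": len(prots)}
             for key, prots in sorted(persistence.venn.items())]),
        "stats": pd.DataFrame(stats_rows),
    }, OUT)

    print(f"protein x genotype profiles: {len(profiles)}")
    for row in stats_rows:
        t = row["chase_time"]
        print(f"day {t:>4g}: {persistence.common_counts[t]:>3d} common proteins | "
              f"persisting {100 * persistence.fractions[t]:5.1f}% | "
              f"mean R mut {row['mean_mut']:.3f} vs ctrl {row['mean_ctrl']:.3f} | "
              f"paired p {row['p_paired']:.2e}")
    print(f"persist at all three times: {len(persistence.all_times_set)} proteins")


if __name__ == "__main__":
    main()
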