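#!/usr/bin/env python
"""Quantify labeling efficiency at the end of the pulse (chase day 0).

Bins per-peptide heavy enrichment (100 * heavy / (heavy + light)) into 5%
bins and reports the unweighted average plus the fraction of peptides above
the 80% success threshold, overall and per genotype.
"""

from pathlib import Path

from pulsechase import labeling_summary, read_peptide_table, write_results
from pulsechase.labeling import summary_frames

DATA = Path("results/data/peptides.tsv")
OUT = Path("results/labeling")


def main() -> None:
    records = read_peptide_table(DATA)
    summary = labeling_summary(records, bin_width=5.0, threshold=80.0)
    top, hist = summary_frames(summary)
    write_results({"labeling_summary": top, "labeling_histogram": hist}, OUT)

    print(f"peptides at day 0:        {summary.n_peptides}")
    print(f"average enrichment:       {summary.average_enrichment:.2f}%")
    print(f"peptides above 80%:       {100 * summary.frac_above_threshold:.1f}%")
    for genotype in ("MUT", "CTRL"):
        sub = labeling_summary([r for r in records if r.genotype.value == genotype])
        print(f"  {genotype:<5} average {sub.average_enrichment:.2f}% over {sub.n_peptides} peptides")


if __name__ == "__main__":
    main()
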