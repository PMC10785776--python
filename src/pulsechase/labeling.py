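"""Labeling-efficiency quantification at the end of the SILAC pulse.

A peptide's enrichment is the heavy share of its total MS1 area, on a 0-100
scale: 100 * heavy / (heavy + light). An enrichment of 90 means ~90% of
that peptide pool was synthesized during the pulse. The summary histograms
per-peptide enrichments at chase time 0 (pulse end) and reports their
unweighted mean plus the fraction exceeding a success threshold
(default 80%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError, UndefinedEnrichmentError
from .records import PeptideQuantRecord


@dataclass
class LabelingSummary:
    bin_edges: np.ndarray          # in percent, spanning [0, 100]
    bin_counts: np.ndarray
    average_enrichment: float      # unweighted mean over peptides, percent
    n_peptides: int
    threshold: float               # percent
    frac_above_threshold: float    # fraction of peptides strictly above threshold


def peptide_enrichment(record: PeptideQuantRecord) -> float:
    """Percent heavy enrichment of one peptide observation."""
    total = record.heavy_area + record.light_area
    if total <= 0:
        raise UndefinedEnrichmentError(
            f"peptide {record.peptide!r}: heavy and light areas are both zero")
    return 100.0 * record.heavy_area / total


def labeling_summary(records: Iterable[PeptideQuantRecord],
                     bin_width: float = 5.0,
                     threshold: float = 80.0,
                     include_unlabeled: bool = True) -> LabelingSummary:
    """Histogram and average per-peptide enrichment at chase time 0.

    Bins are half-open [a, b) with the last bin closed at 100. With
    ``include_unlabeled=False``, light-only identifications (zero heavy
    area) are excluded from the denominator; the default keeps them, which
    is the conservative reading of a combined heavy/light search.
    """
    if bin_width <= 0 or bin_width > 100:
        raise ValueError("bin_width must be in (0, 100]")
    day0 = [r for r in records if r.chase_time == 0.0]
    if not include_unlabeled:
        day0 = [r for r in day0 if r.heavy_area > 0]
    if not day0:
        raise InsufficientDataError("no chase_time-0 records to summarize labeling from")
    enrich = np.array([peptide_enrichment(r) for r in day0])
    edges = np.arange(0.0, 100.0, bin_width)
    edges = np.append(edges, 100.0)
    counts, edges = np.histogram(enrich, bins=edges)
    return LabelingSummary(
        bin_edges=edges,
        bin_counts=counts,
        average_enrichment=float(enrich.mean()),
        n_peptides=len(day0),
        threshold=threshold,
        frac_above_threshold=float((enrich > threshold).mean()),
    )


def summary_frames(summary: LabelingSummary):
    """Flatten a LabelingSummary into (summary, histogram) DataFrames."""
    import pandas as pd

    hist = pd.DataFrame({
        "bin_left": summary.bin_edges[:-1],
        "bin_right": summary.bin_edges[1:],
        "count": summary.bin_counts,
    })
    top = pd.DataFrame([{
        "n_peptides": summary.n_peptides,
        "average_enrichment_pct": summary.average_enrichment,
        "threshold_pct": summary.threshold,
        "frac_above_threshold": summary.frac_above_threshold,
    }])
    return top, hist
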