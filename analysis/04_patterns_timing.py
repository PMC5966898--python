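#!/usr/bin/env python
"""Interpret the fitted patterns: markers, biological labels, onset timing.

Computes the PatternMarker table per platform (flat patterns excluded from
the statistic, technical patterns retained), labels every pattern, dates
the treated/control separation, and reports the methylation-vs-expression
onset delay.
"""

from pathlib import Path

from omicspatterns import (
    classify_patterns, io_prep, pattern_markers, timing_delay,
)
from omicspatterns.pattern_analysis import labels_table, marker_heatmap_order

BASE = Path(__file__).resolve().parent.parent / "results"
FACT = BASE / "factorization"
OUT = BASE / "patterns"
OUT.mkdir(parents=True, exist_ok=True)

meta = io_prep.read_metadata_tsv(BASE / "prepared" / "samples.tsv")
labels = {}
for tag in ("expression", "methylation"):
    A = io_prep.read_matrix_tsv(FACT / f"A_{tag}.tsv")
    P = io_prep.read_matrix_tsv(FACT / f"P_{tag}.tsv")
    labs = classify_patterns(P, meta)
    labels[tag] = labs
    exclude = [l.pattern for l in labs if l.label == "flat"]
    markers = pattern_markers(A, exclude=exclude)
    markers.to_csv(OUT / f"markers_{tag}.tsv", sep="\t")
    labels_table(labs).to_csv(OUT / f"labels_{tag}.tsv", sep="\t")
    order = marker_heatmap_order(markers)
    (OUT / f"heatmap_order_{tag}.txt").write_text("\n".join(order) + "\n")
    shown = ", ".join(f"{l.pattern}={l.label}@{l.separation_generation}" for l in labs)
    print(f"{tag}: {shown} (excluded from markers: {exclude or 'none'})")

delays = timing_delay(labels["expression"], labels["methylation"])
delays.to_csv(OUT / "timing_delays.tsv", sep="\t", index=False)
if len(delays):
    print(f"methylation onset trails the earliest expression onset by "
          f"{delays['delay_min'].median():.0f} generations (median)")
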