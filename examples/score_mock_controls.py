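"""Score the bundled mock-control profiles against the 8-species standard.

Each column is one mock community control (whole cells for extraction
controls); we compute confusion-based performance and observed/expected
abundance ratios per species.
"""

from importlib import resources

import numpy as np
import pandas as pd

from mockbench import (ConfusionCounts, evaluate_control, load_zymo8,
                       oe_ratios, performance, read_abundance_table)

data = resources.files("mockbench.data")
table = read_abundance_table(data.joinpath("extraction_controls_observed.tsv"))
ref = load_zymo8()

# The observed-percent table pools every spurious taxon into an unassigned
# "other" remainder, so detection (TP/FN, percent-correct) comes from it
# while the full false-positive counts come from the confusion table.
conf = pd.read_csv(data.joinpath("extraction_controls_confusion.tsv"),
                   sep="\t", index_col=0)
print("control        TP FP FN  precision sensitivity F   %correct")
fs = []
for cid in table.sample_ids:
    rep = evaluate_control(table, ref, cid)
    tp, fp, fn = (int(conf.at["true_positives", cid]),
                  int(conf.at["false_positives", cid]),
                  int(conf.at["false_negatives", cid]))
    s = performance(ConfusionCounts(tp, fp, fn))
    fs.append(s.f_score)
    print(f"{cid:<14} {tp:>2} {fp:>2} {fn:>2}"
          f"  {s.precision:9.2f} {s.sensitivity:11.2f} {s.f_score:.2f}"
          f" {rep.percent_correct:8.2f}")

print(f"\nmedian F-score {np.median(fs):.2f} "
      f"(range {min(fs):.2f}-{max(fs):.2f})")

print("\nspecies                          theoretical%  O/E median (range)")
for rec in oe_ratios({c: table for c in table.sample_ids}, ref):
    print(f"{rec.species_label:<32} {rec.theoretical_percent:>11.1f}  {rec.formatted()}")

print("\nAn O/E ratio of 1 means the protocol recovered a species at exactly "
      "its known abundance; 0 in the range marks a control where the species "
      "was missed at species rank.")
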