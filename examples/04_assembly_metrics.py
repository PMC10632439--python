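"""Quantify assembly/annotation agreement and the effect of filtering.

Compares a "predicted" intron set against a reference set at exact
coordinates (TP/FP/FN, sensitivity, precision) and shows the percent-change
metric used to summarize how a count moves after filtering.
"""

from splicescreen import compare_sets, percent_change

reference = {("chr1", 200, 300), ("chr1", 500, 900), ("chr2", 40, 140)}
predicted = {("chr1", 200, 300), ("chr1", 500, 900), ("chr1", 1047, 1107)}

r = compare_sets(predicted, reference, level="intron")
print(f"TP={r.TP} FP={r.FP} FN={r.FN}")
print(f"sensitivity = {r.sensitivity:.3f}")
print(f"precision   = {r.precision:.3f}")

# counts of novel (unannotated) introns before and after filtering:
before, after = 100, 90
print(f"percent change {before} -> {after}: {percent_change(before, after):+.1f}%")
# a negative value means filtering removed novel introns — the desired
# direction when the novelties were repeat artifacts.
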