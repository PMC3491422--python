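"""Classify paralog pairs by chromatin-mark status.

Three small mark-survey gene lists are combined by 2-of-3 support; each
paralog pair then falls into class both / mixed / none depending on how
many of its members are targets.
"""

from markdiv import (MarkDataset, class_counts, classify_pairs,
                     integrate_marks, target_set)

surveys = [
    MarkDataset.from_iterable("chip_chip_a", {"AT1G10", "AT1G20", "AT1G30"}),
    MarkDataset.from_iterable("chip_seq", {"AT1G10", "AT1G20", "AT1G40"}),
    MarkDataset.from_iterable("chip_chip_b", {"AT1G20", "AT1G50"}),
]

calls = integrate_marks(surveys, min_support=2)
targets = target_set(calls)
print(f"combined target set (2-of-3 support): {sorted(targets)}")

pairs = [("AT1G10", "AT1G20"),   # both genes marked -> both
         ("AT1G10", "AT1G40"),   # one marked -> mixed
         ("AT1G40", "AT1G50")]   # neither reaches support 2 -> none
classified = classify_pairs(pairs, targets)
for p in classified:
    print(f"{p.gene_a} - {p.gene_b}: {p.mark_class}")

tally = class_counts(classified)
for cls, t in tally.items():
    print(f"class {cls}: {t.count} pairs ({100 * t.fraction:.0f}%)")
# The fractions are the per-class share of all pairs; on real WGD data these
# are the headline class sizes of the analysis.
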