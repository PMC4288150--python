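"""Length statistics and meiotic timing classes for called UTR extensions.

The meiotic 5'/3' extension lengths are compared against the mitotic
reference medians (68 bp for 5' UTRs, 91 bp for 3') with a one-sample
Wilcoxon signed-rank test, and each call's sporulation time-course profile
is classified as early / middle / late by its peak hour.
"""

from mutrscan import (SimConfig, call_mutrs, classify_timing, generate_dataset,
                      length_summary)
from mutrscan.stats import MITOTIC_3P_MEDIAN_BP, MITOTIC_5P_MEDIAN_BP

genome, expr = generate_dataset(SimConfig(seed=1))
calls, _ = call_mutrs(genome.segments, genome.genes, expr)

for side, ref in (("5p", MITOTIC_5P_MEDIAN_BP), ("3p", MITOTIC_3P_MEDIAN_BP)):
    lengths = [c.segment.length for c in calls if c.side == side]
    s = length_summary(lengths, side, ref)
    print(f"{side}: n={s.n} median={s.median_bp:.0f}bp range=[{s.min_bp},{s.max_bp}] "
          f"-> {s.fold_change}x the mitotic median ({ref}bp), "
          f"Wilcoxon P={s.wilcoxon_p:.2g}")

print()
counts = {"early": 0, "middle": 0, "late": 0}
for call in calls:
    t = classify_timing(expr.spii_profile(call.segment_id), call.segment_id)
    counts[t.timing_class] += 1
print(f"timing classes (peak in SPII 1-4h / 5-8h / 9-12h): {counts}")
print()
print("A fold change well above 1 means meiotic isoforms carry substantially")
print("longer UTRs than their mitotic counterparts; the timing classes mirror")
print("the staggered early/middle/late induction waves of meiotic genes.")
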