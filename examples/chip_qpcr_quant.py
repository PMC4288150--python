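"""ChIP and Q-PCR quantification calculators.

Relative ChIP signal is the delta-delta-Ct ratio of IP to input, each
corrected by a control locus; qPCR fold enrichment is the target's IP/input
copy ratio over a negative-control locus; mutant measurements are reported
relative to wild type set at 1.
"""

from mutrscan import (CtQuad, chip_relative_signal, normalize_to_wt,
                      qpcr_fold_enrichment)

q = CtQuad(ct_target_ip=20, ct_control_ip=22, ct_target_input=18, ct_control_input=17)
print(f"relative ChIP signal for Ct ({q.ct_target_ip}, {q.ct_control_ip}, "
      f"{q.ct_target_input}, {q.ct_control_input}): {chip_relative_signal(q):.1f}")

fold = qpcr_fold_enrichment(target_ip_copies=8, target_input_copies=2,
                            neg_ip_copies=4, neg_input_copies=2)
print(f"qPCR fold enrichment (target 8/2 vs negative control 4/2): {fold:.1f}")

norm = normalize_to_wt({"WT": 2.0, "rpd3": 6.0})
print(f"acetylation signal relative to WT: {norm}")
print()
print("Values of 1.0 mean no enrichment/no change; the ChIP example shows an")
print("8-fold binding signal at the target locus after input correction, and")
print("the rpd3 mutant shows 3x the wild-type signal.")
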