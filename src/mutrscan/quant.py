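"""Calculators for ChIP and Q-PCR quantification.

The relative ChIP signal is the standard delta-delta-Ct ratio of the
immunoprecipitate to the input, each corrected by an internal control locus:

    2^-(Ct_target,IP - Ct_control,IP) / 2^-(Ct_target,input - Ct_control,input)

Copy-number fold enrichment divides the target's IP/input copy ratio by the
same ratio for a negative-control locus.  ``normalize_to_wt`` rescales a set
of condition measurements so the wild type is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping


@dataclass(frozen=True)
class CtQuad:
    """PCR cycle thresholds for target and control loci in IP and input."""

    ct_target_ip: float
    ct_control_ip: float
    ct_target_input: float
    ct_control_input: float

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")


def chip_relative_signal(q: CtQuad) -> float:
    delta_ip = q.ct_target_ip - q.ct_control_ip
    delta_input = q.ct_target_input - q.ct_control_input
    return 2.0 ** (-delta_ip) / 2.0 ** (-delta_input)


def qpcr_fold_enrichment(target_ip_copies: float, target_input_copies: float,
                         neg_ip_copies: float, neg_input_copies: float) -> float:
    for name, v in (("target_ip_copies", target_ip_copies),
                    ("target_input_copies", target_input_copies),
                    ("neg_ip_copies", neg_ip_copies),
                    ("neg_input_copies", neg_input_copies)):
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"{name} must be finite and positive, got {v!r}")
    return (target_ip_copies / target_input_copies) / (neg_ip_copies / neg_input_copies)


def normalize_to_wt(values_by_condition: Mapping[str, float], wt_key: str = "WT") -> dict[str, float]:
    if wt_key not in values_by_condition:
        raise KeyError(f"wild-type key {wt_key!r} missing")
    wt = values_by_condition[wt_key]
    if not (math.isfinite(wt) and wt > 0):
        raise ValueError(f"wild-type value must be finite and positive, got {wt!r}")
    return {k: v / wt for k, v in values_by_condition.items()}
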