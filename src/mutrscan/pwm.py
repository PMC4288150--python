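"""Position weight matrices with information-weighted MATCH-style scoring.

A PWM is built from aligned binding sites by counting nucleotides per
position.  Scanning uses the information-weighted score

    S(word) = sum_i I(i) * f(i, word_i),      I(i) = sum_b f(i,b) ln(4 f(i,b))

min-max normalized per matrix (MSS) and over the five consecutive
most-informative columns (CSS).  The natural log is used; the normalization
cancels the base.  Hits require CSS >= 0.9 and MSS >= 0.7 by default, the
conventional cut-offs for high-confidence URS1 prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import reverse_complement

from .io import BASE_INDEX, BASES, PwmRecord

CORE_WIDTH = 5
DEFAULT_MIN_CSS = 0.9
DEFAULT_MIN_MSS = 0.7

#: Synthetic URS1 site collection built around the classical consensus
#: TAGCCGCCGA with mild degeneracy at the flanks and a strongly conserved
#: GCCGCC core, approximating the published logo structure of the
#: TRANSFAC URS1 matrices (which are proprietary and not shipped).
URS1_CONSENSUS = "TAGCCGCCGA"
URS1_SITES = (
    "TAGCCGCCGA",
    "TAGCCGCCGA",
    "TAGCCGCCGA",
    "TAGCCGCCGA",
    "TAGCCGCCGA",
    "AAGCCGCCGA",
    "TCGCCGCCGA",
    "TGGCCGCCGA",
    "TAGCCGCCCA",
    "TAGCCGCCGG",
)


@dataclass(frozen=True)
class Pwm:
    """A frequency matrix with per-column information weights and a 5-column
    core of maximal summed information (leftmost window on ties)."""

    identifier: str
    frequencies: np.ndarray   # (L, 4), rows sum to 1
    information: np.ndarray   # (L,)
    core_start: int

    @property
    def length(self) -> int:
        return self.frequencies.shape[0]

    @property
    def core_positions(self) -> range:
        return range(self.core_start, self.core_start + min(CORE_WIDTH, self.length))

    @property
    def weights(self) -> np.ndarray:
        """Per-cell weighted frequencies I(i) * f(i, b)."""
        return self.information[:, None] * self.frequencies

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.frequencies, axis=1))


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    try:
        return np.array([BASE_INDEX[b] for b in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}; alphabet is ACGT") from None


def pwm_from_counts(counts: np.ndarray, identifier: str = "pwm",
                    pseudocount: float = 0.25) -> Pwm:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must have shape (L, 4)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1, keepdims=True)
    freqs = (counts + pseudocount) / (totals + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log(4 * freqs), 0.0)
    info = terms.sum(axis=1)
    info = np.maximum(info, 0.0)  # guard tiny negative rounding
    width = min(CORE_WIDTH, counts.shape[0])
    window_sums = np.convolve(info, np.ones(width), mode="valid")
    # leftmost window on ties, robust to float summation order
    core_start = int(np.nonzero(window_sums >= window_sums.max() - 1e-12)[0][0])
    return Pwm(identifier, freqs, info, core_start)


def build_pwm(sites: list[str], identifier: str = "pwm", pseudocount: float = 0.25) -> Pwm:
    """Build a PWM from an alignment of equal-length ACGT binding sites."""
    if not sites:
        raise ValueError("need at least one site")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("sites must all have equal length")
    counts = np.zeros((length, 4))
    for site in sites:
        idx = _encode(site)
        counts[np.arange(length), idx] += 1
    return pwm_from_counts(counts, identifier=identifier, pseudocount=pseudocount)


def pwm_from_record(record: PwmRecord, pseudocount: float = 0.25) -> Pwm:
    return pwm_from_counts(record.counts, identifier=record.identifier,
                           pseudocount=pseudocount)


def urs1_pwm(pseudocount: float = 0.25) -> Pwm:
    """The package's consensus-derived URS1 matrix (synthetic approximation)."""
    return build_pwm(list(URS1_SITES), identifier="URS1_consensus", pseudocount=pseudocount)


def _normalized_scores(pwm: Pwm, encoded: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Min-max-normalized information-weighted scores over the given columns.

    ``encoded`` has shape (n_words, L); ``positions`` selects columns.
    A matrix whose selected columns are all uniform (score range zero) is
    maximally permissive: every word scores 1.
    """
    weights = pwm.weights[positions]                      # (k, 4)
    s = np.take_along_axis(weights, encoded[:, positions].T, axis=1)
    raw = s.sum(axis=0) if s.ndim == 2 else s.sum()
    s_min = weights.min(axis=1).sum()
    s_max = weights.max(axis=1).sum()
    if s_max - s_min <= 0:
        return np.ones_like(raw, dtype=float)
    return (raw - s_min) / (s_max - s_min)


def score_window(pwm: Pwm, word: str) -> tuple[float, float]:
    """(MSS, CSS) of a single word of the matrix length."""
    if len(word) != pwm.length:
        raise ValueError(f"word length {len(word)} != matrix length {pwm.length}")
    encoded = _encode(word)[None, :]
    mss = _normalized_scores(pwm, encoded, np.arange(pwm.length))
    css = _normalized_scores(pwm, encoded, np.asarray(list(pwm.core_positions)))
    return float(mss[0]), float(css[0])


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    offset: int          # 0-based forward-strand offset of the match window
    strand: str
    mss: float
    css: float
    word: str            # matched word as read on the hit strand


def _scan_one_strand(pwm: Pwm, sequence: str) -> tuple[np.ndarray, np.ndarray]:
    encoded = _encode(sequence)
    L = pwm.length
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty((0,)), np.empty((0,))
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    mss = _normalized_scores(pwm, windows, np.arange(L))
    css = _normalized_scores(pwm, windows, np.asarray(list(pwm.core_positions)))
    return mss, css


def scan(pwm: Pwm, sequence: str, sequence_id: str = "seq",
         min_css: float = DEFAULT_MIN_CSS, min_mss: float = DEFAULT_MIN_MSS) -> list[MotifHit]:
    """Scan both strands; minus-strand offsets are reported in forward
    coordinates.  Hits are ordered by offset, + before - at equal offset."""
    L = pwm.length
    if len(sequence) < L:
        return []
    hits = []
    mss, css = _scan_one_strand(pwm, sequence)
    for off in np.nonzero((css >= min_css) & (mss >= min_mss))[0]:
        hits.append(MotifHit(sequence_id, int(off), "+", float(mss[off]), float(css[off]),
                             sequence[off:off + L].upper()))
    rc = reverse_complement(sequence)
    mss_rc, css_rc = _scan_one_strand(pwm, rc)
    for off in np.nonzero((css_rc >= min_css) & (mss_rc >= min_mss))[0]:
        fwd_off = len(sequence) - L - int(off)
        hits.append(MotifHit(sequence_id, fwd_off, "-", float(mss_rc[off]),
                             float(css_rc[off]), rc[off:off + L].upper()))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits
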