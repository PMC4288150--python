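"""Motif over-representation tests for target promoter sets vs a background.

Two routes are provided.  ``permutation_enrichment`` scores each sequence by
its average likelihood ratio against a uniform base composition (over all
windows on both strands) and compares the mean target score to size-matched
subsets resampled from the background — the same background mode as
comparing 100-bp windows upstream of meiotic 5' ends against 100-bp windows
upstream of the cognate genes' mitotic starts.  ``fisher_enrichment`` is the
count-based alternative: a one-sided hypergeometric test on the number of
sequences that carry at least one thresholded motif hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from Bio.Seq import reverse_complement

from .pwm import Pwm, _encode


@dataclass(frozen=True)
class EnrichmentResult:
    motif_id: str
    method: str                      # "permutation" or "fisher"
    statistic_observed: float
    p_value: float
    target_n: int
    background_n: int
    null_mean: float = float("nan")
    null_sd: float = float("nan")
    n_permutations: int = 0
    target_hits: int = -1
    background_hits: int = -1
    flags: tuple[str, ...] = ()


def sequence_score(pwm: Pwm, sequence: str,
                   background_freqs: np.ndarray | None = None) -> float:
    """Mean over all windows and both strands of the likelihood ratio
    prod_i f(i, w_i) / q(w_i), with q uniform (0.25) by default.

    Sequences shorter than the matrix have no windows and score 0.
    """
    L = pwm.length
    if len(sequence) < L:
        return 0.0
    if background_freqs is None:
        background_freqs = np.full(4, 0.25)
    ratios = []
    for seq in (sequence, reverse_complement(sequence)):
        encoded = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
        f = np.take_along_axis(pwm.frequencies, windows.T, axis=1)   # (L, n)
        q = background_freqs[windows.T]
        ratios.append(np.exp(np.log(f / q).sum(axis=0)))
    return float(np.concatenate(ratios).mean())


def permutation_enrichment(pwm: Pwm, target_seqs: list[str], background_seqs: list[str],
                           n_perm: int = 999, seed: int = 0,
                           background_freqs: np.ndarray | None = None) -> EnrichmentResult:
    """Permutation test of the mean per-sequence likelihood-ratio score.

    The null resamples size-matched subsets from the background (without
    replacement when the background is large enough, otherwise with
    replacement, flagged).  P = (1 + #{null >= observed}) / (1 + n_perm),
    so P is never exactly zero.  Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    target_scores = np.array([sequence_score(pwm, s, background_freqs) for s in target_seqs])
    bg_scores = np.array([sequence_score(pwm, s, background_freqs) for s in background_seqs])
    observed = float(target_scores.mean())
    k = len(target_scores)
    rng = np.random.default_rng(seed)
    flags: list[str] = []
    replace = k > len(bg_scores)
    if replace:
        flags.append("with_replacement")
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(bg_scores, size=k, replace=replace)
        null[i] = draw.mean()
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return EnrichmentResult(
        motif_id=pwm.identifier, method="permutation", statistic_observed=observed,
        p_value=p, target_n=len(target_seqs), background_n=len(background_seqs),
        null_mean=float(null.mean()), null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        n_permutations=n_perm, flags=tuple(flags),
    )


def fisher_enrichment(target_hits: int, target_n: int,
                      background_hits: int, background_n: int,
                      motif_id: str = "motif") -> EnrichmentResult:
    """One-sided hypergeometric P for over-representation of hit-carrying
    sequences in the target set (urn: all sequences, successes: hit
    carriers, draws: the target set)."""
    for v in (target_hits, target_n, background_hits, background_n):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if target_hits > target_n or background_hits > background_n:
        raise ValueError("hits cannot exceed set sizes")
    total = target_n + background_n
    successes = target_hits + background_hits
    p = float(stats.hypergeom.sf(target_hits - 1, total, successes, target_n))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return EnrichmentResult(
        motif_id=motif_id, method="fisher",
        statistic_observed=float(target_hits), p_value=p,
        target_n=target_n, background_n=background_n,
        target_hits=target_hits, background_hits=background_hits,
    )


def motif_percent(n_with_motif: int, n_total: int) -> int:
    """Percentage of sequences carrying a motif, rounded to the nearest
    integer (e.g. 21/92 -> 23, 61/92 -> 66)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_with_motif <= n_total:
        raise ValueError("n_with_motif must lie in [0, n_total]")
    return int(np.floor(100.0 * n_with_motif / n_total + 0.5))
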