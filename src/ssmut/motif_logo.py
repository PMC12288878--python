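"""Positional over/under-representation of residues around mutated bases.

Foreground: the pentanucleotide centered on each mutated residue (offsets
−2..+2, center excluded). Background: all residues of the ±20 nt windows
pooled, each window's central residue excluded. For each (position,
residue) cell the statistic is a signed −log10 one-sided binomial tail
p-value — positive for over-representation, negative for under — with a
Bonferroni significance threshold across the 16 cells. This mirrors the
semantics of binomial sequence-logo tools; it is an analog of their
height statistic, not a bit-exact reimplementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectrum import CollapsedSub

BASES = "ACGT"
FG_OFFSETS = (-2, -1, 1, 2)
SCORE_CAP = 300.0  # -log10 floor of float64 tails


@dataclass
class LogoInput:
    n_fg: int
    fg_counts: pd.DataFrame  # index FG_OFFSETS, columns BASES
    fg_totals: pd.Series  # per-offset non-N foreground totals
    bg_counts: pd.Series  # pooled background residue counts

    def __post_init__(self) -> None:
        if (self.fg_counts.sum(axis=1) != self.fg_totals).any():
            raise ValueError("per-position foreground counts must sum to totals")


@dataclass
class LogoMatrix:
    scores: pd.DataFrame  # index FG_OFFSETS, columns BASES, signed
    threshold: float

    def top_cells(self, n: int = 2) -> list[tuple[int, str]]:
        flat = self.scores.stack().sort_values(ascending=False)
        return [(int(i), str(b)) for (i, b) in flat.index[:n]]


def build_fg_bg(collapsed_subs: Sequence[CollapsedSub]) -> LogoInput:
    """Foreground/background residue counts from oriented windows. N-padded
    positions are excluded per position (foreground) and from the pooled
    background."""
    if not collapsed_subs:
        raise ValueError("empty substitution list")
    h = collapsed_subs[0].window.halfwidth
    fg = pd.DataFrame(0, index=list(FG_OFFSETS), columns=list(BASES), dtype=int)
    bg = pd.Series(0, index=list(BASES), dtype=int)
    for sub in collapsed_subs:
        seq = sub.window.sequence
        for off in FG_OFFSETS:
            ch = seq[h + off]
            if ch in BASES:
                fg.loc[off, ch] += 1
        for i, ch in enumerate(seq):
            if i != h and ch in BASES:
                bg[ch] += 1
    return LogoInput(
        n_fg=len(collapsed_subs),
        fg_counts=fg,
        fg_totals=fg.sum(axis=1),
        bg_counts=bg,
    )


def residue_scores(logo_input: LogoInput, alpha: float = 0.05) -> LogoMatrix:
    """Signed −log10 binomial tail scores per (offset, residue).

    For each cell, X ~ Binomial(n_position, p_residue) with p from the
    pooled background; the score is −log10 of the smaller of the two
    one-sided tails P[X ≥ k] / P[X ≤ k], signed + for over-representation.
    The threshold is −log10(alpha / 16) (Bonferroni over the cells).
    """
    if logo_input.n_fg < 1:
        raise ValueError("need at least one foreground sequence")
    bg_total = int(logo_input.bg_counts.sum())
    if bg_total < 1:
        raise ValueError("empty background")
    scores = pd.DataFrame(
        0.0, index=list(FG_OFFSETS), columns=list(BASES), dtype=float
    )
    for off in FG_OFFSETS:
        n = int(logo_input.fg_totals[off])
        if n == 0:
            continue
        for base in BASES:
            k = int(logo_input.fg_counts.loc[off, base])
            p_r = logo_input.bg_counts[base] / bg_total
            if p_r == 0.0:
                scores.loc[off, base] = SCORE_CAP if k > 0 else 0.0
                continue
            if k == n * p_r:  # exactly the expectation: no deviation
                scores.loc[off, base] = 0.0
                continue
            upper = stats.binom.sf(k - 1, n, p_r)  # P[X >= k]
            lower = stats.binom.cdf(k, n, p_r)  # P[X <= k]
            over = k > n * p_r
            tail = upper if over else lower
            with np.errstate(divide="ignore"):
                mag = float(min(SCORE_CAP, -np.log10(max(tail, 1e-320))))
            scores.loc[off, base] = mag if over else -mag
    n_cells = len(FG_OFFSETS) * len(BASES)
    return LogoMatrix(scores=scores, threshold=float(-np.log10(alpha / n_cells)))
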