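"""Mutable-motif patterns.

A motif is written like ``cCg``: exactly one uppercase character marks the
mutated (central) base, lowercase characters are required flanking context,
and lowercase ``n`` matches any of A/C/G/T. After pyrimidine collapse the
center is always C or T. The mutation it names is ``pattern→alt``,
e.g. ``cCg→G``; the reverse-complement spelling (``cGg→C``) is counted
cumulatively by the analysis, never as a separate motif.
"""

from __future__ import annotations

from dataclasses import dataclass

_VALID_FLANK = set("acgtn")


@dataclass(frozen=True)
class MotifSpec:
    """A mutable motif such as cCg→G."""

    pattern: str
    alt: str

    def __post_init__(self) -> None:
        uppers = [i for i, ch in enumerate(self.pattern) if ch.isupper()]
        if len(uppers) != 1:
            raise ValueError(
                f"motif {self.pattern!r} must have exactly one uppercase center"
            )
        ci = uppers[0]
        if self.pattern[ci] not in "CT":
            raise ValueError("motif center must be a pyrimidine (C or T)")
        for ch in self.pattern[:ci] + self.pattern[ci + 1 :]:
            if ch not in _VALID_FLANK:
                raise ValueError(f"invalid flank character {ch!r} in {self.pattern!r}")
        if len(self.pattern[:ci]) > 1 or len(self.pattern[ci + 1 :]) > 1:
            raise ValueError("at most one flank character on each side")
        alt = self.alt.upper()
        if alt not in "ACGT" or alt == self.pattern[ci]:
            raise ValueError("alt must be a single base different from the center")
        object.__setattr__(self, "alt", alt)

    @property
    def center_index(self) -> int:
        return next(i for i, ch in enumerate(self.pattern) if ch.isupper())

    @property
    def center(self) -> str:
        """The mutated base letter (uppercase)."""
        return self.pattern[self.center_index]

    @property
    def left(self) -> str:
        """Required 5' flank ('' if unconstrained)."""
        return self.pattern[: self.center_index]

    @property
    def right(self) -> str:
        """Required 3' flank ('' if unconstrained)."""
        return self.pattern[self.center_index + 1 :]

    @property
    def base_change(self) -> str:
        return f"{self.center}>{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.pattern}->{self.alt}"

    def matches_at(self, seq: str, center: int) -> bool:
        """True if `seq` (uppercase) matches the motif with its mutated base
        aligned at index `center`. N in the sequence matches nothing; 'n' in
        the motif matches any ordinary base."""
        seq_u = seq  # callers pass uppercase windows
        flank = self.left + self.center.lower() + self.right
        start = center - len(self.left)
        if start < 0 or start + len(flank) > len(seq_u):
            return False
        for pat_ch, seq_ch in zip(flank, seq_u[start : start + len(flank)]):
            if seq_ch not in "ACGT":
                return False
            if pat_ch == "n":
                continue
            if seq_ch != pat_ch.upper():
                return False
        return True

    def matches_context(self, left_base: str, right_base: str) -> bool:
        """Match only the ±1 flanks (the center is the mutation itself)."""
        for pat, base in ((self.left, left_base), (self.right, right_base)):
            if not pat or pat == "n":
                continue
            if base not in "ACGT" or base != pat.upper():
                return False
        return True
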