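"""Single-residue substitutions and haplotypes (sets of substitutions)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = ["Substitution", "Haplotype", "AMINO_ACIDS"]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class Substitution:
    """A single-residue variant, canonically rendered ``S147P``.

    ``position`` is 1-based; ``ref_aa`` and ``alt_aa`` are one-letter codes.
    """

    sort_index: int = field(init=False, repr=False, compare=True)
    ref_aa: str = field(compare=False)
    position: int = field(compare=False)
    alt_aa: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise ValueError(f"invalid amino acid in {self.ref_aa}{self.position}{self.alt_aa}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"substitution must change the residue: {self}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        object.__setattr__(self, "sort_index", self.position)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Substitution):
            return NotImplemented
        return (self.ref_aa, self.position, self.alt_aa) == (
            other.ref_aa, other.position, other.alt_aa)

    def __hash__(self) -> int:
        return hash((self.ref_aa, self.position, self.alt_aa))

    def __str__(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"

    @classmethod
    def from_string(cls, text: str) -> "Substitution":
        """Parse a ``"S147P"``-style specification."""
        m = _SUB_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse substitution {text!r} (expected e.g. 'S147P')")
        ref, pos, alt = m.groups()
        return cls(ref_aa=ref, position=int(pos), alt_aa=alt)


class Haplotype:
    """A set of substitutions carried together; the empty set is wild type.

    At most one substitution per position.  Hashable and order-free, so it can
    key a family of peak lists.  The short label follows the alt-residue
    convention, e.g. ``H21-P147`` for {P21H, S147P} and ``WT`` for wild type.
    """

    __slots__ = ("_subs",)

    def __init__(self, subs: Iterable[Substitution] = ()) -> None:
        subs = frozenset(subs)
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValueError(f"multiple substitutions at one position: {sorted(subs)}")
        self._subs = subs

    @property
    def subs(self) -> frozenset[Substitution]:
        return self._subs

    @property
    def is_wild_type(self) -> bool:
        return not self._subs

    def __len__(self) -> int:
        return len(self._subs)

    def __iter__(self) -> Iterator[Substitution]:
        return iter(sorted(self._subs))

    def __contains__(self, sub: Substitution) -> bool:
        return sub in self._subs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Haplotype):
            return NotImplemented
        return self._subs == other._subs

    def __hash__(self) -> int:
        return hash(self._subs)

    def __or__(self, other: "Haplotype") -> "Haplotype":
        return Haplotype(self._subs | other._subs)

    @property
    def label(self) -> str:
        if not self._subs:
            return "WT"
        return "-".join(f"{s.alt_aa}{s.position}" for s in sorted(self._subs))

    def __str__(self) -> str:
        return self.label

    def __repr__(self) -> str:
        return f"Haplotype({self.label})"

    def spec_string(self) -> str:
        """Comma-separated full specification, e.g. ``"P21H,S147P"``; ``"WT"`` if empty."""
        if not self._subs:
            return "WT"
        return ",".join(str(s) for s in sorted(self._subs))

    @classmethod
    def from_string(cls, text: str) -> "Haplotype":
        """Parse ``"WT"`` or a ``","``/``"+"``-separated list like ``"P21H,S147P"``."""
        text = text.strip()
        if text.upper() in ("", "WT", "WILDTYPE", "WILD-TYPE"):
            return cls()
        parts = re.split(r"[,+]", text)
        return cls(Substitution.from_string(p) for p in parts if p.strip())
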