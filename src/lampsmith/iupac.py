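"""IUPAC nucleotide code arithmetic.

Shared primitives for every module that touches sequence: code/base-set
lookup, complementation, degenerate expansion and degeneracy counting.
Gap characters are *not* IUPAC codes and are handled by callers.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

CANONICAL = "ACGT"

#: IUPAC code -> set of canonical bases it covers
CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in CODE_TO_BASES.items()}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class IupacError(ValueError):
    """A character outside the IUPAC nucleotide alphabet."""


class DegeneracyCapError(ValueError):
    """Degenerate expansion would exceed the configured cap."""


def validate(seq: str) -> None:
    """Raise :class:`IupacError` naming the first offending position."""
    for i, ch in enumerate(seq):
        if ch not in CODE_TO_BASES:
            raise IupacError(
                f"non-IUPAC character {ch!r} at position {i} in sequence {seq[:30]!r}..."
                if len(seq) > 30
                else f"non-IUPAC character {ch!r} at position {i} in sequence {seq!r}"
            )


def bases(code: str) -> frozenset[str]:
    try:
        return CODE_TO_BASES[code]
    except KeyError:
        raise IupacError(f"non-IUPAC character {code!r}") from None


def code_for(observed: Iterable[str]) -> str:
    """Minimal IUPAC code covering a set of canonical bases."""
    s = frozenset(observed)
    if not s:
        raise IupacError("empty base set has no IUPAC code")
    if not s <= frozenset(CANONICAL):
        raise IupacError(f"base set {sorted(s)} contains non-canonical characters")
    return BASES_TO_CODE[s]


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (degenerate codes map to their complements)."""
    out = []
    for i, ch in enumerate(seq):
        try:
            out.append(COMPLEMENT[ch])
        except KeyError:
            raise IupacError(f"non-IUPAC character {ch!r} at position {i}") from None
    return "".join(reversed(out))


def degeneracy(seq: str) -> int:
    """Product of per-position code cardinalities (1 for a canonical sequence)."""
    n = 1
    for ch in seq:
        n *= len(bases(ch))
    return n


def expand(seq: str, cap: int = 4096) -> set[str]:
    """All canonical sequences encoded by ``seq``.

    Refuses (with guidance) when the expansion would exceed ``cap`` members.
    """
    validate(seq)
    n = degeneracy(seq)
    if n > cap:
        raise DegeneracyCapError(
            f"expansion of {len(seq)}-mer has {n} variants, above the cap of {cap}; "
            "raise the cap explicitly if this is intended"
        )
    return {"".join(p) for p in product(*(sorted(bases(ch)) for ch in seq))}


def contains(code: str, other: str) -> bool:
    """True when every base covered by ``other`` is covered by ``code``.

    This is the match rule for degenerate primers against templates: a primer
    code matches a template base when it covers it.
    """
    return bases(other) <= bases(code)


def can_pair(x: str, y: str) -> bool:
    """True when codes ``x`` and ``y`` can form at least one Watson-Crick pair."""
    comp = frozenset(COMPLEMENT[b] for b in bases(y))
    return bool(bases(x) & comp)
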