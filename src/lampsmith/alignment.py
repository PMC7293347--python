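"""Alignment profiling: the substrate for conserved-region primer design.

Reads aligned FASTA "target" and "non-target" sets sharing one coordinate
frame, summarises per-column variability as degenerate consensus codes, and
computes region-level exclusivity statistics (how different the closest
non-target sequence is over a candidate primer footprint).

Coordinates are 0-based, half-open, in alignment-column space throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import iupac

GAP_CHARS = "-."

Role = Literal["target", "non-target"]


class AlignmentShapeError(ValueError):
    """Sequences of unequal length where an alignment is required."""


class AlignmentParseError(ValueError):
    """A character outside the IUPAC-plus-gap alphabet, located by record and column."""


class FrameError(ValueError):
    """Two alignments that should share a coordinate frame do not."""


@dataclass
class AlignmentSet:
    """An aligned set of sequences playing the target or non-target role."""

    name: str
    role: Role
    ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if self.role not in ("target", "non-target"):
            raise ValueError(f"role must be 'target' or 'non-target', got {self.role!r}")
        if not self.sequences:
            raise ValueError("an alignment needs at least one sequence")
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"alignment {self.name!r} has ragged sequence lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)


@dataclass
class ColumnProfile:
    """Base composition and degenerate consensus of one alignment column."""

    position: int
    base_counts: dict[str, int]  # keys A, C, G, T, '-' and 'ambiguous'
    consensus_code: str
    degeneracy: int
    all_gap: bool = False

    @property
    def has_gap(self) -> bool:
        return self.base_counts["-"] > 0


@dataclass
class RegionProfile:
    """Design statistics for a candidate primer footprint (half-open span)."""

    start: int
    end: int
    target_degeneracy: int
    min_nontarget_mismatches: int
    three_prime_mismatch_flag: bool
    has_target_gap: bool = False


def _normalise(seq: str) -> str:
    return seq.upper().replace("U", "T").replace(".", "-")


def read_alignment(path: str | Path, role: Role, name: str | None = None) -> AlignmentSet:
    """Read an aligned FASTA file into an :class:`AlignmentSet`.

    Case is normalised, RNA ``U`` is mapped to ``T`` and ``.`` gaps to ``-``.
    Ragged records raise :class:`AlignmentShapeError`; a character outside the
    IUPAC-plus-gap alphabet raises :class:`AlignmentParseError` naming the
    record and column.
    """
    path = Path(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _normalise(str(rec.seq))
        for col, ch in enumerate(seq):
            if ch not in iupac.CODE_TO_BASES and ch not in GAP_CHARS:
                raise AlignmentParseError(
                    f"record {rec.id!r}, column {col}: non-IUPAC character {ch!r}"
                )
        ids.append(rec.id)
        seqs.append(seq)
    if not ids:
        raise AlignmentParseError(f"no FASTA records found in {path}")
    return AlignmentSet(name=name or path.stem, role=role, ids=ids, sequences=seqs)


def column_profiles(aln: AlignmentSet) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column.

    The consensus code is the minimal IUPAC code covering every canonical base
    observed in the column (ambiguity codes in the input contribute their full
    expansion).  All-gap columns are flagged and conservatively profiled as
    ``N`` with degeneracy 4.
    """
    profiles = []
    for j in range(aln.length):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, "-": 0, "ambiguous": 0}
        observed: set[str] = set()
        for seq in aln.sequences:
            ch = seq[j]
            if ch in GAP_CHARS:
                counts["-"] += 1
            elif ch in "ACGT":
                counts[ch] += 1
                observed.add(ch)
            else:
                counts["ambiguous"] += 1
                observed |= iupac.bases(ch)
        if not observed:
            profiles.append(
                ColumnProfile(j, counts, consensus_code="N", degeneracy=4, all_gap=True)
            )
        else:
            code = iupac.code_for(observed)
            profiles.append(ColumnProfile(j, counts, code, len(observed)))
    return profiles


def consensus_string(profiles: Sequence[ColumnProfile], start: int = 0, end: int | None = None) -> str:
    """Degenerate consensus over ``[start, end)`` in alignment coordinates."""
    end = len(profiles) if end is None else end
    return "".join(p.consensus_code for p in profiles[start:end])


class NonTargetIndex:
    """Precomputed per-column mismatch matrix of a non-target set vs a target consensus.

    A non-target base mismatches when it is not contained in the target
    consensus code at that column (degenerate positions do not discriminate);
    non-target gaps count as mismatches.  Cumulative sums give O(n_sequences)
    per-span minimum mismatch counts, which the design search calls heavily.
    """

    def __init__(self, target: AlignmentSet, nontarget: AlignmentSet,
                 profiles: Sequence[ColumnProfile] | None = None) -> None:
        if target.length != nontarget.length:
            raise FrameError(
                f"target ({target.length} cols) and non-target ({nontarget.length} cols) "
                "alignments are not in the same coordinate frame"
            )
        self.profiles = list(profiles) if profiles is not None else column_profiles(target)
        cons_sets = [iupac.bases(p.consensus_code) for p in self.profiles]
        mm = np.zeros((nontarget.n, nontarget.length), dtype=np.uint8)
        for i, seq in enumerate(nontarget.sequences):
            for j, ch in enumerate(seq):
                if ch in GAP_CHARS:
                    mm[i, j] = 1
                elif not iupac.bases(ch) <= cons_sets[j]:
                    mm[i, j] = 1
        self.mismatch = mm
        self.cum = np.concatenate(
            [np.zeros((nontarget.n, 1), dtype=np.int32), np.cumsum(mm, axis=1, dtype=np.int32)],
            axis=1,
        )

    def span_counts(self, start: int, end: int) -> np.ndarray:
        return self.cum[:, end] - self.cum[:, start]

    def min_mismatches(self, start: int, end: int) -> int:
        return int(self.span_counts(start, end).min())


def region_profile(
    target: AlignmentSet,
    nontarget: AlignmentSet,
    span: tuple[int, int],
    three_prime_window: int = 5,
    orientation: Literal["plus", "minus"] = "plus",
    index: NonTargetIndex | None = None,
) -> RegionProfile:
    """Design statistics for a candidate footprint.

    ``target_degeneracy`` is the product of column degeneracies over the span;
    ``min_nontarget_mismatches`` is the smallest per-sequence mismatch count in
    the non-target set.  The 3'-terminal window sits at the span end for plus
    orientation and at the span start for minus orientation (both in alignment
    coordinates); the flag reports whether the first non-target sequence
    achieving the minimum mismatches inside that window.
    """
    start, end = span
    if not (0 <= start < end <= target.length):
        raise ValueError(f"span {span} out of bounds for alignment of length {target.length}")
    idx = index if index is not None else NonTargetIndex(target, nontarget)
    profs = idx.profiles
    deg = 1
    has_gap = False
    for p in profs[start:end]:
        deg *= p.degeneracy
        has_gap = has_gap or p.has_gap or p.all_gap
    counts = idx.span_counts(start, end)
    best = int(counts.min())
    argbest = int(np.argmin(counts))
    w = min(three_prime_window, end - start)
    if orientation == "minus":
        wspan = (start, start + w)
    else:
        wspan = (end - w, end)
    flag = bool(idx.mismatch[argbest, wspan[0]:wspan[1]].any())
    return RegionProfile(
        start=start,
        end=end,
        target_degeneracy=deg,
        min_nontarget_mismatches=best,
        three_prime_mismatch_flag=flag,
        has_target_gap=has_gap,
    )


def profiles_to_dataframe(profiles: Sequence[ColumnProfile]) -> pd.DataFrame:
    """CSV-ready table: position, A, C, G, T, gap, consensus, degeneracy."""
    return pd.DataFrame(
        {
            "position": [p.position for p in profiles],
            "A": [p.base_counts["A"] for p in profiles],
            "C": [p.base_counts["C"] for p in profiles],
            "G": [p.base_counts["G"] for p in profiles],
            "T": [p.base_counts["T"] for p in profiles],
            "gap": [p.base_counts["-"] for p in profiles],
            "consensus": [p.consensus_code for p in profiles],
            "degeneracy": [p.degeneracy for p in profiles],
        }
    )


def column_to_reference_map(aln: AlignmentSet, reference_id: str,
                            reference_offset: int = 0) -> dict[int, int]:
    """Map alignment columns to ungapped coordinates of a designated reference record.

    Lets column-space spans be reported in reference coordinates (e.g.
    mitogenome positions).  Columns where the reference is gapped are absent
    from the map.
    """
    try:
        seq = aln.sequences[aln.ids.index(reference_id)]
    except ValueError:
        raise KeyError(f"reference record {reference_id!r} not in alignment") from None
    out: dict[int, int] = {}
    pos = reference_offset
    for j, ch in enumerate(seq):
        if ch not in GAP_CHARS:
            out[j] = pos
            pos += 1
    return out
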