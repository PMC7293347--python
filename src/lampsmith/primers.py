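"""LAMP primer architecture, degeneracy, melting temperature and self-structure.

A LAMP assay uses six primers recognising eight template regions
(5'->3' on the plus strand: F3 F2 LF F1 ... B1 LB B2 B3).  The inner primers
are fusions: FIP = reverse_complement(F1) + F2 and BIP = reverse_complement(B1)
+ B2, where each constituent region's sequence is stored 5'->3' in its own
strand sense.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import pandas as pd
from Bio.SeqUtils import MeltingTemp as _mt

from . import iupac
from .iupac import DegeneracyCapError, reverse_complement  # re-exported

REGION_NAMES = ("F3", "F2", "F1", "LF", "B1", "B2", "B3", "LB")

#: strand sense in which each elementary region's primer anneals
REGION_STRAND: dict[str, str] = {
    "F3": "plus", "F2": "plus", "F1": "plus", "LB": "plus",
    "LF": "minus", "B1": "minus", "B2": "minus", "B3": "minus",
}


class AssemblyError(ValueError):
    """Inner-primer parts with inconsistent region names."""


def expand_degenerate(seq: str, cap: int = 4096) -> set[str]:
    """All canonical sequences a degenerate primer encodes (see :func:`iupac.expand`)."""
    return iupac.expand(seq, cap=cap)


def degeneracy_count(seq: str) -> int:
    """Number of canonical variants: product of per-position IUPAC code sizes."""
    iupac.validate(seq)
    return iupac.degeneracy(seq)


@dataclass(frozen=True)
class PrimerRegion:
    """One of the eight template regions, with its footprint span and primer-sense sequence."""

    name: str
    span: tuple[int, int]
    strand: Literal["plus", "minus"]
    sequence: str

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"region name must be one of {REGION_NAMES}, got {self.name!r}")
        if not self.sequence:
            raise ValueError("region sequence must be non-empty")
        if len(self.sequence) != self.span[1] - self.span[0]:
            raise ValueError(
                f"region {self.name}: sequence length {len(self.sequence)} != span length "
                f"{self.span[1] - self.span[0]}"
            )
        iupac.validate(self.sequence)


@dataclass
class LampPrimer:
    """A synthesised oligo with its headline properties."""

    label: str
    sequence: str
    predicted_tm: float | None = None
    tm_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        iupac.validate(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy_count(self.sequence)


@dataclass
class LampPrimerSet:
    """The four-to-six primer set of a LAMP assay.

    ``fip_parts``/``bip_parts`` carry the constituent regions (F1+F2, B1+B2)
    when known; when present the assembly invariant
    ``fip.sequence == reverse_complement(F1) + F2`` is enforced.
    Loop primers are optional: four-primer assays are valid.
    """

    f3: LampPrimer
    b3: LampPrimer
    fip: LampPrimer
    bip: LampPrimer
    lf: LampPrimer | None = None
    lb: LampPrimer | None = None
    fip_parts: tuple[PrimerRegion, PrimerRegion] | None = None
    bip_parts: tuple[PrimerRegion, PrimerRegion] | None = None
    name: str = "lamp-assay"

    def __post_init__(self) -> None:
        for parts, primer, names in (
            (self.fip_parts, self.fip, ("F1", "F2")),
            (self.bip_parts, self.bip, ("B1", "B2")),
        ):
            if parts is not None:
                anchor, ext = parts
                if (anchor.name, ext.name) != names:
                    raise AssemblyError(f"expected parts {names}, got {(anchor.name, ext.name)}")
                expected = reverse_complement(anchor.sequence) + ext.sequence
                if primer.sequence != expected:
                    raise AssemblyError(
                        f"{primer.label}: sequence does not equal "
                        f"reverse_complement({anchor.name}) + {ext.name}"
                    )

    @property
    def has_loops(self) -> bool:
        return self.lf is not None and self.lb is not None

    def primers(self) -> dict[str, LampPrimer]:
        out = {"F3": self.f3, "B3": self.b3, "FIP": self.fip, "BIP": self.bip}
        if self.lf is not None:
            out["LF"] = self.lf
        if self.lb is not None:
            out["LB"] = self.lb
        return out

    def region_footprints(self) -> dict[str, str]:
        """Plus-strand footprint sequence of each of the 6-8 regions.

        Minus-sense primer sequences are reverse-complemented back to plus
        sense so every footprint can be slid along a plus-strand template.
        Requires ``fip_parts``/``bip_parts`` for the inner regions.
        """
        if self.fip_parts is None or self.bip_parts is None:
            raise ValueError("region footprints need fip_parts and bip_parts")
        f1, f2 = self.fip_parts
        b1, b2 = self.bip_parts
        regions: dict[str, str] = {
            "F3": self.f3.sequence,
            "F2": f2.sequence,
            "F1": f1.sequence if f1.strand == "plus" else reverse_complement(f1.sequence),
            "B1": reverse_complement(b1.sequence) if b1.strand == "minus" else b1.sequence,
            "B2": reverse_complement(b2.sequence) if b2.strand == "minus" else b2.sequence,
            "B3": reverse_complement(self.b3.sequence),
        }
        if self.lf is not None:
            regions["LF"] = reverse_complement(self.lf.sequence)
        if self.lb is not None:
            regions["LB"] = self.lb.sequence
        return regions

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        def prim(p: LampPrimer | None):
            if p is None:
                return None
            return {"label": p.label, "sequence": p.sequence}

        def region(r: PrimerRegion):
            return {"name": r.name, "span": list(r.span), "strand": r.strand,
                    "sequence": r.sequence}

        d = {"name": self.name,
             "primers": {k: prim(v) for k, v in
                         [("f3", self.f3), ("b3", self.b3), ("fip", self.fip),
                          ("bip", self.bip), ("lf", self.lf), ("lb", self.lb)]}}
        if self.fip_parts:
            d["fip_parts"] = [region(r) for r in self.fip_parts]
        if self.bip_parts:
            d["bip_parts"] = [region(r) for r in self.bip_parts]
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "LampPrimerSet":
        def prim(v):
            return None if v is None else LampPrimer(label=v["label"], sequence=v["sequence"])

        def region(v):
            return PrimerRegion(name=v["name"], span=tuple(v["span"]), strand=v["strand"],
                                sequence=v["sequence"])

        p = d["primers"]
        return cls(
            f3=prim(p["f3"]), b3=prim(p["b3"]), fip=prim(p["fip"]), bip=prim(p["bip"]),
            lf=prim(p.get("lf")), lb=prim(p.get("lb")),
            fip_parts=tuple(region(r) for r in d["fip_parts"]) if "fip_parts" in d else None,
            bip_parts=tuple(region(r) for r in d["bip_parts"]) if "bip_parts" in d else None,
            name=d.get("name", "lamp-assay"),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LampPrimerSet":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_table(self) -> pd.DataFrame:
        """Report-style table: label, sequence, length, predicted Tm, degeneracy.

        Degeneracy 1 renders as ``"None"`` in keeping with how such tables are
        conventionally printed; it is stored numerically as 1.
        """
        rows = []
        for p in self.primers().values():
            rows.append(
                {
                    "label": p.label,
                    "sequence": p.sequence,
                    "length_bp": p.length,
                    "predicted_tm_c": None if p.predicted_tm is None else round(p.predicted_tm, 1),
                    "degeneracy": "None" if p.degeneracy == 1 else p.degeneracy,
                }
            )
        return pd.DataFrame(rows)


def assemble_inner_primer(
    anchor_region: PrimerRegion, extension_region: PrimerRegion, label: str | None = None
) -> LampPrimer:
    """Fuse an anchor (F1 or B1) with its extension (F2 or B2) into FIP/BIP.

    The inner primer is reverse_complement(anchor) + extension, so its length
    is the sum of the part lengths.
    """
    pairs = {("F1", "F2"): "FIP", ("B1", "B2"): "BIP"}
    key = (anchor_region.name, extension_region.name)
    if key not in pairs:
        raise AssemblyError(
            f"cannot assemble inner primer from regions {key}; expected (F1, F2) or (B1, B2)"
        )
    seq = reverse_complement(anchor_region.sequence) + extension_region.sequence
    return LampPrimer(label=label or pairs[key], sequence=seq)


# -- melting temperature -----------------------------------------------------

@dataclass(frozen=True)
class TmConditions:
    """Solution conditions for nearest-neighbour Tm prediction.

    Defaults are conventional LAMP design conditions: 50 mM monovalent salt,
    4 mM Mg2+, 1.4 mM total dNTPs, 100 nM oligo, SantaLucia (2004) unified
    parameters with the Owczarzy divalent-aware salt correction.  The
    parameter table and salt-correction method are config-visible so users
    can calibrate against other prediction software.
    """

    na_mM: float = 50.0
    k_mM: float = 0.0
    tris_mM: float = 0.0
    mg_mM: float = 4.0
    dntps_mM: float = 1.4
    oligo_nM: float = 100.0
    nn_table: str = "santalucia2004"
    salt_correction: int = 7  # Owczarzy (2008), divalent-aware

_NN_TABLES = {"santalucia2004": _mt.DNA_NN4, "santalucia1998": _mt.DNA_NN3}


@dataclass(frozen=True)
class TmEstimate:
    """Headline Tm is the worst case (minimum over degenerate expansions)."""

    tm: float
    tm_min: float
    tm_max: float
    n_variants: int


def melting_temperature(
    seq: str, conditions: TmConditions = TmConditions(), cap: int = 4096
) -> TmEstimate:
    """Nearest-neighbour duplex Tm (degenerate primers: min over expansions, plus range)."""
    if len(seq) < 8:
        raise ValueError(f"sequence of length {len(seq)} too short for a duplex Tm model")
    variants = expand_degenerate(seq, cap=cap)
    tms = [
        _mt.Tm_NN(
            v,
            nn_table=_NN_TABLES[conditions.nn_table],
            saltcorr=conditions.salt_correction,
            Na=conditions.na_mM,
            K=conditions.k_mM,
            Tris=conditions.tris_mM,
            Mg=conditions.mg_mM,
            dNTPs=conditions.dntps_mM,
            dnac1=conditions.oligo_nM,
            dnac2=0,
        )
        for v in variants
    ]
    return TmEstimate(tm=min(tms), tm_min=min(tms), tm_max=max(tms), n_variants=len(tms))


# -- self-structure ----------------------------------------------------------

@dataclass(frozen=True)
class SelfStructureScore:
    """Run-length self-structure liabilities (no free-energy model).

    ``dimer_run``: longest antiparallel self-complementary run between two
    copies of the primer.  ``hairpin_stem``: longest intramolecular stem with
    loop length >= 3.  ``three_prime_anchored``: a complementary run at or
    above the anchor threshold touches the 3'-terminal window.
    """

    dimer_run: int
    hairpin_stem: int
    three_prime_anchored: bool

    @property
    def penalty(self) -> int:
        base = max(self.dimer_run, self.hairpin_stem)
        return 2 * base if self.three_prime_anchored else base


def self_structure_score(
    seq: str, three_prime_window: int = 5, anchor_threshold: int = 4
) -> SelfStructureScore:
    """Exhaustive ungapped self-dimer and stem-loop enumeration.

    Degenerate codes pair when any of their expansions can form a Watson-
    Crick pair (worst case).  Deterministic and O(n^3); primers are short.
    """
    iupac.validate(seq)
    n = len(seq)
    window_start = max(0, n - three_prime_window)

    dimer_best = 0
    anchored = False
    # antiparallel pairing: position i of one copy against position j of the
    # other, runs extending with i increasing and j decreasing, i.e. runs lie
    # on anti-diagonals of constant i + j
    for d in range(2 * n - 1):
        run = 0
        for i in range(max(0, d - n + 1), min(n, d + 1)):
            j = d - i
            if iupac.can_pair(seq[i], seq[j]):
                run += 1
                dimer_best = max(dimer_best, run)
                if run >= anchor_threshold:
                    i_lo = i - run + 1  # run covers i in [i_lo, i], j in [j, d - i_lo]
                    if i >= window_start or d - i_lo >= window_start:
                        anchored = True
            else:
                run = 0

    hairpin_best = 0
    min_loop = 3
    for i in range(n):
        for j in range(n - 1, i, -1):
            # stem pairs (i+k, j-k); loop between them must stay >= min_loop
            l = 0
            while (
                i + l < j - l
                and (j - l) - (i + l) - 1 >= min_loop
                and iupac.can_pair(seq[i + l], seq[j - l])
            ):
                l += 1
            hairpin_best = max(hairpin_best, l)

    return SelfStructureScore(
        dimer_run=dimer_best, hairpin_stem=hairpin_best, three_prime_anchored=anchored
    )
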