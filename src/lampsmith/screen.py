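"""In-silico inclusivity/exclusivity screening of a LAMP primer set.

Places each of the six-to-eight primer regions at its minimum-mismatch
ungapped position on a template, weights 3'-window mismatches (which block
polymerase extension) more heavily than body mismatches, and predicts an
amplification class — positive, late, or negative — per template.  This is
the computational analogue of wet-lab specificity panels, where members of
the target complex amplify, a ~5%-divergent neighbour amplifies very late,
and everything more distant stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from Bio import SeqIO

from . import iupac
from .primers import LampPrimerSet, REGION_STRAND

PanelRole = Literal["target-complex", "near-neighbour", "outgroup"]


@dataclass
class TemplateRecord:
    """One template in a screening panel (canonical bases plus N, ungapped)."""

    id: str
    species: str
    sequence: str
    panel_role: PanelRole = "target-complex"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("template sequence must be non-empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"template {self.id!r} has non-canonical characters {sorted(bad)}")


@dataclass
class ClassThresholds:
    """Decision thresholds in weighted mismatches.

    3'-window mismatches weigh ``three_prime_weight`` (default 3), body
    mismatches 1.  Defaults are calibrated so uniformly ~0-2% divergent
    templates screen positive and >=5% divergent templates screen late or
    negative, mirroring the divergence pattern observed in real panels.
    """

    t1: float = 8.0
    t2: float = 20.0
    three_prime_weight: float = 3.0
    three_prime_limit: int = 2
    three_prime_window: int = 5
    not_found_fraction: float = 0.5


@dataclass
class RegionHit:
    """Best ungapped placement of one primer region on a template."""

    region: str
    position: int | None
    mismatches: int
    three_prime_mismatches: int
    found: bool


@dataclass
class ScreenResult:
    template_id: str
    species: str
    hits: dict[str, RegionHit]
    weighted_score: float
    predicted_class: Literal["positive", "late", "negative"]


def _count_mismatches(footprint: str, template: str, offset: int) -> list[bool]:
    """Per-position mismatch flags of a plus-strand footprint at ``offset``.

    IUPAC containment: a degenerate footprint code covering the template base
    is a match; an N in the template mismatches anything narrower than N.
    """
    return [
        not iupac.contains(footprint[k], template[offset + k])
        for k in range(len(footprint))
    ]


def _best_placement(footprint: str, template: str, lo: int, hi: int) -> tuple[int | None, int]:
    """Minimum-mismatch offset (leftmost on ties) of ``footprint`` within [lo, hi)."""
    n, m = len(template), len(footprint)
    lo = max(0, lo)
    hi = min(n - m + 1, hi)
    best_off, best_mm = None, m + 1
    for off in range(lo, hi):
        mm = 0
        for k in range(m):
            if not iupac.contains(footprint[k], template[off + k]):
                mm += 1
                if mm >= best_mm:
                    break
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm


def locate_and_count(
    primer_set: LampPrimerSet,
    template: TemplateRecord,
    thresholds: ClassThresholds = ClassThresholds(),
) -> dict[str, RegionHit]:
    """Per-region minimum-mismatch profile of a primer set on one template.

    The outer regions F3 and B3 anchor the search: their best placements
    bound a window (plus a margin) inside which every interior region is
    placed at its own minimum-mismatch offset.  A region whose best placement
    still mismatches at >= ``not_found_fraction`` of its length is reported
    not-found.
    """
    footprints = primer_set.region_footprints()
    seq = template.sequence
    n = len(seq)

    f3 = footprints["F3"]
    b3 = footprints["B3"]
    f3_off, f3_mm = _best_placement(f3, seq, 0, n)
    b3_lo = (f3_off + len(f3)) if f3_off is not None else 0
    b3_off, b3_mm = _best_placement(b3, seq, b3_lo, n)
    if b3_off is None:  # template too short right of F3; fall back to full scan
        b3_off, b3_mm = _best_placement(b3, seq, 0, n)

    margin = 10
    lo = (f3_off if f3_off is not None else 0) - margin
    hi = ((b3_off + len(b3)) if b3_off is not None else n) + margin

    hits: dict[str, RegionHit] = {}
    for name, fp in footprints.items():
        if name == "F3":
            off, mm = f3_off, f3_mm
        elif name == "B3":
            off, mm = b3_off, b3_mm
        else:
            off, mm = _best_placement(fp, seq, lo, hi)
            if off is None:
                off, mm = _best_placement(fp, seq, 0, n)
        found = off is not None and mm < thresholds.not_found_fraction * len(fp)
        tp = 0
        if off is not None:
            flags = _count_mismatches(fp, seq, off)
            w = min(thresholds.three_prime_window, len(fp))
            # 3' end of a plus-sense primer sits at the footprint's right edge,
            # of a minus-sense primer at its left edge
            tp = sum(flags[-w:]) if REGION_STRAND[name] == "plus" else sum(flags[:w])
        hits[name] = RegionHit(region=name, position=off, mismatches=mm if off is not None else len(fp),
                               three_prime_mismatches=tp, found=found)
    return hits


def weighted_mismatch_score(hits: dict[str, RegionHit],
                            thresholds: ClassThresholds = ClassThresholds()) -> float:
    return float(sum(
        (h.mismatches - h.three_prime_mismatches)
        + thresholds.three_prime_weight * h.three_prime_mismatches
        for h in hits.values()
    ))


def classify_template(hits: dict[str, RegionHit],
                      thresholds: ClassThresholds = ClassThresholds()) -> str:
    """Deterministic class rule.

    negative when any region is not found or the weighted score exceeds
    ``t2``; positive when the score is at most ``t1`` and no F2/B2 3'-window
    mismatch count exceeds the limit; late in between (including
    low-score templates failing only the 3' rule).
    """
    if any(not h.found for h in hits.values()):
        return "negative"
    score = weighted_mismatch_score(hits, thresholds)
    if score > thresholds.t2:
        return "negative"
    three_prime_ok = all(
        hits[r].three_prime_mismatches <= thresholds.three_prime_limit
        for r in ("F2", "B2") if r in hits
    )
    if score <= thresholds.t1 and three_prime_ok:
        return "positive"
    return "late"


def screen_template(primer_set: LampPrimerSet, template: TemplateRecord,
                    thresholds: ClassThresholds = ClassThresholds()) -> ScreenResult:
    hits = locate_and_count(primer_set, template, thresholds)
    return ScreenResult(
        template_id=template.id,
        species=template.species,
        hits=hits,
        weighted_score=weighted_mismatch_score(hits, thresholds),
        predicted_class=classify_template(hits, thresholds),
    )


def screen_panel(primer_set: LampPrimerSet, templates: Sequence[TemplateRecord],
                 thresholds: ClassThresholds = ClassThresholds()) -> pd.DataFrame:
    """Screen a panel; one row per template with per-region mismatch counts."""
    rows = []
    for t in templates:
        r = screen_template(primer_set, t, thresholds)
        row = {"template": r.template_id, "species": r.species,
               "weighted_score": r.weighted_score, "class": r.predicted_class}
        for name, h in r.hits.items():
            row[f"mm_{name}"] = h.mismatches
            row[f"mm3p_{name}"] = h.three_prime_mismatches
        rows.append(row)
    return pd.DataFrame(rows)


def read_panel(path: str | Path, panel_role: PanelRole = "target-complex") -> list[TemplateRecord]:
    """Read a plain FASTA panel; record descriptions become species labels."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() or rec.id
        out.append(TemplateRecord(id=rec.id, species=desc,
                                  sequence=str(rec.seq).upper().replace("U", "T"),
                                  panel_role=panel_role))
    return out


def pairwise_divergence(a: str, b: str) -> float:
    """Percent p-distance over comparable sites (gaps and N excluded)."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    comparable = 0
    diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "ACGT" and y in "ACGT":
            comparable += 1
            if x != y:
                diff += 1
    if comparable == 0:
        raise ValueError("no comparable sites; p-distance undefined")
    return 100.0 * diff / comparable
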