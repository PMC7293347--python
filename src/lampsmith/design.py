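"""Conserved-region scanning for candidate LAMP primer-set layouts.

Mechanises the manual design procedure: scan a target/non-target joint
alignment for eight-region layouts (F3 F2 [LF] F1 B1 [LB] B2 B3, left to
right on the plus strand) that satisfy geometry constraints, stay within a
per-primer degeneracy cap, avoid indel-variable target columns, and rank the
survivors by (i) least target degeneracy, (ii) greatest distance to the
nearest non-target sequence — with mismatches beyond 3 treated as a
saturated bonus — and (iii) least self-structure liability, especially
3'-anchored, plus a Tm-dispersion penalty.

The scan is exhaustive with pruning, left-to-right, and fully deterministic:
ties in rank break by loop-primer presence (six-primer sets amplify faster),
then leftmost F3 start, then smallest amplicon.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentSet, ColumnProfile, NonTargetIndex, column_profiles
from .iupac import reverse_complement
from .primers import (
    LampPrimer,
    LampPrimerSet,
    PrimerRegion,
    REGION_STRAND,
    TmConditions,
    assemble_inner_primer,
    melting_temperature,
    self_structure_score,
)

INNER_ORDER = ("F3", "F2", "F1", "B1", "B2", "B3")


@dataclass
class GeometryConstraints:
    """Allowed region lengths, inter-region spacings and amplicon span.

    Defaults follow common LAMP design guidance: outer and loop primers
    18-26 nt, F2/B2 18-24 nt, F1/B1 20-24 nt, an amplicon (F3 start to B3
    end) of 120-320 columns, and generous spacing windows between adjacent
    regions.  All values are plain data and can be loaded from config.
    """

    region_lengths: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "F3": (18, 26), "B3": (18, 26), "LF": (18, 26), "LB": (18, 26),
        "F2": (18, 24), "B2": (18, 24), "F1": (20, 24), "B1": (20, 24),
    })
    #: spacing (columns) between the end of one region and the start of the next
    gaps: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "F3-F2": (0, 20), "F2-F1": (0, 60), "F1-B1": (0, 100),
        "B1-B2": (0, 60), "B2-B3": (0, 20),
    })
    amplicon_span: tuple[int, int] = (120, 320)

    def __post_init__(self) -> None:
        for name, (lo, hi) in {**self.region_lengths,
                               **self.gaps,
                               "amplicon": self.amplicon_span}.items():
            if lo > hi or lo < 0:
                raise ValueError(f"constraint {name}: empty or negative range ({lo}, {hi})")


@dataclass
class SearchLimits:
    """Caps keeping the exhaustive scan bounded and deterministic."""

    per_primer_degeneracy_cap: int = 16
    max_candidates: int = 500


@dataclass
class ScoreWeights:
    degeneracy: float = 1.0
    exclusivity: float = 1.0
    self_structure: float = 0.5
    tm_spread: float = 0.2
    exclusivity_cap: int = 4  # ">3 mismatches" saturates the exclusivity bonus


@dataclass
class CandidateSet:
    """A geometry-valid layout, optionally degeneracy-applied and scored."""

    regions: dict[str, PrimerRegion]
    primer_set: LampPrimerSet | None = None
    score_components: dict[str, float] = field(default_factory=dict)
    rank_score: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def has_loops(self) -> bool:
        return "LF" in self.regions and "LB" in self.regions

    @property
    def amplicon_span(self) -> tuple[int, int]:
        return (self.regions["F3"].span[0], self.regions["B3"].span[1])


@dataclass
class DesignSearchResult:
    candidates: list[CandidateSet]
    diagnostics: dict[str, int]

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self):
        return len(self.candidates)


class _ColumnData:
    def __init__(self, target: AlignmentSet, profiles: list[ColumnProfile]):
        self.profiles = profiles
        self.deg = np.array([p.degeneracy for p in profiles], dtype=np.int64)
        self.blocked = np.array([p.has_gap or p.all_gap for p in profiles], dtype=bool)
        self.blocked_cum = np.concatenate([[0], np.cumsum(self.blocked)])
        self.consensus = "".join(p.consensus_code for p in profiles)
        # majority canonical base per column (ties alphabetical); used for the
        # pre-degeneracy candidate sequences
        maj = []
        for p in profiles:
            counts = [(p.base_counts[b], b) for b in "ACGT"]
            best = max(counts, key=lambda t: (t[0], -ord(t[1])))
            maj.append(best[1] if best[0] > 0 else "N")
        self.majority = "".join(maj)

    def span_clean(self, start: int, end: int) -> bool:
        return self.blocked_cum[end] - self.blocked_cum[start] == 0

    def span_degeneracy(self, start: int, end: int) -> int:
        return int(np.prod(self.deg[start:end]))


def _region_sequence(cols: _ColumnData, name: str, span: tuple[int, int],
                     degenerate: bool) -> PrimerRegion:
    src = cols.consensus if degenerate else cols.majority
    plus = src[span[0]:span[1]]
    strand = REGION_STRAND[name]
    seq = plus if strand == "plus" else reverse_complement(plus)
    return PrimerRegion(name=name, span=span, strand=strand, sequence=seq)


def _feasible_spans(cols: _ColumnData, length_range: tuple[int, int],
                    deg_cap: int) -> list[tuple[int, int]]:
    lo, hi = length_range
    n = len(cols.deg)
    spans = []
    for start in range(n):
        for length in range(lo, hi + 1):
            end = start + length
            if end > n:
                break
            if not cols.span_clean(start, end):
                continue
            if cols.span_degeneracy(start, end) > deg_cap:
                continue
            spans.append((start, end))
    spans.sort()
    return spans


def _spans_starting_in(spans: list[tuple[int, int]], lo: int, hi: int):
    """Spans with start in [lo, hi], relying on (start, end) sort order."""
    i = bisect_left(spans, (lo, -1))
    while i < len(spans) and spans[i][0] <= hi:
        yield spans[i]
        i += 1


def _pick_loop(spans: list[tuple[int, int]], lo: int, hi: int) -> tuple[int, int] | None:
    """Deterministic loop placement in the open interval [lo, hi): longest,
    then leftmost, feasible span; None when nothing fits."""
    best: tuple[int, int] | None = None
    for s, e in _spans_starting_in(spans, lo, hi):
        if e > hi:
            continue
        if best is None or (e - s, -s) > (best[1] - best[0], -best[0]):
            best = (s, e)
    return best


def enumerate_candidates(
    target: AlignmentSet,
    nontarget: AlignmentSet | None = None,
    constraints: GeometryConstraints | None = None,
    limits: SearchLimits | None = None,
) -> DesignSearchResult:
    """Exhaustive left-to-right scan for geometry-valid layouts.

    Returns candidates (pre-degeneracy, majority-base sequences) in
    deterministic scan order, stopping at ``limits.max_candidates``.  When no
    layout exists the result is empty and ``diagnostics`` summarises how many
    partial layouts each constraint rejected (the tightest failing constraint
    is the one with no surviving spans or the most rejections).
    """
    constraints = constraints or GeometryConstraints()
    limits = limits or SearchLimits()
    profiles = column_profiles(target)
    cols = _ColumnData(target, profiles)
    diag: dict[str, int] = {}

    span_lists = {
        name: _feasible_spans(cols, constraints.region_lengths[name],
                              limits.per_primer_degeneracy_cap)
        for name in constraints.region_lengths
    }
    for name, lst in span_lists.items():
        diag[f"feasible_spans_{name}"] = len(lst)

    amp_lo, amp_hi = constraints.amplicon_span
    gaps = constraints.gaps
    out: list[CandidateSet] = []

    def reject(stage: str) -> None:
        diag[stage] = diag.get(stage, 0) + 1

    done = False
    for f3 in span_lists["F3"]:
        if done:
            break
        if f3[0] + amp_lo > target.length:
            reject("amplicon_min")
            continue
        for f2 in _spans_starting_in(span_lists["F2"], f3[1] + gaps["F3-F2"][0],
                                     f3[1] + gaps["F3-F2"][1]):
            if done:
                break
            for f1 in _spans_starting_in(span_lists["F1"], f2[1] + gaps["F2-F1"][0],
                                         f2[1] + gaps["F2-F1"][1]):
                if done:
                    break
                for b1 in _spans_starting_in(span_lists["B1"], f1[1] + gaps["F1-B1"][0],
                                             f1[1] + gaps["F1-B1"][1]):
                    if done:
                        break
                    for b2 in _spans_starting_in(span_lists["B2"], b1[1] + gaps["B1-B2"][0],
                                                 b1[1] + gaps["B1-B2"][1]):
                        if done:
                            break
                        for b3 in _spans_starting_in(span_lists["B3"],
                                                     b2[1] + gaps["B2-B3"][0],
                                                     b2[1] + gaps["B2-B3"][1]):
                            span = b3[1] - f3[0]
                            if span < amp_lo:
                                reject("amplicon_min")
                                continue
                            if span > amp_hi:
                                reject("amplicon_max")
                                break  # later B3 spans only grow the amplicon
                            regions = {
                                "F3": _region_sequence(cols, "F3", f3, False),
                                "F2": _region_sequence(cols, "F2", f2, False),
                                "F1": _region_sequence(cols, "F1", f1, False),
                                "B1": _region_sequence(cols, "B1", b1, False),
                                "B2": _region_sequence(cols, "B2", b2, False),
                                "B3": _region_sequence(cols, "B3", b3, False),
                            }
                            lf = _pick_loop(span_lists["LF"], f2[1], f1[0])
                            lb = _pick_loop(span_lists["LB"], b1[1], b2[0])
                            if lf is not None:
                                regions["LF"] = _region_sequence(cols, "LF", lf, False)
                            if lb is not None:
                                regions["LB"] = _region_sequence(cols, "LB", lb, False)
                            out.append(CandidateSet(regions=regions))
                            if len(out) >= limits.max_candidates:
                                diag["max_candidates_reached"] = 1
                                done = True
                                break
    diag["candidates"] = len(out)
    return DesignSearchResult(candidates=out, diagnostics=diag)


def apply_degeneracy(candidate: CandidateSet, target: AlignmentSet,
                     limits: SearchLimits | None = None,
                     profiles: list[ColumnProfile] | None = None) -> CandidateSet:
    """Replace every region sequence by the strand-adjusted degenerate
    consensus over its span and (re)assemble the six primers.

    Candidates whose per-primer degeneracy exceeds the cap are flagged, not
    dropped.
    """
    limits = limits or SearchLimits()
    profiles = profiles if profiles is not None else column_profiles(target)
    cols = _ColumnData(target, profiles)
    regions = {
        name: _region_sequence(cols, name, r.span, True)
        for name, r in candidate.regions.items()
    }
    f3 = LampPrimer(label="F3", sequence=regions["F3"].sequence)
    b3 = LampPrimer(label="B3", sequence=regions["B3"].sequence)
    fip = assemble_inner_primer(regions["F1"], regions["F2"], label="FIP")
    bip = assemble_inner_primer(regions["B1"], regions["B2"], label="BIP")
    lf = LampPrimer(label="LF", sequence=regions["LF"].sequence) if "LF" in regions else None
    lb = LampPrimer(label="LB", sequence=regions["LB"].sequence) if "LB" in regions else None
    pset = LampPrimerSet(f3=f3, b3=b3, fip=fip, bip=bip, lf=lf, lb=lb,
                         fip_parts=(regions["F1"], regions["F2"]),
                         bip_parts=(regions["B1"], regions["B2"]))
    flags = list(candidate.flags)
    for p in pset.primers().values():
        if p.degeneracy > limits.per_primer_degeneracy_cap:
            flags.append(f"degeneracy-cap-exceeded:{p.label}")
    return CandidateSet(regions=regions, primer_set=pset, flags=flags)


def score_candidate(
    candidate: CandidateSet,
    nontarget_index: NonTargetIndex,
    weights: ScoreWeights | None = None,
    three_prime_window: int = 5,
    tm_conditions: TmConditions = TmConditions(),
    _tm_cache: dict | None = None,
) -> CandidateSet:
    """Fill score components and the weighted scalar rank.

    rank = w_deg * (-log2 total degeneracy)
         + w_excl * min-over-regions non-target mismatches (capped at 4)
         - w_self * worst self-structure penalty (doubled when 3'-anchored)
         - w_tm * Tm spread across primers.

    Each component is one-directional: worsening it never raises the rank.
    """
    if candidate.primer_set is None:
        raise ValueError("candidate must have assembled primers (run apply_degeneracy)")
    weights = weights or ScoreWeights()
    cache = _tm_cache if _tm_cache is not None else {}
    pset = candidate.primer_set

    total_deg = 1
    for p in pset.primers().values():
        total_deg *= p.degeneracy
    comp_deg = -float(np.log2(total_deg))

    mm = []
    for name, region in candidate.regions.items():
        s, e = region.span
        mm.append(nontarget_index.min_mismatches(s, e))
    comp_excl = float(min(min(mm), weights.exclusivity_cap))

    worst_self = 0.0
    for p in pset.primers().values():
        score = self_structure_score(p.sequence, three_prime_window=three_prime_window)
        worst_self = max(worst_self, float(score.penalty))

    tms = []
    for p in pset.primers().values():
        if p.sequence not in cache:
            cache[p.sequence] = melting_temperature(p.sequence, tm_conditions)
        est = cache[p.sequence]
        p.predicted_tm = est.tm
        p.tm_range = (est.tm_min, est.tm_max)
        tms.append(est.tm)
    tm_spread = float(max(tms) - min(tms))

    rank = (weights.degeneracy * comp_deg
            + weights.exclusivity * comp_excl
            - weights.self_structure * worst_self
            - weights.tm_spread * tm_spread)
    candidate.score_components = {
        "neg_log2_degeneracy": comp_deg,
        "min_nontarget_mismatches": comp_excl,
        "self_structure_penalty": worst_self,
        "tm_spread": tm_spread,
    }
    candidate.rank_score = rank
    return candidate


def validate_candidate_geometry(candidate: CandidateSet,
                                constraints: GeometryConstraints | None = None) -> bool:
    """Re-check a candidate against the geometry invariants from scratch."""
    constraints = constraints or GeometryConstraints()
    r = candidate.regions
    for name in INNER_ORDER:
        if name not in r:
            return False
    spans = [r[name].span for name in INNER_ORDER]
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if not (s1 < e1 <= s2 < e2):
            return False
    for name, region in r.items():
        lo, hi = constraints.region_lengths[name]
        if not lo <= region.span[1] - region.span[0] <= hi:
            return False
    for pair in ("F3-F2", "F2-F1", "F1-B1", "B1-B2", "B2-B3"):
        a, b = pair.split("-")
        gap = r[b].span[0] - r[a].span[1]
        lo, hi = constraints.gaps[pair]
        if not lo <= gap <= hi:
            return False
    if "LF" in r and not (r["F2"].span[1] <= r["LF"].span[0] < r["LF"].span[1] <= r["F1"].span[0]):
        return False
    if "LB" in r and not (r["B1"].span[1] <= r["LB"].span[0] < r["LB"].span[1] <= r["B2"].span[0]):
        return False
    amp = r["B3"].span[1] - r["F3"].span[0]
    return constraints.amplicon_span[0] <= amp <= constraints.amplicon_span[1]


def search(
    target: AlignmentSet,
    nontarget: AlignmentSet,
    constraints: GeometryConstraints | None = None,
    limits: SearchLimits | None = None,
    weights: ScoreWeights | None = None,
    top: int | None = 10,
    tm_conditions: TmConditions = TmConditions(),
) -> DesignSearchResult:
    """Enumerate, degeneracy-apply, score and rank candidate primer sets.

    The returned candidates are sorted best-first; ties break by loop-primer
    presence, then leftmost F3 start, then smallest amplicon.
    """
    result = enumerate_candidates(target, nontarget, constraints, limits)
    profiles = column_profiles(target)
    index = NonTargetIndex(target, nontarget, profiles=profiles)
    tm_cache: dict = {}
    scored = [
        score_candidate(apply_degeneracy(c, target, limits, profiles), index,
                        weights, tm_conditions=tm_conditions, _tm_cache=tm_cache)
        for c in result.candidates
    ]
    scored.sort(key=lambda c: (
        -c.rank_score,
        not c.has_loops,
        c.regions["F3"].span[0],
        c.amplicon_span[1] - c.amplicon_span[0],
    ))
    if top is not None:
        scored = scored[:top]
    return DesignSearchResult(candidates=scored, diagnostics=result.diagnostics)


def render_footprint_map(candidate: CandidateSet, width: int = 80) -> str:
    """Text sketch of the layout: consensus-coordinate ruler plus region bars."""
    start, end = candidate.amplicon_span
    lines = [f"amplicon columns [{start}, {end}) span {end - start}"]
    for name in ("F3", "F2", "LF", "F1", "B1", "LB", "B2", "B3"):
        if name not in candidate.regions:
            continue
        r = candidate.regions[name]
        s, e = r.span
        lines.append(f"{name:>3} [{s:>5}, {e:>5}) {'+' if r.strand == 'plus' else '-'} {r.sequence}")
    return "\n".join(lines)
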