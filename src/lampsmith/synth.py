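"""Synthetic inputs with known ground truth.

Generates everything the rest of the toolkit consumes without any external
data: target/non-target alignments with controlled divergence and planted
polymorphic columns, template panels at specified p-distances, simulated
real-time run files (sigmoid amplification curves, logistic annealing
sweeps, additive Gaussian noise), and a constrained design fixture with a
single feasible primer layout.

Defaults emulate the scale of a COI barcoding study: 658-column barcode
alignments, an 82-sequence target complex and a 2922-sequence congeneric
non-target set.  The substitution model is deliberately simple — uniform
random sites, uniform alternative base, no transition bias or rate
heterogeneity — which is sufficient for screening-threshold calibration but
not a model of real sequence evolution.  All generators are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentSet
from .screen import TemplateRecord

_BASES = np.array(list("ACGT"))


@dataclass
class AlignmentSpec:
    """Recipe for a matched target / non-target alignment pair."""

    length: int = 658
    n_target: int = 82
    n_nontarget: int = 2922
    #: column index -> alternative base segregating within the target set
    polymorphic_columns: dict[int, str] = field(default_factory=dict)
    divergence_pct: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError("divergence must be in [0, 100]")
        if self.length < 1 or self.n_target < 1 or self.n_nontarget < 1:
            raise ValueError("length and sequence counts must be >= 1")
        for col in self.polymorphic_columns:
            if not 0 <= col < self.length:
                raise ValueError(f"polymorphic column {col} outside [0, {self.length})")


def _mutate(seq: np.ndarray, n_sub: int, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    sites = rng.choice(len(seq), size=n_sub, replace=False)
    for s in sites:
        alts = [b for b in "ACGT" if b != out[s]]
        out[s] = alts[rng.integers(3)]
    return out


def make_alignments(spec: AlignmentSpec) -> tuple[AlignmentSet, AlignmentSet, str]:
    """Target and non-target alignments plus the true consensus.

    Target sequences equal the consensus except at the planted polymorphic
    columns, where roughly half the sequences (always at least one, never
    all) carry the alternative base — so the degenerate consensus over such a
    column is exactly two-fold.  Non-target sequences carry substitutions at
    the requested divergence, uniformly placed.
    """
    rng = np.random.default_rng(spec.seed)
    n_sub = int(round(spec.divergence_pct / 100.0 * spec.length))
    if n_sub > spec.length:
        raise ValueError("divergence infeasible for sequence length")

    consensus = _BASES[rng.integers(4, size=spec.length)]
    for col, alt in spec.polymorphic_columns.items():
        if alt not in "ACGT":
            raise ValueError(f"alternative base {alt!r} must be canonical")
        if consensus[col] == alt:  # force a real polymorphism
            consensus[col] = "ACGT"[("ACGT".index(alt) + 1) % 4]

    target_seqs = []
    for i in range(spec.n_target):
        s = consensus.copy()
        for col, alt in spec.polymorphic_columns.items():
            carries = (i == 1) if spec.n_target > 1 else True
            if i > 1:
                carries = bool(rng.random() < 0.5)
            if i == 0:
                carries = False  # sequence 0 is always the reference haplotype
            if carries and spec.n_target > 1:
                s[col] = alt
        target_seqs.append("".join(s))

    nontarget_seqs = [
        "".join(_mutate(consensus, n_sub, rng)) for _ in range(spec.n_nontarget)
    ]

    target = AlignmentSet(
        name="synthetic-target", role="target",
        ids=[f"t{i:03d}" for i in range(spec.n_target)], sequences=target_seqs,
    )
    nontarget = AlignmentSet(
        name="synthetic-nontarget", role="non-target",
        ids=[f"nt{i:04d}" for i in range(spec.n_nontarget)], sequences=nontarget_seqs,
    )
    return target, nontarget, "".join(consensus)


def write_fasta(path: str | Path, ids: list[str], seqs: list[str]) -> None:
    with open(path, "w") as fh:
        for i, s in zip(ids, seqs):
            fh.write(f">{i}\n{s}\n")


def make_panel(consensus: str, divergences: list[float], n_per_level: int,
               seed: int = 0) -> list[TemplateRecord]:
    """Templates at each requested p-distance level from the consensus."""
    rng = np.random.default_rng(seed)
    cons = np.array(list(consensus))
    out = []
    for level in divergences:
        if not 0.0 <= level <= 100.0:
            raise ValueError(f"divergence level {level} outside [0, 100]")
        n_sub = int(round(level / 100.0 * len(consensus)))
        for k in range(n_per_level):
            seq = "".join(_mutate(cons, n_sub, rng))
            role = ("target-complex" if level < 1 else
                    "near-neighbour" if level < 8 else "outgroup")
            out.append(TemplateRecord(
                id=f"div{level:g}_{k:02d}",
                species=f"synthetic {level:g}% divergent",
                sequence=seq, panel_role=role,
            ))
    return out


@dataclass
class WellSpec:
    """Ground truth for one simulated well."""

    label: str
    true_time_min: float | None
    true_anneal_c: float | None
    noise_sd: float = 0.0


@dataclass
class RunSpec:
    """Recipe for a simulated real-time run file.

    Amplification curves are four-parameter logistics in time with inflection
    at the true amplification time; annealing sweeps are logistic transitions
    in temperature whose signed-derivative peak sits at the true anneal
    temperature.  Noise is additive Gaussian per point.
    """

    wells: list[WellSpec]
    duration_min: float = 30.0
    interval_min: float = 0.1
    melt_hi_c: float = 98.0
    melt_lo_c: float = 73.0
    melt_step_c: float = 0.2
    baseline: float = 100.0
    amplitude: float = 900.0
    rise_scale_min: float = 0.25
    melt_base: float = 50.0
    melt_amplitude: float = 800.0
    melt_width_c: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for w in self.wells:
            if w.true_time_min is not None and not 0 < w.true_time_min < self.duration_min:
                raise ValueError(f"true time {w.true_time_min} outside the run duration")
            if w.true_anneal_c is not None and not (
                self.melt_lo_c < w.true_anneal_c < self.melt_hi_c
            ):
                raise ValueError(f"true anneal {w.true_anneal_c} outside the sweep")


def make_run(spec: RunSpec) -> pd.DataFrame:
    """Simulate a run as a long-form DataFrame in the run-CSV dialect
    (columns: well, sample, phase, x, y)."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration_min + 1e-9, spec.interval_min)
    temps = np.arange(spec.melt_hi_c, spec.melt_lo_c - 1e-9, -spec.melt_step_c)
    rows = []
    for i, w in enumerate(spec.wells):
        well_id = f"W{i + 1:02d}"
        if w.true_time_min is None:
            amp = np.full_like(t, spec.baseline)
        else:
            amp = spec.baseline + spec.amplitude / (
                1.0 + np.exp(-(t - w.true_time_min) / spec.rise_scale_min)
            )
        if w.noise_sd > 0:
            amp = amp + rng.normal(0.0, w.noise_sd, size=len(t))
        for x, y in zip(t, amp):
            rows.append((well_id, w.label, "amplification", round(float(x), 6), float(y)))

        if w.true_anneal_c is None:
            melt = np.full_like(temps, spec.melt_base)
        else:
            melt = spec.melt_base + spec.melt_amplitude / (
                1.0 + np.exp((temps - w.true_anneal_c) / spec.melt_width_c)
            )
        if w.noise_sd > 0:
            melt = melt + rng.normal(0.0, w.noise_sd, size=len(temps))
        for x, y in zip(temps, melt):
            rows.append((well_id, w.label, "anneal", round(float(x), 6), float(y)))
    return pd.DataFrame(rows, columns=["well", "sample", "phase", "x", "y"])


def make_dilution_run(
    start_time_min: float = 9.0,
    step_min: float = 1.2,
    n_steps: int = 5,
    replicates: int = 2,
    anneal_c: float = 82.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RunSpec:
    """A five-fold-style dilution ladder: amplification time increases
    linearly with the dilution step (log concentration), emulating slower
    amplification at lower template concentration."""
    wells = []
    for step in range(n_steps):
        for r in range(replicates):
            wells.append(WellSpec(
                label=f"dil_step{step}",
                true_time_min=start_time_min + step_min * step,
                true_anneal_c=anneal_c,
                noise_sd=noise_sd,
            ))
    return RunSpec(wells=wells, seed=seed)


def amplicon_template(primer_set, seed: int = 0, spacer: int = 6,
                      flank: int = 30) -> str:
    """A canonical plus-strand template containing a primer set's amplicon.

    Region footprints are laid out in template order (F3 F2 [LF] F1 B1 [LB]
    B2 B3) separated by random spacers, with random flanks; degenerate
    footprint positions are resolved to one covered base at random (any
    choice matches the degenerate primer).  Screening this template at 0%
    divergence yields zero mismatches by construction.
    """
    from .iupac import bases  # local import; avoids cluttering module top

    rng = np.random.default_rng(seed)

    def resolve(fp: str) -> str:
        return "".join(
            ch if ch in "ACGT" else sorted(bases(ch))[rng.integers(len(bases(ch)))]
            for ch in fp
        )

    def rand(n: int) -> str:
        return "".join(_BASES[rng.integers(4, size=n)])

    fps = primer_set.region_footprints()
    order = [n for n in ("F3", "F2", "LF", "F1", "B1", "LB", "B2", "B3") if n in fps]
    parts = [rand(flank)]
    for i, name in enumerate(order):
        parts.append(resolve(fps[name]))
        if i < len(order) - 1:
            parts.append(rand(spacer))
    parts.append(rand(flank))
    return "".join(parts)


# -- constrained design fixture ---------------------------------------------

@dataclass
class DesignFixture:
    target: AlignmentSet
    nontarget: AlignmentSet
    expected_spans: dict[str, tuple[int, int]]
    planted_columns: dict[int, str]


def make_design_fixture(seed: int = 0, n_target: int = 8, n_nontarget: int = 30,
                        divergence_pct: float = 10.0,
                        plant_polymorphisms: bool = True) -> DesignFixture:
    """A target/non-target pair admitting exactly one primer layout.

    Gap columns in one target sequence (indel-variable sites disqualify
    primer footprints) carve the alignment into islands whose sizes pin each
    region: F3/F2/B2/B3 islands are exactly 18 columns, F1/B1 exactly 20, so
    every region has a single feasible placement and no loop primer fits.
    Two two-fold polymorphic columns are planted in the B1 island and one in
    the B2 island, so the assembled BIP of the (unique) candidate carries
    R/R/Y degeneracy 8.
    """
    islands = [("flank", 4), ("gap", 1), ("F3", 18), ("gap", 1), ("F2", 18),
               ("gap", 4), ("F1", 20), ("gap", 2), ("B1", 20), ("gap", 1),
               ("B2", 18), ("gap", 1), ("B3", 18), ("gap", 1), ("flank", 4)]
    length = sum(w for _, w in islands)
    spans: dict[str, tuple[int, int]] = {}
    gap_cols: list[int] = []
    pos = 0
    for name, width in islands:
        if name == "gap":
            gap_cols.extend(range(pos, pos + width))
        elif name != "flank":
            spans[name] = (pos, pos + width)
        pos += width

    b1s, b2s = spans["B1"], spans["B2"]
    planted = {b1s[0] + 4: "G", b1s[0] + 12: "T", b2s[0] + 6: "G"}  # R, Y, R

    rng = np.random.default_rng(seed)
    consensus = _BASES[rng.integers(4, size=length)]
    for col, alt in planted.items():
        consensus[col] = "A" if alt == "G" else "C"  # A/G -> R, C/T -> Y

    target_seqs = []
    for i in range(n_target - 1):
        s = consensus.copy()
        if plant_polymorphisms:
            for col, alt in planted.items():
                if i % 2 == 1:
                    s[col] = alt
        target_seqs.append("".join(s))
    gapped = consensus.copy().astype(object)
    for col in gap_cols:
        gapped[col] = "-"
    target_seqs.append("".join(gapped))

    n_sub = int(round(divergence_pct / 100.0 * length))
    nontarget_seqs = ["".join(_mutate(consensus, n_sub, rng)) for _ in range(n_nontarget)]

    target = AlignmentSet(name="design-fixture-target", role="target",
                          ids=[f"t{i:02d}" for i in range(n_target)],
                          sequences=target_seqs)
    nontarget = AlignmentSet(name="design-fixture-nontarget", role="non-target",
                             ids=[f"nt{i:02d}" for i in range(n_nontarget)],
                             sequences=nontarget_seqs)
    return DesignFixture(target=target, nontarget=nontarget,
                         expected_spans=spans, planted_columns=planted)
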