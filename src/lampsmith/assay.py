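"""Deterministic assay arithmetic: primer mixes, dilutions, protocol timing.

All concentration and volume arithmetic is carried in exact rationals
(:class:`fractions.Fraction`) and rendered to bench precision only on
output — a five-fold dilution of 10 ng/ul really is 10/625 = 0.016 ng/ul.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import pandas as pd

Number = int | float | str | Fraction


def _frac(x: Number) -> Fraction:
    return x if isinstance(x, Fraction) else Fraction(str(x))


class InfeasibleRecipeError(ValueError):
    """Component volumes exceed the requested total."""


@dataclass
class MixComponent:
    label: str
    stock_uM: Fraction
    volume_uL: Fraction


@dataclass
class MixRecipe:
    """A primer master mix: components, water top-up, total volume."""

    components: list[MixComponent]
    water_uL: Fraction
    total_uL: Fraction

    def __post_init__(self) -> None:
        if self.water_uL < 0:
            raise InfeasibleRecipeError("negative water volume")
        if any(c.volume_uL < 0 for c in self.components):
            raise ValueError("negative component volume")
        s = sum((c.volume_uL for c in self.components), Fraction(0)) + self.water_uL
        if s != self.total_uL:
            raise ValueError(f"components + water ({s}) != total ({self.total_uL})")

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"component": c.label, "stock_uM": float(c.stock_uM),
             "volume_uL": float(c.volume_uL)}
            for c in self.components
        ]
        rows.append({"component": "water", "stock_uM": None, "volume_uL": float(self.water_uL)})
        return pd.DataFrame(rows)


@dataclass
class ReactionSpec:
    """Volumes making up one reaction (defaults: 25 uL with 14 uL master mix,
    10 uL primer mix, 1 uL template)."""

    total_uL: Fraction = Fraction(25)
    master_mix_uL: Fraction = Fraction(14)
    primer_mix_uL: Fraction = Fraction(10)
    template_uL: Fraction = Fraction(1)

    def __post_init__(self) -> None:
        self.total_uL = _frac(self.total_uL)
        self.master_mix_uL = _frac(self.master_mix_uL)
        self.primer_mix_uL = _frac(self.primer_mix_uL)
        self.template_uL = _frac(self.template_uL)
        if self.master_mix_uL + self.primer_mix_uL + self.template_uL > self.total_uL:
            raise ValueError("reaction parts exceed total volume")


@dataclass
class DilutionSeries:
    start_ng_uL: Fraction
    factor: Fraction
    steps: int
    concentrations: list[Fraction]
    labels: list[str]

    def final_fold(self) -> Fraction:
        return self.factor ** self.steps


PRIMER_PAIRS = (("F3", "B3"), ("FIP", "BIP"), ("Floop", "Bloop"))


def primer_mix(
    ratio: Sequence[Number] = (1, 6, 3),
    outer_stock_uM: Number = 10,
    inner_stock_uM: Number = 100,
    loop_stock_uM: Number = 100,
    unit_volume_uL: Number = 10,
    total_uL: Number = 100,
) -> MixRecipe:
    """Primer master mix for an outer:inner:loop molar ratio.

    ``unit_volume_uL`` is the volume of *one outer primer* per ratio unit, so
    one ratio unit corresponds to ``outer_stock * unit_volume`` pmol of each
    primer in the slot.  The conventional 1:6:3 mix with 10 uM outer and
    100 uM inner/loop stocks in 100 uL therefore takes 10 uL each of F3/B3,
    6 uL each of FIP/BIP, 3 uL each of the loop primers and 62 uL of water.
    A loop ratio of 0 builds a four-primer mix.
    """
    if len(ratio) != 3:
        raise ValueError("ratio must have three slots (outer, inner, loop)")
    r = [_frac(x) for x in ratio]
    if r[0] <= 0 or r[1] <= 0 or r[2] < 0:
        raise ValueError("outer and inner ratio entries must be positive, loop >= 0")
    stocks = [_frac(outer_stock_uM), _frac(inner_stock_uM), _frac(loop_stock_uM)]
    unit_amount_pmol = stocks[0] * _frac(unit_volume_uL) / r[0]  # pmol per ratio unit
    total = _frac(total_uL)

    components: list[MixComponent] = []
    for (labels, ratio_i, stock) in zip(PRIMER_PAIRS, r, stocks):
        if ratio_i == 0:
            continue
        vol = ratio_i * unit_amount_pmol / stock
        for label in labels:
            components.append(MixComponent(label=label, stock_uM=stock, volume_uL=vol))
    used = sum((c.volume_uL for c in components), Fraction(0))
    if used > total:
        raise InfeasibleRecipeError(
            f"component volumes sum to {float(used)} uL, exceeding the {float(total)} uL total"
        )
    return MixRecipe(components=components, water_uL=total - used, total_uL=total)


def final_concentrations(mix: MixRecipe, rxn: ReactionSpec = ReactionSpec()) -> dict[str, Fraction]:
    """Per-primer concentration (uM) in the assembled reaction.

    conc = stock * (component volume / mix total) * (primer-mix volume / reaction total).
    """
    if mix.total_uL <= 0 or rxn.total_uL <= 0:
        raise ValueError("volumes must be positive")
    scale = rxn.primer_mix_uL / rxn.total_uL
    return {
        c.label: c.stock_uM * c.volume_uL / mix.total_uL * scale for c in mix.components
    }


def serial_dilution(start_ng_uL: Number, factor: Number, steps: int) -> DilutionSeries:
    """Serial dilution: concentration_i = start / factor**i for i = 0..steps.

    Labels give the cumulative dilution (1:1, 1:factor, ..., 1:factor**steps).
    """
    f = _frac(factor)
    if f <= 1:
        raise ValueError("dilution factor must exceed 1")
    if steps < 0:
        raise ValueError("steps must be >= 0")
    start = _frac(start_ng_uL)
    concs = [start / f**i for i in range(steps + 1)]
    labels = [f"1:{int(f**i) if (f**i).denominator == 1 else float(f**i)}" for i in range(steps + 1)]
    return DilutionSeries(start_ng_uL=start, factor=f, steps=steps,
                          concentrations=concs, labels=labels)


@dataclass(frozen=True)
class HoldStep:
    temperature_c: Fraction
    duration_s: Fraction

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("hold duration must be positive")


@dataclass(frozen=True)
class RampStep:
    start_c: Fraction
    end_c: Fraction
    rate_c_per_s: Fraction

    def __post_init__(self) -> None:
        if self.rate_c_per_s <= 0:
            raise ValueError("ramp rate must be positive")

    @property
    def duration_s(self) -> Fraction:
        return abs(self.start_c - self.end_c) / self.rate_c_per_s


@dataclass
class ProtocolProgram:
    """An ordered sequence of holds and ramps on an instrument."""

    steps: list[HoldStep | RampStep] = field(default_factory=list)


def hold(temperature_c: Number, duration_min: Number) -> HoldStep:
    return HoldStep(temperature_c=_frac(temperature_c), duration_s=_frac(duration_min) * 60)


def ramp(start_c: Number, end_c: Number, rate_c_per_s: Number) -> RampStep:
    return RampStep(start_c=_frac(start_c), end_c=_frac(end_c),
                    rate_c_per_s=_frac(rate_c_per_s))


def protocol_duration(program: ProtocolProgram) -> Fraction:
    """Total program time in minutes: holds plus |dT| / rate for each ramp."""
    total_s = sum((s.duration_s for s in program.steps), Fraction(0))
    return total_s / 60


def render_uM(x: Fraction) -> str:
    return f"{float(x):.1f}"


def render_ng_uL(x: Fraction) -> str:
    return f"{float(x):.3f}"
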