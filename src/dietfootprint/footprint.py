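"""The footprint engine: per-group and total diet greenhouse-gas emissions.

For each food group *g* with recommended daily amount ``REC_g`` (in the
guideline's units), the group's emissions are the consumption-weighted sum

    GHGE_g = sum_c  REC_g * Proportion_c * CF_c * GHGE_c

where ``Proportion_c`` is commodity *c*'s apparent-consumption share of the
group, ``CF_c`` converts one recommendation unit into kilograms of raw
edible commodity (unit conversion composed with the cooked->raw
adjustment), and ``GHGE_c`` is the cradle-to-farm-gate emission intensity
in kg CO2-eq per kg.  Group values are summed to a diet total; guidelines
that state a fixed sugar amount get a single-commodity sugar term, and
guidelines with discretionary calories (energy of unspecified composition)
are grossed up assuming the discretionary energy shares the footprint
intensity of the rest of the diet:

    total = base_total * diet_kcal / (diet_kcal - discretionary_kcal).

The controlled comparison re-evaluates every guideline under one fixed
reference country's consumption pattern, so that remaining differences
reflect the recommendations alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .conversions import (
    MILK_DENSITY_G_PER_ML,
    OZ_TO_G,
    CommodityConversion,
    CompositionTable,
)
from .errors import EmptyGroupError, MissingReferenceError, ValidationError
from .guidelines import GroupRecommendation, GuidelineSet
from .patterns import ConsumptionPattern, restrict_pattern

#: canonical display order for food-group columns
GROUP_ORDER = (
    "protein_foods",
    "dairy",
    "grains",
    "fruit",
    "vegetables",
    "fruit_and_vegetables",
    "oils_fats",
)

#: impact-table label carrying the sugar/sweeteners intensity
SUGAR_COMMODITY = "sugar & sweeteners"


@dataclass
class ImpactFactorTable:
    """Commodity -> emission intensity, kg CO2-eq per kg raw edible food.

    A commodity absent from the table is an explicit absent state: lookups
    raise :class:`MissingReferenceError` rather than returning zero, and
    membership tests drive the exclusion logic upstream.
    """

    intensities: dict[str, float] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        bad = {c: v for c, v in self.intensities.items() if v < 0}
        if bad:
            raise ValidationError(f"negative intensities: {bad}")

    def __contains__(self, commodity: str) -> bool:
        return commodity in self.intensities

    def __len__(self) -> int:
        return len(self.intensities)

    def intensity(self, commodity: str) -> float:
        try:
            return self.intensities[commodity]
        except KeyError:
            raise MissingReferenceError(commodity, "impact-factor table") from None

    @classmethod
    def from_csv(cls, path) -> "ImpactFactorTable":
        """Read {commodity, kg_co2e_per_kg, source_note} rows."""
        df = pd.read_csv(path)
        required = {"commodity", "kg_co2e_per_kg"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        intensities, notes = {}, {}
        for i, row in df.iterrows():
            c = str(row["commodity"])
            v = float(row["kg_co2e_per_kg"])
            if v < 0:
                raise ValidationError(
                    f"{path}, row {i + 2}: negative intensity {v} for {c!r}"
                )
            intensities[c] = v
            if "source_note" in df.columns and isinstance(row["source_note"], str):
                notes[c] = row["source_note"]
        return cls(intensities, notes)

    def to_csv(self, path) -> None:
        rows = [
            {"commodity": c, "kg_co2e_per_kg": v,
             "source_note": self.notes.get(c, "")}
            for c, v in sorted(self.intensities.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class DietFootprint:
    """Per-group and total daily emissions for one guideline set."""

    country: str
    per_group: Mapping[str, float]          # kg CO2-eq/d
    sugar_ghge: float                        # kg CO2-eq/d
    base_total: float                        # sum of per_group + sugar
    total: float                             # after discretionary gross-up
    per_commodity: Mapping[tuple[str, str], float]  # (group, commodity) -> kg CO2-eq/d

    def __post_init__(self):
        parts = sum(self.per_group.values()) + self.sugar_ghge
        if abs(parts - self.base_total) > 1e-9 * max(1.0, abs(self.base_total)):
            raise ValidationError(
                f"{self.country}: base_total {self.base_total} != sum of parts {parts}"
            )
        if self.total < self.base_total - 1e-12:
            raise ValidationError(
                f"{self.country}: total {self.total} below base_total {self.base_total}"
            )


def group_footprint(
    rec_amount: float,
    pattern: ConsumptionPattern,
    conv: Mapping[str, CommodityConversion],
    impacts: ImpactFactorTable,
) -> tuple[float, dict[str, float]]:
    """Consumption-weighted group emissions and per-commodity contributions.

    ``rec_amount`` is in recommendation units; ``conv`` maps each in-pattern
    commodity to its composite unit->kg-raw conversion.  Linear in
    ``rec_amount``; contributions re-sum to the group value exactly.
    """
    if rec_amount < 0:
        raise ValidationError(f"recommended amount must be nonnegative: {rec_amount}")
    contributions: dict[str, float] = {}
    for commodity, share in pattern.shares.items():
        if commodity not in conv:
            raise MissingReferenceError(commodity, "commodity conversion map")
        cf = conv[commodity].factor
        contributions[commodity] = rec_amount * share * cf * impacts.intensity(commodity)
    return sum(contributions.values()), contributions


def apply_discretionary(
    base_total: float, discretionary_kcal: float, diet_kcal: float
) -> float:
    """Gross up emissions to cover discretionary calories pro-rata.

    Assumes the unspecified discretionary energy has the same emission
    intensity per kcal as the rest of the recommended diet; identity at 0.
    """
    if diet_kcal <= 0:
        raise ValidationError(f"diet_kcal must be positive, got {diet_kcal}")
    if not 0 <= discretionary_kcal < diet_kcal:
        raise ValidationError(
            f"discretionary_kcal must lie in [0, diet_kcal): "
            f"{discretionary_kcal} vs {diet_kcal}"
        )
    return base_total * diet_kcal / (diet_kcal - discretionary_kcal)


def build_conversions(
    rec: GroupRecommendation,
    commodities: Sequence[str],
    comp: Optional[CompositionTable] = None,
    cooked_to_raw: Optional[Mapping[str, float]] = None,
    densities: Optional[Mapping[str, float]] = None,
) -> dict[str, CommodityConversion]:
    """Per-commodity composite conversions for one recommendation's unit.

    gram and ounce amounts convert by constants (ml additionally through
    commodity density, defaulting to the milk density); cup and piece
    amounts convert through calorie equivalence per commodity.  The
    cooked->raw factor defaults to 1 for commodities without an entry
    (produce, dairy — foods whose intensity basis matches the consumed
    state).
    """
    cooked_to_raw = cooked_to_raw or {}
    densities = densities or {}
    out: dict[str, CommodityConversion] = {}
    for c in commodities:
        if rec.unit == "g":
            unit_to_kg = 1e-3
        elif rec.unit == "oz":
            unit_to_kg = OZ_TO_G * 1e-3
        elif rec.unit == "ml":
            unit_to_kg = densities.get(c, MILK_DENSITY_G_PER_ML) * 1e-3
        elif rec.unit in ("cup", "piece"):
            if comp is None:
                raise MissingReferenceError(c, "composition table (none supplied)")
            unit_to_kg = comp.cup_to_kg(c)
        else:
            raise ValidationError(
                f"group {rec.group!r}: unit {rec.unit!r} must be resolved to "
                "g/ml/cup before footprint calculation"
            )
        out[c] = CommodityConversion(
            commodity=c,
            unit_to_kg=unit_to_kg,
            cooked_to_raw=cooked_to_raw.get(c, 1.0),
        )
    return out


def diet_footprint(
    gs: GuidelineSet,
    patterns: Mapping[str, ConsumptionPattern],
    conv: Optional[Mapping[str, float]] = None,
    impacts: ImpactFactorTable = None,
    comp: Optional[CompositionTable] = None,
    densities: Optional[Mapping[str, float]] = None,
    sugar_commodity: str = SUGAR_COMMODITY,
) -> DietFootprint:
    """Evaluate one guideline set under a map of group consumption patterns.

    ``conv`` is the per-commodity cooked->raw factor map (identity when
    omitted).  Recommendations with ``allowed_commodities`` are evaluated
    under the pattern restricted and renormalized to that set.  A ``sugar``
    recommendation (grams of sugar/sweeteners) becomes a single-commodity
    term added before the discretionary gross-up.
    """
    if impacts is None:
        raise ValidationError("an impact-factor table is required")
    per_group: dict[str, float] = {}
    per_commodity: dict[tuple[str, str], float] = {}
    sugar_ghge = 0.0
    for rec in gs.recommendations:
        if rec.group == "sugar":
            if rec.unit != "g":
                raise ValidationError(
                    f"{gs.country}: sugar recommendation must be in grams"
                )
            pattern = patterns.get("sugar") or ConsumptionPattern(
                country=gs.country, group="sugar", shares={sugar_commodity: 1.0}
            )
            sugar_conv = build_conversions(rec, pattern.commodities, comp, conv, densities)
            sugar_ghge, contribs = group_footprint(rec.amount, pattern, sugar_conv, impacts)
            for c, v in contribs.items():
                per_commodity[("sugar", c)] = v
            continue
        if rec.group not in patterns:
            raise EmptyGroupError(
                f"{gs.country}: no consumption pattern for group {rec.group!r}"
            )
        pattern = patterns[rec.group]
        if rec.allowed_commodities:
            try:
                pattern = restrict_pattern(pattern, rec.allowed_commodities)
            except EmptyGroupError as exc:
                raise EmptyGroupError(f"{gs.country}: {exc}") from None
        group_conv = build_conversions(rec, pattern.commodities, comp, conv, densities)
        value, contribs = group_footprint(rec.amount, pattern, group_conv, impacts)
        per_group[rec.group] = value
        for c, v in contribs.items():
            per_commodity[(rec.group, c)] = v
    base_total = sum(per_group.values()) + sugar_ghge
    total = apply_discretionary(base_total, gs.discretionary_kcal, gs.diet_kcal)
    return DietFootprint(
        country=gs.country,
        per_group=per_group,
        sugar_ghge=sugar_ghge,
        base_total=base_total,
        total=total,
        per_commodity=per_commodity,
    )


def footprint_table(
    footprints: Sequence[DietFootprint], decimals: Optional[int] = 2
) -> pd.DataFrame:
    """One row per guideline: per-group columns plus the diet total.

    Rounding (default 2 decimal places, matching conventional reporting of
    kg CO2-eq/d) applies at display time only; pass ``decimals=None`` for
    full precision.
    """
    groups = [g for g in GROUP_ORDER
              if any(g in fp.per_group for fp in footprints)]
    rows = []
    for fp in footprints:
        row: dict = {"country": fp.country}
        for g in groups:
            row[g] = fp.per_group.get(g)
        row["sugar"] = fp.sugar_ghge
        row["total"] = fp.total
        rows.append(row)
    df = pd.DataFrame(rows)
    if decimals is not None:
        num = df.columns.drop("country")
        df[num] = df[num].astype(float).round(decimals)
    return df


def controlled_comparison(
    guidelines: Sequence[GuidelineSet],
    reference_patterns: Mapping[str, ConsumptionPattern],
    conv: Optional[Mapping[str, float]] = None,
    impacts: ImpactFactorTable = None,
    comp: Optional[CompositionTable] = None,
    densities: Optional[Mapping[str, float]] = None,
    reference_country: str = "United States",
    decimals: Optional[int] = 2,
) -> pd.DataFrame:
    """Evaluate all guidelines under one reference consumption pattern.

    Every guideline is scored with the reference country's within-group
    patterns (restricted to each guideline's allowed commodities where
    given), so between-country differences reflect the recommendations
    alone.  The ratio column is the reference country's total divided by
    each row's total, computed at full precision and rounded for display.
    """
    footprints = [
        diet_footprint(gs, reference_patterns, conv, impacts, comp, densities)
        for gs in guidelines
    ]
    totals = {fp.country: fp.total for fp in footprints}
    if reference_country not in totals:
        raise ValidationError(
            f"reference country {reference_country!r} not among guidelines "
            f"{sorted(totals)}"
        )
    ref_total = totals[reference_country]
    df = footprint_table(footprints, decimals=None)
    df["reference_ratio"] = [ref_total / t for t in df["total"]]
    if decimals is not None:
        num = df.columns.drop("country")
        df[num] = df[num].astype(float).round(decimals)
    return df


def reference_ratio(reference_total: float, total: float) -> float:
    """Ratio of the reference diet's total emissions to another diet's."""
    if total <= 0:
        raise ValidationError(f"total must be positive, got {total}")
    return reference_total / total


def per_commodity_frame(footprints: Sequence[DietFootprint]) -> pd.DataFrame:
    """Long-format per-commodity breakdown across guidelines."""
    rows = [
        {"country": fp.country, "group": g, "commodity": c, "ghge_kg_co2e_per_d": v}
        for fp in footprints
        for (g, c), v in fp.per_commodity.items()
    ]
    return pd.DataFrame(rows, columns=["country", "group", "commodity",
                                       "ghge_kg_co2e_per_d"])
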