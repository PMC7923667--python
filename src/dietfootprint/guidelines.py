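"""Representation and normalization of food-based dietary guidelines (FBDG).

A national guideline is modelled as a :class:`GuidelineSet`: one daily
quantitative recommendation per food group, the energy level the pattern
was designed for, an optional discretionary-calorie allowance (energy with
unspecified composition), and optionally a fixed sugar/sweetener add-on
carried as its own single-commodity group.

Normalization steps implemented here:

* ranges are collapsed to their midpoint (``midpoint_amount``);
* patterns stated at other energy levels (2500 kcal, 2200 kcal, ...) are
  rescaled pro-rata to a common target, conventionally 2000 kcal
  (``scale_guidelines``);
* heterogeneous units are resolved to grams/day of consumed food
  (``resolve_recommendation``): ounces through the standard 28.3495 g/oz,
  cups through calorie-equivalence against a composition table, "pieces"
  of fruit as one cup each, millilitres through commodity density.

Guideline configs are plain YAML data files, one per country; the code
never hard-codes a country.  A transcription of nine published guideline
sets (seven countries, a vegetarian variant, and the EAT-Lancet reference
diet), already scaled to 2000 kcal, ships as package data — see
:func:`packaged_guidelines`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .conversions import (
    MILK_DENSITY_G_PER_ML,
    OZ_TO_G,
    CompositionTable,
)
from .errors import MissingReferenceError, ValidationError

#: closed set of food-group labels
FOOD_GROUPS = (
    "protein_foods",
    "dairy",
    "grains",
    "fruit",
    "vegetables",
    "oils_fats",
    "fruit_and_vegetables",
    "sugar",
)

#: closed set of recommendation units
UNITS = ("g", "ml", "oz", "cup", "piece", "serving")

#: relative tolerance for subgroup amounts summing to the group amount
_SUBGROUP_RTOL = 0.01


@dataclass(frozen=True)
class GroupRecommendation:
    """One food group's recommended daily amount.

    ``basis`` marks the consumed state the amount refers to: cooked edible
    mass for solids, as-served volume for liquids.  ``allowed_commodities``
    optionally restricts which balance-sheet commodities may satisfy the
    recommendation (e.g. a plant-proteins-only protein group).
    ``subgroup_amounts`` records guidelines that pin sub-quantities within
    the group; when present they must sum to ``amount`` within 1%.
    """

    group: str
    amount: float
    unit: str
    basis: str = "cooked_edible"
    allowed_commodities: Optional[tuple[str, ...]] = None
    subgroup_amounts: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        if self.group not in FOOD_GROUPS:
            raise ValidationError(
                f"unknown food group {self.group!r}; expected one of {FOOD_GROUPS}"
            )
        if self.unit not in UNITS:
            raise ValidationError(
                f"unknown unit {self.unit!r}; expected one of {UNITS}"
            )
        if self.amount < 0:
            raise ValidationError(f"amount must be nonnegative, got {self.amount}")
        if self.subgroup_amounts is not None:
            total = sum(self.subgroup_amounts.values())
            if self.amount > 0 and abs(total - self.amount) > _SUBGROUP_RTOL * self.amount:
                raise ValidationError(
                    f"subgroup amounts for {self.group!r} sum to {total}, "
                    f"not within 1% of {self.amount}"
                )


@dataclass(frozen=True)
class GuidelineSet:
    """A country's full set of daily food-group recommendations."""

    country: str
    diet_kcal: float
    recommendations: tuple[GroupRecommendation, ...]
    discretionary_kcal: float = 0.0
    notes: str = ""

    def __post_init__(self):
        if self.diet_kcal <= 0:
            raise ValidationError(f"diet_kcal must be positive, got {self.diet_kcal}")
        if not 0 <= self.discretionary_kcal < self.diet_kcal:
            raise ValidationError(
                f"discretionary_kcal must lie in [0, diet_kcal): "
                f"{self.discretionary_kcal} vs {self.diet_kcal}"
            )
        groups = [r.group for r in self.recommendations]
        if len(groups) != len(set(groups)):
            raise ValidationError(
                f"{self.country}: duplicate food-group recommendations in {groups}"
            )
        object.__setattr__(self, "recommendations", tuple(self.recommendations))

    def recommendation(self, group: str) -> GroupRecommendation:
        for rec in self.recommendations:
            if rec.group == group:
                return rec
        raise KeyError(group)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(r.group for r in self.recommendations)


def midpoint_amount(low: float, high: float) -> float:
    """Midpoint of a recommendation range; used when guidelines state ranges."""
    if low < 0 or high < low:
        raise ValidationError(f"need 0 <= low <= high, got ({low}, {high})")
    return (low + high) / 2.0


def scale_guidelines(gs: GuidelineSet, target_kcal: float) -> GuidelineSet:
    """Rescale every quantity in a guideline pro-rata to ``target_kcal``.

    All amounts (including subgroup amounts and the discretionary-calorie
    allowance) are multiplied by ``target_kcal / gs.diet_kcal``; scaling to
    the guideline's own energy level is the identity.
    """
    if target_kcal <= 0:
        raise ValidationError(f"target_kcal must be positive, got {target_kcal}")
    k = target_kcal / gs.diet_kcal
    recs = []
    for rec in gs.recommendations:
        sub = None
        if rec.subgroup_amounts is not None:
            sub = {name: amt * k for name, amt in rec.subgroup_amounts.items()}
        recs.append(replace(rec, amount=rec.amount * k, subgroup_amounts=sub))
    return replace(
        gs,
        diet_kcal=target_kcal,
        discretionary_kcal=gs.discretionary_kcal * k,
        recommendations=tuple(recs),
    )


def resolve_recommendation(
    rec: GroupRecommendation,
    comp: Optional[CompositionTable] = None,
    density_table: Optional[Mapping[str, float]] = None,
    commodity: Optional[str] = None,
) -> float:
    """Express a recommendation as grams/day of consumed (cooked edible) food.

    ``commodity`` names the food whose composition/density entry applies for
    cup, piece and ml units; when the composition table holds a single entry
    it is used implicitly.  Volumes use the milk density 1.0305 g/ml unless
    the density table provides a commodity-specific value.  ``serving``
    units are rejected: serving sizes are country-specific and must be
    resolved to g/ml/cup in the guideline config itself.
    """
    if rec.unit == "g":
        return rec.amount
    if rec.unit == "oz":
        return rec.amount * OZ_TO_G
    if rec.unit == "ml":
        density = MILK_DENSITY_G_PER_ML
        if density_table and commodity is not None and commodity in density_table:
            density = density_table[commodity]
        return rec.amount * density
    if rec.unit in ("cup", "piece"):
        # one "piece" of fruit is taken as one cup
        if comp is None:
            raise MissingReferenceError(
                commodity or rec.group, "composition table (none supplied)"
            )
        if commodity is None:
            if len(comp.entries) == 1:
                commodity = next(iter(comp.entries))
            else:
                raise ValidationError(
                    f"cup/piece conversion for group {rec.group!r} needs an "
                    "explicit commodity when the composition table has "
                    f"{len(comp.entries)} entries"
                )
        return rec.amount * comp.cup_to_grams(commodity)
    if rec.unit == "serving":
        raise ValidationError(
            f"group {rec.group!r}: 'serving' units must be resolved to "
            "g/ml/cup in the guideline config"
        )
    raise ValidationError(f"unhandled unit {rec.unit!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# YAML config I/O
# ---------------------------------------------------------------------------

def _rec_from_mapping(m: Mapping, source: str) -> GroupRecommendation:
    try:
        allowed = m.get("allowed_commodities")
        sub = m.get("subgroup_amounts")
        return GroupRecommendation(
            group=m["group"],
            amount=float(m["amount"]),
            unit=m["unit"],
            basis=m.get("basis", "cooked_edible"),
            allowed_commodities=tuple(allowed) if allowed else None,
            subgroup_amounts=dict(sub) if sub else None,
        )
    except KeyError as exc:
        raise ValidationError(f"{source}: recommendation missing key {exc}") from None


def guideline_from_mapping(data: Mapping, source: str = "<config>") -> GuidelineSet:
    try:
        recs = tuple(
            _rec_from_mapping(m, source) for m in data["recommendations"]
        )
        return GuidelineSet(
            country=data["country"],
            diet_kcal=float(data["diet_kcal"]),
            recommendations=recs,
            discretionary_kcal=float(data.get("discretionary_kcal", 0.0)),
            notes=data.get("notes", ""),
        )
    except KeyError as exc:
        raise ValidationError(f"{source}: guideline config missing key {exc}") from None


def load_guideline(path) -> GuidelineSet:
    """Load one guideline config (YAML) from ``path``."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValidationError(f"{path}: expected a mapping at top level")
    return guideline_from_mapping(data, str(path))


def load_guidelines(paths: Sequence) -> list[GuidelineSet]:
    """Load several configs, or every ``*.yaml`` file when given a directory."""
    out: list[GuidelineSet] = []
    for p in paths:
        p = Path(p)
        if p.is_dir():
            out.extend(load_guideline(f) for f in sorted(p.glob("*.yaml")))
        else:
            out.append(load_guideline(p))
    return out


def guideline_to_mapping(gs: GuidelineSet) -> dict:
    recs = []
    for r in gs.recommendations:
        m: dict = {"group": r.group, "amount": r.amount, "unit": r.unit}
        if r.basis != "cooked_edible":
            m["basis"] = r.basis
        if r.allowed_commodities:
            m["allowed_commodities"] = list(r.allowed_commodities)
        if r.subgroup_amounts:
            m["subgroup_amounts"] = dict(r.subgroup_amounts)
        recs.append(m)
    out: dict = {
        "country": gs.country,
        "diet_kcal": gs.diet_kcal,
        "recommendations": recs,
    }
    if gs.discretionary_kcal:
        out["discretionary_kcal"] = gs.discretionary_kcal
    if gs.notes:
        out["notes"] = gs.notes
    return out


def save_guideline(gs: GuidelineSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(guideline_to_mapping(gs), fh, sort_keys=False)


def packaged_guidelines() -> list[GuidelineSet]:
    """The nine guideline sets shipped as package data, 2000-kcal scaled."""
    root = resources.files("dietfootprint").joinpath("data/guidelines")
    out = []
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            data = yaml.safe_load(entry.read_text())
            out.append(guideline_from_mapping(data, entry.name))
    return out
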