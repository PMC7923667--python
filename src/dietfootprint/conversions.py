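"""Unit and state conversions shared across the pipeline.

Recommendations arrive in heterogeneous units (grams, millilitres, ounces,
cups, "pieces" of fruit) and in the *consumed* state (cooked, edible),
while emission intensities are expressed per kilogram of *raw edible*
food.  This module holds the pure conversion primitives:

* volume -> mass by calorie equivalence (``cup_to_grams``), using food
  composition data: a cup of a food with 662 kcal/cup and 341 kcal/100 g
  weighs 100 * 662 / 341 = ~194 g;
* cooked -> raw mass adjustment (``cooked_to_raw``);
* milk volume -> mass through a fixed density;
* arithmetic averaging of member factors for aggregate commodities such
  as "nuts and products" (``aggregate_conversion``).

All conversions are linear in their mass/volume argument; full precision
is kept internally and rounding happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Mapping

import pandas as pd

from .errors import MissingReferenceError, ValidationError

#: grams per avoirdupois ounce
OZ_TO_G = 28.3495

#: density of milk, g/ml; used for ml <-> g dairy conversions
MILK_DENSITY_G_PER_ML = 1.0305


def cup_to_grams(kcal_per_cup: float, kcal_per_100g: float) -> float:
    """Grams of food whose energy equals one cup, by calorie equivalence.

    Parameters
    ----------
    kcal_per_cup : energy content of one cup of the food (kcal).
    kcal_per_100g : energy content of 100 g of the food (kcal).

    Returns
    -------
    float
        100 * kcal_per_cup / kcal_per_100g, in grams.  Full precision;
        round to the nearest gram only for display.
    """
    if kcal_per_cup <= 0 or kcal_per_100g <= 0:
        raise ValidationError(
            f"energy contents must be positive, got cup={kcal_per_cup}, "
            f"100g={kcal_per_100g}"
        )
    return 100.0 * kcal_per_cup / kcal_per_100g


def aggregate_conversion(member_factors: Iterable[float]) -> float:
    """Unweighted arithmetic mean of member conversion factors.

    Aggregate balance-sheet commodities ("nuts and products", "freshwater
    fish") carry one factor computed as the plain mean over the individual
    foods they contain.
    """
    factors = list(member_factors)
    if not factors:
        raise ValidationError("aggregate_conversion needs at least one factor")
    if any(f <= 0 for f in factors):
        raise ValidationError(f"conversion factors must be positive: {factors}")
    return fmean(factors)


def cooked_to_raw(mass_cooked: float, factor: float) -> float:
    """Convert a cooked-edible mass to the raw-edible mass that produced it.

    ``factor`` is raw mass per unit cooked mass: > 1 for foods that lose
    water in cooking (meats), < 1 for foods that take up water (grains,
    legumes).
    """
    if factor <= 0:
        raise ValidationError(f"cooked-to-raw factor must be positive, got {factor}")
    return mass_cooked * factor


def milk_volume_to_mass(volume_ml: float, density: float = MILK_DENSITY_G_PER_ML) -> float:
    """Convert a milk (or milk-like dairy) volume in ml to grams."""
    if volume_ml < 0:
        raise ValidationError(f"volume must be nonnegative, got {volume_ml}")
    if density <= 0:
        raise ValidationError(f"density must be positive, got {density}")
    return volume_ml * density


@dataclass(frozen=True)
class CompositionEntry:
    kcal_per_cup: float
    kcal_per_100g: float

    def __post_init__(self):
        if self.kcal_per_cup <= 0 or self.kcal_per_100g <= 0:
            raise ValidationError(
                f"composition energies must be positive: {self}"
            )


@dataclass
class CompositionTable:
    """Per-commodity energy densities used for volume->mass conversion."""

    entries: dict[str, CompositionEntry] = field(default_factory=dict)

    def __contains__(self, commodity: str) -> bool:
        return commodity in self.entries

    def entry(self, commodity: str) -> CompositionEntry:
        try:
            return self.entries[commodity]
        except KeyError:
            raise MissingReferenceError(commodity, "composition table") from None

    def cup_to_grams(self, commodity: str) -> float:
        e = self.entry(commodity)
        return cup_to_grams(e.kcal_per_cup, e.kcal_per_100g)

    def cup_to_kg(self, commodity: str) -> float:
        return self.cup_to_grams(commodity) / 1000.0

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        """Read a CSV with columns commodity, kcal_per_cup, kcal_per_100g."""
        df = pd.read_csv(path)
        required = {"commodity", "kcal_per_cup", "kcal_per_100g"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        entries = {}
        for i, row in df.iterrows():
            try:
                entries[str(row["commodity"])] = CompositionEntry(
                    float(row["kcal_per_cup"]), float(row["kcal_per_100g"])
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(f"{path}, row {i + 2}: {exc}") from None
        return cls(entries)


@dataclass(frozen=True)
class CommodityConversion:
    """Composite factor taking a recommendation unit to kg of raw commodity.

    ``unit_to_kg`` converts one recommendation unit (a cup, a gram, a ml of
    dairy...) to kilograms of the commodity in its consumed (cooked edible)
    state; ``cooked_to_raw`` then adjusts to the raw-edible basis on which
    emission intensities are expressed.  The product of the two is the
    per-commodity conversion factor entering the footprint sum.
    """

    commodity: str
    unit_to_kg: float
    cooked_to_raw: float = 1.0

    def __post_init__(self):
        if self.unit_to_kg <= 0 or self.cooked_to_raw <= 0:
            raise ValidationError(
                f"conversion factors must be positive: {self}"
            )

    @property
    def factor(self) -> float:
        """kg raw edible commodity per recommendation unit."""
        return self.unit_to_kg * self.cooked_to_raw


def write_composition_csv(entries: Mapping[str, CompositionEntry], path) -> None:
    rows = [
        {"commodity": c, "kcal_per_cup": e.kcal_per_cup, "kcal_per_100g": e.kcal_per_100g}
        for c, e in sorted(entries.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
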