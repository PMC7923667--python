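"""Apparent-consumption patterns from food-balance-sheet supply data.

National guidelines recommend food *groups* ("protein foods"), not items
("beef", "poultry"), yet emission intensities differ enormously between
items.  To give a group recommendation item-level specificity, the annual
per-capita food supply of each balance-sheet commodity (kg/capita/year) is
used as a proxy for consumption: within each food group, a commodity's
share of the group's total supply is its *apparent-consumption proportion*.

Supply quantities are reported in heterogeneous processing states (carcass
weight for meats, in-shell for nuts and eggs, dry for grains and legumes),
so before taking proportions every commodity is converted to a common
cooked-edible mass basis through an ordered chain of conversion factors
(:func:`to_cooked_edible`).

Commodities with no emission-intensity entry cannot enter the footprint
sum; they are excluded *before* proportions are taken, so shares always
form a proper distribution over usable commodities, and the excluded mass
fraction is recorded on the pattern for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import EmptyGroupError, MissingReferenceError, ValidationError

#: closed set of supply processing states
STATES = ("carcass", "raw_in_shell", "raw_edible", "dry_raw", "as_is")

#: conversion-step vocabulary
STEPS = ("carcass_to_boneless", "raw_to_cooked", "shell_removal", "dry_to_cooked")

#: default conversion chain implied by each processing state
DEFAULT_CHAINS: dict[str, tuple[str, ...]] = {
    "carcass": ("carcass_to_boneless", "raw_to_cooked"),
    "raw_in_shell": ("shell_removal", "raw_to_cooked"),
    "raw_edible": ("raw_to_cooked",),
    "dry_raw": ("dry_to_cooked",),
    "as_is": (),
}

#: declared direction constraints for factor validation
_DIRECTIONS = {"gain", "loss", "none"}


@dataclass(frozen=True)
class CommoditySupplyRecord:
    """One commodity's per-capita supply for one country."""

    country: str
    commodity: str
    group: str
    supply: float  # kg/capita/year, in `state`
    state: str = "as_is"
    conversion_chain: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.supply < 0:
            raise ValidationError(
                f"{self.country}/{self.commodity}: supply must be nonnegative, "
                f"got {self.supply}"
            )
        if self.state not in STATES:
            raise ValidationError(
                f"{self.country}/{self.commodity}: unknown state {self.state!r}"
            )
        if self.conversion_chain is not None:
            bad = set(self.conversion_chain) - set(STEPS)
            if bad:
                raise ValidationError(
                    f"{self.commodity}: unknown conversion steps {sorted(bad)}"
                )

    @property
    def chain(self) -> tuple[str, ...]:
        """Explicit chain if given, else the default implied by the state."""
        if self.conversion_chain is not None:
            return self.conversion_chain
        return DEFAULT_CHAINS[self.state]


@dataclass
class ConversionFactorSet:
    """Per-commodity factors for each processing-state conversion step.

    ``raw_to_cooked`` factors are the average of dry- and wet-method
    cooking factors for meats/fish (< 1, cooking loss) and reflect water
    uptake for grains/legumes cooked from dry (> 1).  Direction is declared
    per factor in the data file, never guessed from the commodity name.
    """

    carcass_to_boneless: dict[str, float] = field(default_factory=dict)
    raw_to_cooked: dict[str, float] = field(default_factory=dict)
    shell_removal: dict[str, float] = field(default_factory=dict)
    dry_to_cooked: dict[str, float] = field(default_factory=dict)

    def table(self, step: str) -> dict[str, float]:
        try:
            return getattr(self, step)
        except AttributeError:
            raise ValidationError(f"unknown conversion step {step!r}") from None

    def factor(self, commodity: str, step: str) -> float:
        table = self.table(step)
        try:
            return table[commodity]
        except KeyError:
            raise MissingReferenceError(commodity, f"conversion step {step!r}") from None

    def cooked_to_raw_factors(self) -> dict[str, float]:
        """Per-commodity cooked->raw factors for the footprint engine.

        Emission intensities apply to raw edible mass while recommendations
        are in cooked mass, so the cooking conversions invert: a meat that
        keeps 72% of its mass when cooked needs 1/0.72 kg raw per cooked kg;
        a grain that cooks up from dry by 2.2x needs 1/2.2 kg dry per cooked
        kg.  Commodities with neither factor default to identity upstream.
        """
        out = {c: 1.0 / f for c, f in self.dry_to_cooked.items()}
        out.update({c: 1.0 / f for c, f in self.raw_to_cooked.items()})
        return out

    @classmethod
    def from_csv(cls, path) -> "ConversionFactorSet":
        """Read {commodity, step, factor, direction} rows.

        direction ∈ {gain, loss, none}: gain requires factor >= 1, loss
        requires factor <= 1.  Reductions (carcass boning, shelling) must
        additionally not exceed 1.
        """
        df = pd.read_csv(path)
        required = {"commodity", "step", "factor", "direction"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        out = cls()
        for i, row in df.iterrows():
            where = f"{path}, row {i + 2}"
            step, factor = str(row["step"]), float(row["factor"])
            direction = str(row["direction"])
            if step not in STEPS:
                raise ValidationError(f"{where}: unknown step {step!r}")
            if factor <= 0:
                raise ValidationError(f"{where}: factor must be positive")
            if direction not in _DIRECTIONS:
                raise ValidationError(f"{where}: unknown direction {direction!r}")
            if direction == "gain" and factor < 1:
                raise ValidationError(f"{where}: declared gain but factor {factor} < 1")
            if direction == "loss" and factor > 1:
                raise ValidationError(f"{where}: declared loss but factor {factor} > 1")
            if step in ("carcass_to_boneless", "shell_removal") and factor > 1:
                raise ValidationError(f"{where}: {step} factor {factor} exceeds 1")
            out.table(step)[str(row["commodity"])] = factor
        return out

    def to_csv(self, path) -> None:
        rows = []
        for step in STEPS:
            for commodity, factor in sorted(self.table(step).items()):
                direction = "gain" if factor >= 1 else "loss"
                rows.append(
                    {"commodity": commodity, "step": step,
                     "factor": factor, "direction": direction}
                )
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class ConsumptionPattern:
    """Within-group commodity proportions on the cooked-edible mass basis."""

    country: str
    group: str
    shares: Mapping[str, float]
    excluded_share: float = 0.0

    #: absolute tolerance on the share sum; generous enough for patterns
    #: transcribed from tables printed at 3 decimal places
    SUM_ATOL = 0.005

    def __post_init__(self):
        object.__setattr__(self, "shares", dict(self.shares))
        if any(not 0 <= v <= 1 for v in self.shares.values()):
            raise ValidationError(f"shares must lie in [0, 1]: {self.shares}")
        if not 0 <= self.excluded_share <= 1:
            raise ValidationError(
                f"excluded_share must lie in [0, 1], got {self.excluded_share}"
            )
        if self.shares:
            total = sum(self.shares.values())
            if abs(total - 1.0) > self.SUM_ATOL:
                raise ValidationError(
                    f"{self.country}/{self.group}: shares sum to {total}, not 1"
                )

    @property
    def commodities(self) -> tuple[str, ...]:
        return tuple(self.shares)


def to_cooked_edible(rec: CommoditySupplyRecord, conv: ConversionFactorSet) -> float:
    """Supply mass converted to cooked edible kg/capita/year.

    Applies the record's conversion chain in order; an empty chain is the
    identity (produce, dairy and other as-is commodities).
    """
    mass = rec.supply
    for step in rec.chain:
        mass *= conv.factor(rec.commodity, step)
    return mass


def compute_pattern(
    records: Sequence[CommoditySupplyRecord],
    conv: ConversionFactorSet,
    impacts,
) -> ConsumptionPattern:
    """Within-group shares over commodities that carry an impact factor.

    ``impacts`` is anything supporting ``commodity in impacts`` (an
    :class:`~dietfootprint.footprint.ImpactFactorTable`).  Exclusion happens
    on the cooked-edible basis before normalization; the dropped mass
    fraction is reported as ``excluded_share``.
    """
    if not records:
        raise EmptyGroupError("no supply records given")
    countries = {r.country for r in records}
    groups = {r.group for r in records}
    if len(countries) > 1 or len(groups) > 1:
        raise ValidationError(
            f"records span multiple countries/groups: {countries} / {groups}"
        )
    cooked = {r.commodity: to_cooked_edible(r, conv) for r in records}
    total = sum(cooked.values())
    included = {c: m for c, m in cooked.items() if c in impacts}
    included_total = sum(included.values())
    if included_total <= 0:
        raise EmptyGroupError(
            f"{next(iter(countries))}/{next(iter(groups))}: no commodity with "
            "positive cooked-edible mass and an impact factor"
        )
    shares = {c: m / included_total for c, m in included.items()}
    excluded_share = 1.0 - included_total / total if total > 0 else 0.0
    return ConsumptionPattern(
        country=next(iter(countries)),
        group=next(iter(groups)),
        shares=shares,
        excluded_share=excluded_share,
    )


def restrict_pattern(
    pattern: ConsumptionPattern, allowed: Iterable[str]
) -> ConsumptionPattern:
    """Restrict shares to ``allowed`` commodities and renormalize.

    Used when a guideline admits only a subset of a group (e.g. a
    plant-proteins-only protein group evaluated under another country's
    consumption pattern).
    """
    allowed = set(allowed)
    kept = {c: s for c, s in pattern.shares.items() if c in allowed}
    total = sum(kept.values())
    if not kept or total <= 0:
        raise EmptyGroupError(
            f"{pattern.country}/{pattern.group}: no overlap between pattern "
            f"commodities {sorted(pattern.shares)} and allowed {sorted(allowed)}"
        )
    return replace(pattern, shares={c: s / total for c, s in kept.items()})


def patterns_for_country(
    records: Sequence[CommoditySupplyRecord],
    conv: ConversionFactorSet,
    impacts,
    country: str,
    groups: Iterable[str],
) -> dict[str, ConsumptionPattern]:
    """Compute one pattern per requested group for one country.

    The combined ``fruit_and_vegetables`` group, used by guidelines that do
    not separate the two, is formed from the union of fruit and vegetable
    supply records.
    """
    recs = [r for r in records if r.country == country]
    out: dict[str, ConsumptionPattern] = {}
    for group in groups:
        if group == "fruit_and_vegetables":
            members = [r for r in recs if r.group in ("fruit", "vegetables",
                                                      "fruit_and_vegetables")]
            members = [replace(r, group="fruit_and_vegetables") for r in members]
        else:
            members = [r for r in recs if r.group == group]
        if not members:
            raise EmptyGroupError(f"{country}: no supply records for group {group!r}")
        out[group] = compute_pattern(members, conv, impacts)
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_SUPPLY_COLUMNS = ("country", "commodity", "group", "supply_kg_per_capita_yr", "state")


def read_supply_csv(path) -> list[CommoditySupplyRecord]:
    """Read balance-sheet-style supply rows.

    Columns: country, commodity, group, supply_kg_per_capita_yr, state, and
    optionally conversion_chain (semicolon-separated step labels overriding
    the state's default chain).  Dairy tables use the identical schema.
    """
    df = pd.read_csv(path)
    missing = set(_SUPPLY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        chain = None
        if "conversion_chain" in df.columns and isinstance(row["conversion_chain"], str):
            chain = tuple(s for s in row["conversion_chain"].split(";") if s)
        try:
            records.append(
                CommoditySupplyRecord(
                    country=str(row["country"]),
                    commodity=str(row["commodity"]),
                    group=str(row["group"]),
                    supply=float(row["supply_kg_per_capita_yr"]),
                    state=str(row["state"]),
                    conversion_chain=chain,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {i + 2}: {exc}") from None
    return records


def write_supply_csv(records: Sequence[CommoditySupplyRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "country": r.country,
            "commodity": r.commodity,
            "group": r.group,
            "supply_kg_per_capita_yr": f"{r.supply:.6f}",
            "state": r.state,
        }
        if r.conversion_chain is not None:
            row["conversion_chain"] = ";".join(r.conversion_chain)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
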