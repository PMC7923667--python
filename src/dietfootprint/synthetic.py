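"""Synthetic study bundles and packaged reference fixtures.

Every pipeline stage is testable without external downloads:

* :func:`gen_supply_table`, :func:`gen_impact_table` and friends generate
  balance-sheet-style supply data, emission intensities, conversion
  factors, composition tables and guideline configs with controlled
  structure.  Within each country x group, cooked-edible commodity shares
  follow a symmetric Dirichlet (proportions live on a simplex) and
  intensities are lognormal (strictly positive, right-skewed) — minimal
  distributional scaffolding, not an attempt to emulate real country
  profiles.  All generators are pure functions of their config and seed.

* :func:`table2_fixture` packages a published worked example: the US
  daily fruit recommendation (2 cups) spread over ten balance-sheet fruit
  commodities with printed consumption proportions, cup->kg conversion
  factors and emission intensities, totalling 0.165 kg CO2-eq/d.

* ``TABLE3_PRINTED`` / ``TABLE4_PRINTED`` transcribe the published
  per-group emission tables (baseline and US-pattern-controlled) for
  regression tests of arithmetic identities; they are reference *outputs*,
  never inputs to the engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .conversions import CommodityConversion
from .errors import ValidationError
from .footprint import SUGAR_COMMODITY, ImpactFactorTable
from .guidelines import GroupRecommendation, GuidelineSet
from .patterns import ConsumptionPattern

SYNTH_GROUPS = ("protein_foods", "dairy", "grains", "fruit", "vegetables", "oils_fats")

#: per-group (state, chain factors) used by the synthetic supply generator;
#: protein commodities flow carcass -> boneless -> cooked, grains cook up
#: from dry, everything else is used as-is
_GROUP_STATE = {
    "protein_foods": "carcass",
    "grains": "dry_raw",
    "dairy": "as_is",
    "fruit": "as_is",
    "vegetables": "as_is",
    "oils_fats": "as_is",
}

#: plausible total cooked-edible group supply, kg/capita/year, loosely
#: matching the magnitude of national balance-sheet data
_GROUP_MASS = {
    "protein_foods": 60.0,
    "dairy": 120.0,
    "grains": 130.0,
    "fruit": 70.0,
    "vegetables": 90.0,
    "oils_fats": 20.0,
}

#: plausible 2000-kcal daily recommendation ranges per group (g or ml)
_REC_RANGE = {
    "protein_foods": (75.0, 170.0),
    "dairy": (118.0, 710.0),
    "grains": (170.0, 660.0),
    "fruit": (100.0, 790.0),
    "vegetables": (200.0, 510.0),
    "oils_fats": (25.0, 56.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study-bundle generator.

    ``share_concentration`` is the symmetric-Dirichlet concentration of
    within-group cooked-edible shares (1 = uniform over the simplex; large
    values concentrate near equal shares).  Intensities are lognormal with
    the given log-scale parameters; the defaults give a median of 1 kg
    CO2-eq/kg with a heavy right tail, the qualitative shape of real
    food-emission data.
    """

    n_countries: int = 7
    commodities_per_group: int = 6
    share_concentration: float = 1.0
    intensity_log_mean: float = 0.0
    intensity_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_countries < 1 or self.commodities_per_group < 1:
            raise ValidationError("counts must be >= 1")
        if self.share_concentration <= 0:
            raise ValidationError("share_concentration must be positive")
        if self.intensity_log_sd < 0:
            raise ValidationError("intensity_log_sd must be nonnegative")


def _countries(cfg: SyntheticConfig) -> list[str]:
    return [f"synthland_{i + 1:02d}" for i in range(cfg.n_countries)]


def _commodities(cfg: SyntheticConfig, group: str) -> list[str]:
    return [f"{group}_c{j + 1:02d}" for j in range(cfg.commodities_per_group)]


def _chain_factors(cfg: SyntheticConfig, group: str, commodity_index: int) -> dict[str, float]:
    """Deterministic per-commodity conversion factors (no RNG: stable
    across supply draws so the conversion CSV matches every bundle)."""
    if _GROUP_STATE[group] == "carcass":
        # boning keeps ~70%, cooking loses ~25%, jittered per commodity
        j = commodity_index
        return {
            "carcass_to_boneless": 0.65 + 0.01 * (j % 5),
            "raw_to_cooked": 0.72 + 0.01 * (j % 4),
        }
    if _GROUP_STATE[group] == "dry_raw":
        # grains/legumes roughly double or triple in mass when cooked
        return {"dry_to_cooked": 2.2 + 0.1 * (commodity_index % 6)}
    return {}


def gen_supply_table(cfg: SyntheticConfig) -> str:
    """Balance-sheet-style supply CSV (all groups except dairy).

    Supplies are drawn so that *cooked-edible* within-group shares follow
    a symmetric Dirichlet(share_concentration); reported supply masses are
    backed out through each commodity's conversion chain.  Byte-identical
    under a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for country in _countries(cfg):
        for group in SYNTH_GROUPS:
            if group == "dairy":
                continue
            shares = rng.dirichlet(
                np.full(cfg.commodities_per_group, cfg.share_concentration)
            )
            total = _GROUP_MASS[group] * rng.lognormal(0.0, 0.2)
            for j, commodity in enumerate(_commodities(cfg, group)):
                cooked = shares[j] * total
                factors = _chain_factors(cfg, group, j)
                supply = cooked / float(np.prod(list(factors.values()))) if factors else cooked
                rows.append(
                    {
                        "country": country,
                        "commodity": commodity,
                        "group": group,
                        "supply_kg_per_capita_yr": f"{supply:.6f}",
                        "state": _GROUP_STATE[group],
                    }
                )
    return pd.DataFrame(rows).to_csv(index=False)


def gen_dairy_table(cfg: SyntheticConfig) -> str:
    """Dairy supply CSV in the same schema (separate source in real data)."""
    rng = np.random.default_rng(cfg.seed + 1)
    n = min(cfg.commodities_per_group, 4)  # real dairy data covers 4 products
    rows = []
    for country in _countries(cfg):
        shares = rng.dirichlet(np.full(n, cfg.share_concentration))
        total = _GROUP_MASS["dairy"] * rng.lognormal(0.0, 0.2)
        for j in range(n):
            rows.append(
                {
                    "country": country,
                    "commodity": f"dairy_c{j + 1:02d}",
                    "group": "dairy",
                    "supply_kg_per_capita_yr": f"{shares[j] * total:.6f}",
                    "state": "as_is",
                }
            )
    return pd.DataFrame(rows).to_csv(index=False)


def gen_impact_table(cfg: SyntheticConfig, withhold: Sequence[str] = ()) -> str:
    """Emission-intensity CSV; ``withhold`` drops named commodities to
    exercise the missing-impact-factor exclusion path."""
    rng = np.random.default_rng(cfg.seed + 2)
    withheld = set(withhold)
    rows = []
    commodities: list[str] = []
    for group in SYNTH_GROUPS:
        if group == "dairy":
            commodities.extend(f"dairy_c{j + 1:02d}"
                               for j in range(min(cfg.commodities_per_group, 4)))
        else:
            commodities.extend(_commodities(cfg, group))
    commodities.append(SUGAR_COMMODITY)
    for commodity in commodities:
        intensity = float(rng.lognormal(cfg.intensity_log_mean, cfg.intensity_log_sd))
        if commodity in withheld:
            continue
        rows.append(
            {
                "commodity": commodity,
                "kg_co2e_per_kg": f"{intensity:.6f}",
                "source_note": "synthetic",
            }
        )
    return pd.DataFrame(rows).to_csv(index=False)


def gen_conversion_table(cfg: SyntheticConfig) -> str:
    """Conversion-factor CSV matching the chains used by the supply table."""
    rows = []
    for group in SYNTH_GROUPS:
        for j, commodity in enumerate(_commodities(cfg, group)):
            for step, factor in _chain_factors(cfg, group, j).items():
                rows.append(
                    {
                        "commodity": commodity,
                        "step": step,
                        "factor": f"{factor:.6f}",
                        "direction": "gain" if factor >= 1 else "loss",
                    }
                )
    return pd.DataFrame(rows).to_csv(index=False)


def gen_composition_table(cfg: SyntheticConfig) -> str:
    """Composition CSV (kcal per cup / per 100 g) for cup-unit guidelines."""
    rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    for group in SYNTH_GROUPS:
        names = (_commodities(cfg, group) if group != "dairy"
                 else [f"dairy_c{j + 1:02d}"
                       for j in range(min(cfg.commodities_per_group, 4))])
        for commodity in names:
            kcal_100g = float(rng.uniform(30, 400))
            grams_per_cup = float(rng.uniform(100, 250))
            rows.append(
                {
                    "commodity": commodity,
                    "kcal_per_cup": f"{kcal_100g * grams_per_cup / 100.0:.6f}",
                    "kcal_per_100g": f"{kcal_100g:.6f}",
                }
            )
    return pd.DataFrame(rows).to_csv(index=False)


def gen_guidelines(cfg: SyntheticConfig) -> list[GuidelineSet]:
    """One synthetic 2000-kcal guideline per country (dairy in ml, rest g)."""
    rng = np.random.default_rng(cfg.seed + 4)
    out = []
    for country in _countries(cfg):
        recs = []
        for group in SYNTH_GROUPS:
            lo, hi = _REC_RANGE[group]
            amount = float(np.round(rng.uniform(lo, hi), 1))
            unit = "ml" if group == "dairy" else "g"
            recs.append(GroupRecommendation(group=group, amount=amount, unit=unit))
        discretionary = float(rng.choice([0.0, 270.0, 300.0]))
        out.append(
            GuidelineSet(
                country=country,
                diet_kcal=2000.0,
                recommendations=tuple(recs),
                discretionary_kcal=discretionary,
                notes="synthetic guideline",
            )
        )
    return out


def write_bundle(cfg: SyntheticConfig, outdir, withhold: Sequence[str] = ()) -> dict[str, Path]:
    """Emit a complete synthetic study bundle into ``outdir``.

    Files: supply.csv, dairy.csv, impacts.csv, conversions.csv,
    composition.csv and guidelines/<country>.yaml — the exact schemas the
    pipeline readers consume.
    """
    from .guidelines import save_guideline

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "supply": outdir / "supply.csv",
        "dairy": outdir / "dairy.csv",
        "impacts": outdir / "impacts.csv",
        "conversions": outdir / "conversions.csv",
        "composition": outdir / "composition.csv",
    }
    paths["supply"].write_text(gen_supply_table(cfg))
    paths["dairy"].write_text(gen_dairy_table(cfg))
    paths["impacts"].write_text(gen_impact_table(cfg, withhold=withhold))
    paths["conversions"].write_text(gen_conversion_table(cfg))
    paths["composition"].write_text(gen_composition_table(cfg))
    gdir = outdir / "guidelines"
    gdir.mkdir(exist_ok=True)
    for gs in gen_guidelines(cfg):
        save_guideline(gs, gdir / f"{gs.country}.yaml")
    paths["guidelines"] = gdir
    return paths


# ---------------------------------------------------------------------------
# Published worked example: US daily fruit recommendation
# ---------------------------------------------------------------------------

#: commodity -> (consumption proportion, cup->kg factor, kg CO2-eq/kg,
#: printed contribution kg CO2-eq/d)
US_FRUIT_ROWS: dict[str, tuple[float, float, float, float]] = {
    "apples and products": (0.178, 0.110, 0.228, 0.009),
    "bananas": (0.113, 0.150, 0.374, 0.013),
    "citrus, other": (0.002, 0.185, 0.438, 0.000),
    "dates": (0.001, 0.075, 2.024, 0.000),
    "grapefruits and products": (0.017, 0.210, 1.210, 0.008),
    "grapes and products": (0.085, 0.120, 0.478, 0.010),
    "lemons, limes, & products": (0.091, 0.210, 0.517, 0.020),
    "oranges, tangerines, mandarins, & products": (0.231, 0.185, 0.347, 0.030),
    "pineapples and products": (0.061, 0.165, 0.914, 0.018),
    "fruits, other": (0.222, 0.196, 0.652, 0.057),
}

US_FRUIT_REC_CUPS = 2.0
US_FRUIT_TOTAL_PRINTED = 0.165


class Table2Fixture(NamedTuple):
    rec: GroupRecommendation
    pattern: ConsumptionPattern
    conversions: dict[str, CommodityConversion]
    impacts: ImpactFactorTable
    printed_contributions: dict[str, float]
    printed_total: float


def table2_fixture() -> Table2Fixture:
    """The published US fruit worked example, exactly as printed.

    Proportions are printed at 3 decimal places (they sum to 1.001; the
    published table rounds the sum to 1.000); the cup->kg factors already
    include any state adjustment, so ``cooked_to_raw`` is 1.
    """
    shares = {c: row[0] for c, row in US_FRUIT_ROWS.items()}
    pattern = ConsumptionPattern(country="United States", group="fruit", shares=shares)
    conversions = {
        c: CommodityConversion(commodity=c, unit_to_kg=row[1])
        for c, row in US_FRUIT_ROWS.items()
    }
    impacts = ImpactFactorTable(
        intensities={c: row[2] for c, row in US_FRUIT_ROWS.items()},
        notes={c: "published worked example" for c in US_FRUIT_ROWS},
    )
    rec = GroupRecommendation(group="fruit", amount=US_FRUIT_REC_CUPS, unit="cup")
    return Table2Fixture(
        rec=rec,
        pattern=pattern,
        conversions=conversions,
        impacts=impacts,
        printed_contributions={c: row[3] for c, row in US_FRUIT_ROWS.items()},
        printed_total=US_FRUIT_TOTAL_PRINTED,
    )


# ---------------------------------------------------------------------------
# Published per-group emission tables (reference outputs for regression
# tests of arithmetic identities; kg CO2-eq/d, printed at 2 dp)
# ---------------------------------------------------------------------------

_T3_COLS = ("protein_foods", "dairy", "grains", "fruit", "vegetables", "oils_fats")

#: baseline: each guideline under its own country's consumption pattern
TABLE3_PRINTED: dict[str, dict] = {
    "Germany":         {"per_group": dict(zip(_T3_COLS, (0.98, 0.81, 0.05, 0.12, 0.20, 0.09))), "total": 2.25},
    "India":           {"per_group": dict(zip(_T3_COLS, (0.03, 0.41, 0.11, 0.05, 0.17, 0.08))), "total": 0.86},
    "Oman":            {"per_group": dict(zip(_T3_COLS, (1.24, 0.17, 0.20, 0.39, 0.27, 0.26))), "total": 2.53},
    "The Netherlands": {"per_group": dict(zip(_T3_COLS, (1.12, 0.89, 0.08, 0.08, 0.12, 0.15))), "total": 2.86},
    "Thailand":        {"per_group": dict(zip(_T3_COLS[:5], (0.63, 0.33, 0.31, 0.47, 0.09))), "total": 1.83},
    "United States":   {"per_group": dict(zip(_T3_COLS, (1.84, 1.10, 0.02, 0.16, 0.16, 0.03))), "total": 3.83},
    "US Vegetarian":   {"per_group": dict(zip(_T3_COLS, (0.06, 1.10, 0.02, 0.16, 0.16, 0.03))), "total": 1.80},
    "Uruguay":         {"per_group": {"protein_foods": 1.50, "dairy": 0.65, "grains": 0.03,
                                      "fruit_and_vegetables": 0.18, "oils_fats": 0.04}, "total": 2.42},
    "EAT-Lancet":      {"per_group": dict(zip(_T3_COLS, (0.79, 0.30, 0.03, 0.08, 0.12, 0.05))), "total": 1.36},
}

#: controlled: every guideline under the US consumption pattern,
#: with the published reference-ratio column
TABLE4_PRINTED: dict[str, dict] = {
    "Germany":         {"per_group": dict(zip(_T3_COLS, (1.37, 0.81, 0.05, 0.12, 0.18, 0.05))), "total": 2.61, "ratio": 1.47},
    "India":           {"per_group": dict(zip(_T3_COLS, (0.02, 0.41, 0.05, 0.05, 0.18, 0.03))), "total": 0.74, "ratio": 5.19},
    "Oman":            {"per_group": dict(zip(_T3_COLS, (1.14, 0.18, 0.44, 0.29, 0.18, 0.05))), "total": 2.29, "ratio": 1.68},
    "The Netherlands": {"per_group": dict(zip(_T3_COLS, (1.51, 0.90, 0.08, 0.09, 0.11, 0.04))), "total": 3.22, "ratio": 1.19},
    "Thailand":        {"per_group": dict(zip(_T3_COLS[:5], (1.61, 0.37, 0.09, 0.47, 0.09))), "total": 2.63, "ratio": 1.46},
    "United States":   {"per_group": dict(zip(_T3_COLS, (1.84, 1.10, 0.02, 0.16, 0.16, 0.03))), "total": 3.83, "ratio": 1.00},
    "US Vegetarian":   {"per_group": dict(zip(_T3_COLS, (0.06, 1.10, 0.02, 0.16, 0.16, 0.03))), "total": 1.80, "ratio": 2.13},
    "Uruguay":         {"per_group": {"protein_foods": 1.24, "dairy": 0.70, "grains": 0.03,
                                      "fruit_and_vegetables": 0.19, "oils_fats": 0.02}, "total": 2.22, "ratio": 1.73},
    "EAT-Lancet":      {"per_group": dict(zip(_T3_COLS, (0.79, 0.30, 0.03, 0.08, 0.12, 0.05))), "total": 1.36, "ratio": 2.82},
}

#: discretionary-calorie allowances (kcal/d of a 2000-kcal diet) behind the
#: grossed-up totals above
DISCRETIONARY_KCAL = {"The Netherlands": 308.0, "United States": 270.0,
                      "US Vegetarian": 290.0}
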