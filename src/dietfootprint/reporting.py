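"""Run configuration and end-to-end pipeline orchestration.

Glues the stages together for a batch run: load guideline configs, scale
them to the target energy level, derive each country's within-group
consumption patterns from the supply tables, evaluate footprints, and emit
result tables as CSV.  The command-line interface in
:mod:`dietfootprint.cli` is a thin wrapper over these functions.

Outputs are deterministic: row order follows input config order, column
order is fixed, and float formatting is explicit, so re-running with
identical inputs yields byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .conversions import CompositionTable
from .errors import ValidationError
from .footprint import (
    DietFootprint,
    ImpactFactorTable,
    controlled_comparison,
    diet_footprint,
    footprint_table,
    per_commodity_frame,
)
from .guidelines import GuidelineSet, load_guidelines, scale_guidelines
from .patterns import (
    CommoditySupplyRecord,
    ConversionFactorSet,
    patterns_for_country,
    read_supply_csv,
    to_cooked_edible,
)

logger = logging.getLogger("dietfootprint")

#: float format for long-format (full-precision) CSV outputs
_FLOAT_FMT = "%.9f"


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run."""

    guideline_paths: Sequence = ()
    supply_path: Optional[str] = None
    dairy_path: Optional[str] = None
    impacts_path: Optional[str] = None
    conversions_path: Optional[str] = None
    composition_path: Optional[str] = None
    out_dir: Optional[str] = None
    target_kcal: float = 2000.0
    reference_country: str = "United States"
    decimals: int = 2

    def __post_init__(self):
        if self.target_kcal <= 0:
            raise ValidationError(
                f"target_kcal must be positive, got {self.target_kcal}"
            )


@dataclass
class LoadedInputs:
    guidelines: list[GuidelineSet]
    records: list[CommoditySupplyRecord]
    conv: ConversionFactorSet
    impacts: ImpactFactorTable
    comp: Optional[CompositionTable]


def load_inputs(cfg: RunConfig) -> LoadedInputs:
    """Read and validate every input file named by the config."""
    guidelines = [
        scale_guidelines(gs, cfg.target_kcal)
        for gs in load_guidelines(cfg.guideline_paths)
    ]
    records: list[CommoditySupplyRecord] = []
    if cfg.supply_path:
        records.extend(read_supply_csv(cfg.supply_path))
    if cfg.dairy_path:
        records.extend(read_supply_csv(cfg.dairy_path))
    conv = (ConversionFactorSet.from_csv(cfg.conversions_path)
            if cfg.conversions_path else ConversionFactorSet())
    if not cfg.impacts_path:
        raise ValidationError("an impact-factor CSV is required")
    impacts = ImpactFactorTable.from_csv(cfg.impacts_path)
    comp = (CompositionTable.from_csv(cfg.composition_path)
            if cfg.composition_path else None)
    return LoadedInputs(guidelines, records, conv, impacts, comp)


def _log_exclusions(inputs: LoadedInputs) -> None:
    """Audit log: every supply commodity without an impact factor, with the
    share of its country-group cooked-edible mass it represents."""
    by_cg: dict[tuple[str, str], float] = {}
    for r in inputs.records:
        by_cg[(r.country, r.group)] = by_cg.get((r.country, r.group), 0.0) + \
            to_cooked_edible(r, inputs.conv)
    for r in inputs.records:
        if r.commodity not in inputs.impacts:
            total = by_cg[(r.country, r.group)]
            share = to_cooked_edible(r, inputs.conv) / total if total > 0 else 0.0
            logger.info(
                "excluded %s/%s/%s: no impact factor (%.1f%% of group supply)",
                r.country, r.group, r.commodity, 100 * share,
            )


def _needed_groups(gs: GuidelineSet) -> list[str]:
    return [r.group for r in gs.recommendations if r.group != "sugar"]


def run_baseline(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, list[DietFootprint]]:
    """Evaluate every guideline under its own country's consumption pattern.

    Returns the per-country summary table (one row per guideline, one
    column per group plus sugar and total), the long-format per-commodity
    breakdown, and the underlying footprint objects.  Writes
    ``baseline.csv`` and ``baseline_per_commodity.csv`` when the config
    names an output directory.
    """
    inputs = load_inputs(cfg)
    if not inputs.guidelines:
        logger.warning("no guideline configs given; emitting empty table")
        empty = pd.DataFrame(columns=["country", "total"])
        _write(cfg, baseline=empty,
               baseline_per_commodity=per_commodity_frame([]))
        return empty, per_commodity_frame([]), []
    _log_exclusions(inputs)
    cooked_to_raw = inputs.conv.cooked_to_raw_factors()
    footprints = []
    for gs in inputs.guidelines:
        patterns = patterns_for_country(
            inputs.records, inputs.conv, inputs.impacts, gs.country,
            _needed_groups(gs),
        )
        fp = diet_footprint(gs, patterns, cooked_to_raw, inputs.impacts, inputs.comp)
        logger.info("%s: total %.2f kg CO2-eq/d", gs.country, fp.total)
        footprints.append(fp)
    table = footprint_table(footprints, decimals=cfg.decimals)
    breakdown = per_commodity_frame(footprints)
    _write(cfg, baseline=table, baseline_per_commodity=breakdown)
    return table, breakdown, footprints


def run_controlled(cfg: RunConfig) -> pd.DataFrame:
    """Evaluate every guideline under the reference country's pattern.

    The reference country's own row is identical to its baseline row; the
    ratio column divides the reference total by each row's total (computed
    at full precision, rounded for display).  Writes ``controlled.csv``.
    """
    inputs = load_inputs(cfg)
    if not inputs.guidelines:
        logger.warning("no guideline configs given; emitting empty table")
        empty = pd.DataFrame(columns=["country", "total", "reference_ratio"])
        _write(cfg, controlled=empty)
        return empty
    countries = {gs.country for gs in inputs.guidelines}
    if cfg.reference_country not in countries and not any(
        r.country == cfg.reference_country for r in inputs.records
    ):
        raise ValidationError(
            f"reference country {cfg.reference_country!r} has no supply data"
        )
    groups = sorted({g for gs in inputs.guidelines for g in _needed_groups(gs)})
    reference_patterns = patterns_for_country(
        inputs.records, inputs.conv, inputs.impacts, cfg.reference_country, groups,
    )
    table = controlled_comparison(
        inputs.guidelines,
        reference_patterns,
        inputs.conv.cooked_to_raw_factors(),
        inputs.impacts,
        inputs.comp,
        reference_country=cfg.reference_country,
        decimals=cfg.decimals,
    )
    _write(cfg, controlled=table)
    return table


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Schema-check all named inputs; returns human-readable problems."""
    problems = []
    try:
        inputs = load_inputs(cfg)
    except (ValidationError, FileNotFoundError) as exc:
        return [str(exc)]
    for gs in inputs.guidelines:
        for rec in gs.recommendations:
            if rec.unit == "serving":
                problems.append(
                    f"{gs.country}/{rec.group}: unresolved 'serving' unit"
                )
    return problems


def _write(cfg: RunConfig, **tables: pd.DataFrame) -> None:
    if not cfg.out_dir:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        path = out / f"{name}.csv"
        fmt = _FLOAT_FMT if name.endswith("per_commodity") else None
        df.to_csv(path, index=False, float_format=fmt)
        logger.info("wrote %s", path)
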