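"""National-inventory arithmetic for emission-reduction scenarios.

Applies a uniform reduction factor (default 60%, the conservative field
estimate for the N2O-respiring inoculant) to selected fertilizer/manure
categories of a country emission-inventory table and reports the resulting
percentage decreases of category, agricultural and total anthropogenic N2O
emissions. The inventory is any long-form CSV/DataFrame with columns
``region, total_kt, agric_kt, category, emission_kt``; no country values
are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["Scenario", "CATEGORIES", "validate_inventory", "apply_scenario",
           "scenario_report"]

CATEGORIES = (
    "liquid_manure_applied",
    "solid_manure_applied",
    "mineral_fertilizer",
    "plant_residues",
    "other",
)

INVENTORY_COLUMNS = ["region", "total_kt", "agric_kt", "category", "emission_kt"]


@dataclass
class Scenario:
    reduction_factor: float = 0.6
    target_categories: tuple = ("liquid_manure_applied",)

    def __post_init__(self) -> None:
        if not 0.0 <= self.reduction_factor <= 1.0:
            raise ValueError("reduction_factor must be in [0, 1]")
        unknown = set(self.target_categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(
                f"unknown categories {sorted(unknown)}; valid: {list(CATEGORIES)}")


def validate_inventory(inv: pd.DataFrame) -> pd.DataFrame:
    missing = set(INVENTORY_COLUMNS) - set(inv.columns)
    if missing:
        raise ValueError(f"inventory missing columns {sorted(missing)}")
    unknown = set(inv["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(
            f"unknown categories {sorted(unknown)}; valid: {list(CATEGORIES)}")
    if (inv["emission_kt"] < 0).any() or (inv["total_kt"] < 0).any():
        raise ValueError("emissions must be >= 0")
    sums = inv.groupby("region")["emission_kt"].sum()
    totals = inv.groupby("region")["total_kt"].first()
    bad = sums[sums > totals * (1 + 1e-9)]
    if len(bad):
        raise ValueError(f"category emissions exceed totals for {list(bad.index)}")
    return inv


def apply_scenario(inv: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Per-region reduced inventory with percentage decreases.

    Targeted categories are multiplied by (1 - factor); all other emissions
    are left unchanged. Returns one row per region with the absolute
    reduction (kt N2O-N yr-1) and the relative decrease of total
    anthropogenic and of agricultural emissions.
    """
    inv = validate_inventory(inv)
    out_cols = ["region", "total_kt", "agric_kt", "reduction_kt", "new_total_kt",
                "new_agric_kt", "total_decrease_pct", "agric_decrease_pct"]
    if len(inv) == 0:
        return pd.DataFrame(columns=out_cols)
    missing = set(scenario.target_categories) - set(inv["category"])
    if missing:
        raise ValueError(
            f"target categories {sorted(missing)} absent from inventory; "
            f"present: {sorted(set(inv['category']))}")
    rows = []
    for region, grp in inv.groupby("region", sort=True):
        total = float(grp["total_kt"].iloc[0])
        agric = float(grp["agric_kt"].iloc[0])
        targeted = grp[grp["category"].isin(scenario.target_categories)]
        reduction = float(targeted["emission_kt"].sum()) * scenario.reduction_factor
        rows.append({
            "region": region,
            "total_kt": total,
            "agric_kt": agric,
            "reduction_kt": reduction,
            "new_total_kt": total - reduction,
            "new_agric_kt": agric - reduction,
            "total_decrease_pct": reduction / total * 100.0 if total else 0.0,
            "agric_decrease_pct": reduction / agric * 100.0 if agric else 0.0,
        })
    return pd.DataFrame(rows, columns=out_cols)


def scenario_report(results: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Deterministically ordered, fixed-precision report table."""
    cols = ["region", "total_kt", "reduction_kt", "new_total_kt",
            "total_decrease_pct", "agric_decrease_pct"]
    out = results.loc[:, cols].sort_values("region", kind="stable")
    for c in cols[1:]:
        out[c] = out[c].astype(float).round(decimals)
    return out.reset_index(drop=True)
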