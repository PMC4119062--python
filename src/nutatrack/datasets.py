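"""Packaged reference datasets.

Two small tables from a published time-lapse study of *Helianthus annuus*
(sunflower) seedling circumnutation, recorded top-view at one frame per
five minutes over 63 hours:

* a per-cycle parameter table for one regularly circumnutating seedling
  ("seedling 14", grown in nutrient solution) — 21 cycles with timestamps
  and all six parameters;
* a per-seedling summary table for sixteen seedlings, eight grown in
  distilled water and eight in nutrient solution, with hypocotyl lengths
  and mean cycle parameters.

The raw coordinate recordings behind these tables were never published;
the tables themselves serve as fixed inputs for consistency checks and as
worked-example data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_io import CycleMetrics, read_cycle_table
from .summary_stats import PlantSummary

_DATA = resources.files(__package__) / "data"


def seedling14_cycles() -> list[CycleMetrics]:
    """The 21-cycle parameter table of the regular example seedling."""
    with resources.as_file(_DATA / "helianthus_seedling14_cycles.csv") as p:
        return read_cycle_table(p)


def seedling_summaries() -> pd.DataFrame:
    """Per-seedling summary rows for both growth conditions.

    Columns: seedling, group (``distilled_water`` / ``nutrient_solution``),
    hypocotyl_length_mm, period_min, length_mm, rate_mm_per_min, shape,
    angle_deg, cw_pct, ccw_pct, ind_pct.
    """
    with resources.as_file(_DATA / "helianthus_seedling_summaries.csv") as p:
        return pd.read_csv(p)


def seedling_summaries_as_plants(group: str) -> list[PlantSummary]:
    """One group's rows as :class:`PlantSummary` objects (n_cycles unknown,
    recorded as 0)."""
    df = seedling_summaries()
    sel = df[df["group"] == group]
    if sel.empty:
        raise ValueError(f"unknown group {group!r}")
    out = []
    for row in sel.itertuples(index=False):
        out.append(
            PlantSummary(
                plant_id=str(row.seedling),
                n_cycles=0,
                mean_period_min=float(row.period_min),
                mean_length_mm=float(row.length_mm),
                mean_rate_mm_per_min=float(row.rate_mm_per_min),
                mean_shape=float(row.shape),
                mean_angle_deg=float(row.angle_deg),
                cw_pct=float(row.cw_pct),
                ccw_pct=float(row.ccw_pct),
                ind_pct=float(row.ind_pct),
                hypocotyl_length_mm=float(row.hypocotyl_length_mm),
            )
        )
    return out


__all__ = [
    "seedling14_cycles",
    "seedling_summaries",
    "seedling_summaries_as_plants",
]
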