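"""Summary statistics on the packaged sunflower reference tables.

Loads the 21-cycle parameter table of one regularly circumnutating
Helianthus annuus seedling and the per-seedling summary table of sixteen
seedlings (eight grown in distilled water, eight in nutrient solution),
then reproduces the per-plant means, group mean +- SE and the
between-group t-tests.
"""

from nutatrack import group_summary, plant_summary, two_sample_ttest
from nutatrack.datasets import (
    seedling14_cycles,
    seedling_summaries,
    seedling_summaries_as_plants,
)
from nutatrack.util import round_half_up

cycles = seedling14_cycles()
s = plant_summary(cycles, "14")
print(f"seedling 14: {s.n_cycles} cycles")
print(f"  mean period {round_half_up(s.mean_period_min):.0f} min")
print(f"  mean length {round_half_up(s.mean_length_mm):.0f} mm")
print(f"  mean rate   {round_half_up(s.mean_rate_mm_per_min, 2):.2f} mm/min")
print(f"  mean shape  {round_half_up(s.mean_shape, 2):.2f}")
print(f"  mean angle  {round_half_up(s.mean_angle_deg):.0f} deg")
print(f"  directions  cw {s.cw_pct:.0f}%  ccw {s.ccw_pct:.0f}%  ? {s.ind_pct:.0f}%")

for group in ("distilled_water", "nutrient_solution"):
    plants = seedling_summaries_as_plants(group)
    g = group_summary(plants)
    print(f"\n{group} (n={g.n_plants}):")
    print(
        f"  period {round_half_up(g.mean['period_min']):.0f}"
        f" +- {round_half_up(g.se['period_min']):.0f} min"
    )
    print(
        f"  rate   {round_half_up(g.mean['rate_mm_per_min'], 2):.2f}"
        f" +- {round_half_up(g.se['rate_mm_per_min'], 2):.2f} mm/min"
    )
    print(
        f"  hypocotyl {round_half_up(g.mean['hypocotyl_length_mm']):.0f}"
        f" +- {round_half_up(g.se['hypocotyl_length_mm']):.0f} mm"
    )

df = seedling_summaries()
water = df[df.group == "distilled_water"]
nutrient = df[df.group == "nutrient_solution"]
for column, label in (
    ("hypocotyl_length_mm", "hypocotyl length"),
    ("period_min", "period"),
    ("length_mm", "cycle length"),
):
    t, p, tier = two_sample_ttest(water[column], nutrient[column])
    print(f"\nt-test, {label}: t = {t:.2f}, p = {p:.2e}  ({tier})")
print(
    "\nShorter hypocotyls but longer periods in distilled water - the\n"
    "nutrient contrast the summary statistics are built to expose."
)
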