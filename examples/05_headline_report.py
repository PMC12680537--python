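"""Recompute the headline comparisons from the bundled fixture values.

Everything printed here is derived at run time from fixture inputs via
the accounting/energetics operations: group totals with conservative
uncertainty ranges, the marine decline and human growth, composition
shares and the case-study products.
"""

import json

from biomove.fixtures import load_fixtures
from biomove.report import run_report

doc = run_report(load_fixtures())

land = doc["sections"]["land_groups"]
total = land["terrestrial_wildlife_total"]
print(f"terrestrial wildlife: {total['mean']:.0f} Gt km/yr "
      f"(range {total['low']:.0f}-{total['high']:.0f}, bound {total['upper_bound']:.0f})")
print(f"wild mammal weighted daily distance: "
      f"{land['wild_mammal_weighted_daily_distance']['km_per_day']:.1f} km/d")

r = doc["sections"]["ratios"]
print(f"human biomass: {r['human_biomass_gt']:.3f} Gt; "
      f"humans / terrestrial wildlife = {r['human_to_terrestrial_wildlife']:.0f}x; "
      f"walking share {r['walking_share_percent']:.0f}%")

c = doc["sections"]["change"]
print(f"marine decline since 1850: {c['marine_decline_percent']:.1f}%; "
      f"human growth: {c['human_fold_change']:.0f}-fold")
print("marine composition (%):", json.dumps(c["marine_composition_percent"]))

cases = doc["sections"]["case_studies"]
print(f"arctic terns: {cases['arctic_terns']['movement_t_km_yr']:.2g} t km/yr; "
      f"humpbacks: {cases['humpback_whales']['movement_gt_km_yr']:.0f} Gt km/yr; "
      f"prokaryote bound: {cases['bacteria_upper_bound_gt_km_yr']:.0f} Gt km/yr")
print("Each number above is a product, ratio or share of fixture inputs — "
      "the report never copies a derived value.")
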