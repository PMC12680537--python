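"""Locomotion energy of animal groups and humans via cost of transport.

Builds the headline energy table from the bundled fixture movements and
group-average COTs: energy [TWh/yr] = movement [Gt km/yr] x COT / 3.6.
"""

from biomove import energetics as en
from biomove.fixtures import load_fixtures
from biomove.report import TABLE1_ROWS

fx = load_fixtures()
rows = [(label, fx.value(name), fx.get(name).cot, fx.get(name).analogue)
        for label, name in TABLE1_ROWS]
table = en.build_energy_table(rows)

print(f"{'group':32s} {'Gt km/yr':>9s} {'COT':>5s} {'TWh/yr':>10s} {'GW':>8s}")
for r in table:
    print(f"{r.group:32s} {r.movement_gt_km_yr:9,.0f} {r.cot_avg:5.1f} "
          f"{r.energy_twh_yr:10,.0f} {r.power_gw:8,.1f}")

walker = en.cot(70.0, en.DEFAULT_COT_REGISTRY["walk_run"])
print(f"\n70-kg walker: {walker:.2f} J/kg/m "
      f"= {en.cot_to_kcal_per_kg_km(walker):.2f} kcal/kg/km")
print("A group's COT is a movement-weighted average, so efficient large "
      "animals dominate; powers are the energies spread over the year.")
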