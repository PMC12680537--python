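"""Estimate annual travel distance from simulated GPS tracks.

Simulates a migratory population (great-circle legs plus a foraging
random walk), measures each individual's path length from hourly fixes,
and bootstraps a species-level annual distance.
"""

from biomove import trajectory as traj
from biomove.synthetic import TrackSimConfig, gen_tracks

bundle = gen_tracks(seed=7, config=TrackSimConfig(n_individuals=10))

for track in bundle.data[:3]:
    s = traj.path_length(track)
    truth = bundle.truth["per_individual"][track.individual_id]["integrated_km"]
    print(f"{track.individual_id}: path {s.path_km:,.0f} km over "
          f"{s.covered_days:.1f} d (true {truth:,.0f} km, "
          f"coverage {s.coverage_fraction:.0%})")

species = traj.species_annual_distance(bundle.data, seed=7)
print(f"\nspecies annual distance: {species.mean:,.0f} km/yr "
      f"(bootstrap 95% CI {species.low:,.0f}-{species.high:,.0f})")
print(f"generator truth:        {bundle.truth['mean_annual_km']:,.0f} km/yr")
print("Hourly fixes recover the integrated path within a fraction of a "
      "percent; coarser sampling always underestimates (chords cut corners).")
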