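"""Code fixes to locations, detect dwell-time stops, and encode trips.

A stop is 120 s or more at one coded location; a trip is the travel
between two stops, written as origin letter (uppercase) + destination
letter (lowercase): Home->School is 'Ab', School->Shops is 'Bd'.
"""

import numpy as np

from tracklink import assign_locations, build_sequences, detect_stops, extract_trips
from tracklink.synth import make_map, make_schedule, simulate_track

world = make_map(["c01"], seed=5)
rng = np.random.default_rng(5)
schedule = make_schedule(world, "c01", days=1, start_date="2011-03-14", rng=rng, p_offroad=0.0)
fixes, _ = simulate_track(schedule, world, rng, noise_sd_m=0.0, dropout=0.0, artifact_rate=0.0)

coded = assign_locations(fixes, world.landuse, world.places)
stops = detect_stops(coded)
trips = extract_trips(stops, coded)
sequences = build_sequences(trips)

print("stops (location, minutes):")
for s in stops:
    print(f"  {s.location_code}  {s.duration_s / 60:5.1f} min")
print()
print("trips:")
for t in trips:
    print(f"  {t.code}: {t.origin} -> {t.destination}, "
          f"{t.on_road_fraction:.0%} of fixes on roads")
print()
for seq in sequences:
    print(f"day code string: {seq.code_string!r}")
print("That string is one side of the sequence alignment; the diary gives the other.")
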