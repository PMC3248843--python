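"""Simulate a small ground-truthed cohort and look at what it contains.

A cohort is a synthetic neighbourhood (land-use grid plus per-child home
and school parcels), a week of scheduled activity per child, a 10-second
GPS fix stream for each child, the implied true trip list, and a travel
diary that is a deliberately degraded copy of the truth.
"""

from tracklink import simulate_cohort

cohort = simulate_cohort(n_children=4, days=7, seed=7)

print(f"map polygons:      {len(cohort.world.landuse)}")
print(f"GPS fixes:         {len(cohort.fixes):,}")
print(f"true trips:        {len(cohort.true_trips)}")
print(f"diary trips:       {len(cohort.diary)} (after omissions/collapses)")
print(f"injected defects:  {len(cohort.defect_ledger)}")
print()
pid = "c01"
day = cohort.diary.query("participant_id == @pid").iloc[:5]
print(f"first diary rows for {pid} (origin -> destination, mode, accompaniment):")
for r in day.itertuples(index=False):
    print(f"  {r.date} #{r.seq_index}: {r.origin} -> {r.destination}  ({r.mode or '?'}, {r.accompaniment or '?'})")
print()
print("The gap between true and diary trip counts is the under-reporting")
print("the sequence-alignment linkage method has to survive.")
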