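"""Align a day of GPS trips against a day of diary trips.

The aligner is Needleman-Wunsch global alignment over two-letter trip
codes, extended with a 2:1 chain step: two consecutive GPS trips X->Y,
Y->Z may jointly match a single diary trip X->Z, because diaries often
report a chained journey as one trip.
"""

from tracklink import align

# The child went School -> Shops -> Home; the diary says School -> Home.
result = align(["Bd", "Da"], ["Ba"])
print("GPS ['Bd', 'Da'] vs diary ['Ba']:")
for p in result.pairs:
    print(f"  step={p.step}  class={p.match_class}  gps={p.gps_indices}  diary={p.diary_index}")
print(f"  counts: {result.counts}")
print()

# A richer day with a duplicate trip: order decides which copy matches.
gps = ["Ac", "Ca", "Ab", "Ba", "Ac"]
diary = ["Ab", "Ba", "Ac"]
result = align(gps, diary)
print(f"GPS {gps} vs diary {diary} (score {result.score}):")
for p in result.pairs:
    g = ",".join(gps[i] for i in p.gps_indices) or "-"
    d = diary[p.diary_index] if p.diary_index is not None else "-"
    print(f"  {g:>6} ~ {d:<3} {p.match_class}")
print()
print("The diary's final 'Ac' pairs with the *second* GPS 'Ac' because the")
print("alignment respects the order of trips, not their clock times.")
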