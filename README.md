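# tracklink

Link GPS tracks to travel diaries by global alignment of trip-code
sequences.

## The problem

Health-geography and mobility studies increasingly pair body-worn GPS
units with self-reported travel diaries: the GPS says *where* a
participant went, the diary says *why*, *how* (mode) and *with whom*
(accompaniment). Joining the two records is hard because diary clock
times are unreliable — participants misremember times and their watches
disagree with the GPS clock — so timestamp joins fail, and matching by
hand in a desktop GIS does not scale beyond a few participants.

`tracklink` implements a partially automated alternative: reduce each
day of each participant's GPS record *and* diary to an ordered sequence
of trips, encode every trip by its origin and destination land-use
categories, and link the two sequences by **global sequence alignment**,
relying on the *order* of trips rather than their reported times. It was
built with child independent-mobility cohorts in mind (week-long
deployments, 10 s logging epochs, diaries kept by 9–11-year-olds) but
nothing in it is specific to children.

## The method

1. **Clean** the fix stream: drop fixes with speed > 160 km/h, HDOP > 5,
   or fewer than 4 visible satellites (strict inequalities; boundary
   values survive).
2. **Code locations**: point-in-polygon against a land-use map whose
   categories carry single letters — Home **A**, School **B**,
   Residential **C**, Shops **D**, Open space **E**, Sports **F**,
   Church **G**, Medical **H**, Other schools **I**, Other **K** (J is
   skipped), plus a `ROAD` pseudo-code for the street network. Each
   participant's own home and school parcels override the base map.
3. **Detect trips**: a *stop* is ≥ 120 s dwell at one coded location; a
   *trip* is the travel between consecutive stops, encoded as uppercase
   origin + lowercase destination (`Ab` = Home→School, `Bd` =
   School→Shops). A day becomes a code string such as `"AbBdDa"`.
4. **Align** the GPS day against the diary day with Needleman–Wunsch.
   With GPS prefix *i* and diary prefix *j*:

   ```
   S(i,j) = max( S(i-1,j-1) + s(g_i, d_j),          # 1:1 pairing
                 S(i-2,j-1) + chain,  if admissible  # 2 GPS : 1 diary
                 S(i-1,j)   + gap,                   # GPS trip unmatched
                 S(i,j-1)   + gap )                  # diary trip unmatched
   ```

   `s` scores a **full** match (+2, both letters agree), **partial**
   (+1, exactly one agrees) or mismatch (−1); `gap` = −1; the **chain**
   step (+2) is admissible when consecutive GPS trips X→Y, Y→Z bracket a
   single diary trip X→Z — diaries habitually collapse chained journeys
   into one entry — and classifies all three trips as partial.
5. **Transfer** mode and accompaniment from each matched diary trip onto
   the matched GPS trip(s) and their fixes, then tabulate full / partial
   / unmatched rates (as percentages of all diary trips) by diary
   quality, with Pearson chi-squared tests of independence.

Diary **quality** is scored mechanically per participant: missing-data
rows + researcher-entered rows + sequence inconsistencies (a trip that
does not start where the previous one ended); scores > 4 classify the
participant's diaries as *lower* quality.

Because real cohort data of this kind cannot be redistributed, the
package ships a first-class **synthetic cohort generator**: a planar
grid neighbourhood, child activity schedules, noisy 10 s GPS tracks with
injected quality artifacts, and diaries degraded by trip omission, chain
collapse, field blanking and researcher flags — every defect recorded in
a truth ledger so each pipeline stage is testable against ground truth.

## A worked example

```python
from tracklink import align

result = align(["Bd", "Da"], ["Ba"])   # GPS: School->Shops, Shops->Home
for p in result.pairs:                 # diary: School->Home
    print(p.step, p.match_class, p.gps_indices, p.diary_index)
print(result.counts)
```

prints

```
chain partial (0, 1) 0
{'full': 0, 'partial': 1, 'unmatched_diary': 0, 'unmatched_gps': 0, 'n_gps': 2, 'n_diary': 1}
```

— the two GPS trips are jointly matched to the single diary trip as a
2:1 chain step: one partially matched diary trip, nothing unmatched.
The `examples/` directory has one short script per capability
(simulation, cleaning, trip detection, alignment, full pipeline); each
prints the numbers it computes and what they mean. The same pipeline is
scriptable from the shell:

```
tracklink simulate --seed 7 --children 40 --days 7 --out sim/
tracklink run --config config.yaml --out out/
```

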