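# Methods

This note records the models, parameter choices and numerical decisions
behind `tracklink`, and what the synthetic-data experiments do and do
not demonstrate.

## Linkage model

The package treats GPS–diary linkage as alignment of two categorical
sequences per participant-day. The premise is that diary *times* are
unreliable but diary *order* is mostly right, so the only trustworthy
shared structure between the two records is the ordered list of trips,
each reduced to an (origin category, destination category) pair. All
matching therefore happens on two-letter trip codes; reported clock
times are parsed and stored but never used.

### Trip codes and the location taxonomy

Ten land-use categories carry the letters A–I and K (J is skipped to
avoid confusion with I in hand-written diaries): Home, School,
Residential, Shops, Open space, Sports facilities, Church, Medical,
Other schools, Other. "Home" and "School" are *relative* categories: a
fix is A or B only inside the participant's own home or school parcel,
which override the base map; another child's home codes as Residential
and a school the participant does not attend as Other schools. Fixes on
the street network carry the pseudo-code `ROAD`, which drives trip
detection but can never be a trip endpoint.

Overlap precedence in coding is: own home > own school > non-road
land-use polygons (smallest area first) > road > K, applied
deterministically; boundary fixes count as inside (geometric `covers`
semantics). The precedence rule matters only for maps with overlapping
polygons; the synthetic map is a partition, so every fix has a unique
answer there.

### Cleaning

Three filters with strict comparisons: speed > 160 km/h, HDOP > 5,
< 4 visible satellites. Boundary values (exactly 160, 5, 4) pass. A fix
*missing* a quality field is retained by that filter — the filters act
only on positive evidence — with a `strict_missing` switch to invert
that for devices whose missing fields indicate failure. Duplicate
(participant, timestamp) records keep the first occurrence. No
smoothing, map-matching or drift correction is attempted.

### Stop/trip segmentation

* **Dwell threshold** 120 s (the conventional choice in trip-detection
  work): a maximal run of consecutive fixes sharing one non-ROAD code
  lasting ≥ 120 s is a stop. At the 10 s epoch that is 13 fixes.
* **Gap tolerance** 300 s (package default; chosen because indoor signal
  dropout is ubiquitous in child GPS data): a same-location signal gap
  up to this long is bridged into one stop; a longer gap splits the run.
* A trip spans consecutive stops; it departs when the first stop ends
  and arrives when the second begins. Its `on_road_fraction` is the
  share of intermediate fixes coded ROAD; trips below
  `min_on_road_fraction` (default 0.5) are flagged `off_road` and
  excluded from alignment sequences (they stay in the trips table),
  reflecting the method's known blind spot for off-road travel. A trip
  between two stops with *no* intermediate fixes gets fraction 0.0 and
  the flag.
* Same-location stop pairs (Home→Home play, say) become trips only when
  at least one intermediate fix left the stop's polygon; they are
  included in sequences by default and can be switched off. This
  reconciles a strict "different locations" trip definition with the
  observable reality of children's looping play near home.
* Sequences are per civil date; an episode spanning midnight belongs to
  the date of its departure.

### Scoring scheme

Published descriptions of this matching approach define full/partial
match semantics but not numeric scores, so the defaults here are the
package's own: full +2, partial +1, mismatch −1, gap −1, chain step +2
total. The constraints that matter (enforced at construction):

* full > partial > mismatch — match quality is ordered;
* gap < partial — explaining a diary trip beats deleting it;
* chain > 2·gap — a chain step beats gapping both GPS trips away; with
  the defaults it also beats partial+gap (0) and any decomposition.

All five values are configurable for sensitivity runs. A chain step is
admissible only when the GPS pair is an unbroken chain (destination of
the first = origin of the second) *and* both outer endpoints equal the
diary trip's endpoints; one-ended chain matches are not allowed. Only
2 GPS : 1 diary chains exist — the asymmetry mirrors the direction of
diary under-reporting — and chains of three or more links are out of
scope.

The traceback is deterministic: on score ties the step priority is 1:1
pairing > chain > gap in the diary sequence (GPS trip unmatched) > gap
in the GPS sequence (diary trip unmatched), preferring explanations
that account for diary trips.

A diagonal step can pair two trips sharing no letter (score −1 beats
the −2 of two gaps). Such a `mismatch` pair counts as one unmatched
diary trip *and* one unmatched GPS trip in all reporting, preserving
the accounting identity full + partial + unmatched = diary trips.

### Diary quality score

The qualitative notion "errors and inconsistencies per child" is
operationalised as three countable indicators, summed over a
participant's whole diary set:

1. rows with any blank field (origin, destination, mode or
   accompaniment);
2. rows flagged as researcher-entered;
3. within-day sequence breaks: destination of trip *t* ≠ origin of trip
   *t*+1 (pairs with a missing endpoint are skipped).

Scores > 4 classify as "lower" quality, ≤ 4 as "higher". Because the
original scoring was by inspection, absolute scores are not comparable
to any published per-child values; the threshold and the three rules
are configurable. Note the rule cannot see an omitted *first or last*
trip of a day — only interior omissions leave a detectable break.

## The synthetic cohort

The generator produces the study shape the method targets: 40 children
× 7 days, 10 s epoch, ~4 true trips per child-day (≈1,100 diary-scale
trips per cohort), split into two school arms with different diary
discipline. Specific choices:

* **World**: a planar grid of 80 m square blocks separated by 20 m road
  corridors; every child owns a distinct home block; two school blocks;
  one block each for shops, park, sports, church, medical, a school
  nobody attends, and "other"; the rest residential. Coordinates are
  metres in a local frame (the pipeline treats them as a planar CRS).
* **Schedules**: weekdays are home → school (≈6.5 h) → 0–3 after-school
  stops → home; weekends are home-based outings, 45% of which chain two
  stops before returning. Dwells are 15–75 min, so every episode
  clears the 120 s stop threshold by two orders of magnitude. Travel
  follows road corridors at walking/cycling/driving speeds
  (1.3/3.5/9 m/s); a configurable fraction of trips (default 8%) cut
  straight across blocks instead, exercising the off-road exclusion.
* **Tracks**: one fix per 10 s inside a 07:00–19:00 monitored window
  (a full 24 h adds volume but no structure), Gaussian position jitter
  (default 3 m), independent fix dropout (default 1%), and a default 1%
  of fixes given exactly one injected threshold violation — these are
  the cleaning filters' ground truth.
* **Diaries**: true trips degraded by chain collapse (left-to-right,
  non-overlapping), omission, field blanking (mode or accompaniment
  only, so degraded diaries remain alignable), researcher flags and
  clock jitter. Default rates are 30/18/18/10% for the sloppy arm and
  6/10/2/0.5% for the tidy arm — chosen once as plausible for
  child-kept versus adult-checked diaries, and sufficient for the
  quality score to separate the arms. Every injected defect is logged.
* **Determinism**: one cohort seed; per-child generators are spawned
  from (seed, child index), so cohorts are byte-reproducible and any
  child can be regenerated alone.

### What the synthetic experiments show — and don't

With noiseless tracks and verbatim diaries the full pipeline recovers
100% of diary trips as full matches, and with every chainable diary
pair collapsed it recovers 100% of collapsed trips as chain steps; the
share of true trips recovered as full matches is non-increasing in the
omission rate. These are *internal-consistency* results: they show the
segmentation, coding and alignment machinery is lossless on data that
satisfies its assumptions, and degrades monotonically as the diary
degrades. They do not certify performance on real tracks, whose
failure modes — urban-canyon multipath, long indoor dropouts, off-road
shortcuts, diaries that misreport categories rather than omit trips —
are deliberately not all modelled (the generator has no multipath
physics, no category-confusion errors, and simple polyline routes).
Real-data match rates should be expected to be substantially lower, as
the two-arm default cohort (~96% matched) is still far gentler than
field data.

## Numerical and engineering notes

* Percentages are raw count ratios rounded half-up to one decimal, and
  counts are always written beside them; counts, not printed
  percentages, are the source of truth.
* Chi-squared tests are plain Pearson (no continuity correction) via
  `scipy.stats.chi2_contingency`; degenerate margins are refused by
  name. p-values display as three significant figures with a "< 0.001"
  floor.
* Geometry uses shapely 2 vectorised predicates with an STRtree; no
  geographic reprojection library is bundled — planar inputs are used
  as-is and geographic (lon/lat) speeds use a haversine on the mean
  Earth radius (6,371,008.8 m).
* The aligner is O(n·m) time and memory per day with an O(1) chain
  lookback; daily sequences are short (≲ 15 trips), so cohort-scale
  alignment is effectively instant next to point-in-polygon coding.
* Empty days, empty sequences, empty diaries and empty files all flow
  through every stage; alignment of an empty side yields all-gaps with
  score gaps × gap.
* Problem sizes in the test-suite experiments: exhaustive alignment
  oracles run over all sequence pairs up to 2×2 on the six-code
  alphabet plus a 300-pair seeded sample up to 5×4; end-to-end recovery
  runs the full 40 × 7 cohort; the omission-monotonicity experiment
  averages 20 replicates at three omission levels against a fixed GPS
  record.

## Known limitations

* Chains longer than two links are not matched (by design); days
  dominated by looping unstructured movement resist trip-based
  linkage altogether.
* The quality score is order-sensitive but cannot detect edge-of-day
  omissions or fabricated-but-consistent entries.
* Location coding trusts the map: a fix in an overlapping or miscoded
  polygon is silently miscoded; there is no buffer snapping for
  near-boundary fixes.
* The scoring scheme's absolute values are conventions; only the
  ordering constraints above are principled. Per-trip decisions on
  ambiguous days can legitimately differ under other admissible
  schemes, which is why they are configurable.
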