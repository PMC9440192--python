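# Methods

## Model

`stscan` detects space-time clusters of point events (suspected suicides
geocoded to small census areas) against a population-at-risk baseline. The
null model is discrete Poisson: the count in each (location, day) cell is
Poisson with mean proportional to the location's census population,
homogeneous in time, and inference conditions on the observed grand total
`N`. The conditional null expectation of a window `Z` is therefore

    E(Z) = N · pop(Z)/pop_total · days(Z)/days_total .

Candidate clusters are cylinders. The spatial base at a centre location is
the nested sequence of its nearest neighbours (great-circle distance on a
6371 km sphere), each prefix a zone, stopping once the zone would exceed a
fraction `max_pop_fraction` (default 0.5) of the total population. This
realizes a circle of continuously varying radius exactly, for
point-referenced locations. The temporal extent is any interval of at most
`t_max_days` (default 30) at `aggregation_days` resolution (default 1);
prospective mode keeps only intervals ending on the study end date, i.e.
clusters still active when the analysis runs.

Each cylinder is scored with the one-sided Poisson log-likelihood ratio
(high-rate direction only — the application is excess incidence):

    LLR = O ln(O/E) + (N−O) ln((N−O)/(N−E))  if O > E, else 0,

with the convention 0·ln 0 = 0 so that O = N stays finite. The reported
relative risk is (O/E)/((N−O)/(N−E)), +infinity when every case lies inside
the window (exported as null with an `all_cases_inside` flag, since strict
JSON has no Infinity literal).

Reporting: the most-likely cluster is the maximal-LLR cylinder with at
least `min_cases` (default 2) observed cases; secondary clusters follow in
decreasing LLR subject to no geographic overlap (disjoint member-location
sets) with better-ranked clusters — temporal overlap is allowed. Ties are
broken by smaller radius, earlier start, then centre id, making output
deterministic. Because all windows of a zone share one member set, only
each zone's best window can ever be reported; the scanner exploits this.

## Monte-Carlo inference

Conditioned on `N`, the null cell counts are one multinomial draw with
probabilities E(cell)/N. Each of `R` replicates (default 999) redraws the
counts, rescans the identical cylinder set, and records the maximum LLR.
The p-value of a reported cluster is rank/(R+1), the observed LLR's rank
among the replicate maxima; every reported cluster is referenced against
the same replicate-maximum distribution, which is exact for the most-likely
cluster and conservative for secondaries. With R = 999 the attainable
p-values are 0.001, …, 1.000; significance uses p < alpha (default 0.05).
Replicate maxima are evaluated over all cylinders without the `min_cases`
filter, which adds a small extra conservatism when the null maximum comes
from a single-case window.

Each replicate draws from its own RNG stream spawned from the master seed
(`numpy.random.SeedSequence`), so results are independent of internal
batching. In prospective mode, cells outside the live temporal window
cannot enter any cylinder, so they are pooled into one remainder cell
before the draw — the law of the statistic is unchanged but the draw
dimension shrinks from locations × days to locations × window length.

Two performance choices matter at scale. With equal-length time units the
expectation depends only on window length, and the LLR is increasing in O
at fixed E, so per (zone, length) only the maximum windowed count over
start positions is scored; that inner sliding-window maximum is a compiled
(numba) kernel. Unequal units (a truncated final aggregation block) fall
back to scoring every start position.

## Surveillance replay

`prospective_replay` runs the prospective scan at each date of an analysis
schedule (daily/weekly/monthly/yearly), using only cases dated on or before
the analysis date and a study period truncated there — causality holds by
construction. An alarm is any analysis whose reported clusters include one
with p < alpha; the most-likely cluster is recorded even when
non-significant, and a recurrence-interval column (1/p, in analysis
periods) is included for users who prefer that scale. Analysis `i` uses
seed `master + i` (mod 2^31). The population denominator is one census
snapshot held fixed across the replay; intercensal drift is out of scope.

## Synthetic data

The generator emulates a decade of county-scale data whose real counterpart
is access-restricted: by default 100 small areas placed uniformly in a
1°×1° box at the latitude of County Cork, log-normal populations
(median 300, sigma 1 — a few towns, many sparse areas), and a baseline
Poisson process with expected total 388 cases over 2008–2017, uniform in
time and proportional to population — exactly the scan's null. A
`fixed_n` option conditions on an exact total via the multinomial.
Planted clusters multiply the rate by a relative risk inside a circle ×
interval window, adding excess cases on top of the baseline. Optional
demographics (gender 80/20 male/female, ages from a clipped normal(40, 15),
a four-level method mix dominated by hanging) are plausible marginals for
Irish suicide data, intended only to exercise the breakdown tables.

What the generator does not emulate: seasonality (a sinusoidal multiplier
hook exists but defaults off), spatial population drift over time,
settlement geography (locations are uniform, not clustered into towns), and
demographic risk gradients. Tests passing on synthetic data therefore
validate the statistical machinery under the model's own assumptions, not
robustness to real-data violations of them.

## Validation design and problem sizes

- **Oracle equivalence**: on 50 random instances (≤ 6 locations, ≤ 12
  days) the scanner must match a brute-force recount over every explicitly
  enumerated cylinder.
- **Type-I error**: 200 null datasets at 6 locations × 30 days with exactly
  24 cases each, R = 999; the rejection count at alpha = 0.05 must fall in
  the exact binomial 99% band [2, 19]. The size was chosen so that per-cell
  expectations (≈ 0.13) make two-case windows dominate the null maxima,
  keeping the min-cases conservatism negligible.
- **Power/recovery**: 25 locations in a 0.5° box over 180 days, baseline
  100 expected cases, one planted 12 km × 14-day cylinder at RR = 20
  (≈ 30 expected excess cases, comfortably above the ≥ 5 design floor);
  the most-likely cluster must attain the minimum p (0.001) with spatial
  Jaccard ≥ 0.5 against truth in ≥ 90% of 50 seeds.
- **Determinism**: identical seeds must reproduce byte-identical dataset
  files, replicate maxima, p-values and GeoJSON exports.

## Numerical and edge-case conventions

- Duration is reported as end − start in days (a same-day cluster has
  duration 0), matching the published table convention.
- The singleton {centre} zone is always a candidate even when that location
  alone exceeds the population cap; otherwise a dominant location — or a
  single-location geometry, where only temporal windows can score — could
  never be scanned. The cap applies from the second member on.
- Locations with zero population get zero expectation and can never anchor
  a reported cluster on their own (E > 0 is required).
- An empty case list yields an empty result, not an error; Monte-Carlo
  replication is skipped when there is nothing to test.
- Coordinates are WGS84 throughout; no projection is applied. Spherical
  haversine distance stands in for the ellipsoid (sub-0.5% error at county
  scale).
- Age groups are half-open, low-inclusive decadal bins by default
  ([0,10), …, 90+), with age computed at the event date from the birth
  date when no age is recorded.

## Known limitations

Circular windows only (no elliptic or irregular shapes); no covariate or
seasonality adjustment; a single population snapshot over the study period;
no multiplicity adjustment across repeated prospective analyses (the
recurrence interval is provided instead); p-values from rank Monte-Carlo
only, with granularity 1/(R+1).
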