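# Methods

## Scope and model

`dietprint` implements footprint accounting, not life-cycle assessment:
every environmental quantity is a linear combination of daily intake
masses with fixed per-kg intensities.  Three pressures are tracked.

**Water** and **GHGE** come straight from per-item intensity coefficients
(L/kg and kg CO₂-eq/kg of fresh weight as consumed).  **Nitrogen** is the
nitrogen content of ingested protein — protein mass divided by the item's
nitrogen (Jones) conversion factor — on the assumption that, outside of
net muscle accretion, dietary nitrogen is excreted and lost to the
environment.  This is a consumption-side nitrogen estimate only; nitrogen
from production, energy use and waste streams is out of scope, so the
number is a lower bound on a full nitrogen footprint.

## Intake normalization

Survey records report an amount per day, week or month.  Normalization
divides weekly amounts by exactly 7 and monthly amounts by exactly 30
(never calendar-aware), and converts beverage millilitres to grams through
a per-item density, default 1.0 g/ml (appropriate for water-based drinks;
overridable per item).  Rows that fail validation (unknown item, malformed
number, negative amount, unknown unit) are routed to a rejects ledger with
a reason, never silently dropped; the pipeline aborts when more than a
configurable fraction (default 5%) of rows is rejected.

## Composite dishes

A composite dish (salad, traditional dish, sandwich) carries no direct
coefficients; a standardized recipe gives its ingredients' mass fractions,
which must sum to 1 (±1e-9).  Resolution is linear: each intensity, the
energy density and the protein content are fraction-weighted sums.  The
composite's nitrogen factor is *not* averaged; it is chosen so that
composite nitrogen equals Σ fraction·protein/factor exactly, preserving
per-ingredient additivity (dividing pooled protein by a pooled factor
would not).  Nesting is allowed to depth 3 with cycle detection;
resolution is idempotent and invariant to ingredient order.

## Cohort statistics

- Per-kcal cohort statistics are **means of per-person ratios**: each
  participant's footprint is scaled to 1000 kcal of their own energy
  intake, then averaged.  This is deliberate — when energy varies between
  people the ratio of cohort means is a different (and smaller-variance)
  number, and the per-person convention is the one consistent with the
  survey tables this package mirrors.  The cohort value at another
  reference energy (e.g. 2500 kcal) is the per-1000-kcal mean × ref/1000.
  Participants with zero recorded energy are excluded from per-kcal
  summaries (with a logged count) and retained in absolute ones.
- Group aggregation divides by the cohort size, so non-consumers dilute a
  group's per-capita mean; groups sum to categories
  (animal/vegetable/other) and categories to the cohort total by
  construction, and percent contributions therefore sum to 100.
- Continuous summaries use the sample SD (n−1); annualization multiplies
  g/d by 365 and divides by 1000 (kg/year).
- Display rounding is half-up (ties away from zero) at 2 decimals for
  footprints and percentages and applied only in reports; CSV/JSON
  ledgers keep full precision.

## Benchmarks

Boundary ratios divide the cohort-mean footprint by a per-capita daily
limit (defaults: 786 L water, 1,866 g CO₂-eq, 27.4 g N per person per
day; GHGE is converted kg→g before the ratio) and print an integer
percent.

The Double-Pyramid comparison ranks pyramid groups by descending
cohort-mean intake (g/d) and compares each group's rank with the band of
ranks its recommended tier occupies.  Bands rather than single ranks are
used because a tier can hold several groups; a group is over-consumed if
it ranks better (smaller) than its band and under-consumed if worse.
Ties break lexicographically by group label, so the report is independent
of input row order, and it is invariant under any monotone rescaling of
all intakes.  The packaged spec has four tiers over six groups —
fruits & vegetables; grains & cereals; {olive oil, milk & yogurt, other
protein foods}; red meat & sweets — chosen so the qualitative
recommendation ordering is encoded while groups that the pyramid does not
place (drinking water, herbs, hot beverages) stay outside the ranking.
With intakes shaped like the calibration survey, red meat & sweets is
flagged over-consumed and olive oil under-consumed; the exact observed
rank of the flagged tiers depends on how finely groups are split, so the
report should be read by deviation direction, not rank number.

## Synthetic cohort generator

The generator emulates the calibration survey's statistical structure:

- **Group intakes** (21 intake groups; means 0.6–1440 g- or ml/d) are
  drawn per participant from log-normal marginals whose arithmetic mean
  and SD match the configured values exactly via moment matching
  (σ² = ln(1+cv²), μ = ln m − σ²/2).  Log-normals are used because
  intakes are non-negative and right-skewed and several configured SDs
  are near or above their means, which a normal cannot satisfy without
  truncation.  SD = 0 degenerates to a point mass.
- **Item splitting**: each group's mass is divided across its catalogue
  items by a symmetric Dirichlet (α = 2), so expected item intake is the
  group mean over the item count.
- **Frequency re-expression**: each record is reported daily, weekly or
  monthly (default mix 0.5/0.3/0.2); weekly/monthly amounts are the daily
  mass ×7/×30, and the ground-truth daily table is *defined* as the
  normalized record, so the round-trip is exact by construction.
- **Demographics** are independent categorical draws at the configured
  level probabilities; **anthropometrics** are per-gender normals
  (floored at physiological minima).  Household size and room-count
  distributions are chosen so roughly 63% of households exceed one person
  per room.
- Groups are mutually independent by default (the calibration tables
  carry no covariance information); an optional knob shares a person-level
  Gaussian factor across groups, inducing positive correlation between
  total intake mass and energy without disturbing the marginals.
- One integer seed drives everything; identical seeds reproduce the
  bundle byte-for-byte.

What the generator does **not** emulate: within-person day-to-day recall
variance (the configured SDs are treated as purely between-person),
group–group correlation structure, seasonal or regional intake
differences, and any dependence of diet on demographics.  Tests passing
on synthetic cohorts therefore validate the accounting pipeline, not
conclusions about any real population.

## Fixture catalogue calibration

The packaged ~45-item catalogue spans every footprint group and includes
a composite dish with a recipe (tabbouleh), a zero-protein item (olive
oil) and beverages reported in ml.  Its water/GHGE intensities and
protein contents are *effective group-level values*, back-derived so that
the expected per-group footprints (group mean intake × coefficient, with
symmetric item splits and the recipe-resolved composite) are internally
consistent with the survey's published per-group footprint table; the
cohort expectations are then 2,862.39 L, 4.43 kg CO₂-eq and 12.72 g N per
day.  They are order-of-magnitude realistic (beef ≈ 26 kg CO₂-eq/kg,
olive oil ≈ 21,000 L/kg) but are not literal commodity LCA values — in
particular the very small nuts/olives group inherits an inflated water
intensity, and groups with no published footprint row (herbs & spices,
drinking water, alcoholic beverages) carry zero coefficients so category
sums stay conserved.  Nitrogen factors are 5.83 for grains, 6.38 for
dairy, 5.46 for nuts and 6.25 elsewhere, all within the plausible 5–7
range enforced by the item validator.

## Parameter recovery

`parameter_recovery_check` compares the pipeline against the
config-implied ground truth: each group's recovered mean intake against
its configured mean, and the cohort footprint means against
Σ (group mean / item count) × item coefficient.  Deviations are
standardized by the *sample* standard error (SD/√n of the realized
cohort) — for heavy-tailed groups (intake CV up to ~10) the sample SE
co-inflates with outliers, making the z-score better calibrated than one
based on the configured SD — and flagged beyond 3 SE.  At n = 444 the
grains group has SE ≈ 6.4 g/d around a 317 g/d mean.

## Problem sizes and numerical choices

The test suite exercises micro-cohorts (≤ 20 participants × ≤ 10 items)
against a per-record loop oracle at 1e-9 relative tolerance, pipeline
runs at n = 15–30, and generator calibration checks at the full n = 444;
the acceptance script reruns the complete pipeline at n = 444, which
takes a few seconds.  Degenerate inputs are defined explicitly: empty
intake gives a zero footprint with undefined per-kcal fields (an error if
requested, never a silent NaN), zero protein gives zero nitrogen, and an
empty cohort is rejected.  Fraction-sum tolerance for recipes is 1e-9;
month length, year length, Atwater factors (4/4/9), BMI cut-points
(18.5/25, three bands) and the crowding threshold (strictly > 1
person/room) are fixed constants documented in code.

## Known limitations

- Coefficient uncertainty is not propagated; reported SDs reflect
  between-person variation only.
- No reconciliation rule when two coefficient sources disagree for an
  item; the `source` tag preserves provenance and the last loaded table
  wins only by explicit user choice.
- The nitrogen estimate is consumption-side only (see above).
- Significance testing between strata and post-hoc power analysis are out
  of scope; summaries are descriptive.
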