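# Methods

## Problem setting

A clinic's month is a batch of EC bookable examination slots. Each
booked appointment ends in exactly one of three statuses — realized,
canceled, or no-show — so the status fractions ARP + ACR + NSPR = 1
and every monthly ledger must satisfy the integer conservation
`realized + canceled + no_show = total`. Rates are kept as exact
fractions internally; presentation rounds percentages to one decimal
with halves away from zero, and summary statistics (mean, sample SD
with the n−1 denominator, median) are presented as integers by
truncation toward zero — the conventions under which the bundled
reference deployment ledger reproduces cell for cell. Two of the
reference table's derived percentage rows (the combined share and the
standby-to-web ratio) are not reproducible from its own counts under
any simple rounding rule; the report therefore always recomputes
percentage rows from counts and treats only the counts as
authoritative.

## Attendance-risk tree

The tree is induced by greedy recursive partitioning. At each node
the feature with maximal information gain is chosen:

    IG(D, f) = H(D) − Σ_v (|D_v|/|D|) · H(D_v),   H in bits.

Categorical features split multiway (one child per observed value);
numeric features are binned beforehand — age into the eight brackets
0–10 … 61–70 plus a 71+ extension, travel time at population
quantiles (four bins by default). Splitting stops at label purity, at
`max_depth` (default 6), or when no split keeps every child at
`min_leaf` rows (default 5). Ties in gain break by schema order so
fitted trees are reproducible. Defaults favour shallow, inspectable
trees: the policy's users need legible decision paths more than the
last fraction of a percent of accuracy.

Leaf probabilities are Laplace-smoothed (+1 per class), so no
predicted probability is exactly 0 or 1 and the reserve-pool ranking
has a strict order. Three-class labels (realized/canceled/no-show)
are the default since cancellations and no-shows enter the
provisioning formula separately; a binarized show/not-show mode
exists, splitting the not-show mass by the training base
cancel:no-show ratio. Feature values unseen in training route through
the majority child with a logged warning — a live scheduler must
always return an estimate. Continuous learning refits on a sliding
window (default 50,000 most recent rows); an empty update is the
identity, and two sequential updates equal one concatenated update
within the same window.

An alternative logistic-form scorer fits p(show) by iteratively
reweighted least squares on the one-hot binned design with a small
ridge term (1e−6) for stability on sparse or separable designs; it
satisfies the same risk-prediction contract.

## Standby provisioning and backfill

`SA = ⌈EC·ACR + EC·NSPR⌉` standby bookings are provisioned; the
ceiling (guarded by rounding the product to 9 decimals first, so
binary float noise cannot add a phantom slot) means coverage is never
under-provisioned. `CA = max(0, ⌈EC·ACR − ARP·AR + EC·NSPR⌉)`
accounts for promotions already made; it can go negative when
promotions exceed the expected shortfall and is clamped at zero. AR is
the running count of substitute→primary promotions in the current
period; whether the rates feeding the formulas come from the current
or the prior month is the caller's choice (the experiment loop uses
the previous month's ledger).

The reserve pool is ordered by predicted attendance probability
(descending), then self-reported travel time (ascending — patients
who can reach the clinic fastest fill sudden vacancies best), then
booking order (FIFO); the order is total and permutation-invariant.
Promotion takes the pool head for the slot's physician; an empty pool
is a logged no-op, not an error. The callback cycle requires a
horizon of at least 60 minutes, queries primaries with predicted
attendance below the threshold (default 0.6, the aggregate baseline
realization rate), cancels and backfills every decline, and repeats —
promoted patients are themselves queried on the next pass — until no
unconfirmed high-risk primary remains or the pool is exhausted.

## Synthetic population and simulator

The generator emulates the structure of a large urban booking stream:

* status split ≈ 60/29/11 overall, with cancellation propensity
  rising across age brackets (defaults 0.20 → 0.38, weighted mean
  0.294) and a mildly falling no-show profile (0.13 → 0.09, weighted
  mean 0.110);
* gender and district effects as odds multipliers (defaults 0.9–1.15;
  free parameters — real conditional rates by gender/district are not
  published anywhere we could calibrate to);
* lognormal self-reported travel times (median 30 min, σ = 0.5);
* per-patient behavioural persistence (probability 0.2 of repeating
  the previous outcome) over a Poisson(3) history.

One month is a batch, not a continuous clock: per-slot timing matters
only for comparing cancellation lead times against the callback
horizon. Cancellation leads are exponential (mean 24 h) truncated at
the booking-to-slot interval, honouring the empirical pattern that
cancellations cluster close to the slot. Cancellations with at least
one hour of lead are backfillable.

All randomness flows from one root seed through `SeedSequence`
spawning. Outcome draws are indexed by patient, not by policy or pool
size, which has two deliberate consequences: (i) baseline and standby
runs at the same seed share identical web-stream outcomes, making the
policy comparison paired; (ii) a larger pool replays a smaller pool's
promotion sequence as a prefix, so the utilization gain is
non-decreasing in pool size by construction. Callback responses are
truthful reports of the patient's drawn outcome — the simulator knows
ground truth, the fitted model never does, keeping predictor and
generator honestly separated.

The baseline policy refills a fixed share (default 0.45) of vacated
slots with an ad-hoc walk-in stream; this is what keeps a pre-policy
clinic near the reported 75–85% utilization band despite a 60%
realization rate. Under the standby policy that legacy stream is
replaced by systematic promotion from the ranked pool. The web-stream
ledger rows are identical under both policies; recovered standby
visits are reported in a separate ledger field, mirroring how the
reference deployment table reports them. Revenue is
`unit_price × realized visits` with a configurable unit price; no
decomposition of deployment revenue figures is attempted.

## Experiments the tests run

* **Bracket-risk recovery** — populations of 10,000 with no-show
  rates rising linearly 0.06 → 0.16 across brackets, no
  gender/district effects, persistence 0. The tree is fitted on one
  row per logged appointment (each patient's Poisson(4) history plus
  one fresh outcome, ≈ 50,000 rows) over the demographic schema with
  `min_leaf = 50`; mean predicted no-show per bracket recovers the
  generating rates within ±0.02 and monotonically. Fitting on the
  full appointment log rather than one row per patient is exactly
  what the live system does and is what makes the per-bracket
  sampling error small enough for a meaningful check.
* **Paired policy effect** — uniform 60/29/11 rates, EC = 5,000,
  population 8,000, pool capped at SA. One hundred seeded months in
  the test suite (fifty in the acceptance script, which also runs the
  recovery loop); the standby policy's realized-per-capacity exceeds
  the baseline's in ≥ 95 of 100 paired months, and the gain is
  non-decreasing in pool size. These sizes were chosen as the
  smallest that make the binomial margins comfortable.
* **Oracle equivalence** — information gain and root splits against
  brute-force recomputation on ~1,500 seeded datasets of ≤ 12 rows ×
  3 binary features; Spearman's ρ against the exhaustive rank formula
  for every permutation up to n = 6.

## What passing tests do and do not show

The generator produces clean conditional structure: exact bracket
rates, independent patients (persistence aside), no seasonality, no
physician or hour-of-day effects, no informative missingness. Passing
recovery and policy tests therefore demonstrates the correctness of
the machinery — induction, ranking, promotion bookkeeping,
provisioning arithmetic — not that a real clinic will see a specific
utilization gain. The reference deployment's observed improvements
(≈ 10 percentage points of attendance, ≈ 6 of utilization) are field
observations under conditions we cannot regenerate; the simulator's
gains are direction-consistent with them but not calibrated to them.

## Numerical choices and degenerate inputs

* Entropy of an empty count vector, rates of an empty month,
  correlation of a constant series, and sample SD of a single
  observation all raise typed errors rather than returning NaN.
* Spearman's ρ uses mid-rank ties and the two-sided t approximation
  (via scipy); p-values are reported, never used for gating, and no
  multiple-testing correction is applied to the single planned
  correlation.
* Capacity utilization is display-capped at 100%.
* Probabilities adjusted by odds multipliers are validated to leave
  non-negative attendance mass; infeasible configurations raise at
  generation time.

## Known limitations

Intra-day queueing, service-time variability, physician-level
heterogeneity and walk-in streams beyond the legacy refill share are
out of scope. The ARP definition in circulation is ambiguous
("appointments made over total"); it is implemented as
realized/total, the only reading consistent with the reference
ledger's printed percentages. The pool-ordering key beyond predicted
attendance and travel time is underdetermined; FIFO booking order is
used as the final tie-break.
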