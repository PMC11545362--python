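# clinicflow

Outpatient clinics lose a large share of their examination capacity to
cancellations and no-shows: in a typical large urban hospital roughly
60% of web/call-center bookings are kept, ~29% are canceled and ~11%
end as no-shows, leaving monthly capacity utilization stuck around
75–85% even with ad-hoc walk-in refills. `clinicflow` is a toolkit for
clinic operations teams and health-services researchers that models
this loss and recovers it with a *standby appointment* policy: predict
each patient's attendance risk, provision a ranked reserve pool of
standby bookings, promote the first-booked standby into every vacated
slot, and confirm high-risk primaries by callback before their slot.

## The model

For one physician-month with examination capacity **EC** and status
fractions **ARP** (realized), **ACR** (canceled), **NSPR** (no-show),
the number of standby (substitute) bookings to provision is

```
SA = EC·ACR + EC·NSPR
```

and, once **AR** substitutes have already been promoted to primary,
the complementary top-up is

```
CA = (EC·ACR − ARP·AR) + EC·NSPR        (clamped at 0)
```

Fractional values are ceiled so reserve coverage is never
under-provisioned. When a primary booking is canceled, the
first-booked standby for that physician is promoted into the vacated
slot (FIFO) and notified; a pre-appointment callback cycle queries
primaries whose predicted attendance probability falls below a
threshold (default 0.6) and immediately backfills every decline,
repeating until nothing is left to fill or the pool is empty. Calls
are never placed later than one hour before the slot.

Attendance risk comes from a decision tree induced from scratch by
greedy information-gain partitioning over categorical patient features
(age bracket, gender, district, binned travel time, past-behaviour
bin), with Laplace-smoothed leaf probabilities and deterministic
schema-order tie-breaks. An IRLS-fitted logistic scorer is available
behind the same prediction contract. The model refits on a sliding
window as new outcomes arrive (continuous learning). A seeded
synthetic-population generator and month-level simulator support
paired baseline-vs-standby policy experiments.

## Worked example

```python
import clinicflow as cf
from clinicflow.simulate import fit_initial_model

# the bundled reference deployment ledger (seven months)
june = cf.reference_ledgers()[0]
rates = cf.compute_rates(june)
params = cf.derive_parameters(june, ec=1000)
print(cf.substitute_count(params))

stats = cf.summary_stats(cf.STANDBY_SERIES_AUG_DEC)

# paired policy comparison on a synthetic population
pop = cf.uniform_rate_population(3000, seed=11)
model = fit_initial_model(pop)
clinic = cf.ClinicConfig(ec=2000)
base = cf.simulate_month("baseline", pop, clinic, seed=12)
stby = cf.simulate_month("standby", pop, clinic, model=model, seed=12)
```

This prints / yields:

```
June: realized 57.1%  canceled 31.6%  no-show 11.3%
SA for EC=1000 at June rates: 429
standby series: mean 4680, sd 1104, median 4683
baseline utilization 77.8%  standby 83.1%
standby visits recovered: 462 of 800 promotions
```

Reading the numbers: June's 92,527 bookings split 57.1/31.6/11.3
percent across realized/canceled/no-show, so a physician with 1,000
monthly slots should provision ⌈315.9 + 113.0⌉ = 429 standby
bookings. The five full-operation months of the reference ledger
recovered a mean of 4,680 standby visits per month (sample SD 1,104,
median 4,683). In the paired simulation, the standby policy lifts
utilization from 77.8% to 83.1% on the same outcome draws.

A CLI wraps the same functions:

```
clinicflow simulate --months 6 --seed 42 --out out/
clinicflow fit --log appointments.csv --out model.json
clinicflow plan --model model.json --log appointments.csv
clinicflow report --ledgers out/ledgers_standby.csv
clinicflow metrics --ledgers out/ledgers_standby.csv --window 5
```

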