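# Methods

This package estimates the incremental cost-effectiveness of adopting the
2016 WHO eight-contact antenatal care (ANC) schedule in Rwanda, relative to
the current four-visit policy, over a one-year implementation period for a
hypothetical cohort of 373,679 pregnant women (the number attending ANC at
least once in 2014). All money is 2015 USD.

## Model structure

The analysis is a deterministic decision model with one stochastic
component (attendance):

1. **Visit costing.** Each schedule is an ordered list of per-visit unit
   costs. A woman attending `k` visits receives the content of scheduled
   visits `1..k` in order; her cost is the cumulative sum. This is a known
   simplification — a woman attending twice late in pregnancy in reality
   receives late-visit content, not visits 1–2. Visits beyond the schedule
   length (a 9th–11th contact) are not separately specified anywhere, so
   each is costed at the $6 routine-visit price, the cheapest recurring
   visit type; this is configurable (`overflow_visit_cost_usd`).
   Unit costs: four-visit model $21/6/6/11 (total $44); eight-contact model
   $24/6/10/6/6/10/6/11 (total $79). The $3 difference in visit 1 is the
   routine obstetric ultrasound; visits 3 and 6 add repeat bacteriuria ($3)
   and anaemia ($0.75) tests to the $6 routine visit.

2. **Attendance simulation.** Per-woman visit counts are normal draws with
   scenario mean and SD, rounded half-away-from-zero to integers and
   clipped to the scenario range: scenario 1 "conservative" mean 5, range
   [1, 8]; scenario 2 mean 6, range [2, 10]; scenario 3 "ambitious" mean 7,
   range [3, 11]. The SD of the eight-contact scenarios is not separately
   specified; we carry over SD = 0.8 from the observed current-practice
   distribution (mean 3.3, median 3, SD 0.8). That single choice reproduces
   the reference per-woman cost means ($53/$61/$69), their SDs (~6.6–7.2)
   and the scenario ranges as natural extremes of ~374k rounded normal
   draws. National cost is the exact integer-cent sum over the cohort,
   replicated 100 times from independent RNG streams spawned off one master
   seed (results do not depend on execution order). The replication
   max–min spread relative to the mean is a reliability diagnostic with a
   0.2% default threshold (observed ~0.01–0.1%).
   A closed-form oracle evaluates the same model analytically: the count
   pmf is `Φ((k+½−μ)/σ) − Φ((k−½−μ)/σ)` with tail mass folded into the
   range endpoints; expected cost and SD follow directly. Property tests
   require simulation and oracle to agree within 3 Monte-Carlo standard
   errors for arbitrary schedules and scenarios.
   A degenerate "full utilisation" scenario (everyone attends exactly four
   visits of the current schedule, $44/woman) is costed but excluded from
   the ICER matrix — it is a utilisation counterfactual of the *current*
   policy, not the new one.

3. **Outcome scenarios from expert elicitation.** Eight specialists gave
   expected perinatal and maternal mortality reductions in two Delphi
   rounds; round-2 answers supersede round-1, and non-response in round 2
   confirms round 1. For each indicator independently, final estimates are
   sorted and split into two equal halves; the lower-half mean is the
   *pessimistic* parameter and the upper-half mean the *optimistic* one.
   Reference parameters: perinatal −22.5%/−55%, maternal −7%/−52.5%.
   For odd panel sizes (not encountered in the reference panel) the middle
   value joins the lower half — the conservative direction; ties sort
   stably by (value, expert id). Values are point estimates in [0, 100];
   reductions are stored positive, the sign is a reporting convention.

4. **Deaths averted and life-years saved.** Deaths averted = baseline
   annual deaths (10,076 perinatal; 371 maternal) × reduction, rounded
   half-up. Each averted death earns the present value of one life-year per
   remaining year, via an end-of-year annuity `A(n, r) = (1−(1+r)^−n)/r`
   at r = 3%/yr (`A(n, 0) = n`). The discounting formula is a standard
   convention adopted here; it matches the implied reference factors to
   three figures. Maternal deaths use the remaining female life expectancy
   (66 years) per 5-year age group, weighted by the age distribution of
   maternal deaths; perinatal deaths use a single horizon.

5. **ICERs and thresholds.** Incremental cost = simulated mean national
   cost − current-practice national cost ($13,939,970, with $37/woman — a
   fixed input from the primary micro-costing study, not re-simulated).
   ICER = incremental cost / total LYS, for every one of the 3 × 2
   costing × outcome combinations — deliberately including implausible
   pairings, as no joint model of attendance and effectiveness is
   available. Classification against the Rwandan GDP per capita ($697):
   ≤ 1× GDP "very cost-effective", ≤ 3× "cost-effective", > 3× "not
   cost-effective", boundaries inclusive. The rule is phrased per DALY
   averted; it is applied per LYS here, equivalent for pure-mortality
   gains without age weighting or disability.

## The two discounting variants

The methods convention for perinatal life expectancy (64 years, both
sexes) and the published life-years table are mutually inconsistent: the
published perinatal cells imply an annuity factor of ≈28.60, i.e. a
66-year horizon (`A(66, 0.03) = 28.595`), not `A(64, 0.03) = 28.306`. The
two published perinatal cells even imply factors differing in the third
decimal (64,827/2267 = 28.5960 vs 158,466/5542 = 28.5936), so no single
convention reproduces all cells exactly. Both conventions ship:

* `variant: "stated"` — perinatal horizon 64 years;
* `variant: "implied"` — perinatal horizon 66 years (default; reproduces
  the reference totals of 65,366 and 162,509 LYS to ~0.01%).

Reports and manifests always state the active variant and horizon.

## Synthetic data

The generators produce inputs with the statistical structure the pipeline
assumes; they are test scaffolding, not data with empirical content.

* **Expert panels** are built by inverse design: the half means are fixed
  at the target scenario parameters first, then panel members are spread
  arithmetically around each half mean (symmetric offsets cancel exactly,
  so the half-split recovers the targets to machine precision by
  construction — this is what parameter-recovery tests rely on). A
  configurable fraction of experts "revise" between rounds; the rest
  answer once and are treated as confirming.
* **Attendance surveys** reuse the simulation's rounding/clipping rules.
  Because rounding inflates the SD of the underlying normal (~in
  quadrature with √(1/12) ≈ 0.29), the latent SD is calibrated from the
  exact count pmf so that the *observed* integer counts recover the target
  mean and SD (defaults 3.3/0.8, median 3).
* **Maternal age distribution.** The primary age table of maternal deaths
  was not available, so a synthetic one is supplied: 5-year reproductive
  age groups (midpoints 17.5–47.5) whose shares are an exact linear blend
  of a younger- and an older-skewed plausible profile, calibrated so the
  discounted years per maternal death equal 4044/195 ≈ 20.738, the factor
  implied by the reference optimistic maternal cell
  (`anc_cea.synthetic.calibrated_maternal_age_shares`). Only this
  aggregate factor is identified by the reference results; the individual
  shares are not empirical estimates.

What passing tests therefore show: the pipeline arithmetic, the
distributional model and the aggregation rules are correct and
reproducible. What they do not show: anything about real attendance
behaviour, real expert beliefs, or the true age pattern of maternal
deaths.

## Known internal inconsistency of the reference results

The reference scenario-3 national total (24,895,023) is inconsistent with
its own per-woman mean (69 × 373,679 ≈ 25.86M). This package treats the
per-woman mean as the primitive (it follows from the documented
attendance model), so the simulated scenario-3 total is ~25.86M, its cost
increase ~86% (not the published 79%) and its pessimistic-scenario ICER
~$182/LYS (not $168). All classifications are unaffected — every cell
remains far below the $697 threshold. Scenarios 1 and 2 and the
full-utilisation row are internally consistent and reproduce exactly
(42%, 64%, 18% cost increases; ICER corner $36).

## Numerical choices

* Money: integer cents internally (int64); cohort totals are exact.
  Tables round to whole dollars; JSON keeps full precision.
* Rounding: half-up for deaths averted, reported ICERs and whole-percent
  cost increases; visit counts round half-away-from-zero before clipping.
* Reproducibility: one master seed per run, logged in the manifest;
  per-scenario and per-replication streams are spawned deterministically
  (`numpy` `SeedSequence`). Identical config + seed ⇒ byte-identical
  reports.
* Degenerate inputs: zero-SD scenarios take a deterministic path; a
  costing-only run (no CEA-eligible scenario) produces an empty ICER
  matrix rather than an error; LYS ≤ 0 makes the ICER undefined
  (dominance analysis is out of scope) and raises.

## Problem sizes

The default reference run is full scale — 373,679 women × 100
replications × 4 scenarios (~150M draws) — and completes in a few seconds
vectorized. Unit and property tests use cohorts of 10³–10⁵ with
tolerances set from Monte-Carlo standard errors at those sizes.

## Limitations

Morbidity, quality-of-life and DALY outcomes are out of scope, as are
one-off implementation costs (ultrasound machines, training), household
vs health-sector cost shares, visit timing/gestational age, any link
between an individual woman's attendance and her mortality risk, and
probabilistic sensitivity analysis.
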