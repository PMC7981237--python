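# Methods

## The model

`eggsink` implements a discrete-time, Nicholson–Bailey-class
consumer–resource model for two aphid hosts sharing one parasitoid: a
suitable host H1 (parasitoid offspring complete development, s1 ≈ 1), an
unsuitable host H2 (offspring die as larvae, s2 ≈ 0, but parasitism
still costs the host, µ2 > 0) and female parasitoids P. One generation
maps (H1, H2, P) to

    H_i' = H_i · g(H_i) · (1 − (s_i + µ_i)(1 − f(ε_i)))
    P'   = X · (s1 H1 (1 − f(ε_1)) + s2 H2 (1 − f(ε_2)))

with

    g(H) = exp(r (1 − H/K))            Ricker density dependence
    f(ε) = (1 + ε/k)^(−k)              negative-binomial escape
    ε_i  = a_i β P / (β + a1 H1 + a2 H2)   egg-limited encounter rate

The shared denominator of ε is the *egg sink*: every host of either
species competes for the parasitoid's finite egg supply β, so adding
unsuitable hosts strictly lowers the encounter rate suffered by
suitable hosts (∂ε1/∂H2 < 0 whenever a2 > 0). X converts successful
parasitism into next-generation female attackers.

Assumptions worth stating: generations are discrete and synchronized
across all three species; all per-generation quantities (g, f, ε) are
evaluated from the pre-step state (synchronous update); abundances are
continuous and non-negative by construction (the survival factor
1 − (s+µ)(1−f) lies in [0, 1] because s + µ ≤ 1 is enforced at
construction); extinction is absorbing and no quasi-extinction floor is
applied; there is no spatial structure and no demographic stochasticity.

### Default parameters

| symbol | default | meaning |
|---|---|---|
| r1 = r2 | 2 | per-generation intrinsic growth (dimensionless exponent) |
| K1 = K2 | 1000 | carrying capacity (individuals) |
| a1, a2 | 1, 0.45 | relative search rates (a2/a1 from the no-choice egg ratio 1/2.2) |
| β | 16 | maximum parasitoid fecundity (eggs/female/generation) |
| k | 0.75 | aggregation of attack risk (shared by both hosts; the source is ambiguous about per-host k_i, and the escape function uses a single k) |
| s1, s2 | 1, 0 | susceptibility (offspring-producing fraction of parasitized hosts) |
| µ1, µ2 | 0, 0.4 | nonreproductive parasitism cost |
| X | 0.29 | female fraction among viable emerging adults (emergence × sex ratio) |

Note on µ2: the reported group fecundity means (12.2 vs 30.7 nymphs)
imply µ2 = 1 − 12.2/30.7 ≈ 0.60, while the packaged default keeps the
published value 0.4. The estimator returns the formula value; the
default config pins the published one. Both give the same qualitative
outcome (apparent predation) and the tests exercise both.

At r = 2 the Ricker map sits exactly at its period-doubling threshold:
a host alone is marginally stable and oscillates around K with slowly
(algebraically) decaying amplitude. This is why the unsuitable host
alone "cycles about K" at the 100-generation horizon while the damped
three-species system reaches a point equilibrium.

## Scenarios, attractors and classification

Two invasion protocols (100 generations, injections at generation 30,
invader abundances 50 per host and 1 parasitoid): (a) the unsuitable
host invades the resident suitable-host/parasitoid system; (b) the
suitable host and parasitoid invade the resident unsuitable host.
Injections are additive at the start of the named generation.

`detect_attractor` inspects the final `window = 20` states. A window is
an equilibrium when every species' successive relative change stays
below `tol_eq = 1e−4` (≈0.1 individual at K = 1000 — tight enough to
separate a damped approach from a cycle, loose enough that a standard
100-generation run of the damped three-species system, still ~1e−5 from
its fixed point, is recognized as converged). Otherwise periods
2..`max_period = 10` are scanned for recurrence within
`tol_cycle = 1e−2`; the looser cycle tolerance accommodates the
marginal Ricker cycle, whose period-2 recurrence error is ~1e−3 at
generations 80–100. Cycle means are averaged over one detected period.

`classify_interaction` compares three runs — suitable host +
parasitoid; unsuitable host alone (parasitoid seeded, extinct when
s2 = 0); all three species — on equilibrium values or cycle means. A
relative change below the 1% dead-band counts as no effect. Sign pairs
map to labels: (+/−) apparent predation, (−/−) apparent competition,
(+/+) apparent mutualism, (0/0) neutral; one-sided pairs are labelled
apparent commensalism (+/0) or amensalism (−/0). Non-stationary
attractors flag the report inconclusive.

At the defaults this yields apparent predation: the suitable host rises
1.54-fold and the parasitoid 1.22-fold when the egg sink is present,
while the unsuitable host drops ~8% (to ≈917) when the suitable host
and parasitoid arrive.

Known discrepancy: the source description of scenario (a) has the
invading unsuitable host transiently exceeding its carrying capacity.
Under the printed equations and defaults the post-invasion peak is
≈945 < K for any invasion generation — the resident parasitoid
(P ≈ 78) suppresses the invader's first growth steps. The invader does
overshoot its eventual equilibrium (945 > 917) and settles through
~15 generations of decreasing oscillation. We implement the equations
faithfully and leave the carrying-capacity-overshoot check failing
rather than altering the update rule.

## Estimators

All estimators pool counts across replicates (ratios of sums), avoiding
small-denominator instability, and are invariant to replicate
duplication.

* **a2/a1** — mean no-choice egg deposition into the unsuitable host
  over the mean into the suitable host (2.2-fold ratio → 0.45).
* **β** — mean per-female egg supply, laid (all species) + residual at
  dissection, pooled over every dissected female in all four
  treatments (the egg complement is a property of the female, not the
  treatment), rounded to the nearest integer. This is a declared
  operationalization of "maximum daily fecundity"; the exact published
  computation is not recoverable, so the estimator is deliberately
  simple and transparent.
* **X** — total emerged females ÷ total mummies over suitable-host
  replicates with ≥ 10 mummies (the published cutoff), i.e. emergence
  folded into the female share: 0.6 × 0.48 ≈ 0.29.
* **s_i** — emerged-producing mummies ÷ parasitized hosts, per species,
  over no-choice development replicates. Parasitized hosts per
  replicate are not observed directly and are approximated by the
  per-female mean no-choice egg deposition (from the oviposition
  assay), capped at the number of hosts exposed (default 50). Optional
  snapping moves estimates within 0.25 of an endpoint to exactly 0 or
  1 (a fully suitable/unsuitable host); the pipeline snaps by default.
* **µ2** — 1 − (mean lifetime fecundity, parasitized)/(mean, control),
  clamped to [0, 1]. Longevity enters only through lifetime fecundity.

## The synthetic-microcosm generator

The generator emulates the three laboratory experiments so the
estimators and the full pipeline are testable without the archived raw
data; it is calibrated to the published *ratios* (absolute per-replicate
egg counts were never published and are config choices).

Per female, an egg supply S is drawn — by default
Binomial(20, 0.8), i.e. a complement capped by ovariole number with
mean 16 and variance 3.2; Poisson and negative-binomial
(overdispersed) supplies are config switches. Eggs are allocated
between species proportionally to attack weights (ratio·d1 : d2 at
densities d), scaled by a treatment-level lay fraction (0.625 in the
20-host oviposition tubes, giving ~10 laid + ~6 residual; 0.95 on the
50-host plants). The default "quota" allocation deposits the expected
share up to integer rounding (floor + Bernoulli remainder), modelling a
female distributing a fixed complement nearly deterministically over a
24-h trial with abundant hosts; a "multinomial" switch restores
egg-by-egg stochasticity. Residual = supply − laid always holds.

Development replicates chain binomials: parasitized (= allocated eggs,
capped at hosts exposed; superparasitized eggs are wasted) → mummies
(mummification 0.95 suitable, 0 unsuitable) → emerged (0.6) → females
(0.48). Survival replicates draw geometric lifetimes (memoryless daily
hazard; means 28 d control, 20 d parasitized — the published 1.4-fold
reduction) and Poisson daily nymphs after a 7-day pre-reproductive
period, with the daily mean back-solved so expected lifetime fecundity
hits the group targets (30.7 and 12.2):
m = F / (L̄ (1 − 1/L̄)^prerep). The egg-load ~ tibia table draws tibia
lengths N(0.25 mm, 0.02 mm) and egg load = round(max(0, 164.79·x −
24.68 + noise)) with noise variance signal_var·(1/R² − 1) targeting
R² = 0.39 (at the mean tibia the line gives ≈16.5 eggs, consistent with
β = 16).

What the generator does *not* emulate: between-female variation tied to
body size (supply and tibia are drawn independently; the real
correlation is the separate egg-load table), host-feeding, within-day
time budgets, plant/arena microstructure, and realistic right tails of
aphid lifespan (geometric lifetimes are long-tailed). Passing recovery
tests therefore show the estimators are consistent for data with this
statistical structure, not that the laboratory data had it.

## Monte-Carlo study sizes and numerical choices

Recovery tests use 200 seeded replicates of the assay generators
(25 replicates/treatment, as in the study design) for a2/a1, X and β,
and 100 seeded end-to-end replicates
(generate → estimate → simulate → classify). Large-n calibration checks
use 500 replicates or 10⁴ individuals. These sizes give the coverage
assertions ≥ 2.7σ of margin under the design variances while keeping
the default test run fast. All randomness flows through
`numpy.random.default_rng` seeded per assay via `SeedSequence(seed,
spawn_key)`; every table is bit-reproducible from its config.

Degenerate inputs are defined rather than left to chance: zero
parasitoids give ε = 0 and f = 1 exactly; empty systems stay empty;
zero-egg assays raise explicit undefined-ratio/insufficient-data
errors; β̂ = 0 is reported but rejected when building model parameters
(the model requires β > 0).

## Limitations

Heuristic, strategic model: two hosts, one parasitoid, no stochastic or
spatial versions (types permit more hosts but this is untested). No
analytic stability analysis — attractors are detected numerically from
finite trajectories, so a cycle with period > 10 or slower-than-1e−4
transients would be misread at the default horizon. Estimator
confidence is characterized only by Monte-Carlo spread.
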