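# Methods

## Growth model

Crustacean growth is episodic: carapace length (CL) is constant between
moults and jumps at ecdysis. Averaged over a cohort, stepped growth traces
a smooth von Bertalanffy envelope

    L(t) = L∞ − (L∞ − L0) e^(−k t),

and the package's estimators assume exactly that population-level
behaviour. `L∞` (mm CL) and `k` (yr⁻¹) are estimated separately because
they are strongly negatively correlated when fitted jointly from either
data source alone.

### Powell–Wetherall estimation of L∞

Under steady state — constant recruitment, constant exponential total
mortality `Z`, VBGF growth, and full selection above a recruitment length —
the mean length above a cutoff `L′` obeys the Beverton–Holt relation
`L̄ = (Z L′ + k L∞)/(Z + k)`. Writing `y = L̄ − L′ = a + b L′` and fitting
ordinary least squares over cutoffs at the bin lower edges from the
recruitment length upwards yields `L∞ = −a/b` and `Z/k = −(1+b)/b`. A valid
fit requires `b ∈ (−1, 0)`; anything else is reported as a degenerate fit,
never silently clamped. Cutoffs stop at the last bin whose tail still
contains a configurable minimum number of individuals (default 5), since
tail means over a handful of animals are too noisy to regress on. When the
table is built from raw lengths, tail means use the raw values; pre-binned
tables use bin midpoints.

### Forced Gulland–Holt estimation of k

Each tag return supplies an annualized rate `r = ΔL/(Δt/365.25)` (mm yr⁻¹)
at mean length `L̄ = (L₁+L₂)/2`. The classical Gulland–Holt plot regresses
`r` on `L̄`; the *forced* variant fixes `L∞` and fits the single parameter
`k` by least squares through the point `(L∞, 0)`:

    k̂ = Σ rᵢ (L∞ − L̄ᵢ) / Σ (L∞ − L̄ᵢ)².

Records with `L̄ ≥ L∞` carry no information about a VBGF slope and are
excluded with a logged warning. Pooling liberty periods concatenates the
filtered records and fits once, which makes the pooled estimate an
`x²`-weighted average of the per-period estimates.

Filtering before estimation drops records with zero or negative growth,
unreadable (missing) tag identities, or missing fields; every exclusion is
returned with a per-record reason so the accounting can be audited.

### Moult-mode classification

Increment windows assign a moult count per record: `< 4.49` mm = one moult,
`5.50–8.49` mm = two, `> 8.49` mm = three or more. The 4.49–5.50 mm gap is
labelled *unclassified* and excluded from the two-group starting-size
comparison; the windows are configurable. The comparison itself defaults to
a pooled-variance two-sample t test (Welch is exposed), the wild-vs-captive
comparison reports the min-convention Mann–Whitney U with mid-rank ties,
and the size-vs-growth association is a Spearman rank correlation. All
p-values are two-sided.

Captive moult detection: an event is a CL increase of more than 0.5 mm
between successive observations that is *sustained* — every later
observation stays above the pre-jump CL plus the threshold — or an
externally flagged observation (shell fragments, soft shell).

## Synthetic population

The simulator emulates a lightly exploited inshore population tagged in
early summer and recovered roughly one or two years later.

Moulting and growth design. Females moult once per year, males once plus a
second time with probability `p(CL) = clamp(2.18 − 0.05·CL, 0, 1)` —
decreasing in size, averaging ≈ 0.5 over the male release range. Each moult
advances the animal along its sex's VBGF envelope by a fixed envelope time
τ: one year for females, `1/(1 + p̄)` years for males (`p̄` the mean
second-moult probability). Two consequences drive everything downstream:

* the population-mean annual growth matches the envelope exactly, so the
  forced Gulland–Holt estimator is consistent in the noise-free limit; and
* one- and two-moult males separate by one moult increment, reproducing the
  bimodal male increment distribution (modes near 3–4.5 and 6–8.5 mm with
  the default parameters) while females stay unimodal.

An alternative design in which each moult jumps to the envelope evaluated
at the *calendar* moult time was rejected: it makes an animal's total
increment depend only on its last moult date, which collapses the male
bimodality and biases `k̂` low by the mean ratio of last-moult time to
liberty time. The `stepped_growth` operation still implements calendar-time
jumps as its default (useful for envelope-tracking trajectories and tested
as such); the simulator passes explicit envelope times. A corollary of the
chosen design is that individual fast-growing males sit above the
population-mean envelope — only the population mean tracks it.

Timing. Moult timing is seasonal via 12 monthly multinomial weights per
sex: wild females peak April–May (post-spawning) and wild males are spread
March–October; the captive-series generator instead uses the holding-tank
pattern (males November–December, females April–May, none in June). An
animal's cycle phase is anchored to its own previous moult, which generally
pre-dates release, so releases made shortly after the moult season carry
almost a full year of accrual. Animals whose next moult falls after
recapture form the zero-growth class that the filter removes.

Sampling design. Releases occur on the study's three actual dates (5 June,
19 June, 17 July); release CLs are uniform on 26.9–40.2 mm (males) and
22.0–44.6 mm (females); liberty is Normal(344, 34) days truncated positive
(the sd back-computed from the reported standard error); recapture CL adds
Gaussian measurement error (default sd 0.1 mm) and is rounded to 0.1 mm.
Catch samples draw from the steady-state density
`f(L) ∝ (L∞ − L)^(Z/k − 1)` on `[L_c, L∞]` by inverse-CDF, which satisfies
the Beverton–Holt relation by construction. Defaults `Z/k = 2` and
`L_c = 25` mm were chosen once because they give a simulated male mean
catch size of 40.3 mm, matching the ~40 mm observed in the study system;
neither value is printed in the source data.

What the generator does *not* emulate: spatial structure, tag loss, tagging
mortality, moult-linked catchability, individual growth variability beyond
the moult-count mechanism, and year-to-year environmental variation.
Passing recovery tests therefore show the estimators are correct under
their own assumptions, not that field estimates are unbiased.

### Known structural biases of the recovery experiment

Two small biases survive in the simulate → estimate round trip and are
worth understanding because real tag-recapture studies share them:

* kept one-moulters release a full envelope-year of growth over a mean
  liberty of only ~344 days, pushing male `k̂` up by ~2–5%;
* unmoulted females that measurement noise nudges past the `ΔL > 0` filter
  contribute near-zero rates, pulling female `k̂` down by ~1–4%.

Both directions mirror the behaviour of single-period versus pooled
estimates in real data. At the test problem sizes (100 000 catch lengths,
5 000 tag returns) both parameters are recovered within 5% for both sexes;
`L∞` is recovered within ~0.3%.

## Conversions

Total length is linear in CL; for increments the intercept cancels, so
`ΔTL = 3.3166·ΔCL`, the through-origin least-squares slope over the seven
published male per-class (ΔCL, ΔTL) pairs. Weight is allometric,
`W = w_a·CL³`, with `w_a = 7.31·10⁻⁴` g mm⁻³ calibrated in closed form so
the mean weight over the tagged release-size distribution equals the
reported 29 g. Both constants are provenance-tagged as derived rather than
measured and are plain configuration — replace them with measured
morphometric parameters when available.

## Numerical choices

* The VBGF envelope uses `expm1`, keeping `L(0) = L0` exact and resolving
  increments at large `k·t`.
* The forced Gulland–Holt slope is the closed-form normal-equation
  solution; tests verify it against an independent grid-plus-parabola
  least-squares search to 1e-9.
* Displayed table values round half away from zero to one decimal
  (`round_display`), matching fisheries-table conventions; all internal
  computation is full precision.
* Date arithmetic uses calendar days; rates annualize by 365.25.
* Determinism: every simulation consumes a single `numpy` Generator seeded
  from the config, and machine-readable outputs are written with sorted
  keys, so identical configurations give byte-identical outputs.

## Problem sizes

The shipped validation uses 100 000 catch lengths and 5 000 tag returns for
parameter recovery, 10 000 draws for distributional equivalence of the
steady-state sampler (against a 100 000-draw rejection oracle, so oracle
noise does not dominate the comparison), and 500–2 000 records for the
behavioural checks — sizes at which the stochastic error of each check is
several times smaller than the tolerance it is checked against.

## Limitations

* The Powell–Wetherall slope-to-parameter map assumes knife-edge, constant
  selection above the recruitment length; dome-shaped selectivity would
  bias `L∞`.
* `Z/k` from the regression is a by-product, not a calibrated mortality
  estimate; no confidence intervals beyond OLS standard errors are
  provided.
* Moult-mode windows are tuned to the male year-1 increment scale; they are
  not meaningful for multi-year liberty periods without rescaling.
* The captive generator reproduces summary behaviour (moult probability,
  timing, small increments), not tank-level dynamics.
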