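# Methods

## Model

All survival computations use the complete linear-quadratic model

    S = exp(−α D − G β D²),   0 < G ≤ 1,

for one treatment fraction of total dose D delivered as n equal
sub-fractions. α [Gy⁻¹] captures lethal single-track damage, β [Gy⁻²] the
pairwise interaction of sublethal lesions, and the Lea–Catcheside factor G
the first-order repair (rate μ = ln 2 / T½ [h⁻¹]) of sublethal damage during
delivery. Standing assumptions, shared by all three G formulations:
mono-exponential repair kinetics, no proliferation or cell-cycle
redistribution over the fraction, radiosensitivity constant in time, and
equal sub-fraction doses with equal spacing. These are reasonable for
in-vitro assays over minutes-to-hours windows; they are the main caveat for
extrapolating to multi-day clinical schedules.

## The three protraction factors

**Incomplete repair (`g_mu`).** Exposures are treated as instantaneous;
repair happens only during the n−1 intervals Δt. With θ = exp(−μΔt),

    G = (2/n²) · [θ/(1−θ)] · [n − (1−θⁿ)/(1−θ)] + 1/n,

equivalently the exhaustive pair sum (1/n²)·Σᵢⱼ θ^|i−j| (used as the test
oracle). Exact limits: G = 1 at Δt = 0 or n = 1; G = 1/n as Δt → ∞.

**Continuous constant-rate (`g_brenner`).** The fraction is one exposure of
duration τ at constant dose rate; interval structure is deliberately
ignored. G = 2(μτ + e^(−μτ) − 1)/(μτ)², the normalized double integral of
e^(−μ(t−t′)) over ordered time pairs in the exposure.

**Pairwise Lea–Catcheside (`g_keall`).** n boxcar exposures of duration τ
separated by radiation-free gaps Δt (start-to-start period τ + Δt). Writing
x = μτ, g_B(x) for the continuous kernel above, and φ = exp(−μ(τ+Δt)),

    G = g_B(x)/n + (4 / (n² x²)) · (cosh x − 1) · Σ_{k=1}^{n−1} (n−k) φᵏ.

This form was re-derived from the defining double integral over the actual
dose-rate profile (the within-exposure term collects same-exposure pairs,
the cosh cross-kernel the geometric sum over exposure pairs) because
published typesettings of it are frequently garbled. Its correctness is
gated on three independent checks rather than on any printed formula: it
equals `g_brenner` exactly at n = 1, converges to `g_mu` as τ → 0, and
matches brute-force numerical integration of the full dose-rate profile to
better than 1e-9.

**Dispatch.** `survival_complete` maps a schedule to each formulation's
arguments: `mu` uses the interval under the scheme's spacing convention,
`keall` uses the beam-on time and the radiation-free gap, and `brenner`
treats the whole fraction as a single continuous exposure spanning the
overall treatment time T — the only reading under which that method responds
to T while remaining invariant to the sub-fraction count, which is exactly
the qualitative behaviour it is meant to exhibit. Single-exposure (n = 1)
schedules are continuous delivery; the study pipeline computes them with the
acute model for every method, since the intermittent-delivery formulations
are not intended for that case.

## Timing conventions

Schedules are described in minutes (doses Gy, dose rate Gy/min, default
0.81 Gy/min, a Co-60 teletherapy rate); repair kinetics in hours. The
conversion happens once, at the `FractionScheme` boundary.

How the interval Δt follows from an "overall treatment time" T is genuinely
ambiguous, so both readings are first-class:

* `start_to_start`: Δt = T/(n−1) — exposure starts are spaced evenly;
  beam-on time is not subtracted;
* `gap`: Δt = (T − nτ)/(n−1) — the radiation-free time between exposures.

The benchmark grid demonstrably mixes them: its two-fraction series is a
split-dose design whose quoted times are the intervals themselves
(start-to-start reproduces those rows to ≤ 0.002 survival units, gap misses
by up to 0.017), while its 4- and 8-sub-fraction rows quote windows that
include beam-on (gap reproduces them to ≤ 0.002, start-to-start misses by up
to 0.014). `build_study_grid(spacing="auto")` therefore applies
start-to-start for n ≤ 2 and gap for n ≥ 4; either uniform convention can be
forced, and the two bracket the ambiguity. Schedules whose exposures would
physically overlap (gap < 0, or start-to-start spacing shorter than the
beam-on time) are rejected at construction.

The study grid covers D ∈ {2, 4, 6} Gy × n ∈ {1, 2, 4, 8}, with
T ∈ {15, 30, 60, 120, 180, 240} min for n = 2 and T ∈ {30, 60, 240} min for
n ∈ {4, 8} (39 schedules). All doses split evenly (the 6 Gy grid uses
4 × 1.5 Gy and 8 × 0.75 Gy; a published description of the 4-fraction arm of
that dose is internally inconsistent, and the even split is the only
self-consistent choice).

## Parameter estimation

`fit_alpha_beta` fits the acute model to survival-vs-dose tables
(canonically 2–10 Gy) in two stages: ordinary least squares on the
linearized form −ln S̄ = αD + βD² through the origin for starting values,
then Levenberg–Marquardt on the survival scale, where the multiplicative
assay noise actually lives. Fits operate on per-condition replicate means —
the natural summary when each condition is a plate of wells repeated across
experiments. The refinement is deliberately unbounded so the degenerate
pure-exponential case (β = 0) returns β̂ ≈ 0 with a finite standard error
instead of sticking to a constraint boundary; non-positive estimates are
flagged through an explicit `status` field, as is non-convergence — a
result is never silently wrong.

`estimate_t_half` fits the one free parameter T½ of the two-fraction
incomplete-repair curve

    S(Δt) = exp(−2αd − (1+θ)/2 · β (2d)²),   θ = exp(−(ln 2/T½) Δt),

to a split-dose recovery series (default d = 2 Gy per fraction; the fraction
size is an explicit argument because published designs do not always state
it), with α and β fixed from the dose-response stage. A survival drop with
increasing interval larger than three standard errors of the replicate mean
is physiologically implausible and sets `status="nonmonotone-data"`; the fit
still runs. Standard errors come from the Jacobian at the optimum
(asymptotic); R² is computed on the survival scale.

## Synthetic data

The generators emulate the *statistical design* of MTT survival experiments,
not the assay itself: per-condition replicates (default 21 = 7 wells × 3
independent experiments) drawn as model value × lognormal factor with exact
mean 1 and coefficient of variation `cv` (default 0.04, the magnitude of the
benchmark's reported ± dispersions), clipped at 1 because survival is a
fraction of control. Lognormal noise keeps survivals positive and mimics the
multiplicative error of absorbance ratios. Deliberately not modelled:
plate-position effects, between-experiment batch shifts, absorbance
nonlinearity, and low-dose hypersensitivity — so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to real-world assay artefacts.

The grid-experiment generator perturbs the incomplete-repair predictions, so
at cv = 0 its "experimental" column equals the theoretical one by
construction and model-comparison machinery can be validated end to end.
Dispersions can be summarized per well (default; matches the magnitude of
the benchmark's ± values) or over the three experiment means.

## Numerical choices

* Series expansions guard the cancellation-prone regions: the continuous
  kernel g_B switches to 1 − x/3 + x²/12 − x³/60 below μτ = 1e-4, the
  (cosh x − 1)/x² cross-kernel to 1/2 + x²/24 below the same threshold (and
  is otherwise computed from `expm1`, which is exact near 0), and `g_mu` to
  its first-order form 1 − μΔt(n²−1)/(3n) below μΔt = 1e-6; 1−θ and 1−θⁿ go
  through `expm1` elsewhere.
* The pairwise cross-term sum Σ(n−k)φᵏ is evaluated directly in O(n) — all
  terms positive, no cancellation — with φᵏ computed as exp(k log φ) so deep
  tails underflow gracefully.
* Monte-Carlo study sizes: parameter-recovery checks use 200 seeds at the
  default replicate structure (seconds of runtime); generator-unbiasedness
  checks use 10⁴ replicates per condition (3-standard-error CLT bands).
  Reports are deterministic: fixed column order, 3-decimal CSV formatting,
  full precision in JSON.

## Limitations

* Single-fraction scope: no multi-day schedules, proliferation, or
  redistribution/reoxygenation; no biologically effective dose summaries.
* Mono-exponential repair only; bi-exponential kinetics would need a second
  rate.
* Equal sub-fraction doses and spacing only.
* Agreement metrics are descriptive (RMSE, maximum deviation, sign counts);
  no inferential testing is attempted on synthetic replicates, which would
  only echo the generator's assumptions back as significance.
* The benchmark's figure-only series (2 and 6 Gy) are exercised through
  qualitative property checks (monotonicity, orderings), not numeric
  reproduction; only the 4 Gy table anchors quantitative agreement.
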