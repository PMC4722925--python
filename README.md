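# lqfrac

Linear-quadratic (LQ) survival modelling for fractionated and protracted
radiotherapy delivery.

Modern delivery techniques (IMRT, gated and stereotactic treatments) split a
single treatment fraction into many beam-on segments and stretch it over tens
of minutes to hours. During that time cells repair sublethal radiation
damage, so the biological effect of the same physical dose shrinks. `lqfrac`
is for radiobiologists and medical physicists who want to quantify that
effect: it predicts cell survival for arbitrary intra-fraction delivery
schedules, estimates the underlying radiobiological parameters from
measurements, and reproduces a published benchmark comparing three competing
models against MTT survival assays of F10B16 melanoma and 4T1 breast
adenocarcinoma cells.

## Model

The complete LQ model for a fraction of total dose *D* is

    S = exp(−αD − G·βD²)

where α [Gy⁻¹] and β [Gy⁻²] are the cell line's LQ coefficients and
G ∈ (0, 1] is the Lea–Catcheside protraction factor, which discounts the
quadratic (sublethal-lesion interaction) term for first-order repair at rate
μ = ln 2 / T½ during delivery. G = 1 recovers the acute model
S = exp(−αD − βD²). For a fraction split into *n* equal sub-fractions the
package implements three formulations of G:

* **incomplete repair** (`mu`) — instantaneous exposures separated by
  intervals Δt; `G = (2/n²)·[θ/(1−θ)]·[n − (1−θⁿ)/(1−θ)] + 1/n` with
  θ = exp(−μΔt);
* **continuous delivery** (`brenner`) — one constant-rate exposure of
  duration τ; `G = 2(μτ + e^(−μτ) − 1)/(μτ)²`, intervals ignored;
* **pairwise Lea–Catcheside** (`keall`) — *n* finite exposures of duration τ
  with radiation-free gaps Δt; within-exposure and cross-exposure lesion
  pairs integrated exactly. It reduces to `brenner` at n = 1 and to `mu` as
  τ → 0.

Bundled parameters (MTT assays, Co-60 at 0.81 Gy/min): F10B16 α = 0.0956,
β = 0.0177, T½ = 0.524 h; 4T1 α = 0.0424, β = 0.0399, T½ = 0.344 h.

## Worked example

Two fractions of 2 Gy separated by 4 hours, compared with the benchmark
measurements:

```python
from lqfrac import (load_reference_cell_lines, make_scheme, survival_complete,
                    load_reference_grid, schemes_from_reference, predict_grid,
                    compare_methods)

lines = load_reference_cell_lines()
scheme = make_scheme(total_dose=4, n_subfractions=2, overall_time=240)
for name, p in lines.items():
    pred = survival_complete(p, scheme, "mu")
    print(f"{name}: G = {pred.g_value:.4f}, S = {pred.survival:.3f}")

ref = load_reference_grid()
grid = predict_grid(schemes_from_reference(ref), lines)
report = compare_methods(grid, ref)
for m, stats in sorted(report["per_method"].items(), key=lambda kv: kv[1]["rmse"]):
    print(f"{m:8s} RMSE = {stats['rmse']:.4f}  max|diff| = {stats['max_abs_diff']:.4f}")
```

prints

```
F10B16: G = 0.5025, S = 0.592
4T1: G = 0.5002, S = 0.613
mu       RMSE = 0.0181  max|diff| = 0.0582
keall    RMSE = 0.0185  max|diff| = 0.0599
brenner  RMSE = 0.0402  max|diff| = 0.1216
basic    RMSE = 0.1103  max|diff| = 0.2283
```

With a 4 h interval almost all sublethal damage is repaired between the two
fractions (G ≈ 1/2, the fully-fractionated limit for n = 2), so survival
rises from 0.514 (acute 4 Gy) to 0.592 for F10B16 and from 0.446 to 0.613
for 4T1 — the larger-β, shorter-T½ 4T1 line gains more from protraction.
Across the whole benchmark the incomplete-repair formulation tracks the
measurements most closely, which is the package's headline model-comparison
result.

The same operations are available from a CLI (`lqfrac predict`, `lqfrac fit`,
`lqfrac simulate`, `lqfrac compare`, `lqfrac reproduce-reference`); run
`lqfrac --help`.

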