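"""Synthetic survival measurements with the structure of MTT plate assays.

The generators emulate the measurement designs the study pipeline consumes —
survival-vs-dose curves, two-fraction split-dose recovery series, and the
full fractionation-grid experiment — without modelling the assay chemistry
itself.  Replicate structure defaults to 7 wells x 3 independent experiments
per condition (21 values); measurement error is multiplicative lognormal with
a configurable coefficient of variation and exact mean 1, so replicate means
are unbiased for the generating model and survivals stay positive.  Values
are clipped at 1.0 by default, since survival is reported as a fraction of
the unirradiated control.

Everything is driven by ``numpy.random.default_rng``: identical seed and
configuration give bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import MeasurementTable
from .schedule import CellLineParams, FractionScheme, ValidationError
from .survival import survival_basic, survival_complete

WELLS_PER_EXPERIMENT = 7
N_EXPERIMENTS = 3


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative measurement-noise configuration.

    cv : coefficient of variation of the lognormal factor (0 = noiseless).
    replicates_per_condition : total wells per condition
        (default 21 = 7 wells x 3 experiments).
    seed : RNG seed; the same seed reproduces the same table bit for bit.
    clip : clip generated survivals at 1.0 (fractions of control).
    """

    cv: float = 0.04
    replicates_per_condition: int = WELLS_PER_EXPERIMENT * N_EXPERIMENTS
    seed: int | None = None
    clip: bool = True

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValidationError(f"cv must be >= 0, got {self.cv}")
        if self.replicates_per_condition < 1:
            raise ValidationError("replicates_per_condition must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def factors(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Lognormal factors with mean exactly 1 and sd ``cv`` (small-cv)."""
        if self.cv == 0:
            return np.ones(size)
        sigma2 = math.log1p(self.cv**2)
        return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def _draw_condition(model_value: float, noise: NoiseModel,
                    rng: np.random.Generator) -> tuple[float, ...]:
    vals = model_value * noise.factors(rng, noise.replicates_per_condition)
    if noise.clip:
        vals = np.minimum(vals, 1.0)
    return tuple(float(v) for v in vals)


def simulate_dose_response(params: CellLineParams, doses, noise: NoiseModel
                           ) -> MeasurementTable:
    """Replicated survival-vs-dose table around the acute LQ model.

    ``doses`` in Gy (the canonical design is 2, 4, 6, 8, 10 Gy).  Each
    condition holds ``noise.replicates_per_condition`` draws of
    ``survival_basic(D)`` times a lognormal factor.
    """
    doses = [float(d) for d in doses]
    if not doses or any(d <= 0 for d in doses):
        raise ValidationError("doses must be a non-empty list of positive values")
    rng = noise.rng()
    reps = tuple(
        _draw_condition(survival_basic(params, d), noise, rng) for d in doses
    )
    return MeasurementTable(
        kind="dose_response", x=tuple(doses), replicates=reps,
        meta={"cell_line": params.name},
    )


def simulate_split_dose(params: CellLineParams, d: float, intervals, noise: NoiseModel
                        ) -> MeasurementTable:
    """Two-fraction split-dose recovery series.

    Two instantaneous fractions of ``d`` Gy separated by each interval
    (minutes); the generating curve is the n=2 incomplete-repair model, the
    same curve :func:`lqfrac.fitting.estimate_t_half` fits, so a noiseless
    round-trip recovers ``params.t_half`` exactly.
    """
    if d <= 0:
        raise ValidationError(f"d must be > 0, got {d}")
    intervals = [float(t) for t in intervals]
    if not intervals or any(t < 0 for t in intervals):
        raise ValidationError("intervals must be non-empty and >= 0 (minutes)")
    rng = noise.rng()
    mu = params.mu
    reps = []
    for dt_min in intervals:
        theta = math.exp(-mu * dt_min / 60.0)
        g = (1.0 + theta) / 2.0
        total = 2.0 * d
        s = math.exp(-params.alpha * total - g * params.beta * total * total)
        reps.append(_draw_condition(s, noise, rng))
    return MeasurementTable(
        kind="split_dose", x=tuple(intervals), replicates=tuple(reps),
        meta={"cell_line": params.name, "dose_per_fraction": d, "n_fractions": 2},
    )


def simulate_grid_experiment(
    params_by_line: dict[str, CellLineParams],
    schemes: list[FractionScheme],
    noise: NoiseModel,
    aggregate: str = "wells",
) -> pd.DataFrame:
    """Emulated experimental column for a schedule grid.

    For every (cell line, scheme) pair the incomplete-repair prediction is
    perturbed by the noise model and summarized as mean +/- SD, formatted like
    a fractionation-experiment report.  ``aggregate`` picks the dispersion:
    ``"wells"`` takes the SD over all replicates, ``"experiments"`` over the
    per-experiment means (7 wells per experiment).

    One fraction of the total RNG stream per condition, in deterministic
    (cell line, scheme) order, so a fixed seed reproduces the grid exactly.
    """
    if aggregate not in ("wells", "experiments"):
        raise ValidationError(f"aggregate must be 'wells' or 'experiments', got {aggregate!r}")
    rng = noise.rng()
    rows = []
    for name in sorted(params_by_line):
        params = params_by_line[name]
        for scheme in schemes:
            method = "mu" if scheme.n_subfractions >= 2 else "basic"
            pred = survival_complete(params, scheme, method)
            vals = np.asarray(_draw_condition(pred.survival, noise, rng))
            if aggregate == "experiments" and len(vals) % WELLS_PER_EXPERIMENT == 0:
                means = vals.reshape(-1, WELLS_PER_EXPERIMENT).mean(axis=1)
            else:
                means = vals
            sd = float(np.std(means, ddof=1)) if len(means) > 1 else 0.0
            rows.append({
                "cell_line": name,
                "n_subfractions": scheme.n_subfractions,
                "dose_per_subfraction": scheme.dose_per_subfraction,
                "total_dose": scheme.total_dose,
                "overall_time": scheme.overall_time,
                "method": method,
                "g_value": pred.g_value,
                "survival": pred.survival,
                "experimental_mean": float(np.mean(vals)),
                "experimental_sd": sd,
            })
    df = pd.DataFrame(rows)
    df["abs_diff"] = (df["survival"] - df["experimental_mean"]).abs()
    return df
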