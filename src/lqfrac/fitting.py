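"""Derivation of LQ parameters from survival measurements.

Two estimation stages populate a cell line's parameter record:

1. ``fit_alpha_beta`` — alpha [Gy^-1] and beta [Gy^-2] from a survival-vs-dose
   table via the acute LQ model S = exp(-alpha*D - beta*D**2).
2. ``estimate_t_half`` — the sublethal-repair half-time T1/2 [h] from a
   two-fraction split-dose recovery series, holding alpha/beta fixed.

Both use a linearized start followed by nonlinear least-squares refinement on
the survival scale, fitting per-condition replicate means (the natural summary
when each condition is a handful of wells repeated across experiments).
Standard errors come from the Jacobian at the optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .schedule import ValidationError

TABLE_KINDS = ("dose_response", "split_dose")


class InsufficientDataError(ValidationError):
    """Too few distinct conditions to identify the requested parameters."""


@dataclass(frozen=True)
class MeasurementTable:
    """Replicated survival-fraction observations keyed by dose or interval.

    ``x`` holds the per-condition covariate: dose [Gy] for
    ``kind="dose_response"``, inter-fraction interval [min] for
    ``kind="split_dose"``.  Survival values are fractions of the unirradiated
    control, so a dose-response table implicitly passes through (0, 1).
    """

    kind: str
    x: tuple[float, ...]
    replicates: tuple[tuple[float, ...], ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TABLE_KINDS:
            raise ValidationError(f"kind must be one of {TABLE_KINDS}, got {self.kind!r}")
        if len(self.x) != len(self.replicates):
            raise ValidationError("x and replicates must have equal length")
        for xi, reps in zip(self.x, self.replicates):
            if xi < 0:
                raise ValidationError(f"condition value must be >= 0, got {xi}")
            if len(reps) < 1:
                raise ValidationError(f"condition x={xi} has no replicates")
            for s in reps:
                if not (0.0 < s <= 1.0):
                    raise ValidationError(
                        f"survival values must lie in (0, 1], got {s} at x={xi}"
                    )

    @property
    def means(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.replicates])

    @property
    def sds(self) -> np.ndarray:
        return np.array([float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
                         for r in self.replicates])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"condition_x": xi, "replicate_id": j, "survival": s}
            for xi, reps in zip(self.x, self.replicates)
            for j, s in enumerate(reps)
        ]
        return pd.DataFrame(rows, columns=["condition_x", "replicate_id", "survival"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str, meta: dict | None = None
                   ) -> "MeasurementTable":
        required = {"condition_x", "replicate_id", "survival"}
        if not required.issubset(df.columns):
            raise ValidationError(f"table must have columns {sorted(required)}")
        xs, reps = [], []
        for xi, grp in df.groupby("condition_x", sort=True):
            xs.append(float(xi))
            reps.append(tuple(float(s) for s in grp["survival"]))
        return cls(kind=kind, x=tuple(xs), replicates=tuple(reps), meta=meta or {})

    @classmethod
    def from_csv(cls, path: str, kind: str, meta: dict | None = None
                 ) -> "MeasurementTable":
        return cls.from_frame(pd.read_csv(path), kind=kind, meta=meta)


@dataclass(frozen=True)
class FitResult:
    """Point estimates with asymptotic uncertainties and fit diagnostics.

    ``status`` is ``"converged"`` on success; any other value (e.g.
    ``"failed"``, ``"nonpositive-estimate"``, ``"nonmonotone-data"``) flags a
    problem explicitly — downstream code must never have to guess whether a
    fit silently went wrong.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    r_squared: float
    residuals: tuple[float, ...]
    status: str = "converged"
    message: str = ""

    @property
    def converged(self) -> bool:
        return self.status != "failed"

    def to_dict(self) -> dict:
        return {
            "estimates": dict(self.estimates),
            "standard_errors": dict(self.standard_errors),
            "r_squared": self.r_squared,
            "status": self.status,
        }


def _r_squared(observed: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - fitted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_alpha_beta(table: MeasurementTable) -> FitResult:
    """Fit alpha and beta to a dose-response table.

    Stage 1 solves the linearized model -ln(S_mean) = alpha*D + beta*D**2
    through the origin by ordinary least squares; stage 2 refines both
    parameters by Levenberg-Marquardt on the survival scale, where the
    measurement noise actually lives.
    """
    if table.kind != "dose_response":
        raise ValidationError(f"expected a dose_response table, got {table.kind!r}")
    doses = np.asarray(table.x, dtype=float)
    if np.count_nonzero(doses > 0) < 3 or len(np.unique(doses[doses > 0])) < 3:
        raise InsufficientDataError("need >= 3 distinct positive doses to fit alpha/beta")
    s_mean = table.means

    design = np.column_stack([doses, doses**2])
    coef, *_ = np.linalg.lstsq(design, -np.log(s_mean), rcond=None)
    p0 = [max(coef[0], 1e-8), max(coef[1], 1e-8)]

    def model(d, a, b):
        return np.exp(-a * d - b * d * d)

    try:
        popt, pcov = curve_fit(model, doses, s_mean, p0=p0, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - hard to trigger with valid data
        return FitResult(
            estimates={"alpha": float("nan"), "beta": float("nan")},
            standard_errors={"alpha": float("nan"), "beta": float("nan")},
            r_squared=float("nan"),
            residuals=(),
            status="failed",
            message=str(exc),
        )
    fitted = model(doses, *popt)
    ses = np.sqrt(np.diag(pcov))
    status = "converged"
    if popt[0] <= 0 or popt[1] < 0:
        status = "nonpositive-estimate"
    return FitResult(
        estimates={"alpha": float(popt[0]), "beta": float(popt[1])},
        standard_errors={"alpha": float(ses[0]), "beta": float(ses[1])},
        r_squared=_r_squared(s_mean, fitted),
        residuals=tuple(float(r) for r in (s_mean - fitted)),
        status=status,
    )


def split_dose_survival(delta_t_min, alpha: float, beta: float, d: float,
                        t_half: float):
    """Two-fraction incomplete-repair survival curve used for T1/2 estimation.

    S(dt) = exp(-2*alpha*d - (1 + theta)/2 * beta * (2d)**2),
    theta = exp(-ln2/t_half * dt) — the n=2 incomplete-repair G applied to the
    total dose 2d.  ``delta_t_min`` in minutes, ``t_half`` in hours.
    """
    dt_h = np.asarray(delta_t_min, dtype=float) / 60.0
    theta = np.exp(-math.log(2.0) / t_half * dt_h)
    g = (1.0 + theta) / 2.0
    total = 2.0 * d
    return np.exp(-alpha * total - g * beta * total * total)


def estimate_t_half(table: MeasurementTable, alpha: float, beta: float,
                    d: float = 2.0) -> FitResult:
    """Estimate the repair half-time from a split-dose recovery series.

    The design is two equal fractions of ``d`` Gy separated by the measured
    interval (minutes).  Only T1/2 is free; alpha and beta are taken from the
    dose-response stage.  Survival should rise with the interval as sublethal
    damage from the first fraction is repaired; a decline larger than the
    replicate scatter is flagged (``status="nonmonotone-data"``) but the fit
    still runs.
    """
    if table.kind != "split_dose":
        raise ValidationError(f"expected a split_dose table, got {table.kind!r}")
    if alpha <= 0 or beta <= 0 or d <= 0:
        raise ValidationError("alpha, beta and d must be strictly positive")
    intervals = np.asarray(table.x, dtype=float)
    if len(np.unique(intervals)) < 3:
        raise InsufficientDataError("need >= 3 distinct intervals to estimate t_half")
    s_mean = table.means

    status = "converged"
    order = np.argsort(intervals)
    drops = np.diff(s_mean[order])
    counts = np.array([len(r) for r in table.replicates], dtype=float)[order][1:]
    sem = table.sds[order][1:] / np.sqrt(counts)
    if np.any(drops < -(3.0 * sem + 1e-12)):
        status = "nonmonotone-data"

    def model(dt_min, t_half):
        return split_dose_survival(dt_min, alpha, beta, d, t_half)

    try:
        popt, pcov = curve_fit(model, intervals, s_mean, p0=[0.5], maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover
        return FitResult(
            estimates={"t_half": float("nan")},
            standard_errors={"t_half": float("nan")},
            r_squared=float("nan"),
            residuals=(),
            status="failed",
            message=str(exc),
        )
    fitted = model(intervals, *popt)
    se = float(np.sqrt(pcov[0, 0]))
    if popt[0] <= 0:
        status = "nonpositive-estimate"
    return FitResult(
        estimates={"t_half": float(popt[0])},
        standard_errors={"t_half": se},
        r_squared=_r_squared(s_mean, fitted),
        residuals=tuple(float(r) for r in (s_mean - fitted)),
        status=status,
    )
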