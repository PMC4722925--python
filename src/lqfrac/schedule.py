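"""Cell-line radiobiological parameters and intra-fraction delivery schedules.

A treatment *fraction* may be delivered as ``n`` equal sub-fractions (beam-on
segments), as happens segment-by-segment in IMRT or gated delivery.  The
survival models need three timing quantities per schedule: the repair rate
constant mu (h^-1), the beam-on time per sub-fraction tau, and the
inter-sub-fraction interval delta_t.

Two unit systems coexist: schedule descriptions use minutes and Gy/min (how
treatment times are quoted clinically), while repair kinetics use hours (how
sublethal-repair half-times are quoted).  The conversion happens exactly once,
through the ``*_h`` properties; model code only ever sees hours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any

MIN_PER_HOUR = 60.0

#: How the inter-sub-fraction interval is derived from the overall time T
#: (start of first exposure to delivery of the last):
#:   start_to_start -- delta_t = T / (n - 1): interval between exposure starts,
#:                     beam-on time not subtracted (exposures treated as points);
#:   gap            -- delta_t = (T - n * tau) / (n - 1): radiation-free time
#:                     between the end of one exposure and the start of the next.
SPACING_CONVENTIONS = ("start_to_start", "gap")


class ValidationError(ValueError):
    """A parameter or schedule field violates its physical constraints."""


class InfeasibleScheduleError(ValidationError):
    """The requested exposures cannot fit in the requested overall time."""


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not (value > 0) or not math.isfinite(value):
            raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class CellLineParams:
    """Linear-quadratic parameters of one cell line.

    Attributes
    ----------
    name : str
        Cell-line label, e.g. ``"F10B16"``.
    alpha : float
        Linear LQ coefficient [Gy^-1] (lethal single-track damage).
    beta : float
        Quadratic LQ coefficient [Gy^-2] (pairwise sublethal-lesion interaction).
    t_half : float
        Sublethal-damage repair half-time [h].
    """

    name: str
    alpha: float
    beta: float
    t_half: float

    def __post_init__(self) -> None:
        _require_positive(alpha=self.alpha, beta=self.beta, t_half=self.t_half)

    @property
    def mu(self) -> float:
        """First-order repair rate constant [h^-1], ln(2) / t_half."""
        return math.log(2.0) / self.t_half

    @property
    def alpha_beta_ratio(self) -> float:
        """alpha/beta [Gy]; low values indicate strong repair capacity."""
        return self.alpha / self.beta

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "alpha": self.alpha,
            "beta": self.beta,
            "t_half_h": self.t_half,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CellLineParams":
        return cls(
            name=d["name"],
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            t_half=float(d["t_half_h"]),
        )


def make_cell_params(name: str, alpha: float, beta: float, t_half: float) -> CellLineParams:
    """Validate and build a :class:`CellLineParams` record.

    Parameters are as for :class:`CellLineParams`; ``t_half`` in hours.
    The repair rate ``mu`` is derived, never stored, so it can never drift
    out of sync with ``t_half``.
    """
    return CellLineParams(name=name, alpha=alpha, beta=beta, t_half=t_half)


@dataclass(frozen=True)
class FractionScheme:
    """One treatment fraction delivered as ``n`` equal sub-fractions.

    ``overall_time`` runs from the start of the first exposure to the delivery
    of the last; how the interval ``delta_t`` follows from it depends on
    ``spacing`` (see :data:`SPACING_CONVENTIONS`).

    Derived quantities (``dose_per_subfraction``, ``tau``, ``delta_t``) are
    properties so the stored state is exactly the user-facing description.
    """

    total_dose: float                      # D [Gy]
    n_subfractions: int                    # n >= 1
    overall_time: float                    # T [min]
    dose_rate: float = 0.81                # r [Gy/min]
    spacing: str = "start_to_start"

    def __post_init__(self) -> None:
        _require_positive(
            total_dose=self.total_dose,
            overall_time=self.overall_time,
            dose_rate=self.dose_rate,
        )
        if not isinstance(self.n_subfractions, int) or self.n_subfractions < 1:
            raise ValidationError(
                f"n_subfractions must be an integer >= 1, got {self.n_subfractions!r}"
            )
        if self.spacing not in SPACING_CONVENTIONS:
            raise ValidationError(
                f"spacing must be one of {SPACING_CONVENTIONS}, got {self.spacing!r}"
            )
        n, tau = self.n_subfractions, self.tau
        # tolerance absorbs rounded schedule descriptions such as "4 Gy in 5 min"
        # at 0.81 Gy/min, where beam-on is 4.938 min
        if n == 1:
            if self.overall_time < tau * (1.0 - 1e-9) - 1e-9:
                raise InfeasibleScheduleError(
                    f"single exposure of {tau:.3f} min cannot fit in "
                    f"{self.overall_time:.3f} min"
                )
        elif self.spacing == "gap":
            if self.delta_t < -1e-9:
                raise InfeasibleScheduleError(
                    f"{n} exposures of {tau:.3f} min beam-on do not fit in "
                    f"{self.overall_time:.3f} min"
                )
        else:  # start_to_start: exposures overlap when starts are < tau apart
            if self.delta_t < tau * (1.0 - 1e-9):
                raise InfeasibleScheduleError(
                    f"start-to-start interval {self.delta_t:.3f} min is shorter "
                    f"than the beam-on time {tau:.3f} min"
                )

    # -- derived dose/timing quantities (minutes at this surface) ------------

    @property
    def dose_per_subfraction(self) -> float:
        """d = D / n [Gy]."""
        return self.total_dose / self.n_subfractions

    @property
    def tau(self) -> float:
        """Beam-on time per sub-fraction, tau = d / r [min]."""
        return self.dose_per_subfraction / self.dose_rate

    @property
    def delta_t(self) -> float:
        """Inter-sub-fraction interval [min] under the stored convention.

        Zero for ``n == 1`` (no interval exists).
        """
        n = self.n_subfractions
        if n == 1:
            return 0.0
        if self.spacing == "start_to_start":
            return self.overall_time / (n - 1)
        return (self.overall_time - n * self.tau) / (n - 1)

    @property
    def gap(self) -> float:
        """Radiation-free time between consecutive exposures [min].

        What an exposure-duration-aware model (the Lea-Catcheside pairwise
        form) needs: ``delta_t`` itself under the gap convention, and
        ``delta_t - tau`` start-to-start.  Clipped to zero for rounding-level
        negatives.
        """
        if self.n_subfractions == 1:
            return 0.0
        if self.spacing == "gap":
            return max(self.delta_t, 0.0)
        return max(self.delta_t - self.tau, 0.0)

    # -- hour-denominated views consumed by the survival models --------------

    @property
    def tau_h(self) -> float:
        return self.tau / MIN_PER_HOUR

    @property
    def delta_t_h(self) -> float:
        return self.delta_t / MIN_PER_HOUR

    @property
    def gap_h(self) -> float:
        return self.gap / MIN_PER_HOUR

    @property
    def overall_time_h(self) -> float:
        return self.overall_time / MIN_PER_HOUR

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "total_dose_gy": self.total_dose,
            "n_subfractions": self.n_subfractions,
            "overall_time_min": self.overall_time,
            "dose_rate_gy_per_min": self.dose_rate,
            "spacing": self.spacing,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "FractionScheme":
        return cls(
            total_dose=float(d["total_dose_gy"]),
            n_subfractions=int(d["n_subfractions"]),
            overall_time=float(d["overall_time_min"]),
            dose_rate=float(d.get("dose_rate_gy_per_min", 0.81)),
            spacing=str(d.get("spacing", "start_to_start")),
        )


def make_scheme(
    total_dose: float,
    n_subfractions: int,
    overall_time: float,
    dose_rate: float = 0.81,
    spacing: str = "start_to_start",
) -> FractionScheme:
    """Validate and build a :class:`FractionScheme`.

    Raises
    ------
    ValidationError
        On non-positive doses/times or an unknown spacing convention.
    InfeasibleScheduleError
        When the beam-on segments physically overlap (total exposure time
        exceeds the overall time under the gap convention, or
        ``delta_t < tau`` start-to-start).
    """
    return FractionScheme(
        total_dose=total_dose,
        n_subfractions=n_subfractions,
        overall_time=overall_time,
        dose_rate=dose_rate,
        spacing=spacing,
    )


def load_cell_params_json(path: str) -> CellLineParams:
    with open(path) as fh:
        return CellLineParams.from_dict(json.load(fh))


def load_scheme_json(path: str) -> FractionScheme:
    with open(path) as fh:
        return FractionScheme.from_dict(json.load(fh))
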