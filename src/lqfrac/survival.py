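"""Protraction (G) factors and the complete linear-quadratic survival model.

The complete LQ model for a fraction of total dose D delivered over a finite
time is

    S = exp(-alpha * D - G * beta * D**2),

where the dimensionless Lea-Catcheside factor G in (0, 1] discounts the
quadratic (sublethal-lesion interaction) term for first-order repair, rate
``mu``, occurring during protracted or split delivery.  G = 1 recovers the
basic acute-exposure model.

Three formulations of G for a fraction split into ``n`` equal sub-fractions
are implemented, named after the delivery feature each resolves:

``g_mu``
    Incomplete-repair form: exposures are instantaneous, repair happens only
    in the intervals ``delta_t`` between them,

        G = (2/n**2) * [th/(1-th)] * [n - (1-th**n)/(1-th)] + 1/n,
        th = exp(-mu*delta_t).

``g_brenner``
    Continuous constant-rate delivery over a single exposure of duration
    ``tau``; intervals are ignored,

        G = 2*(mu*tau + exp(-mu*tau) - 1) / (mu*tau)**2.

``g_keall``
    Full pairwise form: n exposures of duration ``tau`` at constant dose rate,
    separated by radiation-free gaps ``delta_t``; reduces exactly to
    ``g_brenner`` at n=1 and to ``g_mu`` as tau -> 0.

All rates are per hour and all times in hours; callers working from schedules
should pass the ``*_h`` properties of :class:`~lqfrac.schedule.FractionScheme`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .schedule import CellLineParams, FractionScheme, ValidationError

METHODS = ("basic", "mu", "brenner", "keall")

# below these arguments the closed forms lose digits to cancellation and a
# truncated series (error < 1e-16 at the threshold) takes over
_SMALL_MU_TAU = 1e-4
_SMALL_MU_DT = 1e-6


@dataclass(frozen=True)
class SurvivalPrediction:
    """One (scheme, cell line, method) survival computation."""

    method: str
    g_value: float
    survival: float
    scheme: FractionScheme
    cell_line: str


def _check_domain(**nonneg: float) -> None:
    for name, value in nonneg.items():
        if value < 0 or not math.isfinite(value):
            raise ValidationError(f"{name} must be non-negative and finite, got {value!r}")


def _continuous_kernel(x: float) -> float:
    """g_B(x) = 2*(x - 1 + exp(-x)) / x**2, the single-exposure G."""
    if x < _SMALL_MU_TAU:
        # 1 - x/3 + x^2/12 - x^3/60 + O(x^4)
        return 1.0 - x / 3.0 + x * x / 12.0 - x * x * x / 60.0
    return 2.0 * (x - 1.0 + math.exp(-x)) / (x * x)


def _coshm1_over_x2(x: float) -> float:
    """(cosh(x) - 1) / x**2 without cancellation; -> 1/2 as x -> 0."""
    if x < _SMALL_MU_TAU:
        return 0.5 + x * x / 24.0
    return 0.5 * (math.expm1(x) + math.expm1(-x)) / (x * x)


def _lagged_weight_sum(n: int, log_q: float) -> float:
    """sum_{k=1}^{n-1} (n - k) * q**k for q = exp(log_q), log_q <= 0.

    Direct O(n) summation: every term is positive, so there is no
    cancellation for q arbitrarily close to 1.  q**k goes through the log to
    keep large-n tails from underflowing multiplicatively.
    """
    total = 0.0
    for k in range(1, n):
        total += (n - k) * math.exp(k * log_q)
    return total


def g_mu(mu: float, n: int, delta_t: float) -> float:
    """Incomplete-repair G for ``n`` instantaneous doses ``delta_t`` hours apart.

    Assumes no repair during beam-on.  Exact limits: 1 at ``n == 1`` or
    ``delta_t == 0`` (the doses merge into one acute exposure) and ``1/n`` as
    ``delta_t -> inf`` (fully repaired, independent sub-fractions).
    """
    if not isinstance(n, int) or n < 1:
        raise ValidationError(f"n must be an integer >= 1, got {n!r}")
    _check_domain(mu=mu, delta_t=delta_t)
    if mu == 0:
        raise ValidationError("mu must be strictly positive")
    if n == 1:
        return 1.0
    x = mu * delta_t
    if x < _SMALL_MU_DT:
        # theta -> 1: G = 1 - x*(n**2 - 1)/(3n) + O(x**2)
        return 1.0 - x * (n * n - 1.0) / (3.0 * n)
    theta = math.exp(-x)
    one_minus_theta = -math.expm1(-x)
    one_minus_theta_n = -math.expm1(-n * x)
    bracket = n - one_minus_theta_n / one_minus_theta
    return (2.0 / (n * n)) * (theta / one_minus_theta) * bracket + 1.0 / n


def g_brenner(mu: float, tau: float) -> float:
    """Constant-dose-rate G for one continuous exposure of ``tau`` hours.

    Equals the normalized double integral of exp(-mu*(t - t')) over ordered
    time pairs within the exposure.  Interval structure between sub-fractions
    is deliberately ignored by this formulation.
    """
    _check_domain(mu=mu, tau=tau)
    if mu == 0:
        raise ValidationError("mu must be strictly positive")
    return _continuous_kernel(mu * tau)


def g_keall(mu: float, n: int, tau: float, delta_t: float) -> float:
    """Pairwise Lea-Catcheside G for ``n`` constant-rate exposures.

    Each exposure lasts ``tau`` hours; consecutive exposures are separated by
    a radiation-free gap ``delta_t`` hours, so exposure starts repeat with
    period ``tau + delta_t``.  With ``x = mu*tau`` and
    ``phi = exp(-mu*(tau + delta_t))``:

        G = g_B(x)/n
            + (4 / (n**2 * x**2)) * (cosh(x) - 1) * sum_{k=1}^{n-1} (n-k) phi**k

    The first term collects within-exposure lesion pairs, the second term
    cross-exposure pairs.  For ``n == 1`` it is exactly :func:`g_brenner`; as
    ``tau -> 0`` it converges to :func:`g_mu`.  ``tau == 0`` is routed to
    :func:`g_mu` directly since the per-exposure kernel is a 0/0 form there.
    """
    if not isinstance(n, int) or n < 1:
        raise ValidationError(f"n must be an integer >= 1, got {n!r}")
    _check_domain(mu=mu, tau=tau, delta_t=delta_t)
    if mu == 0:
        raise ValidationError("mu must be strictly positive")
    if tau == 0:
        return g_mu(mu, n, delta_t)
    x = mu * tau
    within = _continuous_kernel(x) / n
    if n == 1:
        return within
    log_phi = -mu * (tau + delta_t)
    cross = (4.0 / (n * n)) * _coshm1_over_x2(x) * _lagged_weight_sum(n, log_phi)
    return within + cross


def survival_basic(params: CellLineParams, total_dose: float) -> float:
    """Acute-exposure LQ survival, S = exp(-alpha*D - beta*D**2)."""
    _check_domain(total_dose=total_dose)
    return math.exp(-params.alpha * total_dose - params.beta * total_dose**2)


def _g_for(params: CellLineParams, scheme: FractionScheme, method: str) -> float:
    n = scheme.n_subfractions
    if method == "basic":
        return 1.0
    if method == "mu":
        # n == 1 degenerates to a single acute dose: G = 1 by the model's
        # own Delta_t -> 0 limit
        return g_mu(params.mu, n, scheme.delta_t_h) if n >= 2 else 1.0
    if method == "brenner":
        # intervals ignored: the whole fraction is treated as one continuous
        # exposure spanning the overall treatment time, so G responds to T
        # but not to n
        return g_brenner(params.mu, scheme.overall_time_h)
    if method == "keall":
        return g_keall(params.mu, n, scheme.tau_h, scheme.gap_h)
    raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")


def survival_complete(
    params: CellLineParams, scheme: FractionScheme, method: str
) -> SurvivalPrediction:
    """Complete-LQ survival for a scheme under one G-factor formulation.

    Dispatches to the matching G computation using the scheme's derived
    timing quantities (``mu`` from the cell line, ``n``, ``tau``, ``delta_t``)
    and returns both G and S.  ``method="basic"`` ignores timing entirely.
    """
    g = _g_for(params, scheme, method)
    d = scheme.total_dose
    s = math.exp(-params.alpha * d - g * params.beta * d * d)
    return SurvivalPrediction(
        method=method, g_value=g, survival=s, scheme=scheme, cell_line=params.name
    )
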