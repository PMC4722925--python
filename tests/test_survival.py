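"""G-factor formulations: limits, oracles, equivalences, and survival values."""

import math

import numpy as np
import pytest
from scipy.integrate import dblquad

from lqfrac import (
    ValidationError,
    g_brenner,
    g_keall,
    g_mu,
    make_cell_params,
    make_scheme,
    survival_basic,
    survival_complete,
)

MU_F10B16 = math.log(2) / 0.524


def pairwise_theta_sum(mu, n, delta_t):
    """Brute-force incomplete-repair G: (1/n^2) sum_ij theta^|i-j|."""
    theta = math.exp(-mu * delta_t)
    return sum(theta ** abs(i - j) for i in range(n) for j in range(n)) / n**2


def lea_catcheside_numeric(mu, n, tau, gap):
    """Full Lea-Catcheside G by numerical double integration over the
    actual dose-rate profile: n boxcar exposures of length tau separated by
    radiation-free gaps.  Independent of any closed form."""
    period = tau + gap
    starts = [k * period for k in range(n)]
    d = 1.0 / n
    rate = d / tau
    total = 0.0
    for i in range(n):
        # within-exposure ordered pairs
        v, _ = dblquad(
            lambda tp, t: rate * rate * math.exp(-mu * (t - tp)),
            starts[i], starts[i] + tau, lambda t: starts[i], lambda t: t,
            epsabs=1e-13, epsrel=1e-12,
        )
        total += 2 * v
        for j in range(i):
            v, _ = dblquad(
                lambda tp, t: rate * rate * math.exp(-mu * (t - tp)),
                starts[i], starts[i] + tau,
                lambda t: starts[j], lambda t: starts[j] + tau,
                epsabs=1e-13, epsrel=1e-12,
            )
            total += 2 * v
    return total


class TestLimits:
    def test_single_fraction_and_zero_interval_give_unity(self):
        assert g_mu(1.3, 1, 5.0) == 1.0
        assert g_mu(1.3, 2, 0.0) == pytest.approx(1.0, abs=1e-9)
        assert g_mu(2.0, 7, 1e-12) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 3, 8, 16])
    def test_fully_repaired_subfractions_give_one_over_n(self, n):
        assert g_mu(1.3, n, 1e4) == pytest.approx(1.0 / n, abs=1e-9)

    def test_acute_exposure_limit_of_continuous_kernel(self):
        assert g_brenner(1.3, 0.0) == pytest.approx(1.0, abs=1e-9)
        assert g_brenner(1.0, 1e-9) == pytest.approx(1.0, abs=1e-9)

    def test_zero_dose_survives_fully(self, f10b16):
        assert survival_basic(f10b16, 0.0) == 1.0


class TestGMu:
    def test_two_fraction_closed_form(self):
        # n=2 reduces to (1 + theta)/2 with theta = exp(-mu*dt)
        g = g_mu(MU_F10B16, 2, 4.0)
        assert g == pytest.approx((1 + math.exp(-MU_F10B16 * 4.0)) / 2, abs=1e-12)
        assert g == pytest.approx(0.50252, abs=1e-5)

    def test_matches_pairwise_sum_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            mu = rng.uniform(0.3, 3.0)
            n = int(rng.integers(1, 17))
            dt = rng.uniform(0.0, 8.0)
            assert g_mu(mu, n, dt) == pytest.approx(
                pairwise_theta_sum(mu, n, dt), abs=1e-10)

    def test_strictly_decreasing_in_interval(self):
        gs = [g_mu(MU_F10B16, 4, dt) for dt in np.linspace(0.01, 6, 40)]
        assert all(b < a for a, b in zip(gs, gs[1:]))

    def test_invalid_count_rejected(self):
        with pytest.raises(ValidationError):
            g_mu(1.0, 0, 1.0)


class TestGBrenner:
    def test_matches_double_integral_quadrature(self):
        for x in np.logspace(-3, math.log10(30), 12):
            mu, tau = 1.0, float(x)
            v, _ = dblquad(
                lambda tp, t: math.exp(-mu * (t - tp)),
                0, tau, 0, lambda t: t, epsabs=1e-13, epsrel=1e-12,
            )
            assert g_brenner(mu, tau) == pytest.approx(2 * v / tau**2, abs=1e-8)

    def test_large_argument_expansion(self):
        # G -> 2(x-1)/x^2 for large x
        assert g_brenner(1.0, 20.0) == pytest.approx(2 / 20 - 2 / 400, abs=1e-8)

    def test_negative_exposure_time_rejected(self):
        with pytest.raises(ValidationError):
            g_brenner(1.0, -0.1)


class TestGKeall:
    def test_single_exposure_equals_continuous_kernel(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mu = rng.uniform(0.3, 3.0)
            tau = rng.uniform(1e-4, 2.0)
            assert g_keall(mu, 1, tau, 0.0) == pytest.approx(
                g_brenner(mu, tau), abs=1e-9)

    def test_instantaneous_exposure_limit_recovers_incomplete_repair(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            mu = rng.uniform(0.3, 3.0)
            n = int(rng.integers(2, 9))
            dt = rng.uniform(0.0, 6.0)
            assert g_keall(mu, n, 1e-6, dt) == pytest.approx(
                g_mu(mu, n, dt), abs=1e-4)

    def test_zero_exposure_time_routes_to_incomplete_repair(self):
        assert g_keall(1.3, 4, 0.0, 2.0) == g_mu(1.3, 4, 2.0)

    @pytest.mark.parametrize("n,tau,gap", [(2, 0.0823, 0.5), (3, 0.0823, 0.5),
                                           (4, 0.02, 1.0), (2, 0.3, 0.05)])
    def test_matches_numerical_lea_catcheside_integral(self, n, tau, gap):
        assert g_keall(MU_F10B16, n, tau, gap) == pytest.approx(
            lea_catcheside_numeric(MU_F10B16, n, tau, gap), abs=1e-9)

    def test_long_intervals_leave_only_within_exposure_term(self):
        mu, n, tau = 1.32280, 2, 0.0823
        assert g_keall(mu, n, tau, 1e3) == pytest.approx(
            g_brenner(mu, tau) / n, abs=1e-12)


class TestSurvival:
    def test_acute_survival_matches_published_single_exposure_values(self, f10b16, t4t1):
        # published to 3 decimals from rounded inputs: 0.513 and 0.445
        assert survival_basic(f10b16, 4.0) == pytest.approx(0.513, abs=0.005)
        assert survival_basic(f10b16, 4.0) == pytest.approx(0.5140, abs=5e-4)
        assert survival_basic(t4t1, 4.0) == pytest.approx(0.445, abs=0.005)

    def test_incomplete_repair_matches_published_split_dose_values(self, f10b16, t4t1):
        scheme = make_scheme(4, 2, 240, 0.81, "start_to_start")
        assert survival_complete(f10b16, scheme, "mu").survival == pytest.approx(
            0.591, abs=0.005)
        assert survival_complete(t4t1, scheme, "mu").survival == pytest.approx(
            0.613, abs=0.005)

    def test_basic_dispatch_ignores_timing(self, f10b16):
        for t in (15, 60, 240):
            pred = survival_complete(f10b16, make_scheme(4, 2, t), "basic")
            assert pred.g_value == 1.0
            assert pred.survival == survival_basic(f10b16, 4.0)

    def test_single_fraction_incomplete_repair_degenerates_to_acute(self, f10b16):
        pred = survival_complete(f10b16, make_scheme(4, 1, 5), "mu")
        assert pred.g_value == 1.0
        assert pred.survival == survival_basic(f10b16, 4.0)

    def test_unknown_method_rejected(self, f10b16):
        with pytest.raises(ValidationError, match="method"):
            survival_complete(f10b16, make_scheme(4, 2, 60), "lq4")

    def test_negative_dose_rejected(self, f10b16):
        with pytest.raises(ValidationError):
            survival_basic(f10b16, -1.0)

    @pytest.mark.parametrize("method", ["mu", "brenner", "keall"])
    def test_survival_increases_with_overall_time(self, f10b16, method):
        times = [15, 30, 60, 120, 240]
        surv = [survival_complete(f10b16, make_scheme(4, 2, t), method).survival
                for t in times]
        assert all(b > a for a, b in zip(surv, surv[1:]))

    def test_ranges(self, f10b16, t4t1):
        for params in (f10b16, t4t1):
            for method in ("basic", "mu", "brenner", "keall"):
                for t in (15, 60, 240):
                    p = survival_complete(params, make_scheme(4, 2, t), method)
                    assert 0 < p.g_value <= 1
                    assert 0 < p.survival <= 1

    def test_higher_beta_shorter_half_time_gains_more_from_protraction(
            self, f10b16, t4t1):
        # 4T1 (larger beta, shorter T1/2) benefits more from a 4 h split
        scheme = make_scheme(4, 2, 240)
        gain = {}
        for p in (f10b16, t4t1):
            split = survival_complete(p, scheme, "mu").survival
            gain[p.name] = split / survival_basic(p, 4.0)
        assert gain["4T1"] >= gain["F10B16"]
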