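"""Equilibrium calibration of (beta, gamma, tau, alpha) to four targets.

For each sampled :class:`~pwidsim.params.ParameterSet` the free parameters
are solved so that the stationary composition reproduces the set's sampled
values of (1) non-injection illicit drug-use prevalence, (2) injector
prevalence, (3) the proportion of initiations that are self-initiated and
(4) baseline OAT coverage.  The stationarity conditions and the four
target conditions are solved jointly as one root problem in the seven
compartments plus the four free parameters, with a damped least-squares
fallback for stubborn draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares, root

from .dynamics import (
    N_REF,
    CompartmentState,
    RateSet,
    _core,
    composition_residual,
    find_equilibrium,
)
from .params import ParameterSet

__all__ = [
    "CalibrationObservables",
    "CalibrationError",
    "CalibratedParameterSet",
    "observables",
    "calibrate",
    "alpha_for_coverage",
]

logger = logging.getLogger(__name__)

RESIDUAL_TOL = 1e-9


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CalibrationObservables:
    """The four calibrated quantities evaluated at a model state."""

    prev_nonidu: float
    prev_pwid: float
    prop_unassisted: float
    oat_coverage: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.prev_nonidu, self.prev_pwid, self.prop_unassisted, self.oat_coverage]
        )


def observables(s: CompartmentState, r: RateSet) -> CalibrationObservables:
    """Prevalences, self-initiation share and OAT coverage at state ``s``."""
    s.validate()
    pwid = s.pwid
    if pwid <= 0:
        raise ValueError("OAT coverage undefined with no injectors")
    _, fluxes = _core(s.as_array(), r)
    assisted, unassisted = fluxes[0], fluxes[1]
    total_init = assisted + unassisted
    if total_init <= 0:
        raise ValueError("self-initiated share undefined with no initiations")
    n = s.total
    return CalibrationObservables(
        prev_nonidu=s.v / n,
        prev_pwid=pwid / n,
        prop_unassisted=unassisted / total_init,
        oat_coverage=s.oat_enrolled / pwid,
    )


@dataclass(frozen=True)
class CalibratedParameterSet:
    """A parameter set with fitted rates and its baseline equilibrium."""

    params: ParameterSet
    beta: float
    gamma: float
    tau: float
    alpha: float
    equilibrium: CompartmentState
    residual: np.ndarray
    converged: bool
    xi_oat_factor: float | None = None

    def rates(self, alpha: float | None = None) -> RateSet:
        xi_oat = None
        if self.xi_oat_factor is not None:
            xi_oat = self.params.xi * self.xi_oat_factor
        return RateSet.from_parameters(
            self.params,
            beta=self.beta,
            gamma=self.gamma,
            tau=self.tau,
            alpha=self.alpha if alpha is None else alpha,
            xi_oat=xi_oat,
        )


def _targets(p: ParameterSet) -> np.ndarray:
    return np.array(
        [
            p.target_prev_nonidu,
            p.target_prev_pwid,
            p.target_prop_unassisted,
            p.target_oat_coverage,
        ]
    )


def _initial_guess(p: ParameterSet, n_total: float) -> tuple[np.ndarray, np.ndarray]:
    """Balance-based starting state (persons) and (beta, gamma, tau, alpha)."""
    p1, p2, u, c = _targets(p)
    mu = p.mu_b
    ov_mix = p.mu_ov * ((1 - c) + c * p.rr_oat_ov)
    total_init = p2 * n_total * (p.xi + mu + ov_mix)
    tau0 = max(u * total_init, 1e-9)
    alpha0 = max(c / (1 - c) * (p.rho + p.xi + mu), 1e-9)
    e0 = min(0.5 * n_total, p.xi * p2 * n_total / mu)
    v0 = p1 * n_total
    hist = 0.35
    a0 = (1 - c) * (1 - hist) * p2 * n_total
    b0 = (1 - c) * hist * p2 * n_total
    c0 = c * (1 - hist) * p2 * n_total
    d0 = c * hist * p2 * n_total
    g0 = max(0.05 * n_total, n_total - v0 - p2 * n_total - e0)
    w0 = (
        a0
        + p.rr_history * b0
        + p.rr_oat * c0
        + p.rr_history * p.rr_oat * d0
    )
    beta0 = max((1 - u) * total_init * n_total / (w0 * v0), 1e-9)
    gamma0 = max((p.theta * g0 - total_init) / v0 - mu, 1e-3)
    state0 = np.array([g0, v0, a0, b0, c0, d0, e0])
    return state0, np.array([beta0, gamma0, tau0, alpha0])


def _joint_residual(
    z: np.ndarray,
    p: ParameterSet,
    scales: np.ndarray,
    n_total: float,
    xi_oat_factor: float | None,
) -> np.ndarray:
    x = z[:7] * n_total
    beta, gamma, tau, alpha = np.abs(z[7:]) * scales
    xi_oat = None if xi_oat_factor is None else p.xi * xi_oat_factor
    r = RateSet.from_parameters(p, beta, gamma, tau, alpha, xi_oat=xi_oat)
    h = composition_residual(x, r) / n_total
    _, fluxes = _core(x, r)
    assisted, unassisted = fluxes[0], fluxes[1]
    n = x.sum()
    pwid = x[2:6].sum()
    t = _targets(p)
    return np.concatenate(
        [
            h[1:],  # stationarity (the G component is redundant: sum(h) == 0)
            [n / n_total - 1.0],
            [
                x[1] / n - t[0],
                pwid / n - t[1],
                unassisted / (assisted + unassisted) - t[2],
                (x[4] + x[5]) / pwid - t[3],
            ],
        ]
    )


def calibrate(
    p: ParameterSet,
    n_total: float = N_REF,
    xi_oat_factor: float | None = None,
) -> CalibratedParameterSet:
    """Fit (beta, gamma, tau, alpha) so the equilibrium hits ``p``'s targets.

    ``xi_oat_factor`` applies a distinct cessation rate
    ``xi_oat = xi * xi_oat_factor`` to the on-OAT compartments during both
    calibration and any downstream runs (used by sensitivity analyses).
    Deterministic given ``p``; non-convergence is flagged, not raised.
    """
    p.validate()
    state0, scales = _initial_guess(p, n_total)
    z0 = np.concatenate([state0 / n_total, np.ones(4)])
    args = (p, scales, n_total, xi_oat_factor)

    sol = root(_joint_residual, z0, args=args, method="hybr", options={"xtol": 1e-13})
    z = sol.x
    resid = _joint_residual(z, *args)
    ok = sol.success and np.max(np.abs(resid)) < RESIDUAL_TOL and (z[:7] > -1e-12).all()

    if not ok:
        ls = least_squares(
            _joint_residual,
            z0,
            args=args,
            method="lm",
            xtol=1e-15,
            ftol=1e-15,
            max_nfev=4000,
        )
        resid_ls = _joint_residual(ls.x, *args)
        if np.max(np.abs(resid_ls)) < np.max(np.abs(resid)):
            z, resid = ls.x, resid_ls
        ok = np.max(np.abs(resid)) < RESIDUAL_TOL and (z[:7] > -1e-12).all()
        if not ok:
            logger.warning("calibration failed (max residual %.3g)", np.max(np.abs(resid)))

    x = np.clip(z[:7], 0.0, None) * n_total
    beta, gamma, tau, alpha = np.abs(z[7:]) * scales
    eq = CompartmentState.from_array(x)
    return CalibratedParameterSet(
        params=p,
        beta=float(beta),
        gamma=float(gamma),
        tau=float(tau),
        alpha=float(alpha),
        equilibrium=eq,
        residual=resid[7:].copy(),
        converged=bool(ok),
        xi_oat_factor=xi_oat_factor,
    )


def alpha_for_coverage(
    cal: CalibratedParameterSet,
    coverage: float,
    tol: float = 1e-10,
) -> float:
    """OAT enrollment rate whose new equilibrium coverage equals ``coverage``.

    Scale-up is read as *sustained* coverage: alpha is solved against the
    stationary composition under the otherwise-unchanged calibrated rates.
    """
    if not 0 <= coverage < 1:
        raise ValueError("coverage must lie in [0, 1)")
    if coverage == 0:
        return 0.0

    guess = cal.equilibrium

    def gap(alpha: float) -> float:
        nonlocal guess
        eq = find_equilibrium(cal.rates(alpha=alpha), n_total=guess.total, guess=guess)
        guess = eq
        return eq.oat_enrolled / eq.pwid - coverage

    base = max(cal.alpha, 1e-6)
    g0 = gap(base)
    if abs(g0) < tol:
        return base
    if g0 < 0:
        lo, hi = base, base * 2
        while gap(hi) < 0:
            lo, hi = hi, hi * 2
            if hi > 1e6:
                raise CalibrationError("coverage target unreachable")
    else:
        lo, hi = base / 2, base
        while gap(lo) > 0:
            hi, lo = lo, lo / 2
            if lo < 1e-12:
                return 0.0
    return float(brentq(gap, lo, hi, xtol=tol))
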