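"""Seven-compartment dynamics of injection drug use initiation.

Compartments
------------
``G``  not using illicit drugs (cannabis excluded)
``V``  using illicit drugs other than / in addition to cannabis, injection-naive
``A``  injectors, no history of assisting an initiation, not on OAT
``B``  injectors, history of assisting, not on OAT
``C``  injectors, no history, on OAT
``D``  injectors, history, on OAT
``E``  former injectors (permanent cessation)

The assisted-initiation force is proportional to the effect-weighted
injector prevalence ``(A + RR_I*B + RR_OAT*C + RR_I*RR_OAT*D) / N`` acting
on the naive drug-using pool ``V``; a fixed number of unassisted
(self-)initiations ``tau`` per year is added.  Entrants replace all
non-overdose deaths, so the total population declines only through
overdose deaths and the small excess-death fractions applied at OAT entry
and exit.  Because those losses are not replaced, the system has no strict
fixed point with injectors present; ``find_equilibrium`` returns the state
whose composition is stationary (the derivative is parallel to the state),
which the trajectory tracks exactly while the population drifts down by
~0.01% per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .params import ParameterSet

__all__ = [
    "N_REF",
    "FLUX_LABELS",
    "CompartmentState",
    "RateSet",
    "Trajectory",
    "IntegrationError",
    "EquilibriumError",
    "excess_overdose_fractions",
    "initiation_flux",
    "derivatives",
    "integrate",
    "find_equilibrium",
]

logger = logging.getLogger(__name__)

#: Reference population size; outcomes are reported per million.
N_REF = 1_000_000.0

#: Order of the instantaneous / cumulative event fluxes.
FLUX_LABELS = (
    "assisted_initiations",
    "unassisted_initiations",
    "history_transitions_off_oat",
    "history_transitions_on_oat",
    "oat_entries",
    "oat_exits",
    "cessations",
    "background_deaths",
    "overdose_deaths",
    "oat_transition_excess_deaths",
)

# four weeks expressed as a fraction of a year
_FOUR_WEEKS = 4.0 / 52.0

# unassisted initiations are throttled once the naive pool drops below
# this many persons, so tau can never drive V negative
_TAU_THROTTLE_V = 10.0


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails or produces invalid states."""


class EquilibriumError(RuntimeError):
    """Raised when no stationary composition can be found."""


@dataclass(frozen=True)
class CompartmentState:
    g: float
    v: float
    a: float
    b: float
    c: float
    d: float
    e: float

    @property
    def total(self) -> float:
        return self.g + self.v + self.a + self.b + self.c + self.d + self.e

    @property
    def pwid(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def oat_enrolled(self) -> float:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.v, self.a, self.b, self.c, self.d, self.e])

    @classmethod
    def from_array(cls, x: Iterable[float]) -> "CompartmentState":
        g, v, a, b, c, d, e = (float(u) for u in x)
        return cls(g, v, a, b, c, d, e)

    def validate(self) -> None:
        x = self.as_array()
        if (x < 0).any():
            raise ValueError(f"negative compartment in {self}")
        if self.total <= 0:
            raise ValueError("total population must be positive")


@dataclass(frozen=True)
class RateSet:
    """All rate constants needed to evaluate the model derivatives.

    ``xi_oat`` is the cessation rate applied to the on-OAT compartments; it
    defaults to ``xi`` (no OAT effect on time to permanent cessation) and is
    varied in sensitivity analyses.  With ``tau_tracks_population`` (the
    default) the unassisted-initiation count scales with ``N / N_REF``,
    which makes the stationary composition an exact invariant of the flow;
    at ``N = N_REF`` the flux equals ``tau`` exactly.
    """

    mu_b: float
    mu_ov: float
    theta: float
    xi: float
    rho: float
    m: float
    rr_history: float
    rr_oat: float
    rr_oat_ov: float
    beta: float
    gamma: float
    tau: float
    alpha: float
    delta_enter: float
    delta_exit: float
    xi_oat: float | None = None
    tau_tracks_population: bool = True
    #: implement the cessation outflow of compartment B as ``-xi*B``
    #: (bookkeeping-consistent) rather than the literal ``-xi*V``
    xi_b_applies_to_b: bool = True

    def __post_init__(self) -> None:
        if self.xi_oat is None:
            object.__setattr__(self, "xi_oat", self.xi)

    def validate(self) -> None:
        if min(self.beta, self.gamma, self.alpha, self.tau) < 0:
            raise ValueError("beta, gamma, tau, alpha must be non-negative")
        if not (0 <= self.delta_enter < 1 and 0 <= self.delta_exit < 1):
            raise ValueError("delta fractions must lie in [0, 1)")

    @classmethod
    def from_parameters(
        cls,
        p: ParameterSet,
        beta: float,
        gamma: float,
        tau: float,
        alpha: float,
        xi_oat: float | None = None,
        **kwargs,
    ) -> "RateSet":
        d_enter, d_exit = excess_overdose_fractions(p)
        return cls(
            mu_b=p.mu_b,
            mu_ov=p.mu_ov,
            theta=p.theta,
            xi=p.xi,
            rho=p.rho,
            m=p.m,
            rr_history=p.rr_history,
            rr_oat=p.rr_oat,
            rr_oat_ov=p.rr_oat_ov,
            beta=beta,
            gamma=gamma,
            tau=tau,
            alpha=alpha,
            delta_enter=d_enter,
            delta_exit=d_exit,
            xi_oat=xi_oat,
            **kwargs,
        )

    def with_alpha(self, alpha: float) -> "RateSet":
        return replace(self, alpha=alpha)


def excess_overdose_fractions(p: ParameterSet) -> tuple[float, float]:
    """Excess-death fractions applied at OAT entry and exit.

    The first four weeks on and the first four weeks after OAT carry extra
    overdose risk; the per-transition death fractions are::

        delta_exit  = mu_ov * (rr_oat_out - 1) * 4/52
        delta_enter = mu_ov * rr_oat_ov * (rr_oat_in - 1) * 4/52

    Negative values (an RR draw below one) are clipped to zero.
    """
    d_exit = p.mu_ov * (p.rr_oat_out - 1.0) * _FOUR_WEEKS
    d_enter = p.mu_ov * p.rr_oat_ov * (p.rr_oat_in - 1.0) * _FOUR_WEEKS
    if d_exit < 0 or d_enter < 0:
        logger.debug("clipping negative excess-death fraction to zero")
    return max(0.0, d_enter), max(0.0, d_exit)


def _core(x: np.ndarray, r: RateSet) -> tuple[np.ndarray, np.ndarray]:
    """Derivatives of the seven compartments and the ten event fluxes."""
    g, v, a, b, c, d, e = x
    n = g + v + a + b + c + d + e
    if n <= 0:
        raise ValueError("total population must be positive")

    weighted = a + r.rr_history * b + r.rr_oat * c + r.rr_history * r.rr_oat * d
    assisted = r.beta * weighted / n * v
    tau_eff = r.tau
    if r.tau_tracks_population:
        tau_eff *= n / N_REF
    if v < _TAU_THROTTLE_V:
        tau_eff *= max(v, 0.0) / _TAU_THROTTLE_V

    f_ab = r.m * r.beta * a / n * v
    f_cd = r.m * r.beta * r.rr_oat * c / n * v
    entries = r.alpha * (a + b)
    exits = r.rho * (c + d)
    cess_off = r.xi * (a + b)
    cess_on = r.xi_oat * (c + d)
    od = r.mu_ov * (a + b) + r.rr_oat_ov * r.mu_ov * (c + d)
    sigma = r.mu_b * n  # entrants replace all non-overdose deaths

    dg = sigma - r.theta * g + r.gamma * v - r.mu_b * g
    dv = r.theta * g - r.gamma * v - assisted - tau_eff - r.mu_b * v
    da = (
        assisted
        + tau_eff
        - f_ab
        - r.alpha * a
        + r.rho * c * (1.0 - r.delta_exit)
        - r.xi * a
        - (r.mu_b + r.mu_ov) * a
    )
    xi_b_term = r.xi * b if r.xi_b_applies_to_b else r.xi * v
    db = (
        f_ab
        - r.alpha * b
        + r.rho * d * (1.0 - r.delta_exit)
        - xi_b_term
        - (r.mu_b + r.mu_ov) * b
    )
    dc = (
        r.alpha * a * (1.0 - r.delta_enter)
        - r.rho * c
        - f_cd
        - r.xi_oat * c
        - (r.mu_b + r.rr_oat_ov * r.mu_ov) * c
    )
    dd = (
        r.alpha * b * (1.0 - r.delta_enter)
        + f_cd
        - r.rho * d
        - r.xi_oat * d
        - (r.mu_b + r.rr_oat_ov * r.mu_ov) * d
    )
    de = cess_off + cess_on - r.mu_b * e

    deriv = np.array([dg, dv, da, db, dc, dd, de])
    fluxes = np.array(
        [
            assisted,
            tau_eff,
            f_ab,
            f_cd,
            entries,
            exits,
            cess_off + cess_on,
            sigma,  # background deaths (equal to entrants by construction)
            od,
            r.delta_enter * entries + r.delta_exit * exits,
        ]
    )
    return deriv, fluxes


def initiation_flux(s: CompartmentState, r: RateSet) -> tuple[float, float]:
    """Instantaneous assisted and unassisted initiation rates (persons/yr)."""
    s.validate()
    _, fluxes = _core(s.as_array(), r)
    return float(fluxes[0]), float(fluxes[1])


def derivatives(s: CompartmentState, r: RateSet) -> tuple[np.ndarray, dict[str, float]]:
    """Compartment time-derivatives and named instantaneous event fluxes."""
    s.validate()
    deriv, fluxes = _core(s.as_array(), r)
    return deriv, dict(zip(FLUX_LABELS, (float(f) for f in fluxes)))


@dataclass(frozen=True)
class Trajectory:
    """A solved trajectory: states and cumulative event fluxes over time."""

    times: np.ndarray
    states: np.ndarray  # (n_times, 7)
    cum_fluxes: np.ndarray  # (n_times, 10), order FLUX_LABELS

    def state_at(self, i: int) -> CompartmentState:
        return CompartmentState.from_array(self.states[i])

    @property
    def totals(self) -> np.ndarray:
        return self.states.sum(axis=1)

    @property
    def pwid_size(self) -> np.ndarray:
        return self.states[:, 2:6].sum(axis=1)

    def index_at(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6:
            raise ValueError(f"time {t} not on the output grid")
        return i

    def cumulative(self, label: str, t: float) -> float:
        return float(self.cum_fluxes[self.index_at(t), FLUX_LABELS.index(label)])

    def annual_flux(self, label: str, year: int) -> float:
        """Integral of a flux over the year interval ``(year-1, year]``."""
        j = FLUX_LABELS.index(label)
        return float(
            self.cum_fluxes[self.index_at(float(year)), j]
            - self.cum_fluxes[self.index_at(float(year - 1)), j]
        )

    def to_frame(self):
        import pandas as pd

        comp = pd.DataFrame(
            self.states, columns=list("GVABCDE"), index=pd.Index(self.times, name="time")
        )
        flux = pd.DataFrame(
            self.cum_fluxes, columns=list(FLUX_LABELS), index=comp.index
        )
        return comp, flux


def integrate(
    s0: CompartmentState,
    r: RateSet,
    horizon: float,
    output_step: float = 1.0 / 12.0,
    rtol: float = 1e-8,
    atol: float | None = None,
) -> Trajectory:
    """Integrate the model over ``horizon`` years.

    The state vector is augmented with running integrals of the ten event
    fluxes so that annual outcomes are exact time-integrals rather than
    grid-sampled rates.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    s0.validate()
    r.validate()
    n_steps = round(horizon / output_step)
    if abs(n_steps * output_step - horizon) > 1e-9:
        raise ValueError("horizon must be a multiple of output_step")
    times = np.linspace(0.0, horizon, n_steps + 1)
    n0 = s0.total
    if atol is None:
        atol = 1e-8 * n0

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        deriv, fluxes = _core(y[:7], r)
        return np.concatenate([deriv, fluxes])

    y0 = np.concatenate([s0.as_array(), np.zeros(len(FLUX_LABELS))])
    sol = solve_ivp(
        rhs, (0.0, horizon), y0, method="LSODA", t_eval=times, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationError(f"solver failed: {sol.message}")
    states = sol.y[:7].T.copy()
    if states.min() < -1e-9 * n0:
        raise IntegrationError(
            f"negative compartment beyond tolerance: min={states.min():.3g}"
        )
    np.clip(states, 0.0, None, out=states)
    cum = sol.y[7:].T.copy()
    np.maximum.accumulate(cum, axis=0, out=cum)  # guard monotonicity at solver noise
    return Trajectory(times=times, states=states, cum_fluxes=cum)


def composition_residual(x: np.ndarray, r: RateSet) -> np.ndarray:
    """Derivative with the uniform population drift projected out.

    Zero exactly when the composition of ``x`` is invariant under the flow,
    i.e. ``f(x)`` is parallel to ``x``.
    """
    f, _ = _core(x, r)
    n = x.sum()
    return f - (f.sum() / n) * x


def find_equilibrium(
    r: RateSet,
    n_total: float = N_REF,
    guess: CompartmentState | None = None,
    tol: float = 1e-11,
) -> CompartmentState:
    """Stationary-composition state with total population ``n_total``.

    Solves ``f(x) - (1'f(x)/N) x = 0`` together with ``sum(x) = n_total``.
    Falls back to a long-horizon integration (renormalised) before a final
    polish if the root solve stalls.
    """
    r.validate()
    if guess is None:
        guess = _default_guess(r, n_total)

    def F(z: np.ndarray) -> np.ndarray:
        x = z * n_total
        h = composition_residual(x, r) / n_total
        return np.concatenate([h[1:], [x.sum() / n_total - 1.0]])

    def solved(sol) -> bool:
        # hybr sometimes reports spurious non-convergence at tight xtol;
        # judge by the residual itself
        return np.max(np.abs(F(sol.x))) < tol and (sol.x > -1e-12).all()

    z0 = guess.as_array() / n_total
    sol = root(F, z0, method="hybr", options={"xtol": 1e-13})
    if not solved(sol):
        # relaxation fallback: integrate toward the invariant ray, renormalise
        x = np.maximum(guess.as_array(), 1e-9)
        for _ in range(4):
            traj = integrate(CompartmentState.from_array(x), r, 200.0, output_step=10.0)
            x = traj.states[-1]
            x = x / x.sum() * n_total
        sol = root(F, x / n_total, method="hybr", options={"xtol": 1e-13})
        if not solved(sol):
            from scipy.optimize import least_squares

            sol = least_squares(F, x / n_total, xtol=3e-16, ftol=3e-16, gtol=3e-16)
            if not solved(sol):
                raise EquilibriumError("no stationary composition found")
    x = np.clip(sol.x, 0.0, None) * n_total
    x *= n_total / x.sum()
    return CompartmentState.from_array(x)


def _default_guess(r: RateSet, n_total: float) -> CompartmentState:
    """Rough balance-based starting composition."""
    mu = r.mu_b
    # two-compartment balance ignoring injectors
    v = r.theta / (r.gamma + mu + 1e-12) / (1 + r.theta / (r.gamma + mu + 1e-12))
    pwid = 0.011
    cov = min(0.95, r.alpha / (r.alpha + r.rho + r.xi + mu + 1e-12))
    hist = 0.35
    e = min(0.5, r.xi * pwid / mu)
    a = pwid * (1 - cov) * (1 - hist)
    b = pwid * (1 - cov) * hist
    c = pwid * cov * (1 - hist)
    d = pwid * cov * hist
    g = max(0.05, 1.0 - v - pwid - e)
    x = np.array([g, v, a, b, c, d, e])
    x = x / x.sum() * n_total
    return CompartmentState.from_array(x)
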