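"""Parameter space: sampling distributions and Monte Carlo parameter sets.

Every epidemiological and behavioural input of the initiation model is
described by a :class:`DistributionSpec`.  The default table
(:data:`DEFAULT_DISTRIBUTIONS`) covers demography, overdose mortality,
drug-use transitions, OAT effect sizes and the four calibration targets.
Duration-valued inputs (injection career length, OAT enrollment spell) are
sampled on the duration scale and inverted to rates, so the summaries of
those rows follow the harmonic-mean convention used when reporting them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "DEFAULT_DISTRIBUTIONS",
    "PARAMETER_ORDER",
    "DURATION_SCALE_PARAMS",
    "sample_distribution",
    "sample_parameter_sets",
    "summarize_samples",
    "sets_to_frame",
    "frame_to_sets",
]

logger = logging.getLogger(__name__)

_FAMILIES = {
    "beta",
    "uniform",
    "triangular",
    "lognormal",
    "three_param_gamma",
    "scaled_poisson",
    "fixed",
}

_MAX_RESAMPLE = 100


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one scalar model input.

    Parameters
    ----------
    family:
        One of ``beta``, ``uniform``, ``triangular``, ``lognormal``,
        ``three_param_gamma``, ``scaled_poisson`` or ``fixed``.
    params:
        Family-specific parameters:

        ============== ==========================================
        beta            ``a``, ``b`` (shapes)
        uniform         ``low``, ``high``
        triangular      ``low``, ``mode``, ``high``
        lognormal       ``median``, ``sdlog``
        three_param_gamma  ``shape``, ``scale``, ``loc``
        scaled_poisson  ``lam``, ``divisor``
        fixed           ``value``
        ============== ==========================================

        The lognormal is parameterised by its median (``exp`` of the log
        mean), so the arithmetic mean of draws exceeds ``median`` by
        ``exp(sdlog**2 / 2)``.
    transform:
        ``identity`` or ``reciprocal``.  ``reciprocal`` marks a
        duration-valued quantity whose inverse is the model rate: the draw
        is taken on the duration scale and ``1/draw`` is returned.
    """

    family: str
    params: Mapping[str, float]
    transform: str = "identity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        self.validate()

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.transform not in ("identity", "reciprocal"):
            raise ValueError(f"unknown transform {self.transform!r}")
        p = self.params
        for v in p.values():
            if not math.isfinite(float(v)):
                raise ValueError(f"non-finite parameter in {self}")
        if self.family == "beta" and not (p["a"] > 0 and p["b"] > 0):
            raise ValueError("beta shapes must be positive")
        if self.family == "uniform" and not p["low"] < p["high"]:
            raise ValueError("uniform requires low < high")
        if self.family == "triangular" and not (
            p["low"] <= p["mode"] <= p["high"] and p["low"] < p["high"]
        ):
            raise ValueError("triangular requires low <= mode <= high")
        if self.family == "lognormal" and not (p["median"] > 0 and p["sdlog"] > 0):
            raise ValueError("lognormal requires median > 0 and sdlog > 0")
        if self.family == "three_param_gamma" and not (
            p["shape"] > 0 and p["scale"] > 0
        ):
            raise ValueError("gamma shape/scale must be positive")
        if self.family == "scaled_poisson" and not (
            p["lam"] > 0 and p["divisor"] > 0
        ):
            raise ValueError("scaled_poisson requires lam > 0 and divisor > 0")

    def draw(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        """Draw on the *natural* (pre-transform) scale."""
        p = self.params
        if self.family == "beta":
            return rng.beta(p["a"], p["b"], size)
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.family == "triangular":
            return rng.triangular(p["low"], p["mode"], p["high"], size)
        if self.family == "lognormal":
            return rng.lognormal(math.log(p["median"]), p["sdlog"], size)
        if self.family == "three_param_gamma":
            return p["loc"] + rng.gamma(p["shape"], p["scale"], size)
        if self.family == "scaled_poisson":
            return rng.poisson(p["lam"], size) / p["divisor"]
        # fixed
        if size is None:
            return float(p["value"])
        return np.full(size, float(p["value"]))


def sample_distribution(
    spec: DistributionSpec,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw from ``spec``, applying its transform.

    A ``reciprocal`` transform returns the inverse of the sampled duration
    (a rate per year).  Non-finite draws (e.g. the reciprocal of a zero
    duration) are resampled up to a bounded retry count.
    """
    spec.validate()
    x = np.asarray(spec.draw(rng, size if size is not None else 1), dtype=float)
    if spec.transform == "reciprocal":
        with np.errstate(divide="ignore"):
            y = 1.0 / x
    else:
        y = x
    for _ in range(_MAX_RESAMPLE):
        bad = ~np.isfinite(y)
        if not bad.any():
            break
        redraw = np.asarray(spec.draw(rng, int(bad.sum())), dtype=float)
        y[bad] = 1.0 / redraw if spec.transform == "reciprocal" else redraw
    else:
        raise RuntimeError(f"could not obtain finite draw from {spec}")
    if size is None:
        return float(y[0])
    return y


@dataclass(frozen=True)
class ParameterSet:
    """One Monte Carlo draw of all model inputs plus calibration targets.

    Rates are per person-year.  ``xi`` and ``rho`` are the inverses of the
    sampled injection-career and OAT-enrollment durations.  ``m_inv`` is the
    mean number of assisted initiations per newly assisting injector; the
    model uses ``m = 1/m_inv`` as the history-transition scaling.
    """

    mu_b: float
    mu_ov: float
    theta: float
    xi: float
    rho: float
    m_inv: float
    rr_history: float
    rr_oat: float
    rr_oat_out: float
    rr_oat_in: float
    rr_oat_ov: float
    target_prev_nonidu: float
    target_prev_pwid: float
    target_prop_unassisted: float
    target_oat_coverage: float

    @property
    def m(self) -> float:
        return 1.0 / self.m_inv

    @property
    def idu_duration(self) -> float:
        return 1.0 / self.xi

    @property
    def oat_duration(self) -> float:
        return 1.0 / self.rho

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"{f.name} is not finite")
        if min(self.mu_b, self.theta, self.xi, self.rho) <= 0:
            raise ValueError("rates must be strictly positive")
        if self.mu_ov < 0:
            raise ValueError("overdose rate must be non-negative")
        if self.m_inv < 1:
            raise ValueError("m_inv must be >= 1")
        for name in ("rr_history", "rr_oat", "rr_oat_ov"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rr_oat_out < 0 or self.rr_oat_in < 0:
            raise ValueError("overdose RRs must be non-negative")
        for name in (
            "target_prev_nonidu",
            "target_prev_pwid",
            "target_prop_unassisted",
            "target_oat_coverage",
        ):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


#: Sampling order.  Held fixed so that a given seed yields the same
#: underlying draws regardless of later point overrides (common random
#: numbers for sensitivity analyses).
PARAMETER_ORDER: tuple[str, ...] = (
    "mu_b",
    "mu_ov",
    "theta",
    "xi",
    "rho",
    "m_inv",
    "rr_history",
    "rr_oat",
    "rr_oat_out",
    "rr_oat_in",
    "rr_oat_ov",
    "target_prev_nonidu",
    "target_prev_pwid",
    "target_prop_unassisted",
    "target_oat_coverage",
)

#: Parameters whose summaries are reported on the duration scale.
DURATION_SCALE_PARAMS: tuple[str, ...] = ("xi", "rho")

DEFAULT_DISTRIBUTIONS: dict[str, DistributionSpec] = {
    # mean life span from age 10 of 69.3 years, inverted to a death rate
    "mu_b": DistributionSpec("fixed", {"value": 69.3}, transform="reciprocal"),
    # excess overdose deaths among out-of-treatment injectors, per 100 py
    "mu_ov": DistributionSpec("scaled_poisson", {"lam": 62, "divisor": 10_000}),
    "theta": DistributionSpec("beta", {"a": 31.46, "b": 1239.87}),
    # injection career duration in years -> cessation rate
    "xi": DistributionSpec(
        "triangular", {"low": 5.0, "mode": 15.0, "high": 25.0}, transform="reciprocal"
    ),
    # OAT enrollment spell in years -> dropout rate
    "rho": DistributionSpec(
        "uniform", {"low": 0.25, "high": 1.25}, transform="reciprocal"
    ),
    "m_inv": DistributionSpec(
        "three_param_gamma", {"shape": 0.830, "scale": 1.0, "loc": 1.0}
    ),
    "rr_history": DistributionSpec("lognormal", {"median": 4.93, "sdlog": 0.19}),
    "rr_oat": DistributionSpec("lognormal", {"median": 0.55, "sdlog": 0.21}),
    "rr_oat_out": DistributionSpec("lognormal", {"median": 2.38, "sdlog": 0.23}),
    "rr_oat_in": DistributionSpec("lognormal", {"median": 1.97, "sdlog": 0.37}),
    "rr_oat_ov": DistributionSpec("lognormal", {"median": 0.21, "sdlog": 0.26}),
    "target_prev_nonidu": DistributionSpec("beta", {"a": 1000.0, "b": 10_102.0}),
    "target_prev_pwid": DistributionSpec("beta", {"a": 13.34, "b": 1153.06}),
    "target_prop_unassisted": DistributionSpec("beta", {"a": 18.92, "b": 93.33}),
    "target_oat_coverage": DistributionSpec("beta", {"a": 9.94, "b": 36.76}),
}


def sample_parameter_sets(
    n: int,
    seed: int,
    overrides: Mapping[str, DistributionSpec] | None = None,
) -> list[ParameterSet]:
    """Draw ``n`` independent parameter sets, deterministically in ``seed``.

    ``overrides`` substitutes the distribution of individual parameters
    (e.g. a ``fixed`` spec for a one-way sensitivity analysis); the draws of
    all other parameters are unaffected, because each parameter consumes a
    fixed-size block of the random stream in :data:`PARAMETER_ORDER`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dists = dict(DEFAULT_DISTRIBUTIONS)
    if overrides:
        unknown = set(overrides) - set(dists)
        if unknown:
            raise ValueError(f"unknown parameters in overrides: {sorted(unknown)}")
        dists.update(overrides)

    columns: dict[str, np.ndarray] = {}
    for name in PARAMETER_ORDER:
        # independent substream per parameter: overriding one parameter's
        # family cannot perturb another parameter's draws
        rng = np.random.default_rng(np.random.SeedSequence((seed, hash_name(name))))
        columns[name] = np.asarray(sample_distribution(dists[name], rng, n))

    if (columns["mu_ov"] == 0).any():
        logger.warning(
            "%d zero overdose-rate draws", int((columns["mu_ov"] == 0).sum())
        )

    sets = []
    for i in range(n):
        p = ParameterSet(**{name: float(columns[name][i]) for name in PARAMETER_ORDER})
        p.validate()
        sets.append(p)
    return sets


def hash_name(name: str) -> int:
    """Stable non-negative integer derived from a parameter name."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**32)
    return h


def sets_to_frame(sets: Sequence[ParameterSet]) -> pd.DataFrame:
    """One row per parameter set, one column per field."""
    return pd.DataFrame([{f.name: getattr(p, f.name) for f in fields(p)} for p in sets])


def frame_to_sets(frame: pd.DataFrame) -> list[ParameterSet]:
    names = [f.name for f in fields(ParameterSet)]
    return [
        ParameterSet(**{n: float(row[n]) for n in names})
        for _, row in frame.iterrows()
    ]


def summarize_samples(sets: Iterable[ParameterSet]) -> pd.DataFrame:
    """Per-parameter mean and 2.5-97.5 percentile interval.

    Duration-valued parameters (``xi``, ``rho``) are summarised on the
    duration scale, with the mean taken as the reciprocal of the mean rate
    (harmonic-mean convention) and the interval as the reciprocal of the
    opposite rate percentiles.
    """
    frame = sets_to_frame(list(sets))
    if frame.empty:
        raise ValueError("empty collection of parameter sets")
    rows = []
    for name in PARAMETER_ORDER:
        x = frame[name].to_numpy()
        if name in DURATION_SCALE_PARAMS:
            mean = 1.0 / x.mean()
            lo = 1.0 / np.percentile(x, 97.5)
            hi = 1.0 / np.percentile(x, 2.5)
            scale = "duration"
        else:
            mean = x.mean()
            lo, hi = np.percentile(x, [2.5, 97.5])
            scale = "rate" if name in ("mu_b", "theta") else "natural"
        rows.append(
            {"parameter": name, "scale": scale, "mean": mean, "q2.5": lo, "q97.5": hi}
        )
    return pd.DataFrame(rows).set_index("parameter")
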