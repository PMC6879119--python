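"""Synthetic three-city injector cohorts with specified true effect sizes.

The real multicohort participant records are not deposited, so the
regression and pooling stages are exercised on generated stand-ins that
reproduce the published site-level marginals (sample sizes, exposure and
covariate prevalences) and embed user-chosen true relative risks on the
multiplicative risk scale.  Covariates are drawn independently from their
marginals — the correlation structure of the real cohorts is unknown and
deliberately not invented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SiteSpec",
    "default_site_specs",
    "generate_cohort",
    "generate_all_sites",
    "SITE_MODEL_COVARIATES",
]

logger = logging.getLogger(__name__)

INJ_FREQ_LEVELS = ("none", "less_than_daily", "daily")

#: Default true RRs for the exposures (the pooled published values) and
#: modest non-null covariate effects.  The covariate effect sizes are not
#: estimates of anything — they exist so adjustment is non-trivial.
DEFAULT_TRUE_RRS: dict[str, float] = {
    "history_prior": 4.93,
    "oat_recent": 0.55,
    "male": 1.2,
    "unstable_housing": 1.3,
    "inj_less_than_daily": 1.3,
    "inj_daily": 1.6,
    "meth_inject": 1.2,
    "speedball_inject": 1.1,
    "age_per_10y": 0.9,
}

#: Default model formula terms per site: no OAT exposure for Tijuana
#: (enrollment prevalence 2.1%), speedball collected in Vancouver only.
SITE_MODEL_COVARIATES: dict[str, dict[str, list[str]]] = {
    "Vancouver": {
        "exposures": ["oat_recent", "history_prior"],
        "covariates": ["age", "gender", "cohort", "unstable_housing", "inj_freq",
                       "meth_inject", "speedball_inject"],
    },
    "SanDiego": {
        "exposures": ["oat_recent", "history_prior"],
        "covariates": ["age", "gender", "unstable_housing", "inj_freq", "meth_inject"],
    },
    "Tijuana": {
        "exposures": ["history_prior"],
        "covariates": ["age", "gender", "unstable_housing", "inj_freq", "meth_inject"],
    },
}


@dataclass(frozen=True)
class SiteSpec:
    """Marginals and true effect sizes for one site's synthetic cohort."""

    name: str
    n: int
    outcome_prev: float
    oat_prev: float
    history_prev: float
    age_mean: float
    age_sd: float
    male_prev: float
    unstable_housing_prev: float
    inj_freq_probs: tuple[float, float, float]  # none / less-than-daily / daily
    meth_prev: float
    speedball_prev: float | None = None  # None: variable not collected
    cohort_probs: Mapping[str, float] | None = None  # Vancouver sub-cohorts
    true_rrs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_RRS))

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("outcome_prev", "oat_prev", "history_prev", "male_prev",
                     "unstable_housing_prev", "meth_prev"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(sum(self.inj_freq_probs) - 1) > 1e-9:
            raise ValueError("injection-frequency proportions must sum to 1")
        if self.speedball_prev is not None and not 0 <= self.speedball_prev <= 1:
            raise ValueError("speedball prevalence must lie in [0, 1]")
        if self.cohort_probs is not None and abs(sum(self.cohort_probs.values()) - 1) > 1e-9:
            raise ValueError("cohort proportions must sum to 1")

    def replace(self, **kwargs) -> "SiteSpec":
        return replace(self, **kwargs)


def _norm3(a: float, b: float, c: float) -> tuple[float, float, float]:
    s = a + b + c
    return (a / s, b / s, c / s)


def default_site_specs() -> dict[str, SiteSpec]:
    """Published site-level marginals for the three cities.

    The Vancouver sub-cohort split is not published at this granularity;
    the default split is a documented convention, not data.
    """
    return {
        "Vancouver": SiteSpec(
            name="Vancouver",
            n=1737,
            outcome_prev=0.045,
            oat_prev=0.494,
            history_prev=0.227,
            age_mean=42.98,
            age_sd=12.57,
            male_prev=0.623,
            unstable_housing_prev=0.251,
            # printed proportions sum to 100.1%; renormalised
            inj_freq_probs=_norm3(0.340, 0.310, 0.351),
            meth_prev=0.346,
            speedball_prev=0.068,
            cohort_probs={"ARYS": 0.2, "ACCESS": 0.3, "VIDUS": 0.5},
        ),
        "SanDiego": SiteSpec(
            name="SanDiego",
            n=346,
            outcome_prev=0.052,
            oat_prev=0.197,
            history_prev=0.353,
            age_mean=46.82,
            age_sd=11.29,
            male_prev=0.717,
            unstable_housing_prev=0.399,
            inj_freq_probs=(0.301, 0.376, 0.323),
            meth_prev=0.457,
        ),
        "Tijuana": SiteSpec(
            name="Tijuana",
            n=532,
            outcome_prev=0.043,
            oat_prev=0.021,
            history_prev=0.118,
            age_mean=41.05,
            age_sd=8.68,
            male_prev=0.615,
            unstable_housing_prev=0.152,
            inj_freq_probs=(0.173, 0.070, 0.757),
            meth_prev=0.117,
        ),
    }


def _risk_multipliers(frame: pd.DataFrame, rrs: Mapping[str, float]) -> np.ndarray:
    mult = np.ones(len(frame))
    mult *= np.asarray(rrs.get("history_prior", 1.0)) ** frame["history_prior"].to_numpy()
    mult *= np.asarray(rrs.get("oat_recent", 1.0)) ** frame["oat_recent"].to_numpy()
    mult *= rrs.get("male", 1.0) ** (frame["gender"] == "male").to_numpy()
    mult *= rrs.get("unstable_housing", 1.0) ** frame["unstable_housing"].to_numpy()
    mult *= rrs.get("inj_less_than_daily", 1.0) ** (
        frame["inj_freq"] == "less_than_daily"
    ).to_numpy()
    mult *= rrs.get("inj_daily", 1.0) ** (frame["inj_freq"] == "daily").to_numpy()
    mult *= rrs.get("meth_inject", 1.0) ** frame["meth_inject"].to_numpy()
    if frame["speedball_inject"].notna().any():
        mult *= rrs.get("speedball_inject", 1.0) ** frame["speedball_inject"].fillna(0).to_numpy()
    age_dev = (frame["age"].to_numpy() - frame["age"].mean()) / 10.0
    mult *= rrs.get("age_per_10y", 1.0) ** age_dev
    return mult


def generate_cohort(
    spec: SiteSpec,
    seed: int,
    n: int | None = None,
    max_truncation: float = 0.01,
) -> pd.DataFrame:
    """Generate one site's synthetic participant records.

    The outcome is Bernoulli with risk ``baseline * prod(RR^exposure)``,
    where the baseline risk is solved so the marginal outcome prevalence
    (expected over the drawn covariates) matches ``spec.outcome_prev``.
    Individual risks above one are truncated; the truncation rate must stay
    below ``max_truncation``.  Deterministic given ``seed``.
    """
    spec.validate()
    n = spec.n if n is None else n
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(
            columns=["site", "recent_assist", "oat_recent", "history_prior", "age",
                     "gender", "cohort", "unstable_housing", "inj_freq",
                     "meth_inject", "speedball_inject"]
        )

    frame = pd.DataFrame(
        {
            "site": spec.name,
            "oat_recent": (rng.random(n) < spec.oat_prev).astype(int),
            "history_prior": (rng.random(n) < spec.history_prev).astype(int),
            "age": rng.normal(spec.age_mean, spec.age_sd, n).clip(18, 90),
            "gender": np.where(rng.random(n) < spec.male_prev, "male", "female"),
            "unstable_housing": (rng.random(n) < spec.unstable_housing_prev).astype(int),
            "inj_freq": rng.choice(INJ_FREQ_LEVELS, size=n, p=spec.inj_freq_probs),
            "meth_inject": (rng.random(n) < spec.meth_prev).astype(int),
        }
    )
    if spec.speedball_prev is not None:
        frame["speedball_inject"] = (rng.random(n) < spec.speedball_prev).astype(float)
    else:
        frame["speedball_inject"] = np.nan
    if spec.cohort_probs is not None:
        labels = list(spec.cohort_probs)
        frame["cohort"] = rng.choice(labels, size=n, p=[spec.cohort_probs[k] for k in labels])
    else:
        frame["cohort"] = spec.name

    mult = _risk_multipliers(frame, spec.true_rrs)

    def prev_gap(base: float) -> float:
        return float(np.minimum(base * mult, 1.0).mean()) - spec.outcome_prev

    hi = 1.0
    if prev_gap(hi) < 0:
        raise ValueError("target outcome prevalence unattainable")
    base = brentq(prev_gap, 1e-12, hi, xtol=1e-14)
    risk = np.minimum(base * mult, 1.0)
    trunc_rate = float((base * mult > 1.0).mean())
    if trunc_rate >= max_truncation:
        raise ValueError(f"risk truncation rate {trunc_rate:.3%} exceeds limit")
    if trunc_rate > 0:
        logger.info("truncated %d risks above 1", int((base * mult > 1.0).sum()))

    frame["recent_assist"] = (rng.random(n) < risk).astype(int)
    frame["inj_freq"] = pd.Categorical(frame["inj_freq"], categories=INJ_FREQ_LEVELS)
    return frame


def generate_all_sites(
    specs: Mapping[str, SiteSpec] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Concatenate all sites, with per-site child seeds spawned from ``seed``."""
    specs = default_site_specs() if specs is None else specs
    ss = np.random.SeedSequence(seed).spawn(len(specs))
    frames = [
        generate_cohort(spec, int(child.generate_state(1)[0]))
        for spec, child in zip(specs.values(), ss)
    ]
    return pd.concat(frames, ignore_index=True)
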