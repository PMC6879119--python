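"""Baseline and OAT scale-up scenario runs with Monte Carlo uncertainty.

A scenario starts from a calibrated baseline equilibrium; scale-up replaces
the enrollment rate at t=0 with the value whose sustained coverage equals
the target.  Annual initiations are integrals of the initiation flux over
each year, and relative reductions are computed per parameter set against
that set's own baseline run before averaging (mean of ratios).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibratedParameterSet, alpha_for_coverage, calibrate
from .dynamics import IntegrationError, Trajectory, integrate
from .params import DistributionSpec, ParameterSet, sample_parameter_sets

__all__ = [
    "ScenarioResult",
    "UncertaintySummary",
    "run_scenario",
    "relative_reduction",
    "uncertainty_analysis",
    "OUTCOMES",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("total_initiations", "assisted_initiations", "unassisted_initiations", "pwid_size")


@dataclass(frozen=True)
class ScenarioResult:
    """Annual outcome series for one parameter set under one scenario."""

    coverage: float | None  # None = baseline
    years: np.ndarray  # 1..horizon
    assisted: np.ndarray
    unassisted: np.ndarray
    pwid_size: np.ndarray  # at each year's end
    trajectory: Trajectory | None = None

    @property
    def total(self) -> np.ndarray:
        return self.assisted + self.unassisted

    def reductions_vs(self, baseline: "ScenarioResult") -> pd.DataFrame:
        """Per-year percent reductions of initiations and PWID size."""
        return pd.DataFrame(
            {
                "year": self.years,
                "initiation_reduction_pct": [
                    relative_reduction(b, s) for b, s in zip(baseline.total, self.total)
                ],
                "pwid_reduction_pct": [
                    relative_reduction(b, s)
                    for b, s in zip(baseline.pwid_size, self.pwid_size)
                ],
            }
        )


def relative_reduction(baseline_value: float, scenario_value: float) -> float:
    """``100 * (baseline - scenario) / baseline``."""
    if baseline_value <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (baseline_value - scenario_value) / baseline_value


def run_scenario(
    cal: CalibratedParameterSet,
    coverage: float | str = "baseline",
    years: int = 10,
    keep_trajectory: bool = False,
) -> ScenarioResult:
    """Run one scenario for one calibrated set over ``years`` years."""
    if not cal.converged:
        raise ValueError("parameter set did not converge in calibration")
    if coverage == "baseline":
        rates = cal.rates()
        cov: float | None = None
    else:
        cov = float(coverage)
        rates = cal.rates(alpha=alpha_for_coverage(cal, cov))
    traj = integrate(cal.equilibrium, rates, horizon=float(years))
    yrs = np.arange(1, years + 1)
    assisted = np.array(
        [traj.annual_flux("assisted_initiations", y) for y in yrs]
    )
    unassisted = np.array(
        [traj.annual_flux("unassisted_initiations", y) for y in yrs]
    )
    pwid = np.array([traj.pwid_size[traj.index_at(float(y))] for y in yrs])
    return ScenarioResult(
        coverage=cov,
        years=yrs,
        assisted=assisted,
        unassisted=unassisted,
        pwid_size=pwid,
        trajectory=traj if keep_trajectory else None,
    )


@dataclass
class UncertaintySummary:
    """Cross-set summary of scenario outcomes.

    ``per_set`` holds one row per (converged set, scenario) with year-10
    outcomes and reductions; ``summary`` aggregates mean and 2.5-97.5
    percentile intervals.  ``parameter_table`` aligns row-wise with the set
    index for sensitivity analyses.
    """

    n_sets: int
    seed: int
    coverages: tuple[float, ...]
    years: int
    per_set: pd.DataFrame
    parameter_table: pd.DataFrame
    n_converged: int
    failed_sets: list[int] = field(default_factory=list)

    @property
    def summary(self) -> pd.DataFrame:
        rows = []
        for scen, grp in self.per_set.groupby("scenario"):
            for col in grp.columns:
                if col in ("scenario", "set_index"):
                    continue
                x = grp[col].to_numpy()
                rows.append(
                    {
                        "scenario": scen,
                        "outcome": col,
                        "mean": x.mean(),
                        "q2.5": np.percentile(x, 2.5),
                        "q97.5": np.percentile(x, 97.5),
                    }
                )
        return pd.DataFrame(rows)

    def mean_reduction(self, coverage: float, outcome: str = "initiation_reduction_pct") -> float:
        grp = self.per_set[self.per_set["scenario"] == f"coverage_{coverage:g}"]
        return float(grp[outcome].mean())


def uncertainty_analysis(
    n_sets: int,
    seed: int,
    coverages: tuple[float, ...] = (0.4, 0.5, 0.6),
    years: int = 10,
    overrides: dict[str, DistributionSpec] | None = None,
    pins: dict[str, float] | None = None,
    multipliers: dict[str, float] | None = None,
    xi_oat_factor: float | None = None,
    parameter_sets: list[ParameterSet] | None = None,
) -> UncertaintySummary:
    """Sample, calibrate and run baseline plus scale-up scenarios.

    ``pins`` replaces sampled parameter values with point values and
    ``multipliers`` rescales them, both *after* sampling so that the random
    draws of every other parameter are unchanged (common random numbers).
    ``parameter_sets`` bypasses sampling entirely.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if parameter_sets is None:
        sets = sample_parameter_sets(n_sets, seed, overrides=overrides)
    else:
        sets = list(parameter_sets)[:n_sets]
    if pins or multipliers:
        mod = []
        for p in sets:
            kw = dict(pins or {})
            for k, f in (multipliers or {}).items():
                kw[k] = getattr(p, k) * f
            mod.append(p.replace(**kw))
        sets = mod

    records = []
    failed: list[int] = []
    for i, p in enumerate(sets):
        cal = calibrate(p, xi_oat_factor=xi_oat_factor)
        if not cal.converged:
            failed.append(i)
            continue
        try:
            base = run_scenario(cal, "baseline", years=years)
            row_base = {
                "set_index": i,
                "scenario": "baseline",
                "total_initiations": base.total[-1],
                "assisted_initiations": base.assisted[-1],
                "unassisted_initiations": base.unassisted[-1],
                "pwid_size": base.pwid_size[-1],
                "initiation_reduction_pct": 0.0,
                "pwid_reduction_pct": 0.0,
            }
            rows = [row_base]
            for cov in coverages:
                scen = run_scenario(cal, cov, years=years)
                red = scen.reductions_vs(base)
                rows.append(
                    {
                        "set_index": i,
                        "scenario": f"coverage_{cov:g}",
                        "total_initiations": scen.total[-1],
                        "assisted_initiations": scen.assisted[-1],
                        "unassisted_initiations": scen.unassisted[-1],
                        "pwid_size": scen.pwid_size[-1],
                        "initiation_reduction_pct": red["initiation_reduction_pct"].iloc[-1],
                        "pwid_reduction_pct": red["pwid_reduction_pct"].iloc[-1],
                    }
                )
        except (IntegrationError, ValueError) as exc:  # pragma: no cover
            logger.warning("scenario run failed for set %d: %s", i, exc)
            failed.append(i)
            continue
        records.extend(rows)

    n_conv = len(sets) - len(failed)
    if n_conv < 0.5 * len(sets):
        raise RuntimeError(
            f"only {n_conv}/{len(sets)} parameter sets converged; aborting"
        )
    if failed:
        logger.warning("%d/%d sets excluded", len(failed), len(sets))

    from .params import sets_to_frame

    ptable = sets_to_frame(sets)
    ptable["converged"] = ~ptable.index.isin(failed)
    return UncertaintySummary(
        n_sets=len(sets),
        seed=seed,
        coverages=tuple(coverages),
        years=years,
        per_set=pd.DataFrame(records),
        parameter_table=ptable,
        n_converged=n_conv,
        failed_sets=failed,
    )
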