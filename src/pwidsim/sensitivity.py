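"""Global (PRCC) and one-way sensitivity of the scale-up impact.

PRCC rank-transforms every sampled input and the outcome, then correlates
the residuals after regressing each on all remaining inputs.  The one-way
analyses re-run the 60%-coverage uncertainty analysis with one parameter
pinned, rescaled, or with a distinct on-OAT cessation rate, using common
random numbers, and report the relative deviation of the mean year-10
initiation reduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scenarios import UncertaintySummary, uncertainty_analysis

__all__ = [
    "PRCCResult",
    "OneWaySpec",
    "OneWayResult",
    "ONE_WAY_PRESETS",
    "prcc",
    "prcc_for_summary",
    "one_way_analysis",
    "one_way_battery",
]

logger = logging.getLogger(__name__)

#: Inputs entering the PRCC (all non-degenerate sampled parameters).
PRCC_INPUTS = (
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


@dataclass(frozen=True)
class PRCCResult:
    outcome: str
    n_sets: int
    coefficients: pd.Series  # index = parameter labels

    def __getitem__(self, label: str) -> float:
        return float(self.coefficients[label])


def _rank_residual(col: np.ndarray, others: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(col)), others])
    coef, *_ = np.linalg.lstsq(design, col, rcond=None)
    return col - design @ coef


def prcc(
    inputs: np.ndarray | pd.DataFrame,
    output: np.ndarray,
    labels: list[str] | None = None,
    outcome: str = "outcome",
) -> PRCCResult:
    """Partial rank correlation of each input column with ``output``.

    Constant columns yield ``nan`` (undefined) and are reported as such.
    """
    if isinstance(inputs, pd.DataFrame):
        labels = list(inputs.columns)
        X = inputs.to_numpy(dtype=float)
    else:
        X = np.asarray(inputs, dtype=float)
        if labels is None:
            labels = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(output, dtype=float)
    n, k = X.shape
    if len(y) != n:
        raise ValueError("inputs and output are misaligned")
    if n < k + 2:
        raise ValueError("need at least (parameters + 2) observations")

    rX = np.column_stack([rankdata(X[:, j]) for j in range(k)])
    ry = rankdata(y)
    coefs = np.full(k, np.nan)
    for j in range(k):
        if np.ptp(X[:, j]) == 0:
            continue  # constant input: PRCC undefined
        keep = [i for i in range(k) if i != j and np.ptp(X[:, i]) > 0]
        others = rX[:, keep]
        ex = _rank_residual(rX[:, j], others)
        ey = _rank_residual(ry, others)
        denom = np.sqrt((ex**2).sum() * (ey**2).sum())
        coefs[j] = float((ex * ey).sum() / denom) if denom > 0 else np.nan
    return PRCCResult(
        outcome=outcome, n_sets=n, coefficients=pd.Series(coefs, index=labels)
    )


def prcc_for_summary(
    result: UncertaintySummary,
    coverage: float = 0.6,
    outcome: str = "initiation_reduction_pct",
) -> PRCCResult:
    """PRCC of the sampled parameters against a year-10 scenario outcome."""
    scen = result.per_set[result.per_set["scenario"] == f"coverage_{coverage:g}"]
    ptable = result.parameter_table
    conv = ptable[ptable["converged"]].reset_index()
    merged = conv.merge(scen, left_on="index", right_on="set_index")
    X = merged[list(PRCC_INPUTS)]
    y = merged[outcome].to_numpy()
    return prcc(X, y, outcome=f"{outcome}@coverage_{coverage:g}")


@dataclass(frozen=True)
class OneWaySpec:
    """One override: a pinned value, a multiplier, or an on-OAT cessation factor."""

    label: str
    pins: dict[str, float] | None = None
    multipliers: dict[str, float] | None = None
    xi_oat_factor: float | None = None

    def __post_init__(self) -> None:
        n = sum(bool(x) for x in (self.pins, self.multipliers, self.xi_oat_factor))
        if n != 1:
            raise ValueError("exactly one override must be specified")


#: The nine preset one-way analyses.
ONE_WAY_PRESETS: dict[str, OneWaySpec] = {
    "non_idu_prev_low": OneWaySpec("non-IDU prevalence 8.5%", pins={"target_prev_nonidu": 0.085}),
    "non_idu_prev_high": OneWaySpec("non-IDU prevalence 9.5%", pins={"target_prev_nonidu": 0.095}),
    "pwid_prev_low": OneWaySpec("PWID prevalence 0.62%", pins={"target_prev_pwid": 0.0062}),
    "pwid_prev_high": OneWaySpec("PWID prevalence 1.83%", pins={"target_prev_pwid": 0.0183}),
    "idu_duration_low": OneWaySpec("injection career 5 years", pins={"xi": 1 / 5}),
    "idu_duration_high": OneWaySpec("injection career 25 years", pins={"xi": 1 / 25}),
    "overdose_double": OneWaySpec("overdose rate doubled", multipliers={"mu_ov": 2.0}),
    # on-OAT time to permanent cessation lengthened / shortened by 25%
    "oat_slows_cessation": OneWaySpec("OAT +25% time to cessation", xi_oat_factor=1 / 1.25),
    "oat_speeds_cessation": OneWaySpec("OAT -25% time to cessation", xi_oat_factor=1 / 0.75),
}


@dataclass(frozen=True)
class OneWayResult:
    label: str
    deviation_pct: float
    mean_reduction_base: float
    mean_reduction_modified: float
    n_sets: int
    normalize: str

    @staticmethod
    def compute(
        label: str,
        r_base: float,
        r_mod: float,
        n_sets: int,
        normalize: str = "modified",
    ) -> "OneWayResult":
        if normalize == "modified":
            dev = 100.0 * (r_mod - r_base) / r_mod
        elif normalize == "baseline":
            dev = 100.0 * (r_mod - r_base) / r_base
        else:
            raise ValueError("normalize must be 'modified' or 'baseline'")
        return OneWayResult(label, dev, r_base, r_mod, n_sets, normalize)


def _modified_run(
    spec: OneWaySpec,
    n_sets: int,
    seed: int,
    coverage: float,
    years: int,
) -> UncertaintySummary:
    return uncertainty_analysis(
        n_sets,
        seed,
        coverages=(coverage,),
        years=years,
        pins=spec.pins,
        multipliers=spec.multipliers,
        xi_oat_factor=spec.xi_oat_factor,
    )


def one_way_analysis(
    spec: OneWaySpec,
    n_sets: int,
    seed: int,
    coverage: float = 0.6,
    years: int = 10,
    normalize: str = "modified",
    base: UncertaintySummary | None = None,
) -> OneWayResult:
    """Deviation of the scale-up impact under one override.

    Both runs use the same seeded draws (common random numbers).  The
    default normalisation divides the impact difference by the modified
    analysis's impact; ``normalize='baseline'`` divides by the unmodified
    one.  Positive deviations mean a larger reduction in initiations.
    """
    if base is None:
        base = uncertainty_analysis(n_sets, seed, coverages=(coverage,), years=years)
    mod = _modified_run(spec, n_sets, seed, coverage, years)
    return OneWayResult.compute(
        spec.label,
        base.mean_reduction(coverage),
        mod.mean_reduction(coverage),
        n_sets,
        normalize,
    )


def one_way_battery(
    n_sets: int,
    seed: int,
    presets: dict[str, OneWaySpec] | None = None,
    coverage: float = 0.6,
    years: int = 10,
    normalize: str = "modified",
    base: UncertaintySummary | None = None,
) -> pd.DataFrame:
    """Run all presets against one shared unmodified run."""
    presets = ONE_WAY_PRESETS if presets is None else presets
    if base is None:
        base = uncertainty_analysis(n_sets, seed, coverages=(coverage,), years=years)
    rows = []
    for name, spec in presets.items():
        res = one_way_analysis(
            spec, n_sets, seed, coverage, years, normalize=normalize, base=base
        )
        rows.append(
            {
                "preset": name,
                "label": spec.label,
                "deviation_pct": res.deviation_pct,
                "mean_reduction_base": res.mean_reduction_base,
                "mean_reduction_modified": res.mean_reduction_modified,
            }
        )
    return pd.DataFrame(rows).set_index("preset")
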