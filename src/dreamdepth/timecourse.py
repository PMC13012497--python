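"""Time-of-night trajectories: polynomial trends, the sleepiness peak, and
the post-4AM depth-vs-sleepiness divergence.

Trends are mixed models with raw powers of clock time (hours relative to
midnight) as fixed effects next to the usual nuisance terms; candidate
orders 1-3 are compared by BIC on ML fits with identical random-effect
structure, and the winner's REML coefficients are reported.  For the
depth/sleepiness trends the respective other rating enters as a covariate
to absorb their shared variance.  The sleepiness peak is the vertex
-b/(2c) of the quadratic fixed-effect polynomial.  The divergence test
stacks depth and sleepiness in long format (two rows per awakening),
restricts to awakenings at or after 4:00 AM, and tests the measure x time
interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glme import FitResult, ModelSpec, design_for, fit_lmm

__all__ = [
    "TrendFit",
    "fit_trend",
    "estimate_peak",
    "measure_by_time_interaction",
    "adjusted_values",
]

_TIME_POWERS = {1: ("time",), 2: ("time", "time2"), 3: ("time", "time2", "time3")}


@dataclass
class TrendFit:
    """Best-BIC polynomial trend for one outcome."""

    outcome: str
    order: int
    fit: FitResult  # REML fit of the winning order
    bic_by_order: dict[int, float]
    covariates: tuple[str, ...]
    time_range: tuple[float, float]

    @property
    def time_coefficients(self) -> pd.DataFrame:
        return self.fit.params.loc[list(_TIME_POWERS[self.order])]


def _with_powers(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    t = df["time"].astype(float)
    df["time2"] = t**2
    df["time3"] = t**3
    cond = np.linalg.cond(np.column_stack([t, t**2, t**3]))
    if cond > 1e6:
        warnings.warn(f"raw time-power design is ill conditioned (cond={cond:.2g})")
    return df


def fit_trend(
    records: pd.DataFrame,
    outcome: str,
    covariates: tuple[str, ...] = (),
    orders: tuple[int, ...] = (1, 2, 3),
    nuisance: tuple[str, ...] = ("experiment", "night"),
) -> TrendFit:
    """Polynomial time trend with BIC order selection.

    ``covariates`` holds extra fixed effects (the co-rating for
    depth/sleepiness models).  Orders whose design cannot be estimated at
    the available n are excluded with a warning.
    """
    df = _with_powers(records).dropna(subset=[outcome, "time", *covariates])
    bics: dict[int, float] = {}
    for order in sorted(orders):
        spec = ModelSpec(
            outcome=outcome,
            predictors=_TIME_POWERS[order],
            nuisance=tuple(covariates) + tuple(nuisance),
        )
        try:
            bics[order] = fit_lmm(df, spec, reml=False).bic
        except ValueError as err:
            warnings.warn(f"order {order} excluded: {err}")
    if not bics:
        raise ValueError("no polynomial order could be fit")
    best = min(bics, key=bics.get)
    spec = ModelSpec(
        outcome=outcome,
        predictors=_TIME_POWERS[best],
        nuisance=tuple(covariates) + tuple(nuisance),
    )
    fit = fit_lmm(df, spec, reml=True)
    return TrendFit(
        outcome=outcome,
        order=best,
        fit=fit,
        bic_by_order=bics,
        covariates=tuple(covariates),
        time_range=(float(df["time"].min()), float(df["time"].max())),
    )


def estimate_peak(trend: TrendFit) -> dict:
    """Vertex of a quadratic trend: time -b/(2c) in hours past midnight.

    Flags a trough when the curvature is positive and warns when the
    extremum falls outside the observed time range.
    """
    if trend.order != 2:
        raise ValueError(f"peak estimation needs a quadratic trend, got order "
                         f"{trend.order}")
    b = float(trend.fit.coef("time").estimate)
    c = float(trend.fit.coef("time2").estimate)
    if c == 0:
        raise ValueError("quadratic coefficient is zero")
    t_star = -b / (2 * c)
    lo, hi = trend.time_range
    in_range = lo <= t_star <= hi
    if not in_range:
        warnings.warn(f"extremum at {t_star:.2f} h lies outside the observed "
                      f"range [{lo:.2f}, {hi:.2f}] h")
    return {"time": t_star, "kind": "peak" if c < 0 else "trough",
            "in_range": bool(in_range)}


def measure_by_time_interaction(records: pd.DataFrame,
                                cutoff: float = 4.0) -> FitResult:
    """Post-cutoff measure-by-time interaction (depth vs sleepiness).

    Awakenings at time >= cutoff contribute two long-format rows (depth and
    sleepiness); the interaction coefficient measures how much more slowly
    sleepiness changes with time than perceived depth.  Reference level of
    ``measure`` is sleep depth.
    """
    need = records.dropna(subset=["sleep_depth", "sleepiness"])
    post = need[need["time"] >= cutoff]
    if post.empty:
        raise ValueError(
            f"no awakenings at or after {cutoff:.1f} h (max time "
            f"{need['time'].max() if len(need) else float('nan'):.1f} h)"
        )
    n_per = post.groupby("participant_id").size()
    keep = n_per[n_per >= 2].index
    post = post[post["participant_id"].isin(keep)]
    long = pd.concat(
        [
            post.assign(value=post["sleep_depth"], measure="depth"),
            post.assign(value=post["sleepiness"], measure="sleepiness"),
        ],
        ignore_index=True,
    )
    spec = ModelSpec(
        outcome="value",
        predictors=("measure*time",),
        nuisance=("experiment", "night"),
        references={"measure": "depth"},
    )
    return fit_lmm(long, spec)


def adjusted_values(records: pd.DataFrame, outcome: str,
                    nuisance: tuple[str, ...] = ("experiment", "night", "time"),
                    ) -> pd.Series:
    """Outcome residualized for nuisance fixed effects and participant
    intercepts, recentered to the raw grand mean (a display transform).
    """
    df = records.dropna(subset=[outcome]).copy()
    spec = ModelSpec(outcome=outcome, predictors=(), nuisance=nuisance)
    fit = fit_lmm(df, spec)
    y, X, names, codes, levels = design_for(df, spec)
    beta = fit.params["estimate"].to_numpy()
    fixed = X[:, 1:] @ beta[1:]  # nuisance contributions, intercept kept
    blup = fit.blups[codes]
    adj = y - fixed - blup
    adj = adj - adj.mean() + y.mean()
    return pd.Series(adj, index=df["record_id"], name=f"{outcome}_adjusted")
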