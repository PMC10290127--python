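"""Nonparametric and semiparametric competing-risks estimation.

Provides the (optionally weighted) Kaplan-Meier product-limit estimator, the
Aalen-Johansen cumulative-incidence estimator for two competing causes of
death, the naive KM complement that treats the competing cause as censoring
(the biased estimator whose behavior the analysis studies), and
cause-specific proportional-hazards fits — the "multi-state model" being the
pair of cause-specific fits.

All curve estimators operate on a shared event-time grid, so the additivity
identity S(t) + F_1(t) + F_2(t) = 1 holds exactly (to rounding) at every
time.  Step curves are right-continuous.

Conventions: events precede censorings at tied times (patients censored at t
remain in the risk set for events at t); Cox fits use Efron tie handling via
lifelines, with robust sandwich standard errors whenever weights are given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "StepCurve",
    "CIFSet",
    "HazardRatioTable",
    "km_estimator",
    "aalen_johansen",
    "naive_cif",
    "cause_specific_cox",
    "multi_state_model",
    "sup_distance",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class StepCurve:
    """Right-continuous step function defined by jump times and post-jump values."""

    times: np.ndarray
    values: np.ndarray
    value_at_0: float
    n_at_risk: np.ndarray | None = None
    variance: np.ndarray | None = None
    kind: str = "survival"

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        vals = np.concatenate([[self.value_at_0], self.values])
        return vals[idx + 1] if t.ndim else float(vals[idx + 1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "estimate": self.values})
        if self.n_at_risk is not None:
            df["n_at_risk"] = self.n_at_risk
        if self.variance is not None:
            df["variance"] = self.variance
        return df


@dataclass
class CIFSet:
    """Overall survival plus one cumulative-incidence curve per cause."""

    survival: StepCurve
    cif: dict[int, StepCurve]

    def additivity_gap(self) -> float:
        """max_t |S(t) + sum_k F_k(t) - 1| on the shared grid."""
        total = self.survival.values.copy()
        for c in self.cif.values():
            total = total + c.values
        return float(np.abs(total - 1.0).max()) if len(total) else 0.0


def sup_distance(a: StepCurve, b: StepCurve) -> float:
    """Supremum distance between two step curves over their joint grid."""
    grid = np.union1d(a.times, b.times)
    if len(grid) == 0:
        return abs(a.value_at_0 - b.value_at_0)
    return float(np.abs(a(grid) - b(grid)).max())


def _check_inputs(time, event, weights):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if (time < 0).any():
        raise ValueError("times must be non-negative")
    if weights is None:
        w = np.ones_like(time)
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
    return time, event, w


def km_estimator(time, event_flag, weights=None) -> StepCurve:
    """(Weighted) Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_j <= t} (1 - d_j / n_j) with weighted event sums d_j and
    weighted at-risk sums n_j at the distinct event times; with unit weights
    this is the classical estimator.  Greenwood variance is attached.
    """
    time, event, w = _check_inputs(time, event_flag, weights)
    event = event.astype(bool)
    if not event.any():
        warnings.warn("no events observed; survival curve is identically 1", stacklevel=2)
        return StepCurve(np.array([]), np.array([]), 1.0, np.array([]), np.array([]))

    ts = np.unique(time[event])
    order = np.argsort(time, kind="stable")
    t_sorted, w_sorted = time[order], w[order]
    # weighted number at risk at each event time: sum of w over time >= t
    rev_cum = np.concatenate([[0.0], np.cumsum(w_sorted[::-1])])[::-1]
    n_at_risk = rev_cum[np.searchsorted(t_sorted, ts, side="left")]
    d = np.zeros_like(ts)
    np.add.at(d, np.searchsorted(ts, time[event]), w[event])

    frac = d / n_at_risk
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), np.inf))
        variance = np.where(surv > 0, surv**2 * gw, 0.0)
    return StepCurve(ts, surv, 1.0, n_at_risk, variance)


def aalen_johansen(time, event) -> CIFSet:
    """Aalen-Johansen cumulative incidence for event codes {0, 1, 2}.

    F_k(t) = sum_{t_j <= t} S(t_j-) d_kj / n_j with S the all-cause KM, all
    computed on the grid of distinct times with any event so that
    S + F_1 + F_2 = 1 holds identically.
    """
    time, event, w = _check_inputs(time, event, None)
    event = event.astype(int)
    if not np.isin(event, [0, 1, 2]).all():
        raise ValueError("event codes must be in {0, 1, 2}")
    any_event = event > 0
    ts = np.unique(time[any_event])

    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    rev_cum = np.concatenate([[0.0], np.cumsum(np.ones_like(t_sorted)[::-1])])[::-1]
    n_at_risk = rev_cum[np.searchsorted(t_sorted, ts, side="left")]

    d = {k: np.zeros_like(ts) for k in (1, 2)}
    for k in (1, 2):
        sel = event == k
        np.add.at(d[k], np.searchsorted(ts, time[sel]), np.ones(sel.sum()))

    haz_all = (d[1] + d[2]) / n_at_risk
    surv = np.cumprod(1.0 - haz_all)
    s_prev = np.concatenate([[1.0], surv[:-1]])
    cif = {
        k: StepCurve(
            ts, np.cumsum(s_prev * d[k] / n_at_risk), 0.0, n_at_risk, kind="incidence"
        )
        for k in (1, 2)
    }
    return CIFSet(survival=StepCurve(ts, surv, 1.0, n_at_risk), cif=cif)


def naive_cif(time, event, cause: int) -> StepCurve:
    """1 - KM with the competing cause treated as censoring.

    In the presence of competing risks this estimator overstates the
    cause-specific cumulative incidence; the overstatement is the phenomenon
    the class-mixture adjustment targets.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    event = np.asarray(event).astype(int)
    km = km_estimator(time, event == cause)
    return StepCurve(
        km.times, 1.0 - km.values, 0.0, km.n_at_risk, km.variance, kind="incidence"
    )


@dataclass
class HazardRatioTable:
    """Per-level hazard ratios for one cause-specific fit (reference HR = 1)."""

    cause: int
    reference: str
    table: pd.DataFrame
    ties: str = "efron"
    robust: bool = False
    n_iterations: int | None = None

    def hr(self, level) -> float:
        return float(self.table.set_index("level").loc[str(level), "hr"])

    def ci(self, level) -> tuple[float, float]:
        row = self.table.set_index("level").loc[str(level)]
        return float(row["ci_low"]), float(row["ci_high"])


def cause_specific_cox(
    time,
    event,
    cause: int,
    covariate,
    weights=None,
    reference=None,
) -> HazardRatioTable:
    """Cause-specific proportional-hazards fit for one competing cause.

    Events of the other cause are censored; the partial likelihood is
    maximized with Efron tie handling (lifelines).  The covariate must be
    categorical; hazard ratios are reported against ``reference`` (default:
    first level in sorted order) with 95% Wald intervals
    exp(coef +/- 1.96 SE).  With weights, robust sandwich SEs are used.
    Levels without any event of the target cause are non-estimable and
    reported as NaN rows.
    """
    if cause not in (1, 2):
        raise ValueError("cause must be 1 or 2")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    cov = pd.Series(covariate).astype(str).to_numpy()
    levels = sorted(set(cov))
    if len(levels) < 2:
        raise ValueError("covariate must have at least two levels")
    reference = str(reference) if reference is not None else levels[0]
    if reference not in levels:
        raise ValueError(f"reference level '{reference}' not among {levels}")

    E = (event == cause).astype(int)
    n_events = {lv: int(E[cov == lv].sum()) for lv in levels}
    estimable = [lv for lv in levels if lv != reference and n_events[lv] > 0]
    dropped = [lv for lv in levels if lv != reference and n_events[lv] == 0]
    if dropped:
        warnings.warn(
            f"level(s) {dropped} have no cause-{cause} events and are non-estimable",
            stacklevel=2,
        )
    if n_events[reference] == 0:
        warnings.warn(
            f"reference level '{reference}' has no cause-{cause} events; "
            "hazard ratios against it are unstable", stacklevel=2,
        )

    df = pd.DataFrame({"_time": time, "_event": E})
    colmap = {}
    for i, lv in enumerate(estimable):
        col = f"x{i}"
        df[col] = (cov == lv).astype(float)
        colmap[col] = lv
    kwargs = {}
    if weights is not None:
        df["_w"] = np.asarray(weights, dtype=float)
        kwargs["weights_col"] = "_w"
        kwargs["robust"] = True
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="_time", event_col="_event", **kwargs)
    summary = cph.summary

    rows = [
        {
            "cause": cause, "level": reference, "n": int((cov == reference).sum()),
            "n_events": n_events[reference], "coef": 0.0, "hr": 1.0,
            "se": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
            "reference": True, "estimable": True,
        }
    ]
    for col, lv in colmap.items():
        coef = float(summary.loc[col, "coef"])
        se = float(summary.loc[col, "se(coef)"])
        rows.append(
            {
                "cause": cause, "level": lv, "n": int((cov == lv).sum()),
                "n_events": n_events[lv], "coef": coef, "hr": float(np.exp(coef)),
                "se": se, "ci_low": float(np.exp(coef - _Z95 * se)),
                "ci_high": float(np.exp(coef + _Z95 * se)),
                "p": float(summary.loc[col, "p"]),
                "reference": False, "estimable": True,
            }
        )
    for lv in dropped:
        rows.append(
            {
                "cause": cause, "level": lv, "n": int((cov == lv).sum()),
                "n_events": 0, "coef": np.nan, "hr": np.nan, "se": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                "reference": False, "estimable": False,
            }
        )
    table = pd.DataFrame(rows)
    return HazardRatioTable(
        cause=cause,
        reference=reference,
        table=table,
        robust=weights is not None,
        n_iterations=getattr(cph, "_n_iterations", None),
    )


def multi_state_model(
    time, event, covariate, weights=None, reference=None
) -> dict[int, HazardRatioTable]:
    """The pair of cause-specific fits (cancer death, other-cause death)."""
    return {
        cause: cause_specific_cox(
            time, event, cause, covariate, weights=weights, reference=reference
        )
        for cause in (1, 2)
    }
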