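"""Kaplan–Meier estimation, log-rank testing, and stratification summaries.

The product-limit estimator and the unweighted (Mantel–Haenszel) two-group
log-rank test are implemented directly on the event tables; tied events and
censorings at the same time follow the standard convention (events first).
A median that the curve never reaches is reported as a distinct
"not reached" state, never coerced to a number.

Aggregated curves pool every (case, run) pair of a Monte Carlo
cross-validation result by predicted arm, so a case re-enters the pooled
risk set once per run. This matches the construction of aggregated
test-fold predictions; the pooled curves are descriptive and their implied
confidence would not be valid inferential uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

NOT_REACHED = "not reached"


@dataclass
class KMCurve:
    """Product-limit curve: step times, survival, risk counts, median."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    median: float | None  # None = not reached

    @property
    def median_reached(self) -> bool:
        return self.median is not None

    @property
    def median_label(self) -> float | str:
        return NOT_REACHED if self.median is None else self.median

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival, "at_risk": self.at_risk})


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    ``times`` are non-negative observation times (months); ``events`` flags
    deaths (True) versus censorings (False). Censored observations thin the
    risk set without producing steps. The median is the earliest time with
    S(t) <= 0.5, or None if the curve never drops that far.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("survival times must be non-negative")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]

    event_times = np.unique(t[e])
    surv, risks = [], []
    s = 1.0
    for ti in event_times:
        n_risk = int((t >= ti).sum())
        d = int((e & (t == ti)).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        risks.append(n_risk)
    surv_arr = np.asarray(surv)
    median = None
    reached = np.flatnonzero(surv_arr <= 0.5 + 1e-12)
    if reached.size:
        median = float(event_times[reached[0]])
    return KMCurve(times=event_times, survival=surv_arr, at_risk=np.asarray(risks, dtype=int),
                   n=len(t), median=median)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Unweighted two-group log-rank test; returns (chi-square, p), 1 df."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    grp_a = np.concatenate([np.ones(ta.size, bool), np.zeros(tb.size, bool)])
    event_times = np.unique(all_t[all_e])

    obs_a = exp_a = var = 0.0
    for ti in event_times:
        at_risk = all_t >= ti
        n = int(at_risk.sum())
        n_a = int((at_risk & grp_a).sum())
        d = int((all_e & (all_t == ti)).sum())
        d_a = int((all_e & (all_t == ti) & grp_a).sum())
        obs_a += d_a
        exp_a += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs_a - exp_a) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class AggregatedKM:
    """Per-arm pooled (case, run) observations and their KM curves."""

    arms: dict[str, KMCurve]
    pooled: dict[str, pd.DataFrame]
    n_runs: int
    empty_arms: tuple[str, ...] = ()


def aggregate_km(mccv_result, clinical: pd.DataFrame) -> AggregatedKM:
    """Pool aggregated test-fold predictions over all runs into two KM arms.

    ``clinical`` must be indexed by case_id with columns ``os_months`` and
    ``event``. Incomplete runs (any case without a prediction) are excluded
    with a warning; an arm that receives no observations is flagged.
    """
    preds = mccv_result.predictions  # (M, n) floats 1/0/NaN
    case_ids = list(mccv_result.case_ids)
    complete = np.isfinite(preds).all(axis=1)
    if not complete.all():
        warnings.warn(f"excluding {int((~complete).sum())} incomplete runs from aggregation",
                      stacklevel=2)
    preds = preds[complete]
    os_m = clinical.loc[case_ids, "os_months"].to_numpy(dtype=float)
    ev = clinical.loc[case_ids, "event"].to_numpy(dtype=bool)

    arms: dict[str, KMCurve] = {}
    pooled: dict[str, pd.DataFrame] = {}
    empty = []
    for arm, value in (("responder", 1.0), ("non_responder", 0.0)):
        runs, cases = np.nonzero(preds == value)
        if cases.size == 0:
            empty.append(arm)
            continue
        df = pd.DataFrame({
            "run": runs,
            "case_id": [case_ids[i] for i in cases],
            "os_months": os_m[cases],
            "event": ev[cases],
        })
        pooled[arm] = df
        arms[arm] = km_estimate(df.os_months, df.event)
    if empty:
        warnings.warn(f"aggregated arms with no observations: {empty}", stacklevel=2)
    return AggregatedKM(arms=arms, pooled=pooled, n_runs=int(complete.sum()),
                        empty_arms=tuple(empty))


def stratification_summary(predictions, truth, clinical: pd.DataFrame) -> dict:
    """Accuracy plus per-arm median OS for one set of case predictions.

    ``predictions``/``truth`` are aligned with ``clinical.index``. Median OS
    of an arm whose curve never crosses 0.5 is reported as "not reached".
    """
    pred = np.asarray(predictions, dtype=float)
    tru = np.asarray(truth, dtype=float)
    if len(pred) != len(tru) or len(pred) != len(clinical):
        raise ValueError("predictions, truth and clinical table must align")
    ok = np.isfinite(pred)
    accuracy = float((pred[ok] == tru[ok]).mean()) if ok.any() else float("nan")
    out = {"accuracy": accuracy, "n": int(len(pred)), "n_predicted": int(ok.sum())}
    for arm, value in (("responder", 1.0), ("non_responder", 0.0)):
        sel = pred == value
        if not sel.any():
            out[f"median_os_{arm}"] = None
            continue
        curve = km_estimate(clinical.os_months.to_numpy()[sel], clinical.event.to_numpy()[sel])
        out[f"median_os_{arm}"] = curve.median_label
    return out
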