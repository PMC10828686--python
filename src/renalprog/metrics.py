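"""Survival-model evaluation: concordance index, integrated Brier score and
cumulative dynamic AUC.

Conventions:

* C-index (Harrell, time-independent): a pair is comparable iff the subject
  with the strictly shorter observed time had the event; tied risk scores
  count 1/2.
* IBS: Brier score with Graf-style inverse-probability-of-censoring weights
  (Kaplan-Meier of the censoring distribution fitted on the evaluation
  cohort), evaluated on 100 equally spaced times between the cohort's
  minimum and maximum event times and trapezoid-integrated, normalized by
  the grid span.
* Cumulative dynamic AUC: Uno's IPCW estimator (delegated to
  scikit-survival) with the mean AUC integrated over the evaluation times.

The risk functional used with curve outputs is ``1 - S(t*)`` at the grid's
median time (the curve output itself defines no scalar risk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sksurv.metrics import cumulative_dynamic_auc as _sksurv_cd_auc
from sksurv.nonparametric import kaplan_meier_estimator
from sksurv.util import Surv

from .survival import SurvivalCurve


def _as_arrays(durations, events):
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("durations and events must be equal-length 1D arrays")
    return t, e


def concordance_index(risks, durations, events) -> tuple[float, int]:
    """Harrell's concordance index and the number of comparable pairs.

    Comparable: the subject with the strictly shorter observed time died.
    Concordant: that subject also has the higher risk score; ties in risk
    count 1/2.
    """
    r = np.asarray(risks, dtype=float)
    t, e = _as_arrays(durations, events)
    if r.shape != t.shape:
        raise ValueError("risks length mismatch")
    # pair (i, j) comparable iff t_i < t_j and e_i == 1
    shorter = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(shorter.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (e.g. all records censored)")
    conc = (r[:, None] > r[None, :]) & shorter
    tied = (r[:, None] == r[None, :]) & shorter
    c = (conc.sum() + 0.5 * tied.sum()) / n_comp
    return float(c), n_comp


def _censoring_survival(durations, events):
    """Step function G(t) = KM estimate of P(censoring time > t)."""
    t, e = _as_arrays(durations, events)
    times, probs = kaplan_meier_estimator((e == 0), t)

    def g(query, before=False):
        q = np.asarray(query, dtype=float)
        # right-continuous step function; G(t^-) via strict inequality
        side = "left" if before else "right"
        idx = np.searchsorted(times, q, side=side) - 1
        out = np.where(idx < 0, 1.0, probs[np.clip(idx, 0, len(probs) - 1)])
        return out

    return g


def brier_scores(curves: list[SurvivalCurve], durations, events,
                 eval_times) -> np.ndarray:
    """IPCW (Graf) Brier score at each evaluation time."""
    t, e = _as_arrays(durations, events)
    if len(curves) != t.size:
        raise ValueError("one curve per patient required")
    eval_times = np.asarray(eval_times, dtype=float)
    g = _censoring_survival(t, e)
    s_hat = np.stack([c.survival_at(eval_times) for c in curves])  # (p, m)
    g_at_t = np.clip(g(eval_times), 1e-12, None)                   # (m,)
    g_at_ti = np.clip(g(t, before=True), 1e-12, None)              # (p,)
    died_by = (t[:, None] <= eval_times[None, :]) & (e[:, None] == 1)
    still_at_risk = t[:, None] > eval_times[None, :]
    contrib = (s_hat ** 2 * died_by / g_at_ti[:, None]
               + (1.0 - s_hat) ** 2 * still_at_risk / g_at_t[None, :])
    return contrib.mean(axis=0)


def integrated_brier_score(curves: list[SurvivalCurve], durations, events,
                           n_grid: int = 100) -> float:
    """Trapezoid-integrated Brier score over an event-time grid.

    The grid holds ``n_grid`` equally spaced times between the cohort's
    minimum and maximum event times; the integral is normalized by the grid
    span.
    """
    t, e = _as_arrays(durations, events)
    ev = t[e == 1]
    if ev.size == 0:
        raise ValueError("no events: IBS undefined")
    lo, hi = float(ev.min()), float(ev.max())
    if not hi > lo:
        raise ValueError("degenerate evaluation grid (min event time == max)")
    times = np.linspace(lo, hi, n_grid)
    bs = brier_scores(curves, t, e, times)
    return float(np.trapezoid(bs, times) / (hi - lo))


def cumulative_dynamic_auc(risks, durations, events, eval_times=None
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-time cumulative/dynamic AUC and the integrated (mean) AUC.

    Evaluation times default to the cohort's event times strictly inside
    the observed follow-up range; times with no cases are skipped by the
    IPCW estimator with a warning.
    """
    r = np.asarray(risks, dtype=float)
    t, e = _as_arrays(durations, events)
    if eval_times is None:
        ev = np.unique(t[e == 1])
        eval_times = ev[(ev > t.min()) & (ev < t.max())]
    eval_times = np.asarray(eval_times, dtype=float)
    if eval_times.size == 0:
        raise ValueError("no valid evaluation times for cumulative dynamic AUC")
    y = Surv.from_arrays(event=e.astype(bool), time=t)
    aucs, mean_auc = _sksurv_cd_auc(y, y, r, eval_times)
    return np.atleast_1d(aucs), eval_times, float(mean_auc)


@dataclass
class MetricsReport:
    c_index: float
    n_comparable_pairs: int
    ibs: float
    cumulative_dynamic_auc: float
    auc_times: np.ndarray | None = None
    auc_values: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"c_index": self.c_index,
                "n_comparable_pairs": self.n_comparable_pairs,
                "ibs": self.ibs,
                "cumulative_dynamic_auc": self.cumulative_dynamic_auc}


def evaluate_survival(curves: list[SurvivalCurve], risks, durations, events,
                      n_grid: int = 100) -> MetricsReport:
    """Full metric panel for a set of predicted curves and risk scores."""
    c, n_comp = concordance_index(risks, durations, events)
    ibs = integrated_brier_score(curves, durations, events, n_grid=n_grid)
    try:
        aucs, times, mean_auc = cumulative_dynamic_auc(risks, durations, events)
    except ValueError as exc:
        warnings.warn(f"cumulative dynamic AUC unavailable: {exc}")
        aucs, times, mean_auc = None, None, float("nan")
    return MetricsReport(c_index=c, n_comparable_pairs=n_comp, ibs=ibs,
                         cumulative_dynamic_auc=mean_auc,
                         auc_times=times, auc_values=aucs)
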