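"""Discrete-time survival modelling with a logistic-hazard likelihood.

The follow-up period ``[0, t_max]`` is divided into ``n`` equidistant
left-closed/right-open intervals.  Each patient's outcome is encoded as two
binary vectors:

* ``survs`` — intervals the patient is known to have survived.  For a death
  at time ``t``: ``survs_i = 1`` iff ``t >= t_i`` (the interval's right
  boundary).  For a censoring at ``t``: ``survs_i = 1`` iff
  ``t >= (t_{i-1} + t_i) / 2`` — the half-interval convention that credits a
  censored patient with an interval once they are observed past its
  midpoint.
* ``survf`` — the single interval in which death occurred (all zero for
  censored patients).

A small network maps a patient's feature vector to ``n`` sigmoid outputs
interpreted as per-interval *conditional survival* probabilities
``1 - h_i`` (``h_i`` the discrete hazard).  The training loss is the
negative full log-likelihood in vectorized form::

    L = -sum_x sum_i [ ln(1 + survs_xi * (pred_xi - 1))
                       + ln(1 - survf_xi * pred_xi) ]

which term-by-term equals ``ln(pred)`` for survived intervals and
``ln(1 - pred)`` for the death interval — the classical discrete-time
likelihood ``h_j * prod_{i<j}(1 - h_i)`` per patient.

The cumulative survival curve is ``S(t_j) = prod_{i<=j} pred_i`` with
``S(0) = 1``, made continuous by linear interpolation between the interval
boundaries (a constant-density assumption within each interval).

The high-level entry point pairs a model with its results:

>>> model = DiscreteTimeSurvival(features, durations, events, n_intervals=15)
>>> res = model.fit(seed=0)
>>> curves = res.predict_curves(features_new)
>>> print(res.summary())
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn

_EPS = 1e-7


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    duration: float
    event: int

    def __post_init__(self):
        if not np.isfinite(self.duration) or self.duration < 0:
            raise ValueError("duration must be finite and non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass(frozen=True)
class TimeGrid:
    """``n`` equidistant left-closed/right-open intervals covering [0, t_max]."""

    boundaries: np.ndarray  # length n + 1, boundaries[0] == 0

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        object.__setattr__(self, "boundaries", b)
        if b.ndim != 1 or b.size < 2 or b[0] != 0.0:
            raise ValueError("boundaries must start at 0 with >= 1 interval")
        widths = np.diff(b)
        if (widths <= 0).any() or np.abs(widths - widths[0]).max() > 1e-9:
            raise ValueError("intervals must be equidistant and increasing")

    @property
    def n_intervals(self) -> int:
        return self.boundaries.size - 1

    @property
    def width(self) -> float:
        return float(self.boundaries[1] - self.boundaries[0])

    @property
    def t_max(self) -> float:
        return float(self.boundaries[-1])


def make_time_grid(max_duration: float, n_intervals: int) -> TimeGrid:
    """Interval width = ``max_duration / n_intervals``."""
    if max_duration <= 0 or n_intervals < 1:
        raise ValueError("max_duration must be > 0 and n_intervals >= 1")
    return TimeGrid(np.linspace(0.0, max_duration, n_intervals + 1))


def encode_labels(duration: float, event: int, grid: TimeGrid
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Encode one record as its (survs, survf) indicator vectors.

    Deaths exactly at the grid's right edge are assigned to the last
    interval (its right boundary treated as closed) so the maximum-duration
    patient is not dropped.  Durations beyond the grid are clamped with a
    warning.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if event not in (0, 1):
        raise ValueError("event must be 0 or 1")
    t = float(duration)
    if t > grid.t_max:
        warnings.warn(f"duration {t} beyond grid maximum {grid.t_max}; clamping")
        t = grid.t_max
    left = grid.boundaries[:-1]
    right = grid.boundaries[1:]
    n = grid.n_intervals
    survf = np.zeros(n, dtype=np.int8)
    if event == 1:
        survs = (t >= right).astype(np.int8)
        j = np.searchsorted(right, t, side="right")
        if j == n:  # death exactly at t_max -> last interval
            j = n - 1
            survs[-1] = 0
        survf[j] = 1
    else:
        midpoints = 0.5 * (left + right)
        survs = (t >= midpoints).astype(np.int8)
    return survs, survf


def encode_dataset(durations, events, grid: TimeGrid
                   ) -> tuple[np.ndarray, np.ndarray]:
    pairs = [encode_labels(t, e, grid) for t, e in zip(durations, events)]
    survs = np.stack([p[0] for p in pairs])
    survf = np.stack([p[1] for p in pairs])
    return survs, survf


def survival_loss(pred: np.ndarray, survs: np.ndarray, survf: np.ndarray
                  ) -> float:
    """Negative full log-likelihood of the discrete-time model (vectorized).

    ``pred`` holds per-interval conditional survival probabilities in (0,1);
    values are clamped to [1e-7, 1 - 1e-7] before the logarithms.
    """
    pred = np.asarray(pred, dtype=float)
    survs = np.asarray(survs)
    survf = np.asarray(survf)
    if pred.shape != survs.shape or pred.shape != survf.shape:
        raise ValueError("pred, survs and survf must share a (p, n) shape")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    ll = np.log1p(survs * (p - 1.0)) + np.log1p(-survf * p)
    return float(-ll.sum())


def _loss_grad(pred, survs, survf):
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    return (-survs / p + survf / (1.0 - p)).astype(np.float32)


class SurvivalNet:
    """Two-layer feed-forward net: input -> 32 (ReLU, BN, dropout) -> n sigmoid."""

    def __init__(self, input_dim: int, hidden: int = 32, n_intervals: int = 15,
                 dropout: float = 0.4, seed: int = 0):
        if input_dim < 1 or hidden < 1 or n_intervals < 1:
            raise ValueError("dimensions must be >= 1")
        rng = np.random.default_rng(seed)
        self.net = _nn.Sequential([
            _nn.Linear(input_dim, hidden, rng),
            _nn.ReLU(),
            _nn.BatchNorm(hidden, spatial=False),
            _nn.Dropout(dropout, rng),
            _nn.Linear(hidden, n_intervals, rng),
            _nn.Sigmoid(),
        ])
        self.input_dim, self.hidden, self.n_intervals = input_dim, hidden, n_intervals

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[None]
        if x.shape[1] != self.input_dim:
            raise ValueError("feature dimension mismatch")
        return self.net.forward(x, train)

    def params(self):
        return self.net.params()


def build_survival_net(input_dim: int, hidden: int = 32, n_intervals: int = 15,
                       dropout: float = 0.4, seed: int = 0) -> SurvivalNet:
    return SurvivalNet(input_dim, hidden, n_intervals, dropout, seed)


def train_survival_net(net: SurvivalNet, features: np.ndarray,
                       survs: np.ndarray, survf: np.ndarray,
                       val_features: np.ndarray, val_survs: np.ndarray,
                       val_survf: np.ndarray, lr: float = 1e-3,
                       max_epochs: int = 500, patience: int = 10,
                       batch_size: int | None = None, seed: int = 0
                       ) -> tuple[SurvivalNet, pd.DataFrame]:
    """Adam training with early stopping on validation loss.

    Stops after ``patience`` consecutive epochs without a new best validation
    loss; the returned network carries the best-epoch parameters.
    """
    x = np.asarray(features, dtype=np.float32)
    if survs.sum() == 0 and survf.sum() == 0:
        raise ValueError("training labels are all zero (no informative records); "
                         "need at least one uncensored or informative record")
    params = net.params()
    state = _nn.state_arrays(net.net)
    opt = _nn.Adam(params, lr)
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    bs = n if batch_size is None else batch_size
    best_val, best_state, stall, log = np.inf, _nn.snapshot(state), 0, []
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            opt.zero_grad()
            pred = net.forward(x[idx], train=True)
            ep_loss += survival_loss(pred, survs[idx], survf[idx])
            net.net.backward(_loss_grad(pred, survs[idx], survf[idx]))
            opt.step()
        val_pred = net.forward(val_features, train=False)
        val_loss = survival_loss(val_pred, val_survs, val_survf)
        log.append({"epoch": epoch, "train_loss": ep_loss / n,
                    "val_loss": val_loss / len(val_features)})
        if val_loss < best_val - 1e-12:
            best_val, best_state, stall = val_loss, _nn.snapshot(state), 0
        else:
            stall += 1
            if stall > patience:
                break
    _nn.restore(state, best_state)
    return net, pd.DataFrame(log)


@dataclass
class SurvivalCurve:
    """Discrete conditional-survival outputs and the derived survival curve."""

    grid: TimeGrid
    conditional: np.ndarray            # (n,) per-interval P(survive i | alive)
    cumulative: np.ndarray = field(init=False)
    knots: np.ndarray | None = None    # (m, 2) interpolated (time, probability)

    def __post_init__(self):
        cond = np.asarray(self.conditional, dtype=float)
        if cond.shape != (self.grid.n_intervals,):
            raise ValueError("conditional must have one value per interval")
        self.conditional = cond
        self.cumulative = np.cumprod(cond)

    def survival_at(self, times) -> np.ndarray:
        """Piecewise-linear S(t) through (0, 1) and the interval boundaries."""
        xs = self.grid.boundaries
        ys = np.concatenate([[1.0], self.cumulative])
        return np.interp(np.asarray(times, dtype=float), xs, ys)


def predict_survival_curve(net: SurvivalNet, feature: np.ndarray,
                           grid: TimeGrid) -> SurvivalCurve:
    cond = net.forward(np.asarray(feature, dtype=np.float32)[None]
                       if np.ndim(feature) == 1 else feature, train=False)
    return SurvivalCurve(grid, cond[0])


def interpolate_curve(curve: SurvivalCurve, n_points: int = 40) -> SurvivalCurve:
    """Evaluate the piecewise-linear curve at ``n_points`` equispaced times.

    The linear segments correspond to a constant event density within each
    interval; values at the grid boundaries equal the discrete curve exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    times = np.linspace(0.0, curve.grid.t_max, n_points)
    knots = np.column_stack([times, curve.survival_at(times)])
    out = SurvivalCurve(curve.grid, curve.conditional.copy())
    out.knots = knots
    return out


# ---------------------------------------------------------------------------
# Model / results pairing


class DiscreteTimeSurvival:
    """Discrete-time survival model over prognostic feature vectors.

    Parameters
    ----------
    features : (p, f) array
        One prognostic feature vector per patient.
    durations, events : length-p arrays
        Observed time in days and the death indicator (1 death, 0 censored).
    n_intervals : int
        Number of equidistant hazard intervals (default 15).
    grid : TimeGrid, optional
        Explicit time grid; by default built from ``max(durations)``.
    """

    def __init__(self, features, durations, events, n_intervals: int = 15,
                 grid: TimeGrid | None = None, patient_ids=None):
        self.features = np.asarray(features, dtype=np.float32)
        self.durations = np.asarray(durations, dtype=float)
        self.events = np.asarray(events, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a (p, f) matrix")
        p = self.features.shape[0]
        if self.durations.shape != (p,) or self.events.shape != (p,):
            raise ValueError("durations/events length mismatch")
        if (self.durations < 0).any():
            raise ValueError("durations must be non-negative")
        if not np.isin(self.events, (0, 1)).all():
            raise ValueError("events must be 0/1")
        self.grid = grid or make_time_grid(float(self.durations.max()), n_intervals)
        self.patient_ids = (list(patient_ids) if patient_ids is not None
                            else [f"p{i}" for i in range(p)])

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame, clinical: pd.DataFrame,
                       n_intervals: int = 15, grid: TimeGrid | None = None):
        """Join a feature table (patient_id + feature columns) with a clinical
        frame (patient_id, duration_days, event)."""
        merged = features.merge(clinical, on="patient_id", how="inner")
        fcols = [c for c in features.columns if c != "patient_id"]
        return cls(merged[fcols].to_numpy(), merged["duration_days"].to_numpy(),
                   merged["event"].to_numpy(), n_intervals=n_intervals,
                   grid=grid, patient_ids=merged["patient_id"].tolist())

    def fit(self, hidden: int = 32, dropout: float = 0.4, lr: float = 1e-3,
            max_epochs: int = 500, patience: int = 10,
            val_fraction: float = 0.2, batch_size: int | None = None,
            seed: int = 0) -> "DiscreteTimeSurvivalResults":
        """Train the survival network and return a results object.

        An internal validation split (``val_fraction`` of patients, event-
        stratified) drives early stopping.  Feature normalization statistics
        are computed on the training portion only.
        """
        if self.events.sum() < 1:
            raise ValueError("need at least one uncensored record to fit")
        rng = np.random.default_rng(seed)
        p = self.features.shape[0]
        idx_event = np.flatnonzero(self.events == 1)
        idx_cens = np.flatnonzero(self.events == 0)
        val_idx = np.concatenate([
            rng.permutation(idx_event)[:max(1, int(round(val_fraction * idx_event.size)))],
            rng.permutation(idx_cens)[:int(round(val_fraction * idx_cens.size))],
        ])
        train_idx = np.setdiff1d(np.arange(p), val_idx)
        mean = self.features[train_idx].mean(axis=0)
        sd = self.features[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        z = (self.features - mean) / sd
        survs, survf = encode_dataset(self.durations, self.events, self.grid)
        net = SurvivalNet(self.features.shape[1], hidden,
                          self.grid.n_intervals, dropout, seed=seed)
        net, history = train_survival_net(
            net, z[train_idx], survs[train_idx], survf[train_idx],
            z[val_idx], survs[val_idx], survf[val_idx],
            lr=lr, max_epochs=max_epochs, patience=patience,
            batch_size=batch_size, seed=seed)
        return DiscreteTimeSurvivalResults(self, net, mean, sd, history,
                                           train_idx, val_idx)


class DiscreteTimeSurvivalResults:
    """Fitted discrete-time survival model: curves, metrics and summary."""

    def __init__(self, model: DiscreteTimeSurvival, net: SurvivalNet,
                 feature_mean, feature_sd, history: pd.DataFrame,
                 train_idx, val_idx):
        self.model = model
        self.net = net
        self.grid = model.grid
        self.feature_mean = feature_mean
        self.feature_sd = feature_sd
        self.history = history
        self.train_idx = train_idx
        self.val_idx = val_idx

    def _normalize(self, features) -> np.ndarray:
        x = np.asarray(features, dtype=np.float32)
        if x.ndim == 1:
            x = x[None]
        return (x - self.feature_mean) / self.feature_sd

    def predict_conditional(self, features) -> np.ndarray:
        """Per-interval conditional survival probabilities, shape (p, n)."""
        return self.net.forward(self._normalize(features), train=False)

    def predict_curves(self, features, n_points: int | None = None
                       ) -> list[SurvivalCurve]:
        cond = self.predict_conditional(features)
        curves = [SurvivalCurve(self.grid, c) for c in cond]
        if n_points is not None:
            curves = [interpolate_curve(c, n_points) for c in curves]
        return curves

    def risk_scores(self, features, at_time: float | None = None) -> np.ndarray:
        """Risk = 1 - S(t*); by default t* is the grid's median time."""
        t_star = (0.5 * self.grid.t_max) if at_time is None else at_time
        curves = self.predict_curves(features)
        return np.array([1.0 - c.survival_at(t_star) for c in curves])

    def evaluate(self, features, durations, events):
        from .metrics import evaluate_survival
        curves = self.predict_curves(features)
        risks = self.risk_scores(features)
        return evaluate_survival(curves, risks, durations, events)

    def summary(self) -> str:
        m = self.model
        best = self.history["val_loss"].min() if len(self.history) else float("nan")
        lines = [
            "Discrete-Time Survival Model (logistic hazard)",
            "=" * 54,
            f"No. patients:        {m.features.shape[0]}",
            f"  deaths / censored: {int(m.events.sum())} / {int((1 - m.events).sum())}",
            f"Feature dimension:   {m.features.shape[1]}",
            f"Time grid:           {self.grid.n_intervals} intervals of "
            f"{self.grid.width:.1f} days, horizon {self.grid.t_max:.0f} days",
            f"Network:             {m.features.shape[1]} -> {self.net.hidden} "
            f"(ReLU, BN, dropout) -> {self.net.n_intervals} (sigmoid)",
            f"Epochs run:          {len(self.history)}",
            f"Best val. loss/pt:   {best:.4f}",
        ]
        return "\n".join(lines)
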