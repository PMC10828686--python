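"""Orchestration: event-stratified three-fold splitting and end-to-end runs.

The splitter divides deceased patients as evenly as possible (difference at
most one) across the train/validation/test parts of every fold, rotating
which third is held out so each patient is tested exactly once over the
three folds.  Overall split sizes follow the 33% test / 10% validation /
57% train fractions.  The same index sets are used for both the grading and
the survival stage of a fold, and augmented copies of a patient never leave
that patient's split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import augment as aug
from . import grading, synthetic
from .preprocess import prepare_sample
from .survival import DiscreteTimeSurvival


@dataclass
class Fold:
    train: list[str]
    val: list[str]
    test: list[str]

    def deceased_counts(self, events: dict[str, int]) -> dict[str, int]:
        return {part: sum(events[pid] for pid in getattr(self, part))
                for part in ("train", "val", "test")}


@dataclass
class FoldPlan:
    folds: list[Fold]

    def validate(self, all_ids: set[str]) -> None:
        for k, fold in enumerate(self.folds):
            parts = [set(fold.train), set(fold.val), set(fold.test)]
            union = parts[0] | parts[1] | parts[2]
            if union != all_ids:
                raise AssertionError(f"fold {k}: union of splits != cohort")
            if (parts[0] & parts[1]) or (parts[0] & parts[2]) or (parts[1] & parts[2]):
                raise AssertionError(f"fold {k}: splits overlap (leakage)")


def _chunk3(items: list, k: int) -> list[list]:
    """Split into 3 near-equal rotation groups; group k first for fold k."""
    sizes = [len(items) // 3] * 3
    for i in range(len(items) % 3):
        sizes[i] += 1
    groups, start = [], 0
    for s in sizes:
        groups.append(items[start:start + s])
        start += s
    return groups


def stratified_threefold_split(clinical: pd.DataFrame,
                               test_frac: float = 1.0 / 3.0,
                               val_frac: float = 0.10,
                               seed: int = 0) -> FoldPlan:
    """Three folds with deceased patients divided evenly across the splits.

    ``clinical`` needs columns ``patient_id`` and ``event``.  Requires at
    least 3 deceased patients.  Within each fold the deceased counts of
    train/val/test differ by at most one; the censored patients fill the
    splits up to the overall fractions.
    """
    events = dict(zip(clinical["patient_id"].astype(str), clinical["event"]))
    rng = np.random.default_rng(seed)
    dead = sorted([p for p, e in events.items() if e == 1])
    cens = sorted([p for p, e in events.items() if e == 0])
    if len(dead) < 3:
        raise ValueError(f"need at least 3 deceased patients, got {len(dead)}")
    rng.shuffle(dead)
    rng.shuffle(cens)
    d_groups = _chunk3(dead, 3)
    c_groups = _chunk3(cens, 3)
    n = len(events)
    folds = []
    for k in range(3):
        d_test = d_groups[k]
        d_val = d_groups[(k + 1) % 3]
        d_train = d_groups[(k + 2) % 3]
        c_test = c_groups[k]
        rest = c_groups[(k + 1) % 3] + c_groups[(k + 2) % 3]
        rest = list(rest)
        rng.shuffle(rest)
        n_val_c = max(0, int(round(val_frac * n)) - len(d_val))
        c_val = rest[:n_val_c]
        c_train = rest[n_val_c:]
        folds.append(Fold(train=sorted(d_train + c_train),
                          val=sorted(d_val + c_val),
                          test=sorted(d_test + c_test)))
    plan = FoldPlan(folds)
    plan.validate(set(events))
    return plan


@dataclass
class EndToEndConfig:
    """Desk-scale defaults; the full-size run uses 128^3 targets and
    width/depth scales of 1.0."""

    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    volume_size: tuple[int, int, int] = (48, 48, 48)
    target_shape: tuple[int, int, int] = (32, 32, 32)
    augment_target_per_class: int | None = None   # None disables augmentation
    grader_width_scale: float = 0.02
    grader_depth_scale: float = 0.1
    grader_epochs: int = 3
    grader_lr: float = 1e-4
    grader_batch_size: int = 4
    survival_hidden: int = 32
    survival_dropout: float = 0.4
    survival_lr: float = 1e-3
    survival_max_epochs: int = 100
    survival_patience: int = 10
    n_intervals: int = 15
    seed: int = 0


def run_end_to_end(config: EndToEndConfig) -> dict:
    """Simulate -> prepare -> (augment) -> grade -> extract -> survive -> evaluate.

    Returns a report dict with one entry per fold plus the across-fold mean
    of C-index, IBS and AUC, and per-stage timings.  Deterministic for a
    fixed config.
    """
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    clinical = synthetic.simulate_survival_dataset(config.cohort)
    volumes = synthetic.simulate_cohort_volumes(clinical, config.volume_size,
                                                seed=config.seed)
    timings["simulate"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    samples = {}
    for pid, vol, mask in volumes:
        grade = int(clinical.loc[clinical.patient_id == pid, "grade"].iloc[0])
        prepared = prepare_sample(vol, mask, grade, pid,
                                  target=config.target_shape)
        samples[pid] = prepared[0]
    timings["prepare"] = time.perf_counter() - t1

    plan = stratified_threefold_split(clinical, seed=config.seed)
    surv_by_id = clinical.set_index("patient_id")
    fold_reports = []
    for k, fold in enumerate(plan.folds):
        tf = time.perf_counter()
        train_s = [samples[p] for p in fold.train]
        val_s = [samples[p] for p in fold.val]
        if config.augment_target_per_class:
            counts = {}
            for s in train_s:
                counts[s.grade] = counts.get(s.grade, 0) + 1
            aplan = aug.plan_class_aware_augmentation(
                counts, config.augment_target_per_class)
            train_s = aug.augment_dataset(train_s, aplan,
                                          seed=config.seed * 7 + k)
        model = grading.GraderModel(config.grader_width_scale,
                                    config.grader_depth_scale,
                                    seed=config.seed + k)
        model, _log = grading.train_grader(
            model, train_s, val_s, epochs=config.grader_epochs,
            lr=config.grader_lr, batch_size=config.grader_batch_size,
            seed=config.seed + k)

        def feats(pids):
            return np.stack([grading.extract_features(model, samples[p])
                             for p in pids])

        fit_ids = fold.train + fold.val
        surv_model = DiscreteTimeSurvival(
            feats(fit_ids),
            surv_by_id.loc[fit_ids, "duration_days"].to_numpy(),
            surv_by_id.loc[fit_ids, "event"].to_numpy(),
            n_intervals=config.n_intervals, patient_ids=fit_ids)
        res = surv_model.fit(hidden=config.survival_hidden,
                             dropout=config.survival_dropout,
                             lr=config.survival_lr,
                             max_epochs=config.survival_max_epochs,
                             patience=config.survival_patience,
                             seed=config.seed + k)
        report = res.evaluate(feats(fold.test),
                              surv_by_id.loc[fold.test, "duration_days"].to_numpy(),
                              surv_by_id.loc[fold.test, "event"].to_numpy())
        fold_reports.append({"fold": k, "c_index": report.c_index,
                             "ibs": report.ibs,
                             "auc": report.cumulative_dynamic_auc,
                             "n_comparable_pairs": report.n_comparable_pairs,
                             "seconds": time.perf_counter() - tf})
    mean = {m: float(np.mean([fr[m] for fr in fold_reports]))
            for m in ("c_index", "ibs", "auc")}
    timings["total"] = time.perf_counter() - t0
    return {"folds": fold_reports, "mean": mean, "timings": timings,
            "n_patients": int(len(clinical)),
            "n_deaths": int(clinical["event"].sum())}
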