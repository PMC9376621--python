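"""Stratified repeated k-fold cross-validation and confusion-matrix metrics.

The harness refits the whole DS-ANFIS pipeline (preprocess -> graph ->
peel -> rules -> hybrid training) inside every training fold and scores
the held-out fold, repeating the k-fold split with fresh shuffles. It
reports per-run mean +/- SD over folds, the across-run mean +/- SD of the
run averages (two different spreads: fold-to-fold variation is much larger
than run-to-run variation of the averages), pooled confusion counts over
all repeats, and the mean rule count.

Fold splitting, confusion counting and the derived percentages are
implemented here; scikit-learn's splitters/metrics serve only as
independent cross-checks in the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import FeatureTable
from .model import (DominantSetAnfis, PipelineConfig, fit_preprocessor)

__all__ = ["ConfusionSummary", "stratified_folds", "confusion", "metrics",
           "repeated_cv", "CVReport"]

logger = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    """Binary confusion counts with class 1 (demented) as positive."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(self.tp + other.tp, self.tn + other.tn,
                                self.fp + other.fp, self.fn + other.fn)


def stratified_folds(labels, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint folds covering all rows with per-fold class counts within
    one of exact proportionality.

    Each class's shuffled indices are dealt to the folds round-robin; the
    dealing offset rotates between classes so overall fold sizes also stay
    within one of each other. A class with fewer than k members leaves some
    folds without it (warned, not fatal).
    """
    labels = np.asarray(labels)
    M = labels.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > M:
        raise ValueError(f"k={k} exceeds number of rows {M}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            logger.warning("class %s has %d members < k=%d; some folds will "
                           "lack it", cls, idx.size, k)
        idx = rng.permutation(idx)
        for pos, row in enumerate(idx):
            folds[(offset + pos) % k].append(int(row))
        offset = (offset + idx.size) % k
    return [np.array(sorted(f), dtype=int) for f in folds]


def confusion(y_true, y_pred, positive: int = 1) -> ConfusionSummary:
    """Standard binary confusion counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionSummary(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def metrics(cs: ConfusionSummary) -> dict:
    """Accuracy, precision, recall, specificity as percentages.

    A zero denominator yields NaN for that metric rather than an error.
    """
    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    return {
        "accuracy": pct(cs.tp + cs.tn, cs.total),
        "precision": pct(cs.tp, cs.tp + cs.fp),
        "recall": pct(cs.tp, cs.tp + cs.fn),
        "specificity": pct(cs.tn, cs.tn + cs.fp),
    }


@dataclass
class CVReport:
    """Everything the repeated-CV harness measured."""

    k: int
    repeats: int
    base_seed: int
    fold_records: list = field(default_factory=list)   # dicts: run, fold, acc, n_rules, n_test
    run_means: list = field(default_factory=list)
    run_sds: list = field(default_factory=list)        # SD over folds within a run
    pooled: ConfusionSummary = field(default_factory=ConfusionSummary)
    failures: list = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.run_means))

    @property
    def sd_across_runs(self) -> float:
        return float(np.std(self.run_means, ddof=0))

    @property
    def mean_rules(self) -> float:
        return float(np.mean([r["n_rules"] for r in self.fold_records]))

    def summary_dict(self) -> dict:
        return {
            "k": self.k,
            "repeats": self.repeats,
            "base_seed": self.base_seed,
            "mean_accuracy_pct": self.mean_accuracy,
            "sd_across_runs_pct": self.sd_across_runs,
            "run_means_pct": list(self.run_means),
            "run_sds_pct": list(self.run_sds),
            "mean_rules": self.mean_rules,
            "pooled_confusion": {"tp": self.pooled.tp, "tn": self.pooled.tn,
                                 "fp": self.pooled.fp, "fn": self.pooled.fn},
            "pooled_metrics": metrics(self.pooled),
            "n_failures": len(self.failures),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary_dict(), sort_keys=True)

    def folds_to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["run", "fold", "accuracy", "n_rules", "n_test"])
            for rec in self.fold_records:
                wr.writerow([rec["run"], rec["fold"], rec["accuracy"],
                             rec["n_rules"], rec["n_test"]])


def repeated_cv(table: FeatureTable, config: PipelineConfig | None = None,
                k: int = 10, repeats: int = 10, base_seed: int = 0) -> CVReport:
    """Stratified k-fold CV repeated with fresh shuffles, full refit per fold.

    Per-run seeds derive deterministically from ``base_seed`` + run index,
    so identical inputs give byte-identical reports. A pipeline failure on
    a fold is recorded and the run flagged — never silently skipped.
    """
    config = config or PipelineConfig()
    if table.labels is None:
        raise ValueError("table has no labels")
    X_all = table.values
    y_all = table.labels
    names = table.columns
    global_prep = None
    if config.fit_scope == "global":
        global_prep = fit_preprocessor(X_all, names)

    report = CVReport(k=k, repeats=repeats, base_seed=base_seed)
    for run in range(repeats):
        seed = (base_seed + run) % (2 ** 31 - 1)
        folds = stratified_folds(y_all, k, seed)
        accs = []
        for fold_id, test_idx in enumerate(folds):
            train_mask = np.ones(len(y_all), dtype=bool)
            train_mask[test_idx] = False
            try:
                mdl = DominantSetAnfis(y_all[train_mask], X_all[train_mask],
                                       feature_names=names, config=config)
                res = mdl.fit(preprocessor=global_prep)
                cls, _ = res.predict(X_all[test_idx])
            except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
                logger.error("run %d fold %d failed: %s", run, fold_id, exc)
                report.failures.append({"run": run, "fold": fold_id,
                                        "error": repr(exc)})
                continue
            cs = confusion(y_all[test_idx], cls)
            acc = 100.0 * np.mean(cls == y_all[test_idx])
            accs.append(acc)
            report.pooled = report.pooled + cs
            report.fold_records.append(
                {"run": run, "fold": fold_id, "accuracy": float(acc),
                 "n_rules": res.n_rules, "n_test": int(test_idx.size)})
            logger.info("run %d fold %d: acc=%.2f%% rules=%d",
                        run, fold_id, acc, res.n_rules)
        if accs:
            report.run_means.append(float(np.mean(accs)))
            report.run_sds.append(float(np.std(accs, ddof=0)))
    return report
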