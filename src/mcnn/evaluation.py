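"""Metrics, bootstrap confidence intervals, and the evaluation experiments.

Four experiment runners cover the protocol used to characterize the model:

- :func:`run_seed_stability` — refit under 10 different seeds with one
  stratified 80/20 split held fixed, summarizing each metric's mean,
  variance, SD and median across runs (the seed-stability analysis).
- :func:`run_split_robustness` — refit over 30 distinct stratified 80/20
  splits; the per-metric median is the headline number.
- :func:`run_channel_ablation` — per split, the accuracy of each
  single-channel network (0.5-thresholded) against the full fused model.
- :func:`run_classifier_comparison` — channel networks fitted once per
  split; all candidate heads fitted on bit-identical per-channel
  probabilities, reported with bootstrap CIs.

All runners derive every seed from one master seed, store the raw per-run
rows they summarize, and are bitwise reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .dataset_io import stratified_split
from .elm import DEFAULT_LAM
from .mcnn_model import CHANNELS, HEAD_KINDS, MCNNModel, make_head

__all__ = [
    "MetricSet",
    "StabilityReport",
    "compute_metrics",
    "bootstrap_ci",
    "run_seed_stability",
    "run_split_robustness",
    "run_channel_ablation",
    "run_classifier_comparison",
]

METRICS = ("accuracy", "balanced_accuracy", "auc", "error")


@dataclass(frozen=True)
class MetricSet:
    """The four reported metrics, optionally with 95% CI bounds."""

    accuracy: float
    balanced_accuracy: float
    auc: float
    error: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        row = {m: getattr(self, m) for m in METRICS}
        for m, (lo, hi) in self.ci.items():
            row[f"{m}_ci_low"], row[f"{m}_ci_high"] = lo, hi
        return row


def compute_metrics(labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> MetricSet:
    """Accuracy, balanced accuracy, AUC and error from scores.

    Accuracy-type metrics threshold the scores (default 0.5, suited to
    probabilities); AUC is the rank statistic with midrank tie handling
    and needs both classes present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same shape")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined: only one class present")
    pred = (scores >= threshold).astype(int)
    accuracy = float((pred == labels).mean())
    sensitivity = float((pred[labels == 1] == 1).mean())
    specificity = float((pred[labels == 0] == 0).mean())
    return MetricSet(
        accuracy=accuracy,
        balanced_accuracy=0.5 * (sensitivity + specificity),
        auc=float(roc_auc_score(labels, scores)),
        error=1.0 - accuracy,
    )


def bootstrap_ci(
    labels: np.ndarray,
    scores: np.ndarray,
    metric: str = "auc",
    B: int = 2000,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[float, float]:
    """95% percentile bootstrap interval for one metric.

    Resampling is stratified (with replacement within each class), so every
    resample contains both classes and the AUC is always defined.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if B < 100:
        raise ValueError("B must be >= 100 for a usable percentile interval")
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.size < 10:
        raise ValueError("need at least 10 samples to bootstrap")
    rng = np.random.default_rng(seed)
    idx_by_class = [np.flatnonzero(labels == c) for c in (0, 1)]
    values = np.empty(B)
    for b in range(B):
        take = np.concatenate([rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_class])
        values[b] = _metric_value(labels[take], scores[take], metric, threshold)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def _metric_value(labels, scores, metric, threshold):
    """One metric only (the bootstrap loop avoids recomputing all four)."""
    if metric == "auc":
        return roc_auc_score(labels, scores)
    pred = scores >= threshold
    if metric == "balanced_accuracy":
        return 0.5 * (pred[labels == 1].mean() + (~pred[labels == 0]).mean())
    acc = (pred == labels).mean()
    return acc if metric == "accuracy" else 1.0 - acc


def evaluate_scores(labels, scores, ci: bool = False, B: int = 2000, seed: int = 0) -> MetricSet:
    """Metrics with optional bootstrap CIs on every metric."""
    base = compute_metrics(labels, scores)
    if not ci:
        return base
    cis = {m: bootstrap_ci(labels, scores, m, B=B, seed=seed) for m in METRICS}
    return MetricSet(**{m: getattr(base, m) for m in METRICS}, ci=cis)


@dataclass
class StabilityReport:
    """Per-run metric rows plus the summary statistics derived from them."""

    per_run: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean / variance / SD / median of each metric over the runs."""
        cols = [m for m in METRICS if m in self.per_run.columns]
        block = self.per_run[cols]
        return pd.DataFrame(
            {
                "mean": block.mean(),
                "variance": block.var(ddof=1),
                "std": block.std(ddof=1),
                "median": block.median(),
            }
        ).T

    def to_csv(self, path: str | Path) -> None:
        self.per_run.to_csv(path, index=False)


def _derived_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_seed_stability(
    images: np.ndarray,
    labels: np.ndarray,
    n_seeds: int = 10,
    master_seed: int = 0,
    lam: float = DEFAULT_LAM,
    head_kind: str = "random_forest",
) -> StabilityReport:
    """Refit the full model ``n_seeds`` times on one fixed stratified
    80/20 split, varying filter initialization and head randomness jointly.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    seeds = _derived_seeds(master_seed, n_seeds + 1)
    split = stratified_split(labels, seed=seeds[0])
    rows = []
    for seed in seeds[1:]:
        model = MCNNModel(input_size=images.shape[1:3], head_kind=head_kind, seed=seed)
        model.fit(images[split.train], labels[split.train], lam=lam)
        metrics = compute_metrics(labels[split.test], model.predict_proba(images[split.test]))
        rows.append({"seed": seed, **metrics.as_dict()})
    return StabilityReport(
        per_run=pd.DataFrame(rows),
        provenance={"experiment": "seed_stability", "master_seed": master_seed,
                    "split_seed": seeds[0], "n_seeds": n_seeds, "lam": lam},
    )


def run_split_robustness(
    images: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 30,
    master_seed: int = 0,
    lam: float = DEFAULT_LAM,
    head_kind: str = "random_forest",
) -> StabilityReport:
    """Refit over ``n_splits`` distinct stratified 80/20 splits; the
    per-metric median across splits is the headline result."""
    seeds = _derived_seeds(master_seed, 2 * n_splits)
    rows = []
    for k in range(n_splits):
        split = stratified_split(labels, seed=seeds[2 * k])
        model = MCNNModel(input_size=images.shape[1:3], head_kind=head_kind, seed=seeds[2 * k + 1])
        model.fit(images[split.train], labels[split.train], lam=lam)
        metrics = compute_metrics(labels[split.test], model.predict_proba(images[split.test]))
        rows.append({"split": k, "split_seed": seeds[2 * k], **metrics.as_dict()})
    return StabilityReport(
        per_run=pd.DataFrame(rows),
        provenance={"experiment": "split_robustness", "master_seed": master_seed,
                    "n_splits": n_splits, "lam": lam},
    )


def run_channel_ablation(
    images: np.ndarray,
    labels: np.ndarray,
    n_splits: int = 30,
    master_seed: int = 0,
    lam: float = DEFAULT_LAM,
    head_kind: str = "random_forest",
) -> StabilityReport:
    """Per split, accuracy of each single-channel network against the full
    fused model; one row per (split, arm) with arms red/green/blue/full."""
    seeds = _derived_seeds(master_seed, 2 * n_splits)
    rows = []
    for k in range(n_splits):
        split = stratified_split(labels, seed=seeds[2 * k])
        model = MCNNModel(input_size=images.shape[1:3], head_kind=head_kind, seed=seeds[2 * k + 1])
        model.fit(images[split.train], labels[split.train], lam=lam)
        test_x, test_y = images[split.test], labels[split.test]
        for channel in CHANNELS:
            probs = model.predict_per_channel(test_x, channel)
            rows.append({"split": k, "arm": channel,
                         "accuracy": float(((probs >= 0.5).astype(int) == test_y).mean())})
        rows.append({"split": k, "arm": "full",
                     "accuracy": compute_metrics(test_y, model.predict_proba(test_x)).accuracy})
    return StabilityReport(
        per_run=pd.DataFrame(rows),
        provenance={"experiment": "channel_ablation", "master_seed": master_seed,
                    "n_splits": n_splits, "lam": lam},
    )


def run_classifier_comparison(
    images: np.ndarray,
    labels: np.ndarray,
    heads: tuple[str, ...] = HEAD_KINDS,
    n_splits: int = 1,
    master_seed: int = 0,
    lam: float = DEFAULT_LAM,
    B: int = 2000,
    ci: bool = True,
) -> StabilityReport:
    """Compare fusion heads on identical per-channel probabilities.

    Per split, the channel networks are fitted once; every candidate head
    is then trained on the same training-probability matrix and scored on
    the same test-probability matrix (their SHA-256 hashes are recorded per
    row, so the identical-input contract is checkable from the report).
    """
    for h in heads:
        if h not in HEAD_KINDS:
            raise ValueError(f"unknown head {h!r}; choose from {HEAD_KINDS}")
    seeds = _derived_seeds(master_seed, 3 * n_splits)
    rows = []
    for k in range(n_splits):
        split = stratified_split(labels, seed=seeds[3 * k])
        base = MCNNModel(input_size=images.shape[1:3], seed=seeds[3 * k + 1])
        base.fit(images[split.train], labels[split.train], lam=lam)
        train_p = base.channel_probabilities(images[split.train])
        test_p = base.channel_probabilities(images[split.test])
        input_hash = hashlib.sha256(train_p.tobytes() + test_p.tobytes()).hexdigest()
        for kind in heads:
            head = make_head(kind, seeds[3 * k + 2])
            head.fit(train_p, labels[split.train])
            positive = list(head.classes_).index(1)
            scores = head.predict_proba(test_p)[:, positive]
            metrics = evaluate_scores(labels[split.test], scores, ci=ci, B=B, seed=seeds[3 * k + 2])
            rows.append({"split": k, "head": kind, "input_hash": input_hash, **metrics.as_dict()})
    return StabilityReport(
        per_run=pd.DataFrame(rows),
        provenance={"experiment": "classifier_comparison", "master_seed": master_seed,
                    "n_splits": n_splits, "heads": list(heads), "lam": lam},
    )
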