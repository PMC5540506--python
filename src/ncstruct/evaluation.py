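"""Multi-class evaluation: confusion matrices, one-vs-rest statistics,
stratified ten-fold cross-validation.

Six statistics are computed per class from the one-vs-rest reduction of the
confusion matrix — accuracy, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F-score 2TP/(2TP+FP+FN), and the
Matthews correlation coefficient — then macro-averaged (unweighted mean
over classes).  The overall trace accuracy (correct / total) is reported
alongside, since macro and micro averages answer different questions.
A statistic whose denominator is zero is reported as 0 with a warning;
that only arises in degenerate folds.

Cross-validation follows the frozen-feature-space protocol: fragments are
mined on each fold's *training* graphs only, the held-out graphs are
projected into that feature space, and the per-fold confusion matrices are
summed elementwise before computing statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np

from .cnn import CnnConfig, train, predict
from .features import feature_matrix_from_mining, project
from .graphs import build_structure_graph
from .mining import MiningParams, mine_closed_fragments
from .records import NcRnaRecord

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "binary_counts",
    "compute_metrics",
    "macro_average",
    "stratified_folds",
    "cross_validate",
    "write_report",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f_score", "mcc")


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str],
) -> np.ndarray:
    """Integer matrix, rows = true class, columns = predicted class."""
    if len(true_labels) == 0:
        raise ValueError("empty label lists")
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true/predicted length mismatch")
    index = {c: i for i, c in enumerate(class_order)}
    conf = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise ValueError(f"unknown true label {t!r}")
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        conf[index[t], index[p]] += 1
    return conf


def binary_counts(confusion: np.ndarray, class_index: int) -> tuple[int, int, int, int]:
    """One-vs-rest (TP, TN, FP, FN) for one class."""
    conf = np.asarray(confusion)
    tp = int(conf[class_index, class_index])
    fn = int(conf[class_index, :].sum() - tp)
    fp = int(conf[:, class_index].sum() - tp)
    tn = int(conf.sum() - tp - fn - fp)
    return tp, tn, fp, fn


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: zero denominator, reporting 0", stacklevel=3)
        return 0.0
    return float(Fraction(num, den))


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """The six statistics from binary counts (exact rationals, then float)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all counts are zero")
    mcc_den_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den_sq == 0:
        warnings.warn("mcc: zero denominator, reporting 0", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / sqrt(mcc_den_sq)
    return {
        "accuracy": _ratio(tp + tn, total, "accuracy"),
        "sensitivity": _ratio(tp, tp + fn, "sensitivity"),
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "precision": _ratio(tp, tp + fp, "precision"),
        "f_score": _ratio(2 * tp, 2 * tp + fp + fn, "f_score"),
        "mcc": mcc,
    }


def macro_average(per_class: Sequence[dict[str, float]]) -> dict[str, float]:
    """Unweighted mean of each statistic over classes."""
    if not per_class:
        raise ValueError("no per-class metrics")
    return {
        name: float(np.mean([m[name] for m in per_class])) for name in METRIC_NAMES
    }


@dataclass(frozen=True)
class EvalReport:
    """Fold-aggregated confusion matrix plus per-class and macro statistics."""

    class_order: tuple[str, ...]
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float  # trace / total ("micro")

    @classmethod
    def from_confusion(
        cls, confusion: np.ndarray, class_order: Sequence[str]
    ) -> "EvalReport":
        conf = np.asarray(confusion, dtype=np.int64)
        per_class = {}
        for i, name in enumerate(class_order):
            tp, tn, fp, fn = binary_counts(conf, i)
            metrics = compute_metrics(tp, tn, fp, fn)
            metrics.update(tp=tp, tn=tn, fp=fp, fn=fn)
            per_class[name] = metrics
        macro = macro_average(
            [{k: per_class[c][k] for k in METRIC_NAMES} for c in class_order]
        )
        overall = float(np.trace(conf)) / float(conf.sum())
        return cls(
            class_order=tuple(class_order),
            confusion=conf,
            per_class=per_class,
            macro=macro,
            overall_accuracy=overall,
        )

    def row_normalized(self) -> np.ndarray:
        """Row-percentage confusion matrix (each true class sums to 100)."""
        conf = self.confusion.astype(float)
        sums = conf.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, 100.0 * conf / sums, 0.0)
        return out


def stratified_folds(
    records: Sequence[NcRnaRecord], k: int = 10, seed: int = 0
) -> list[list[NcRnaRecord]]:
    """k disjoint test partitions: per-class round-robin after a seeded shuffle."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(records):
        raise ValueError(f"k={k} exceeds record count {len(records)}")
    by_class: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        if rec.class_label is None:
            raise ValueError(f"record {rec.id!r} has no class label")
        by_class.setdefault(rec.class_label, []).append(idx)
    rng = np.random.default_rng(seed)
    folds: list[list[NcRnaRecord]] = [[] for _ in range(k)]
    for label in sorted(by_class):
        members = by_class[label]
        if len(members) < k:
            warnings.warn(
                f"class {label!r} has {len(members)} < k={k} members; "
                f"folds will be imbalanced for it"
            )
        order = rng.permutation(len(members))
        for slot, pos in enumerate(order):
            folds[slot % k].append(records[members[pos]])
    return folds


def cross_validate(
    records: Sequence[NcRnaRecord],
    mining_params: MiningParams,
    cnn_config: CnnConfig,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Ten-fold protocol: per-fold mining, frozen-space projection, summed
    confusion matrices.

    Per fold, fragments are mined on the training graphs only and the CNN is
    trained on their containment matrix; the held-out graphs are projected
    into the fold's feature space and predicted.  Fold f trains with seed
    ``cnn_config.seed + f`` so folds are independent but the whole run is
    reproducible.
    """
    for rec in records:
        if rec.structure is None:
            raise ValueError(f"record {rec.id!r} has no structure")
    class_order = sorted({rec.class_label for rec in records})
    folds = stratified_folds(records, k=k, seed=seed)
    conf_total = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for fi, test_recs in enumerate(folds):
        test_ids = {r.id for r in test_recs}
        train_recs = [r for r in records if r.id not in test_ids]
        try:
            train_graphs = [build_structure_graph(r) for r in train_recs]
            fragments = mine_closed_fragments(train_graphs, mining_params)
            if not fragments:
                raise ValueError("mining produced no fragments")
            matrix = feature_matrix_from_mining(train_graphs, fragments)
            cfg = replace(cnn_config, seed=cnn_config.seed + fi)
            model = train(
                matrix,
                [r.class_label for r in train_recs],
                cfg,
                class_order=class_order,
            )
            test_graphs = [build_structure_graph(r) for r in test_recs]
            test_matrix = project(test_graphs, fragments)
            pred, _probs = predict(model, test_matrix)
        except Exception as exc:
            raise RuntimeError(f"cross-validation fold {fi}: {exc}") from exc
        conf_total += confusion_matrix(
            [r.class_label for r in test_recs], pred, class_order
        )
    return EvalReport.from_confusion(conf_total, class_order)


def write_report(report: EvalReport, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.metrics.tsv`` and ``<prefix>.confusion.tsv``."""
    prefix = Path(out_prefix)
    metrics_path = prefix.with_suffix(".metrics.tsv")
    conf_path = prefix.with_suffix(".confusion.tsv")
    with open(metrics_path, "w") as handle:
        handle.write("class\t" + "\t".join(METRIC_NAMES) + "\tTP\tTN\tFP\tFN\n")
        for name in report.class_order:
            m = report.per_class[name]
            handle.write(
                name
                + "\t"
                + "\t".join(f"{m[k]:.6f}" for k in METRIC_NAMES)
                + f"\t{m['tp']}\t{m['tn']}\t{m['fp']}\t{m['fn']}\n"
            )
        handle.write(
            "macro\t" + "\t".join(f"{report.macro[k]:.6f}" for k in METRIC_NAMES)
            + "\t-\t-\t-\t-\n"
        )
        handle.write(f"# overall (trace) accuracy\t{report.overall_accuracy:.6f}\n")
    with open(conf_path, "w") as handle:
        handle.write("true\\pred\t" + "\t".join(report.class_order) + "\n")
        for name, row in zip(report.class_order, report.confusion):
            handle.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    return metrics_path, conf_path
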