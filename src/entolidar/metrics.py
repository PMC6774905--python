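"""Classifier evaluation metrics and derived biological summaries.

Confusion-matrix metrics: overall accuracy (trace over total), per-class
recall N_ii / sum_j N_ij, precision N_ii / sum_j N_ji and the F1 score (their
harmonic mean).  Repeated evaluations are summarised as mean plus a 95%
confidence interval of 1.96 standard errors.  Biological summaries cover
percent changes of class means and the Deakin wingbeat-mass power law
(wingbeat frequency scaling with mass to the 0.3).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "MassEstimate",
    "EvaluationReport",
    "precision_recall_f1",
    "f1_score",
    "overall_accuracy",
    "ci95",
    "percent_change",
    "mass_change_from_wbf",
    "infer_baseline_mass",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer counts N_ij with true class i in rows, predicted class j in columns."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.class_order):
            raise ValueError("class_order must match matrix size")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def index_of(self, label: str) -> int:
        try:
            return self.class_order.index(label)
        except ValueError:
            raise KeyError(f"unknown class label: {label!r}") from None


class ClassMetrics(NamedTuple):
    precision: float
    recall: float
    f1: float


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; nan when both are zero."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f1(cm: ConfusionMatrix, class_label: str) -> ClassMetrics:
    """Per-class precision, recall and F1 from a confusion matrix.

    An empty true row (recall) or predicted column (precision) leaves the
    metric undefined; it is reported as nan with a warning rather than
    silently coerced to zero.
    """
    i = cm.index_of(class_label)
    tp = float(cm.counts[i, i])
    row = float(cm.counts[i, :].sum())
    col = float(cm.counts[:, i].sum())
    recall = tp / row if row > 0 else float("nan")
    precision = tp / col if col > 0 else float("nan")
    if row == 0 or col == 0:
        warnings.warn(f"metrics undefined for class {class_label!r} (empty row or column)")
        f1 = float("nan")
    else:
        f1 = f1_score(precision, recall)
    return ClassMetrics(precision=precision, recall=recall, f1=f1)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correct predictions; equals mean recall for balanced classes."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def ci95(values: Sequence[float]) -> tuple[float, float]:
    """Mean and 95% half-width (1.96 standard errors) of a series.

    A single value yields half-width 0 by convention (callers flag it).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("ci95 of an empty series")
    mean = float(np.nanmean(arr))
    n = int(np.sum(np.isfinite(arr)))
    if n <= 1:
        return mean, 0.0
    sd = float(np.nanstd(arr, ddof=1))
    return mean, 1.96 * sd / math.sqrt(n)


def percent_change(before: float, after: float) -> float:
    """Relative change in percent, 100 * (after/before - 1)."""
    if before <= 0:
        raise ValueError("percent_change requires before > 0")
    return 100.0 * (after / before - 1.0)


@dataclass(frozen=True)
class MassEstimate:
    """Mass change inferred from a wingbeat-frequency change.

    ``baseline_inferred`` marks estimates whose baseline mass was not
    measured but back-solved from a target mass change; such absolute values
    are interpretive, only the relative increase is data-driven.
    """

    baseline_mass_mg: float
    delta_mass_mg: float
    relative_increase: float
    exponent: float
    baseline_inferred: bool = False


def mass_change_from_wbf(
    f_before_hz: float,
    f_after_hz: float,
    baseline_mass_mg: float,
    exponent: float = 0.3,
    baseline_inferred: bool = False,
) -> MassEstimate:
    """Mass change implied by a wingbeat-frequency change under f ~ m**exponent.

    Inverting the power law, ``delta_m = m0 * ((f_after/f_before)**(1/exponent) - 1)``.
    """
    if min(f_before_hz, f_after_hz, baseline_mass_mg, exponent) <= 0:
        raise ValueError("all inputs must be > 0")
    rel = (f_after_hz / f_before_hz) ** (1.0 / exponent) - 1.0
    return MassEstimate(
        baseline_mass_mg=baseline_mass_mg,
        delta_mass_mg=baseline_mass_mg * rel,
        relative_increase=rel,
        exponent=exponent,
        baseline_inferred=baseline_inferred,
    )


def infer_baseline_mass(
    delta_mass_mg: float, f_before_hz: float, f_after_hz: float, exponent: float = 0.3
) -> float:
    """Baseline mass consistent with a given mass change under the power law."""
    if min(delta_mass_mg, f_before_hz, f_after_hz, exponent) <= 0:
        raise ValueError("all inputs must be > 0")
    rel = (f_after_hz / f_before_hz) ** (1.0 / exponent) - 1.0
    if rel <= 0:
        raise ValueError("frequency must increase for a positive mass change")
    return delta_mass_mg / rel


@dataclass
class EvaluationReport:
    """Summary of a repeated cross-validated evaluation.

    Per-class precision/recall/F1 and the overall accuracy, each as a mean
    and 95% CI over repeats, in percent.  ``f1_of_means`` additionally gives
    the F1 of the mean precision and mean recall, which can differ from the
    mean of per-repeat F1s.
    """

    class_order: tuple[str, ...]
    per_class: dict[str, dict[str, tuple[float, float]]]  # metric -> (mean %, ci95 %)
    overall_accuracy: tuple[float, float]  # (mean %, ci95 %)
    f1_of_means: dict[str, float]
    n_repeats: int
    config: dict = field(default_factory=dict)
    degenerate_ci: bool = False
    mean_confusion: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "class_order": list(self.class_order),
            "per_class": {
                c: {m: list(v) for m, v in metrics.items()}
                for c, metrics in self.per_class.items()
            },
            "overall_accuracy": list(self.overall_accuracy),
            "f1_of_means": dict(self.f1_of_means),
            "n_repeats": self.n_repeats,
            "config": self.config,
            "degenerate_ci": self.degenerate_ci,
        }
        if self.mean_confusion is not None:
            d["mean_confusion"] = np.asarray(self.mean_confusion).tolist()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            class_order=tuple(d["class_order"]),
            per_class={
                c: {m: tuple(v) for m, v in metrics.items()}
                for c, metrics in d["per_class"].items()
            },
            overall_accuracy=tuple(d["overall_accuracy"]),
            f1_of_means=d["f1_of_means"],
            n_repeats=d["n_repeats"],
            config=d.get("config", {}),
            degenerate_ci=d.get("degenerate_ci", False),
            mean_confusion=np.asarray(d["mean_confusion"]) if "mean_confusion" in d else None,
        )

    def to_table_frame(self) -> pd.DataFrame:
        """Flat per-class table: 'mean +/- ci %' strings at one decimal."""

        def fmt(mean: float, ci: float) -> str:
            return f"{mean:.1f} ± {ci:.2f}%"

        rows = []
        for c in self.class_order:
            m = self.per_class[c]
            rows.append(
                {
                    "class": c,
                    "precision": fmt(*m["precision"]),
                    "recall": fmt(*m["recall"]),
                    "f1": fmt(*m["f1"]),
                }
            )
        return pd.DataFrame(rows)

    def to_table_csv(self, path) -> None:
        self.to_table_frame().to_csv(path, index=False)
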