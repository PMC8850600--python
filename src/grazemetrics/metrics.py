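"""Confusion-matrix evaluation: sensitivity/specificity/precision, accuracy,
Cohen's Kappa and its Landis–Koch qualitative band.

All metrics reduce the 6×6 observed-vs-predicted count grid.  Per-class
metrics use the one-vs-rest reduction:

* sensitivity = TP / (TP + FN)
* specificity = TN / (TN + FP)
* precision   = TP / (TP + FP)

A metric whose defining denominator is zero (e.g. precision of a behavior
the classifier never predicted) is *not available* and reported as a typed
missing value (``None``), never as zero and never as an exception.

Overall accuracy is trace/total; Cohen's unweighted multi-class Kappa is
κ = (p_o − p_e) / (1 − p_e) with p_e from the row/column marginal products.
The Landis–Koch cut points are implemented as contiguous half-open bands
(−∞,0) poor, [0,0.2] slight, (0.2,0.4] fair, (0.4,0.6] moderate,
(0.6,0.8] substantial, (0.8,1] almost perfect, so every κ ≤ 1 has a band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behaviors import BEHAVIORS

KAPPA_BANDS = (
    "poor",
    "slight",
    "fair",
    "moderate",
    "substantial",
    "almost_perfect",
)


@dataclass
class ConfusionMatrix:
    """6×6 counts; rows = observed class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple[str, ...] = BEHAVIORS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(f"count grid must be {k}x{k}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: str) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against the rest."""
        if cls not in self.classes:
            raise ValueError(f"unknown class {cls!r}")
        i = self.classes.index(cls)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i, :].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


@dataclass
class ClassMetrics:
    """One-vs-rest fractions; ``None`` marks a not-available value."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None


@dataclass
class EvalSummary:
    accuracy: float
    kappa: float | None
    kappa_band: str | None
    per_class: dict[str, ClassMetrics] = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-friendly report; missing values serialize as "NA"."""
        na = lambda v: "NA" if v is None else v  # noqa: E731
        return {
            "accuracy": self.accuracy,
            "kappa": na(self.kappa),
            "kappa_band": na(self.kappa_band),
            "per_class": {
                cls: {
                    "sensitivity": na(m.sensitivity),
                    "specificity": na(m.specificity),
                    "precision": na(m.precision),
                }
                for cls, m in self.per_class.items()
            },
        }


def confusion_matrix(
    observed, predicted, classes: tuple[str, ...] = BEHAVIORS
) -> ConfusionMatrix:
    """Tally observed-vs-predicted label pairs into the fixed class order."""
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValueError("observed and predicted must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for o, p in zip(observed, predicted):
        if o not in index or p not in index:
            raise ValueError(f"unknown label in pair ({o!r}, {p!r})")
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def class_metrics(cm: ConfusionMatrix, cls: str) -> ClassMetrics:
    """Sensitivity, specificity and precision of one behavior class."""
    tp, fn, fp, tn = cm.one_vs_rest(cls)
    return ClassMetrics(
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
    )


def overall_metrics(cm: ConfusionMatrix) -> EvalSummary:
    """Accuracy, Cohen's κ, its band, and every class's one-vs-rest metrics."""
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    p_o = float(np.trace(cm.counts)) / total
    rows = cm.counts.sum(axis=1) / total
    cols = cm.counts.sum(axis=0) / total
    p_e = float(np.dot(rows, cols))
    if abs(1.0 - p_e) < 1e-15:
        kappa = None
        band = None
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        band = kappa_band(kappa)
    return EvalSummary(
        accuracy=p_o,
        kappa=kappa,
        kappa_band=band,
        per_class={cls: class_metrics(cm, cls) for cls in cm.classes},
    )


def kappa_band(kappa: float) -> str:
    """Landis–Koch qualitative band for a Kappa value (κ ≤ 1)."""
    if kappa > 1.0:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0.0:
        return "poor"
    if kappa <= 0.2:
        return "slight"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "substantial"
    return "almost_perfect"
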