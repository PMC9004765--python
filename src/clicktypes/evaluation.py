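"""Confusion matrices, per-class performance metrics, and acoustic presence.

Per-class metrics follow the standard one-vs-rest reading of a square
confusion matrix whose cell (i, j) counts bins of true class i labelled j:

    accuracy    = (TP + TN) / total
    recall      = TP / (TP + FN)
    precision   = TP / (TP + FP)
    specificity = TN / (TN + FP)
    misclassification rate = 1 − accuracy

Ratios with a zero denominator are reported as ``None`` (not available),
never as 0.  The package ships the reference confusion matrices of the
classifier's evaluation at the three Hawaiian monitoring sites (Kona, Pearl
and Hermes Reef, Kauaʻi) as CSV fixtures; site matrices with identical class
order can be summed element-wise for combined-site metrics.

Relative acoustic presence is the percentage of recording days in a
deployment with at least one bin of a class, averaged (unweighted) across
deployments at a site.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "confusion_matrix",
    "class_metrics",
    "combine_matrices",
    "rl_evaluation_filter",
    "relative_presence",
    "load_reference_matrix",
    "REFERENCE_SITES",
    "round_percent",
]

#: sites with shipped reference confusion matrices
REFERENCE_SITES = ("kona", "phr", "kauai")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square class-by-class bin-count matrix; cell (i, j): true i, labelled j."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("counts must be square and match the class list")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def n_bins(self, cls: str) -> int:
        """Manually labelled positive bins of a class (its row sum)."""
        return int(self.counts[self._idx(cls)].sum())

    def _idx(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise KeyError(f"class {cls!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single class; ``None`` marks undefined ratios."""

    class_label: str
    accuracy: Optional[float]
    recall: Optional[float]
    precision: Optional[float]
    specificity: Optional[float]
    misclassification_rate: Optional[float]
    n_bins: int


def confusion_matrix(true_labels: Sequence[str], predicted_labels: Sequence[str],
                     class_order: Sequence[str]) -> ConfusionMatrix:
    """Count (true, predicted) label pairs on a fixed class order."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside class order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=tuple(class_order), counts=counts)


def class_metrics(matrix: ConfusionMatrix, cls: str) -> ClassMetrics:
    """One-vs-rest accuracy/recall/precision/specificity for one class."""
    k = matrix._idx(cls)
    c = matrix.counts
    tp = int(c[k, k])
    fn = int(c[k].sum()) - tp
    fp = int(c[:, k].sum()) - tp
    tn = matrix.total - tp - fn - fp

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    accuracy = ratio(tp + tn, matrix.total)
    return ClassMetrics(
        class_label=cls,
        accuracy=accuracy,
        recall=ratio(tp, tp + fn),
        precision=ratio(tp, tp + fp),
        specificity=ratio(tn, tn + fp),
        misclassification_rate=None if accuracy is None else 1.0 - accuracy,
        n_bins=tp + fn,
    )


def combine_matrices(matrices: Sequence[ConfusionMatrix]) -> ConfusionMatrix:
    """Element-wise sum of matrices sharing one class order."""
    if not matrices:
        raise ValueError("need at least one matrix")
    classes = matrices[0].classes
    for m in matrices[1:]:
        if m.classes != classes:
            raise ValueError("class orders differ between matrices")
    total = np.sum([m.counts for m in matrices], axis=0).astype(int)
    return ConfusionMatrix(classes=classes, counts=total)


def rl_evaluation_filter(bins: pd.DataFrame, min_rl_dbpp: float = 125.0) -> pd.DataFrame:
    """Keep bins whose maximum received level is strictly above the threshold.

    The stricter 125 dB evaluation floor compensates for differing
    hydrophone sensitivities across deployments.
    """
    if len(bins) == 0:
        return bins
    return bins[bins["rl_max_dbpp"] > min_rl_dbpp]


def relative_presence(labelled_bins: pd.DataFrame,
                      deployment_calendar: Mapping[str, int],
                      site_of: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Relative acoustic presence per deployment and (optionally) per site.

    ``labelled_bins`` needs columns ``deployment``, ``day`` (any hashable
    day key) and ``label``; ``deployment_calendar`` maps deployment →
    number of recording days.  The per-deployment value for a class is
    100 · (days with ≥ 1 bin of the class) / (recording days); per-site
    values are unweighted means across that site's deployments.  Deployments
    with zero recording days are excluded.
    """
    rows = []
    classes = sorted(labelled_bins["label"].unique()) if len(labelled_bins) else []
    for dep, n_days in deployment_calendar.items():
        if n_days <= 0:
            continue
        sub = labelled_bins[labelled_bins["deployment"] == dep] if len(labelled_bins) else labelled_bins
        for cls in classes:
            present_days = sub.loc[sub["label"] == cls, "day"].nunique()
            rows.append(
                {
                    "deployment": dep,
                    "site": site_of.get(dep, "") if site_of else "",
                    "class": cls,
                    "percent_days": 100.0 * present_days / n_days,
                }
            )
    per_dep = pd.DataFrame(rows, columns=["deployment", "site", "class", "percent_days"])
    if site_of and len(per_dep):
        per_site = (
            per_dep.groupby(["site", "class"], as_index=False)["percent_days"]
            .mean()
            .assign(deployment="__site_mean__")
        )
        per_dep = pd.concat([per_dep, per_site[per_dep.columns]], ignore_index=True)
    return per_dep


def round_percent(fraction: Optional[float]) -> Optional[float]:
    """Format a fraction as percent, rounded half-up to one decimal."""
    if fraction is None:
        return None
    return float(Decimal(fraction * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def load_reference_matrix(site: str) -> ConfusionMatrix:
    """Load a shipped reference confusion matrix (``kona``, ``phr``, ``kauai``)."""
    if site not in REFERENCE_SITES:
        raise KeyError(f"unknown site {site!r}; expected one of {REFERENCE_SITES}")
    with resources.files("clicktypes.data").joinpath(f"confusion_{site}.csv").open() as fh:
        frame = pd.read_csv(fh, index_col=0)
    if list(frame.index) != list(frame.columns):
        raise ValueError("reference matrix rows and columns disagree")
    return ConfusionMatrix(classes=tuple(frame.columns),
                           counts=frame.to_numpy(dtype=int))
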