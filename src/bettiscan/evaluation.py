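"""Image-level screening evaluation against pathologist labels.

Verdicts are cross-tabulated against a reference condition (cancer vs
benign, or ROI vs benign) and summarized by the four standard screening
rates: sensitivity, specificity, false-positive rate and false-negative
rate, reported as percentages rounded half-up to one decimal (raw ratios
are returned alongside).

The module also carries, as reference data, the published benchmark of the
homology screen on 1825 colonic H&E images: the cancer-detector and
ROI-detector contingency tables and the pathologist-itemized breakdown of
the 422 benign-positive images into ROI and non-ROI categories.  The
category vocabulary is closed and assignment is manual annotation input,
never computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, NamedTuple, Sequence

__all__ = [
    "ContingencyTable",
    "Metrics",
    "FalsePositiveRecord",
    "FP_CATEGORIES",
    "ROI_CATEGORIES",
    "NON_ROI_CATEGORIES",
    "REFERENCE_CANCER_TABLE",
    "REFERENCE_ROI_TABLE",
    "REFERENCE_FP_BREAKDOWN",
    "build_contingency",
    "metrics",
    "format_table",
]


class ContingencyTable(NamedTuple):
    """Image-level 2x2 table: condition (rows) vs screening verdict."""

    tp: int  # condition-positive, flagged
    fp: int  # condition-negative, flagged
    fn: int  # condition-positive, not flagged
    tn: int  # condition-negative, not flagged

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Metrics(NamedTuple):
    """The four screening rates, in percent.

    ``*_raw`` carry the unrounded values; the plain fields are rounded
    half-up to one decimal for reporting.
    """

    sensitivity: float
    specificity: float
    false_positive_rate: float
    false_negative_rate: float
    sensitivity_raw: float
    specificity_raw: float
    false_positive_rate_raw: float
    false_negative_rate_raw: float


# Closed vocabulary of benign-positive (false positive) categories from the
# 1825-image colonic benchmark, split by whether pathologists judged the
# detected area a region of interest.
ROI_CATEGORIES: Mapping[str, int] = {
    "mild atypia": 156,
    "mucosal inflammation": 99,
    "hyperplastic polyps": 34,
    "inflammatory cells": 16,
    "regenerative change": 12,
    "necrosis": 6,
    "lymphoid follicles": 4,
    "lymphocyte aggregation": 4,
}
NON_ROI_CATEGORIES: Mapping[str, int] = {
    "cross sections of inclined glands": 73,
    "numerical artifact": 16,
    "specimen artifact": 2,
}
FP_CATEGORIES = tuple(ROI_CATEGORIES) + tuple(NON_ROI_CATEGORIES)

REFERENCE_FP_BREAKDOWN: Mapping[str, int] = {**ROI_CATEGORIES, **NON_ROI_CATEGORIES}

# Published benchmark tables: scored as a cancer detector and, after
# re-labeling benign ROI-bearing images as condition-positive, as an ROI
# detector.
REFERENCE_CANCER_TABLE = ContingencyTable(tp=1284, fp=422, fn=1, tn=118)
REFERENCE_ROI_TABLE = ContingencyTable(tp=1615, fp=91, fn=1, tn=118)


@dataclass(frozen=True)
class FalsePositiveRecord:
    """Manual annotation of one false-positive image."""

    image_id: str
    category: str
    roi_class: str  # "ROI" | "non-ROI", determined by the category

    def __post_init__(self) -> None:
        if self.category not in FP_CATEGORIES:
            raise ValueError(f"unknown false-positive category: {self.category!r}")
        expected = "ROI" if self.category in ROI_CATEGORIES else "non-ROI"
        if self.roi_class != expected:
            raise ValueError(
                f"category {self.category!r} implies roi_class {expected!r}, "
                f"got {self.roi_class!r}"
            )

    @classmethod
    def from_category(cls, image_id: str, category: str) -> "FalsePositiveRecord":
        roi_class = "ROI" if category in ROI_CATEGORIES else "non-ROI"
        return cls(image_id, category, roi_class)


def build_contingency(
    verdicts: Iterable[tuple[str, bool]],
    labels: Iterable[tuple[str, bool]],
) -> ContingencyTable:
    """Cross-tabulate per-image verdicts against condition labels.

    ``labels`` maps image ids to the reference condition (True =
    condition-positive).  Every verdict must have exactly one label;
    missing or duplicate ids raise ``ValueError`` listing the offenders.
    """
    verdicts = list(verdicts)
    label_list = list(labels)
    if not verdicts or not label_list:
        raise ValueError("verdicts and labels must both be non-empty")

    label_map: dict[str, bool] = {}
    dupes = []
    for image_id, cond in label_list:
        if image_id in label_map:
            dupes.append(image_id)
        label_map[image_id] = bool(cond)
    if dupes:
        raise ValueError(f"duplicate labels for image ids: {sorted(set(dupes))}")
    missing = sorted({i for i, _ in verdicts} - label_map.keys())
    if missing:
        raise ValueError(f"missing labels for image ids: {missing}")

    tp = fp = fn = tn = 0
    for image_id, positive in verdicts:
        cond = label_map[image_id]
        if cond and positive:
            tp += 1
        elif not cond and positive:
            fp += 1
        elif cond and not positive:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def metrics(t: ContingencyTable) -> Metrics:
    """Sensitivity, specificity, FP rate and FN rate of a 2x2 table (%).

    sensitivity = 100*tp/(tp+fn), specificity = 100*tn/(fp+tn); the error
    rates are their complements, so sensitivity + FN rate = 100 and
    specificity + FP rate = 100 exactly before rounding.
    """
    pos = t.tp + t.fn
    neg = t.fp + t.tn
    if pos < 1:
        raise ValueError("undefined metrics: no condition-positive images (tp+fn=0)")
    if neg < 1:
        raise ValueError("undefined metrics: no condition-negative images (fp+tn=0)")
    sens = 100.0 * t.tp / pos
    spec = 100.0 * t.tn / neg
    fpr = 100.0 * t.fp / neg
    fnr = 100.0 * t.fn / pos
    return Metrics(
        _round1(sens), _round1(spec), _round1(fpr), _round1(fnr),
        sens, spec, fpr, fnr,
    )


def format_table(t: ContingencyTable, condition_name: str = "Cancer") -> str:
    """Human-readable rendering mirroring the benchmark table layout."""
    m = metrics(t)
    lines = [
        f"{'':>10}{condition_name:>10}{'Benign':>10}",
        f"{'Positive':>10}{t.tp:>10}{t.fp:>10}",
        f"{'Negative':>10}{t.fn:>10}{t.tn:>10}",
        f"Sensitivity    {m.sensitivity:.1f}",
        f"Specificity    {m.specificity:.1f}",
        f"False positive {m.false_positive_rate:.1f}",
        f"False negative {m.false_negative_rate:.1f}",
    ]
    return "\n".join(lines)
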