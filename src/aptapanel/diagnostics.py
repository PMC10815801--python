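"""Diagnostic evaluation of aptamers and aptamer panels on tissue cohorts.

A labelled cohort is a tidy table with one row per tissue sample: a sample
class (``adjacent`` non-tumoral tissue, ``primary_tumor``, ``metastatic``),
clinical metadata (molecular subtype, stage, grade, TNM string) and one
ordinal staining-intensity column per aptamer, coded 0 = no staining,
1 = (+) low, 2 = (++) moderate, 3 = (+++) high.

A sample counts as *recognized* by an aptamer (or by a panel of aptamers
under the union rule: maximum member intensity) when its intensity reaches
the positivity threshold, by default any staining (>= 1).  Tumor samples
(primary + metastatic pooled, by default) are scored against adjacent
tissue to yield TP/FP/FN/TN and the classical indices

    sensitivity = TP / (TP + FN)
    specificity = TN / (FP + TN)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)

Integer-percent renderings use round-half-away-from-zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import floor
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "TUMOR_CLASSES",
    "ContingencyCounts",
    "DiagnosticIndices",
    "build_contingency",
    "diagnostic_indices",
    "panel_union",
    "evaluate_panels",
    "exhaustive_panels",
    "stratified_recognition",
    "cohort_from_counts",
    "aptamer_columns",
]

CLASSES = ("adjacent", "primary_tumor", "metastatic")
TUMOR_CLASSES = frozenset({"primary_tumor", "metastatic"})
_METADATA_COLUMNS = {"sample_id", "class", "subtype", "stage", "grade", "tnm"}


def aptamer_columns(cohort: pd.DataFrame) -> list[str]:
    """Columns of a cohort table that hold per-aptamer intensities."""
    return [c for c in cohort.columns if c not in _METADATA_COLUMNS]


def _percent_int(x: float) -> int:
    """Round-half-away-from-zero to an integer percent."""
    return int(floor(abs(x) * 100 + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class ContingencyCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class DiagnosticIndices:
    """Sensitivity/specificity/accuracy as fractions, with percent views.

    An index whose denominator is zero is ``None`` (flagged undefined, never
    fabricated).
    """

    sensitivity: float | None
    specificity: float | None
    accuracy: float | None

    def _pct(self, value: float | None) -> int | None:
        return None if value is None else _percent_int(value)

    @property
    def sensitivity_pct(self) -> int | None:
        return self._pct(self.sensitivity)

    @property
    def specificity_pct(self) -> int | None:
        return self._pct(self.specificity)

    @property
    def accuracy_pct(self) -> int | None:
        return self._pct(self.accuracy)


def _combined_intensity(
    cohort: pd.DataFrame, aptamers: str | Sequence[str]
) -> pd.Series:
    if isinstance(aptamers, str):
        aptamers = [aptamers]
    aptamers = list(aptamers)
    if not aptamers:
        raise ValueError("aptamer subset must be nonempty")
    known = set(aptamer_columns(cohort))
    unknown = [a for a in aptamers if a not in known]
    if unknown:
        raise KeyError(f"unknown aptamer column(s) {unknown}; have {sorted(known)}")
    return cohort[aptamers].max(axis=1)


def panel_union(cohort: pd.DataFrame, aptamers: str | Sequence[str]) -> pd.Series:
    """Combined per-sample intensity of a panel: max over member aptamers."""
    return _combined_intensity(cohort, aptamers)


def build_contingency(
    cohort: pd.DataFrame,
    aptamers: str | Sequence[str],
    positivity_threshold: int = 1,
    tumor_classes: Iterable[str] = TUMOR_CLASSES,
) -> ContingencyCounts:
    """Score an aptamer (or panel, under the union rule) against the cohort."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if positivity_threshold not in (1, 2, 3):
        raise ValueError("positivity_threshold must be in {1, 2, 3}")
    tumor_classes = set(tumor_classes)
    if not tumor_classes <= TUMOR_CLASSES:
        raise ValueError(f"tumor_classes must be a subset of {sorted(TUMOR_CLASSES)}")
    seen = set(cohort["class"].unique())
    if not seen <= set(CLASSES):
        raise ValueError(f"unknown sample class values {sorted(seen - set(CLASSES))}")
    positive = _combined_intensity(cohort, aptamers) >= positivity_threshold
    is_tumor = cohort["class"].isin(tumor_classes)
    is_control = cohort["class"] == "adjacent"
    return ContingencyCounts(
        TP=int((positive & is_tumor).sum()),
        FN=int((~positive & is_tumor).sum()),
        FP=int((positive & is_control).sum()),
        TN=int((~positive & is_control).sum()),
    )


def diagnostic_indices(c: ContingencyCounts) -> DiagnosticIndices:
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) > 0 else None
    spec = c.TN / (c.FP + c.TN) if (c.FP + c.TN) > 0 else None
    acc = (c.TP + c.TN) / c.total if c.total > 0 else None
    return DiagnosticIndices(sensitivity=sens, specificity=spec, accuracy=acc)


def evaluate_panels(
    cohort: pd.DataFrame,
    panels: Sequence[Sequence[str]],
    positivity_threshold: int = 1,
    tumor_classes: Iterable[str] = TUMOR_CLASSES,
) -> pd.DataFrame:
    """One indices row per panel (union rule -> contingency -> indices)."""
    rows = []
    for panel in panels:
        panel = [panel] if isinstance(panel, str) else list(panel)
        c = build_contingency(cohort, panel, positivity_threshold, tumor_classes)
        d = diagnostic_indices(c)
        rows.append(
            {
                "panel": "+".join(panel),
                "size": len(panel),
                "TP": c.TP,
                "FP": c.FP,
                "FN": c.FN,
                "TN": c.TN,
                "sensitivity": d.sensitivity,
                "specificity": d.specificity,
                "accuracy": d.accuracy,
                "sensitivity_pct": d.sensitivity_pct,
                "specificity_pct": d.specificity_pct,
                "accuracy_pct": d.accuracy_pct,
            }
        )
    return pd.DataFrame(rows)


def exhaustive_panels(
    cohort: pd.DataFrame,
    aptamers: Sequence[str] | None = None,
    positivity_threshold: int = 1,
    max_aptamers: int = 12,
) -> pd.DataFrame:
    """Evaluate all 2^k - 1 nonempty panels, ranked by sensitivity then
    specificity (descending)."""
    if aptamers is None:
        aptamers = aptamer_columns(cohort)
    aptamers = list(aptamers)
    if len(aptamers) > max_aptamers:
        raise ValueError(
            f"exhaustive search over {len(aptamers)} aptamers exceeds "
            f"max_aptamers={max_aptamers}"
        )
    panels = [
        list(combo)
        for r in range(1, len(aptamers) + 1)
        for combo in itertools.combinations(aptamers, r)
    ]
    table = evaluate_panels(cohort, panels, positivity_threshold)
    return table.sort_values(
        ["sensitivity", "specificity"], ascending=False, ignore_index=True
    )


def stratified_recognition(
    cohort: pd.DataFrame,
    aptamer: str,
    stratify_by: str,
    positivity_threshold: int = 1,
    classes: Iterable[str] | None = None,
    percent_decimals: int = 1,
) -> pd.DataFrame:
    """Per-stratum recognition table: recognized/total, percent, peak intensity.

    ``stratify_by`` is one of ``class``, ``subtype``, ``stage``, ``grade``,
    ``tnm``.  ``classes`` restricts the samples considered (e.g. primary
    tumors only, mirroring a subtype breakdown of primary sites).  Percent is
    ``None`` (flagged undefined) for empty strata.  The intensity summary is
    the maximum intensity observed among recognized samples of the stratum.
    """
    if stratify_by not in {"class", "subtype", "stage", "grade", "tnm"}:
        raise ValueError(f"cannot stratify by {stratify_by!r}")
    sub = cohort if classes is None else cohort[cohort["class"].isin(set(classes))]
    positive = sub[aptamer] >= positivity_threshold
    rows = []
    for stratum, idx in sub.groupby(stratify_by, observed=True, sort=True).groups.items():
        pos = positive.loc[idx]
        n, total = int(pos.sum()), len(idx)
        intensities = sub.loc[idx, aptamer][pos]
        rows.append(
            {
                stratify_by: stratum,
                "recognized": n,
                "total": total,
                "percent": round(100 * n / total, percent_decimals) if total else None,
                "max_intensity": int(intensities.max()) if n else 0,
            }
        )
    return pd.DataFrame(rows)


def cohort_from_counts(
    recognized: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
    intensity: int = 1,
) -> pd.DataFrame:
    """Expand per-class recognized/total marginal counts into a cohort table.

    ``totals`` maps sample class to cohort size; ``recognized`` maps aptamer
    name to per-class recognized counts.  Within each class the first
    ``recognized`` samples are assigned the given intensity and the rest 0 —
    sufficient for any statistic that depends only on per-aptamer marginals
    (single-aptamer contingencies and indices), not for panel unions, which
    need the unpublished per-sample matrix.
    """
    rows = []
    for cls, n_total in totals.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        for i in range(n_total):
            row = {
                "sample_id": f"{cls}_{i + 1}",
                "class": cls,
                "subtype": "unknown",
                "stage": "unknown",
                "grade": "unknown",
                "tnm": "unknown",
            }
            for apt, per_class in recognized.items():
                row[apt] = intensity if i < per_class.get(cls, 0) else 0
            rows.append(row)
    return pd.DataFrame(rows)
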