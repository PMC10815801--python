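"""Bundled worked-example data: published recognition counts of a five-
aptamer breast-tissue panel.

The example dataset is the marginal recognition table of five candidate
aptamers (AptaB1–AptaB5) stained on a 100-sample breast tissue microarray:
10 adjacent non-tumoral tissues, 50 invasive-carcinoma primary sites and 40
lymph-node metastases, with the peak ordinal staining intensity per class.
Only per-class marginals were published, so the expanded per-sample cohort
(:func:`load_tma_cohort`) supports single-aptamer statistics exactly but
not panel unions, which depend on the unpublished per-sample matrix.
"""

from __future__ import annotations

import pandas as pd

from .diagnostics import cohort_from_counts

__all__ = [
    "APTAMERS",
    "TMA_CLASS_TOTALS",
    "tma_recognition_counts",
    "tma_subtype_counts",
    "load_tma_cohort",
]

APTAMERS = ("AptaB1", "AptaB2", "AptaB3", "AptaB4", "AptaB5")

#: cohort composition of the tissue microarray
TMA_CLASS_TOTALS = {"adjacent": 10, "primary_tumor": 50, "metastatic": 40}

#: per-class recognized counts and peak staining intensity (1=+, 2=++, 3=+++)
_TMA_RECOGNITION = {
    "AptaB1": {"adjacent": (1, 1), "primary_tumor": (7, 3), "metastatic": (5, 3)},
    "AptaB2": {"adjacent": (1, 1), "primary_tumor": (18, 3), "metastatic": (5, 2)},
    "AptaB3": {"adjacent": (1, 1), "primary_tumor": (3, 3), "metastatic": (6, 2)},
    "AptaB4": {"adjacent": (4, 1), "primary_tumor": (25, 3), "metastatic": (15, 3)},
    "AptaB5": {"adjacent": (3, 1), "primary_tumor": (20, 3), "metastatic": (27, 3)},
}

#: molecular-subtype breakdown of the 45 subtyped primary-site samples:
#: recognized / total per subtype (28 luminal, 7 HER2, 10 triple-negative)
_TMA_SUBTYPE = {
    "AptaB1": {"luminal": 3, "HER2": 3, "triple_negative": 1},
    "AptaB2": {"luminal": 8, "HER2": 5, "triple_negative": 4},
    "AptaB3": {"luminal": 1, "HER2": 1, "triple_negative": 1},
    "AptaB4": {"luminal": 12, "HER2": 6, "triple_negative": 4},
    "AptaB5": {"luminal": 9, "HER2": 5, "triple_negative": 5},
}

SUBTYPE_TOTALS = {"luminal": 28, "HER2": 7, "triple_negative": 10}


def tma_recognition_counts() -> pd.DataFrame:
    """Long-form recognition marginals: aptamer, class, recognized, total,
    peak intensity."""
    rows = []
    for apt, per_class in _TMA_RECOGNITION.items():
        for cls, (n, intensity) in per_class.items():
            rows.append(
                {
                    "aptamer": apt,
                    "class": cls,
                    "recognized": n,
                    "total": TMA_CLASS_TOTALS[cls],
                    "max_intensity": intensity,
                }
            )
    return pd.DataFrame(rows)


def tma_subtype_counts() -> pd.DataFrame:
    """Primary-site recognition marginals by molecular subtype."""
    rows = []
    for apt, per_sub in _TMA_SUBTYPE.items():
        for sub, n in per_sub.items():
            rows.append(
                {
                    "aptamer": apt,
                    "subtype": sub,
                    "recognized": n,
                    "total": SUBTYPE_TOTALS[sub],
                }
            )
    return pd.DataFrame(rows)


def load_tma_cohort(aptamer: str | None = None) -> pd.DataFrame:
    """Expand the recognition marginals into a per-sample cohort table.

    With ``aptamer=None`` all five aptamer columns are expanded jointly from
    their own marginals (valid for per-aptamer statistics only); naming one
    aptamer restricts the table to that single column.
    """
    names = APTAMERS if aptamer is None else (aptamer,)
    recognized = {
        apt: {cls: n for cls, (n, _) in _TMA_RECOGNITION[apt].items()} for apt in names
    }
    cohort = cohort_from_counts(recognized, TMA_CLASS_TOTALS)
    # restore the published peak intensities on the recognized samples
    for apt in names:
        for cls, (n, intensity) in _TMA_RECOGNITION[apt].items():
            idx = cohort.index[(cohort["class"] == cls) & (cohort[apt] > 0)]
            cohort.loc[idx, apt] = intensity
    return cohort


def load_tma_subtype_cohort(aptamer: str) -> pd.DataFrame:
    """Per-sample table of the 45 subtyped primary-site samples for one
    aptamer, expanded from the subtype marginals."""
    rows = []
    i = 0
    for sub, total in SUBTYPE_TOTALS.items():
        n_pos = _TMA_SUBTYPE[aptamer][sub]
        for j in range(total):
            i += 1
            rows.append(
                {
                    "sample_id": f"P{i:03d}",
                    "class": "primary_tumor",
                    "subtype": sub,
                    "stage": "unknown",
                    "grade": "unknown",
                    "tnm": "unknown",
                    aptamer: 1 if j < n_pos else 0,
                }
            )
    return pd.DataFrame(rows)
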