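"""Proteomic filter cascade nominating candidate aptamer targets.

Starting from a whole-proteome abundance comparison between the selection
cell line (tumor) and its non-tumor control, candidate surface targets are
narrowed in three sequential, independent filters:

1. **fold change** — keep proteins whose tumor/control abundance ratio is at
   least a factor (default 2, boundary inclusive), with a pseudocount
   guarding zero denominators;
2. **membrane** — keep proteins with membrane-proteome evidence AND a
   predicted plasma-membrane localization (both lines of evidence required);
3. **binding phenotype** — keep proteins whose published per-cell-line
   expression calls match the aptamers' recognition pattern: overexpressed
   in every recognized line and under-expressed in every unrecognized line.

``run_cascade`` applies the three filters in order and reports per-stage
survivor counts alongside the final shortlist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BindingPhenotype",
    "CascadeReport",
    "fold_change_filter",
    "membrane_filter",
    "phenotype_filter",
    "run_cascade",
    "status_column",
    "derive_status_from_abundance",
]

REQUIRED_COLUMNS = (
    "protein_id",
    "abundance_target",
    "abundance_control",
    "membrane_evidence",
    "predicted_localization",
)


def status_column(line: str) -> str:
    return f"status_{line}"


@dataclass(frozen=True)
class BindingPhenotype:
    """Cell lines an aptamer panel does / does not recognize."""

    recognized_lines: frozenset[str]
    unrecognized_lines: frozenset[str]

    def __init__(self, recognized_lines: Iterable[str], unrecognized_lines: Iterable[str]):
        object.__setattr__(self, "recognized_lines", frozenset(recognized_lines))
        object.__setattr__(self, "unrecognized_lines", frozenset(unrecognized_lines))
        if not self.recognized_lines or not self.unrecognized_lines:
            raise ValueError("both line sets must be nonempty")
        overlap = self.recognized_lines & self.unrecognized_lines
        if overlap:
            raise ValueError(f"lines {sorted(overlap)} appear in both sets")

    @property
    def lines(self) -> frozenset[str]:
        return self.recognized_lines | self.unrecognized_lines


def _validate(records: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"protein table lacks columns {sorted(missing)}")
    if records["protein_id"].duplicated().any():
        dups = records.loc[records["protein_id"].duplicated(), "protein_id"]
        raise ValueError(f"duplicate protein ids: {sorted(set(dups))}")
    if (records[["abundance_target", "abundance_control"]] < 0).any().any():
        raise ValueError("abundances must be >= 0")


def fold_change_filter(
    records: pd.DataFrame, factor: float = 2.0, pseudocount: float | None = None
) -> pd.DataFrame:
    """Keep proteins with (target + pc) / (control + pc) >= factor.

    The boundary is inclusive ("at least" a given fold increase).  When
    ``pseudocount`` is None it defaults to the smallest positive abundance in
    the table (0 if the table has no positive abundance), so zero-control
    proteins with real target signal survive instead of dividing by zero.
    """
    _validate(records)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if len(records) == 0:
        return records.copy()
    if pseudocount is None:
        values = records[["abundance_target", "abundance_control"]].to_numpy(float)
        positive = values[values > 0]
        pseudocount = float(positive.min()) if positive.size else 0.0
    num = records["abundance_target"] + pseudocount
    den = records["abundance_control"] + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    keep = (ratio >= factor) | ((den == 0) & (num > 0))
    return records[keep].copy()


def membrane_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep proteins with membrane-proteome evidence and a plasma-membrane
    localization call (conjunction of both lines of evidence)."""
    _validate(records)
    keep = records["membrane_evidence"].astype(bool) & (
        records["predicted_localization"] == "plasma_membrane"
    )
    return records[keep].copy()


def phenotype_filter(
    records: pd.DataFrame, phenotype: BindingPhenotype, strict: bool = True
) -> pd.DataFrame:
    """Keep proteins overexpressed in every recognized line and
    under-expressed in every unrecognized line.

    In strict mode (default) an ``unknown`` status fails the requirement; in
    lenient mode unknown statuses are ignored.
    """
    _validate(records)
    for line in sorted(phenotype.lines):
        if status_column(line) not in records.columns:
            raise ValueError(f"no status column for cell line {line!r}")
    keep = pd.Series(True, index=records.index)
    for line in phenotype.recognized_lines:
        status = records[status_column(line)]
        keep &= (status == "over") if strict else (status != "under")
    for line in phenotype.unrecognized_lines:
        status = records[status_column(line)]
        keep &= (status == "under") if strict else (status != "over")
    return records[keep].copy()


@dataclass
class CascadeReport:
    """Per-stage survivor counts and the final shortlist, in filter order."""

    n_input: int
    n_after_fold_change: int
    n_after_membrane: int
    n_after_phenotype: int
    shortlist: list[str] = field(default_factory=list)

    @property
    def stage_counts(self) -> tuple[int, int, int]:
        return (self.n_after_fold_change, self.n_after_membrane, self.n_after_phenotype)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_fold_change": self.n_after_fold_change,
            "n_after_membrane": self.n_after_membrane,
            "n_after_phenotype": self.n_after_phenotype,
            "shortlist": list(self.shortlist),
        }


def run_cascade(
    records: pd.DataFrame,
    phenotype: BindingPhenotype,
    factor: float = 2.0,
    pseudocount: float | None = None,
    strict: bool = True,
) -> CascadeReport:
    """Apply fold-change, membrane and phenotype filters in order."""
    _validate(records)
    stage1 = fold_change_filter(records, factor=factor, pseudocount=pseudocount)
    stage2 = membrane_filter(stage1)
    stage3 = phenotype_filter(stage2, phenotype, strict=strict)
    return CascadeReport(
        n_input=len(records),
        n_after_fold_change=len(stage1),
        n_after_membrane=len(stage2),
        n_after_phenotype=len(stage3),
        shortlist=sorted(stage3["protein_id"].tolist()),
    )


def derive_status_from_abundance(
    abundances: pd.DataFrame, reference: str, fold: float = 2.0
) -> pd.DataFrame:
    """Optional helper: call over/under per cell line from an abundance matrix.

    ``abundances`` is proteins x cell lines (plus a ``protein_id`` column or
    index); a line is called ``over`` when its abundance is >= ``fold`` times
    the reference line's, ``under`` when <= 1/fold times, else ``unknown``.
    Published per-line expression calls, when available, are preferable.
    """
    df = abundances.set_index("protein_id") if "protein_id" in abundances.columns else abundances
    if reference not in df.columns:
        raise ValueError(f"reference line {reference!r} not in table")
    ref = df[reference].astype(float)
    out = pd.DataFrame(index=df.index)
    for line in df.columns:
        if line == reference:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = df[line].astype(float) / ref
        status = np.where(ratio >= fold, "over", np.where(ratio <= 1 / fold, "under", "unknown"))
        status = np.where(~np.isfinite(ratio), "unknown", status)
        out[status_column(line)] = status
    return out.reset_index()
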