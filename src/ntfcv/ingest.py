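"""Build a WeightedTensor from tabular layouts; subject filter; NPY I/O.

Three spreadsheet layouts are supported, all yielding a tensor with mode
order (subject, symptom, day) and day slices stacked in day-label order:

* **wide** — one row per subject, one column per (day, symptom) pair,
  named by exact concatenation day label + symptom name (``"1_1fatigue"``).
* **tidy** — long format, one row per (subject, day, symptom) observation
  with a value column; missing triples become missing cells.
* **sheets** — one subjects-x-symptoms sheet per day, stacked as frontal
  slices.

Missing values map to weight-0 cells.  The subject-completeness filter
keeps a subject when its missing-cell count is strictly below
``max_missing_fraction * J * K`` (default 30% of the symptom-day grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tensor_model import WeightedTensor

__all__ = [
    "LayoutSpec",
    "FilterRule",
    "default_day_labels",
    "reshape_wide",
    "reshape_tidy",
    "reshape_sheets",
    "filter_subjects",
    "save_tensor",
    "load_tensor",
    "read_workbook",
]


def default_day_labels(days_per_dose: int = 7, doses: int = 2) -> list[str]:
    """Dose_day labels: "1_1".."1_7" then "2_1".."2_7" by default."""
    return [f"{d}_{i}" for d in range(1, doses + 1) for i in range(1, days_per_dose + 1)]


@dataclass
class LayoutSpec:
    """Declares the symptom and day vocabularies and the subject ID column."""

    symptom_names: list[str]
    day_labels: list[str]
    subject_id_column: str = "ID"
    day_column: str = "days"
    symptom_column: str = "symptoms"
    value_column: str = "value"

    def __post_init__(self) -> None:
        for name, labels in (("symptom_names", self.symptom_names),
                             ("day_labels", self.day_labels)):
            if not labels:
                raise ValueError(f"{name} must be non-empty")
            if len(set(labels)) != len(labels):
                raise ValueError(f"{name} contains duplicates")


@dataclass
class FilterRule:
    """Keep a subject iff its missing-cell count < max_missing_fraction * J * K."""

    max_missing_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.max_missing_fraction <= 1:
            raise ValueError("max_missing_fraction must be in [0, 1]")


def _tensor_from_array(values: np.ndarray, dim_labels) -> WeightedTensor:
    weights = np.isfinite(values).astype(float)
    return WeightedTensor(values=values, weights=weights, dim_labels=dim_labels)


def reshape_wide(table: pd.DataFrame, spec: LayoutSpec) -> WeightedTensor:
    """Wide layout: rows = subjects, columns = day label + symptom name."""
    i = len(table)
    j, k = len(spec.symptom_names), len(spec.day_labels)
    values = np.full((i, j, k), np.nan)
    for ki, day in enumerate(spec.day_labels):
        for ji, sym in enumerate(spec.symptom_names):
            col = day + sym
            matches = [c for c in table.columns if c == col]
            if len(matches) != 1:
                raise ValueError(
                    f"expected exactly one column {col!r} for day {day!r}, "
                    f"symptom {sym!r}; found {len(matches)}"
                )
            values[:, ji, ki] = pd.to_numeric(table[col], errors="coerce").to_numpy()
    subjects = (
        table[spec.subject_id_column].tolist()
        if spec.subject_id_column in table.columns
        else list(range(i))
    )
    return _tensor_from_array(values, (subjects, spec.symptom_names, spec.day_labels))


def reshape_tidy(table: pd.DataFrame, spec: LayoutSpec) -> WeightedTensor:
    """Tidy (tall narrow) layout: one row per (subject, day, symptom) value."""
    required = {spec.subject_id_column, spec.day_column, spec.symptom_column,
                spec.value_column}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise ValueError(f"tidy table lacks columns {sorted(missing_cols)}")
    bad_days = set(table[spec.day_column]) - set(spec.day_labels)
    if bad_days:
        raise ValueError(f"unknown day labels {sorted(map(str, bad_days))}")
    bad_syms = set(table[spec.symptom_column]) - set(spec.symptom_names)
    if bad_syms:
        raise ValueError(f"unknown symptom labels {sorted(map(str, bad_syms))}")
    keys = table[[spec.subject_id_column, spec.day_column, spec.symptom_column]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (subject, day, symptom) triple {dup}")

    subjects = sorted(table[spec.subject_id_column].unique())
    i_of = {s: n for n, s in enumerate(subjects)}
    j_of = {s: n for n, s in enumerate(spec.symptom_names)}
    k_of = {d: n for n, d in enumerate(spec.day_labels)}
    values = np.full((len(subjects), len(spec.symptom_names), len(spec.day_labels)),
                     np.nan)
    for _, r in table.iterrows():
        values[
            i_of[r[spec.subject_id_column]],
            j_of[r[spec.symptom_column]],
            k_of[r[spec.day_column]],
        ] = r[spec.value_column]
    return _tensor_from_array(values, (subjects, spec.symptom_names, spec.day_labels))


def reshape_sheets(sheets: list[pd.DataFrame], spec: LayoutSpec) -> WeightedTensor:
    """Multi-sheet layout: one subjects-x-symptoms sheet per day, in day order."""
    if len(sheets) != len(spec.day_labels):
        raise ValueError(
            f"{len(sheets)} sheets != {len(spec.day_labels)} day labels"
        )
    shapes = {s.shape for s in sheets}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent sheet shapes {sorted(shapes)}")
    slices = []
    for day, sheet in zip(spec.day_labels, sheets):
        missing_cols = set(spec.symptom_names) - set(sheet.columns)
        if missing_cols:
            raise ValueError(
                f"sheet for day {day!r} lacks symptom columns {sorted(missing_cols)}"
            )
        block = sheet[spec.symptom_names].apply(pd.to_numeric, errors="coerce")
        slices.append(block.to_numpy(dtype=float))
    values = np.stack(slices, axis=2)
    first = sheets[0]
    subjects = (
        first[spec.subject_id_column].tolist()
        if spec.subject_id_column in first.columns
        else list(range(values.shape[0]))
    )
    return _tensor_from_array(values, (subjects, spec.symptom_names, spec.day_labels))


def filter_subjects(
    x: WeightedTensor, rule: FilterRule = FilterRule()
) -> tuple[WeightedTensor, list[int]]:
    """Drop subjects with too many missing cells.

    Keeps subject i iff its weight-0 count is strictly below
    ``rule.max_missing_fraction * J * K``; returns the sub-tensor and the
    kept original indices in order.
    """
    _, j, k = x.shape
    thr = rule.max_missing_fraction * j * k
    missing_per_subject = (x.weights == 0).sum(axis=(1, 2))
    kept = [int(i) for i in np.flatnonzero(missing_per_subject < thr)]
    labels = x.dim_labels
    sub_labels = (
        [labels[0][i] for i in kept] if labels[0] is not None else None,
        labels[1],
        labels[2],
    )
    return (
        WeightedTensor(
            values=x.values[kept], weights=x.weights[kept], dim_labels=sub_labels
        ),
        kept,
    )


def save_tensor(x: WeightedTensor, path: str | Path) -> None:
    """Write the values array (NaN = missing) as a .npy file."""
    np.save(path, x.values.astype(np.float64))


def load_tensor(path: str | Path) -> WeightedTensor:
    """Read a .npy tensor; NaN cells become weight 0.

    Raises on non-3-dimensional arrays and on finite negative entries
    (non-negative factorization requires values >= 0).
    """
    arr = np.asarray(np.load(path), dtype=float)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-dimensional array, got {arr.ndim} dimensions")
    finite = np.isfinite(arr)
    if (arr[finite] < 0).any():
        raise ValueError(
            "The data tensor contains negative elements: take absolute values or "
            "shift so the minimum is 0 before factorizing"
        )
    return WeightedTensor(values=arr, weights=finite.astype(float))


def read_workbook(
    path: str | Path, layout: str, spec: LayoutSpec
) -> WeightedTensor:
    """Read an XLSX workbook in one of the three layouts ("wide", "tidy",
    "sheets"); first row is the header."""
    if layout == "wide":
        return reshape_wide(pd.read_excel(path), spec)
    if layout == "tidy":
        return reshape_tidy(pd.read_excel(path), spec)
    if layout == "sheets":
        book = pd.read_excel(path, sheet_name=None)
        return reshape_sheets(list(book.values()), spec)
    raise ValueError(f"unknown layout {layout!r}")
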