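"""Data model, file I/O and value transforms for immune-marker cohorts.

The central container is :class:`ImmuneProfileMatrix`, a markers x patients
numeric table annotated with the kind of each marker (soluble checkpoint,
cytokine/chemokine/adhesion molecule, or CD137+ T-cell subset) and a
``transform_state`` that records which preprocessing has been applied
(``raw`` concentrations in pg/mL or percent-of-parent, ``log`` after a
log2(x+1) transform, ``znorm`` after per-marker standardisation).

Clinical annotations live in :class:`ClinicalTable`: per-patient response
(R/NR at 6 months), ECOG performance status (PS=0 vs PS>0) and an
overall-survival dichotomy at a configurable cutoff (default 3 months,
separating early progressors from the rest).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateMarkerError,
    DomainError,
    FormatError,
    ParseError,
    ValidationError,
)

MARKER_KINDS = ("checkpoint", "cytokine", "cell_subset")
TRANSFORM_STATES = ("raw", "log", "znorm")

RESPONSE_LABELS = ("R", "NR")
PS_LABELS = ("PS0", "PSgt0")
OS_LABELS = ("le_cutoff", "gt_cutoff")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImmuneProfileMatrix:
    """Markers x patients numeric table with marker-kind annotation.

    Parameters
    ----------
    values
        DataFrame indexed by marker id with one column per patient id.
        Cells are finite floats or NaN (explicitly missing).
    marker_kinds
        Mapping marker id -> one of ``checkpoint``, ``cytokine``,
        ``cell_subset``.
    transform_state
        One of ``raw``, ``log``, ``znorm``.
    """

    values: pd.DataFrame
    marker_kinds: dict[str, str]
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(f"unknown transform_state {self.transform_state!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            raise ValidationError(f"duplicate marker ids: {sorted(idx[idx.duplicated()])}")
        if cols.duplicated().any():
            raise ValidationError(f"duplicate patient ids: {sorted(cols[cols.duplicated()])}")
        vals = self.values.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValidationError("non-finite (infinite) cell in profile matrix")
        unknown = [m for m in idx if self.marker_kinds.get(m) not in MARKER_KINDS]
        if unknown:
            raise ValidationError(f"markers without a valid kind annotation: {unknown}")
        self.values = self.values.astype(float)

    # -- convenience views -------------------------------------------------
    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_patients(self) -> int:
        return self.values.shape[1]

    def subset_markers(self, markers) -> "ImmuneProfileMatrix":
        missing = [m for m in markers if m not in self.values.index]
        if missing:
            raise ValidationError(f"unknown markers requested: {missing}")
        return replace(self, values=self.values.loc[list(markers)])

    def subset_patients(self, patients) -> "ImmuneProfileMatrix":
        missing = [p for p in patients if p not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown patients requested: {missing}")
        return replace(self, values=self.values[list(patients)])

    def markers_of_kind(self, kind: str) -> list[str]:
        if kind not in MARKER_KINDS:
            raise ValidationError(f"unknown marker kind {kind!r}")
        return [m for m in self.marker_ids if self.marker_kinds[m] == kind]


@dataclass
class ClinicalTable:
    """Per-patient categorical labels defining the three clinical contrasts.

    ``table`` is indexed by patient id with columns ``response`` (R/NR),
    ``performance_status`` (PS0/PSgt0), optional ``os_months`` and
    ``os_group`` (le_cutoff/gt_cutoff relative to ``os_cutoff_months``).
    """

    table: pd.DataFrame
    os_cutoff_months: float = 3.0

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValidationError("duplicate patient ids in clinical table")
        for col, labels in (("response", RESPONSE_LABELS),
                            ("performance_status", PS_LABELS)):
            if col not in t.columns:
                raise ValidationError(f"clinical table missing column {col!r}")
            bad = set(t[col].dropna()) - set(labels)
            if bad:
                raise ValidationError(f"invalid {col} labels: {sorted(bad)}")
        if "os_group" in t.columns:
            bad = set(t["os_group"].dropna()) - set(OS_LABELS)
            if bad:
                raise ValidationError(f"invalid os_group labels: {sorted(bad)}")
            if "os_months" in t.columns and t["os_months"].notna().all():
                os_m = t["os_months"].astype(float)
                if (os_m < 0).any():
                    raise ValidationError("negative os_months")
                expect = np.where(os_m <= self.os_cutoff_months, "le_cutoff", "gt_cutoff")
                mism = t.index[(t["os_group"].notna()) & (t["os_group"] != expect)]
                if len(mism):
                    raise ValidationError(
                        f"os_group inconsistent with os_months at cutoff "
                        f"{self.os_cutoff_months}: patients {list(mism)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.table.index)

    def labels(self, variable: str) -> pd.Series:
        if variable not in self.table.columns:
            raise ValidationError(f"clinical variable {variable!r} not present")
        return self.table[variable]

    def check_covers(self, patients) -> None:
        missing = [p for p in patients if p not in self.table.index]
        if missing:
            raise ValidationError(f"patients without a clinical row: {missing}")

    def summary(self) -> dict:
        """Counts per clinical label, JSON-serialisable."""
        out: dict[str, dict[str, int]] = {}
        for col in ("response", "performance_status", "os_group"):
            if col in self.table.columns:
                out[col] = {str(k): int(v)
                            for k, v in self.table[col].value_counts().items()}
        out["n_patients"] = len(self.table)
        return out


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group clinical contrast: condition A vs condition B.

    Condition A is conventionally the adverse state (NR, PS>0, early
    progression) so that a ``+/0`` edge reads "correlated in the adverse
    group, uncorrelated in the favourable one".
    """

    name: str
    condition_A_label: str
    condition_B_label: str

    _COLUMNS = {"response": "response",
                "performance_status": "performance_status",
                "os_group": "os_group"}

    def __post_init__(self) -> None:
        if self.name not in self._COLUMNS:
            raise ValidationError(f"unknown contrast name {self.name!r}")
        if self.condition_A_label == self.condition_B_label:
            raise ValidationError("contrast conditions must differ")

    @property
    def column(self) -> str:
        return self._COLUMNS[self.name]

    def split(self, clin: ClinicalTable, patients=None,
              min_group: int = 4) -> tuple[list[str], list[str]]:
        """Partition ``patients`` (default: all) into (group A, group B)."""
        labels = clin.labels(self.column)
        if patients is not None:
            clin.check_covers(patients)
            labels = labels.loc[list(patients)]
        a = [p for p, v in labels.items() if v == self.condition_A_label]
        b = [p for p, v in labels.items() if v == self.condition_B_label]
        if len(a) < min_group or len(b) < min_group:
            raise ValidationError(
                f"contrast {self.name}: groups of size {len(a)}/{len(b)} "
                f"below the minimum of {min_group}")
        return a, b


#: The three standard contrasts, adverse condition first.
STANDARD_CONTRASTS = {
    "response": ContrastSpec("response", "NR", "R"),
    "performance_status": ContrastSpec("performance_status", "PSgt0", "PS0"),
    "os_group": ContrastSpec("os_group", "le_cutoff", "gt_cutoff"),
}


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _delimiter_for(path, delimiter=None) -> str:
    if delimiter is not None:
        return delimiter
    s = str(path)
    return "," if s.endswith(".csv") else "\t"


def load_profiles(path, kind_map: dict[str, str], *, orientation: str = "markers_as_columns",
                  delimiter: str | None = None,
                  on_unknown_marker: str = "error") -> ImmuneProfileMatrix:
    """Read a profile matrix from CSV/TSV.

    The default orientation is patients as rows (first column = patient id)
    and markers as columns; ``orientation="markers_as_rows"`` reads the
    transposed layout. Unknown markers (absent from ``kind_map``) are either
    rejected (``on_unknown_marker="error"``) or dropped (``"drop"``).
    """
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file or missing header") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: no data columns found (missing header?)")
    if orientation == "markers_as_columns":
        df = df.T  # -> markers x patients
    elif orientation != "markers_as_rows":
        raise ValidationError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    # locate non-numeric cells before coercing, so errors can name them
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        marker = bad.index[bad.any(axis=1)][0]
        patient = bad.columns[bad.loc[marker]][0]
        raise ParseError(
            f"{path}: non-numeric value {df.loc[marker, patient]!r} "
            f"at marker {marker!r}, patient {patient!r}")

    unknown = [m for m in coerced.index if m not in kind_map]
    if unknown:
        if on_unknown_marker == "drop":
            coerced = coerced.drop(index=unknown)
        else:
            raise ValidationError(f"{path}: markers not in kind map: {unknown}")
    kinds = {m: kind_map[m] for m in coerced.index}
    return ImmuneProfileMatrix(values=coerced, marker_kinds=kinds)


def write_profiles(m: ImmuneProfileMatrix, path, *, orientation: str = "markers_as_columns",
                   delimiter: str | None = None) -> None:
    """Write a profile matrix in the same dialect :func:`load_profiles` reads."""
    sep = _delimiter_for(path, delimiter)
    df = m.values.T if orientation == "markers_as_columns" else m.values
    label = "patient_id" if orientation == "markers_as_columns" else "marker_id"
    df.to_csv(path, sep=sep, index_label=label)


def load_clinical(path, *, delimiter: str | None = None,
                  os_cutoff_months: float = 3.0) -> ClinicalTable:
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, header=0)
    df.index = df.index.astype(str)
    return ClinicalTable(table=df, os_cutoff_months=os_cutoff_months)


def write_clinical(clin: ClinicalTable, path, *, delimiter: str | None = None) -> None:
    sep = _delimiter_for(path, delimiter)
    clin.table.to_csv(path, sep=sep, index_label="patient_id")


def write_cohort_summary(clin: ClinicalTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(clin.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def log_transform(m: ImmuneProfileMatrix, *, base: float = 2.0,
                  pseudocount: float = 1.0) -> ImmuneProfileMatrix:
    """log_base(x + pseudocount), the variance-stabilising first step.

    Concentrations are non-negative and right-skewed; with the default
    base 2 and pseudocount 1, a zero concentration maps to 0 and group
    differences downstream read directly as log2 fold changes.
    """
    if m.transform_state != "raw":
        raise ValidationError(f"log_transform requires raw state, got {m.transform_state!r}")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 if np.isfinite(np.nanmin(vals)) else False:
        raise DomainError("negative value in raw profile matrix")
    if (vals[~np.isnan(vals)] < 0).any():
        raise DomainError("negative value in raw profile matrix")
    out = np.log(vals + pseudocount) / math.log(base)
    return replace(m, values=pd.DataFrame(out, index=m.values.index,
                                          columns=m.values.columns),
                   transform_state="log")


def z_normalize(m: ImmuneProfileMatrix, *, ddof: int = 1) -> ImmuneProfileMatrix:
    """Standardise each marker row to mean 0 and unit sample variance.

    Missing cells are ignored in the moments and propagated. A marker with
    fewer than two distinct non-missing values cannot be standardised and
    raises :class:`DegenerateMarkerError` naming it.
    """
    vals = m.values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=ddof, keepdims=True)
    degenerate = [mk for mk, s in zip(m.marker_ids, sd.ravel())
                  if not np.isfinite(s) or s == 0]
    if degenerate:
        raise DegenerateMarkerError(degenerate)
    out = (vals - mean) / sd
    return replace(m, values=pd.DataFrame(out, index=m.values.index,
                                          columns=m.values.columns),
                   transform_state="znorm")


def binarize_os(clin: ClinicalTable, cutoff_months: float = 3.0) -> ClinicalTable:
    """Dichotomise overall survival at ``cutoff_months`` into le/gt groups."""
    t = clin.table
    if "os_months" not in t.columns or t["os_months"].isna().any():
        raise ValidationError("binarize_os requires os_months for every patient")
    os_m = t["os_months"].astype(float)
    if (os_m < 0).any():
        raise ValidationError("negative os_months")
    new = t.copy()
    new["os_group"] = np.where(os_m <= cutoff_months, "le_cutoff", "gt_cutoff")
    return ClinicalTable(table=new, os_cutoff_months=cutoff_months)
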