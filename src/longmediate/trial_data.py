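"""Patient-level longitudinal trial data: model, CSV IO, analysis sets.

The data model is deliberately small: a :class:`TrialDataset` is a list of
:class:`Patient` records, each carrying an ordered list of :class:`Visit`
measurements (week since randomization, urinary albumin-to-creatinine ratio
[UACR, mg/g creatinine], systolic/diastolic blood pressure [mmHg], and
estimated glomerular filtration rate [eGFR, mL/min/1.73 m²]) plus categorical
subgroup attributes (sex, BMI class, ...).

Units are documented, not converted: the reader validates only positivity
and finiteness where the downstream log transform requires it (UACR must be
strictly positive).

Missingness follows the complete-case-per-endpoint rule: ``analysis_set``
keeps patients with complete baseline (UACR, SBP, eGFR) and a non-missing
UACR at the requested endpoint week.  No imputation is performed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import EstimationError, FormatError, ValidationError

__all__ = [
    "Visit",
    "Patient",
    "TrialDataset",
    "read_trial_table",
    "write_trial_table",
    "analysis_set",
    "subgroup",
]

#: measurement columns stored on a Visit, in canonical order
MEASUREMENTS = ("uacr", "sbp", "dbp", "egfr")

#: attribute columns recognised in CSV files (extra columns are also kept)
KNOWN_ATTRIBUTES = (
    "sex",
    "bmi_class",
    "hba1c_class",
    "uacr_class",
    "egfr_class",
    "dpp4_use",
    "sglt2_use",
)

_LONG_REQUIRED = ("patient_id", "arm", "week") + MEASUREMENTS


@dataclass(frozen=True)
class Visit:
    """Measurements at one scheduled week; ``None`` marks a missing value."""

    week: int
    uacr: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    egfr: float | None = None

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValidationError(f"visit week must be >= 0, got {self.week}")
        if self.uacr is not None and not (self.uacr > 0 and math.isfinite(self.uacr)):
            raise ValidationError(
                f"UACR must be positive and finite (log transform), got {self.uacr}"
            )
        for name in ("sbp", "dbp", "egfr"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")

    def value(self, measurement: str) -> float | None:
        if measurement not in MEASUREMENTS:
            raise KeyError(f"unknown measurement {measurement!r}")
        return getattr(self, measurement)


@dataclass
class Patient:
    """One randomized patient: arm, visit trajectory, subgroup attributes."""

    id: str
    arm: int
    visits: list[Visit] = field(default_factory=list)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in (0, 1):
            raise ValidationError(
                f"patient {self.id}: arm must be 0 (control) or 1 (active), got {self.arm}"
            )
        self.visits = sorted(self.visits, key=lambda v: v.week)
        weeks = [v.week for v in self.visits]
        if len(weeks) != len(set(weeks)):
            dup = next(w for w in weeks if weeks.count(w) > 1)
            raise ValidationError(f"patient {self.id}: duplicate visit at week {dup}")

    def visit(self, week: int) -> Visit | None:
        for v in self.visits:
            if v.week == week:
                return v
        return None

    @property
    def baseline(self) -> Visit | None:
        return self.visit(0)

    def has_complete_baseline(self) -> bool:
        """Baseline UACR, SBP and eGFR all present (inclusion requirement)."""
        b = self.baseline
        return b is not None and b.uacr is not None and b.sbp is not None and b.egfr is not None


@dataclass
class TrialDataset:
    """A collection of patients plus free-form provenance metadata."""

    patients: list[Patient] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate patient id {dup!r}")

    def __len__(self) -> int:
        return len(self.patients)

    def arms(self) -> set[int]:
        return {p.arm for p in self.patients}

    def weeks(self) -> list[int]:
        """All visit weeks observed anywhere in the dataset, sorted."""
        return sorted({v.week for p in self.patients for v in p.visits})

    def uacr_weeks(self) -> list[int]:
        return sorted(
            {v.week for p in self.patients for v in p.visits if v.uacr is not None}
        )

    def attribute_levels(self, attribute: str) -> list[str]:
        levels = {
            p.attributes[attribute] for p in self.patients if attribute in p.attributes
        }
        if not levels and not any(attribute in p.attributes for p in self.patients):
            raise KeyError(f"unknown attribute {attribute!r}")
        return sorted(levels)


# ---------------------------------------------------------------------------
# CSV IO
# ---------------------------------------------------------------------------

_WIDE_COL = re.compile(r"^(uacr|sbp|dbp|egfr)_w(\d+)$")


def _cell(x) -> float | None:
    return None if pd.isna(x) else float(x)


def read_trial_table(path, layout: str = "long") -> TrialDataset:
    """Read a patient-level trial CSV.

    Long layout: one row per patient-visit with columns
    ``patient_id, arm, week, uacr, sbp, dbp, egfr`` plus optional attribute
    columns.  Wide layout: one row per patient with ``patient_id, arm``,
    attribute columns, and per-week measurement columns named like
    ``uacr_w0, uacr_w4, ..., sbp_w0, ...``.  ``"."`` or an empty cell marks
    a missing value.
    """
    df = pd.read_csv(
        path, na_values=["."], dtype={"patient_id": str}, float_precision="round_trip"
    )
    if layout == "long":
        return _from_long(df, source=str(path))
    if layout == "wide":
        return _from_wide(df, source=str(path))
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def _validated_visit(pid, week, values) -> Visit:
    try:
        return Visit(week=week, **values)
    except ValidationError as exc:
        raise ValidationError(f"patient {pid}, week {week}: {exc}") from None


def _from_long(df: pd.DataFrame, source: str) -> TrialDataset:
    missing = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"long CSV is missing column(s): {', '.join(missing)}")
    attr_cols = [c for c in df.columns if c not in _LONG_REQUIRED]
    patients = []
    for pid, grp in df.groupby("patient_id", sort=True):
        arms = set(grp["arm"].astype(int))
        if len(arms) > 1:
            raise ValidationError(f"patient {pid}: arm is not constant across rows")
        weeks = grp["week"].astype(int).tolist()
        if len(weeks) != len(set(weeks)):
            dup = next(w for w in weeks if weeks.count(w) > 1)
            raise ValidationError(f"patient {pid}: duplicate visit at week {dup}")
        visits = [
            _validated_visit(
                pid, int(row["week"]), {m: _cell(row[m]) for m in MEASUREMENTS}
            )
            for _, row in grp.iterrows()
        ]
        attrs = {}
        for c in attr_cols:
            vals = grp[c].dropna()
            if len(vals):
                attrs[c] = str(vals.iloc[0])
        patients.append(Patient(id=str(pid), arm=arms.pop(), visits=visits, attributes=attrs))
    return TrialDataset(patients=patients, meta={"source": source, "layout": "long"})


def _from_wide(df: pd.DataFrame, source: str) -> TrialDataset:
    for c in ("patient_id", "arm"):
        if c not in df.columns:
            raise FormatError(f"wide CSV is missing column(s): {c}")
    meas_cols: dict[str, tuple[str, int]] = {}
    attr_cols = []
    for c in df.columns:
        if c in ("patient_id", "arm"):
            continue
        m = _WIDE_COL.match(c)
        if m:
            meas_cols[c] = (m.group(1), int(m.group(2)))
        else:
            attr_cols.append(c)
    if not meas_cols:
        raise FormatError("wide CSV has no measurement columns (e.g. uacr_w0)")
    patients = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        by_week: dict[int, dict[str, float | None]] = {}
        for c, (meas, week) in meas_cols.items():
            by_week.setdefault(week, {})[meas] = _cell(row[c])
        visits = [
            _validated_visit(pid, w, vals)
            for w, vals in sorted(by_week.items())
            if any(v is not None for v in vals.values())
        ]
        attrs = {c: str(row[c]) for c in attr_cols if not pd.isna(row[c])}
        patients.append(Patient(id=pid, arm=int(row["arm"]), visits=visits, attributes=attrs))
    return TrialDataset(patients=patients, meta={"source": source, "layout": "wide"})


def to_long_frame(ds: TrialDataset) -> pd.DataFrame:
    """Long-format DataFrame view (one row per patient-visit)."""
    attr_cols = sorted({a for p in ds.patients for a in p.attributes})
    rows = []
    for p in ds.patients:
        for v in p.visits:
            row = {"patient_id": p.id, "arm": p.arm, "week": v.week}
            row.update({m: v.value(m) for m in MEASUREMENTS})
            row.update({a: p.attributes.get(a) for a in attr_cols})
            rows.append(row)
    return pd.DataFrame(rows, columns=list(_LONG_REQUIRED) + attr_cols)


def write_trial_table(ds: TrialDataset, path, layout: str = "long") -> None:
    """Write a dataset back to CSV; inverse of :func:`read_trial_table`."""
    if layout == "long":
        to_long_frame(ds).to_csv(path, index=False)
        return
    if layout != "wide":
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    attr_cols = sorted({a for p in ds.patients for a in p.attributes})
    weeks = ds.weeks()
    rows = []
    for p in ds.patients:
        row: dict = {"patient_id": p.id, "arm": p.arm}
        row.update({a: p.attributes.get(a) for a in attr_cols})
        for m in MEASUREMENTS:
            for w in weeks:
                v = p.visit(w)
                row[f"{m}_w{w}"] = None if v is None else v.value(m)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analysis-set construction
# ---------------------------------------------------------------------------


def analysis_set(ds: TrialDataset, endpoint_week: int) -> TrialDataset:
    """Complete-case analysis set for one endpoint week.

    Keeps patients with a complete baseline (non-missing UACR, SBP, eGFR at
    week 0) and a non-missing UACR at ``endpoint_week``; the per-timepoint
    inclusion rule under which per-week analysis sets may differ in size.
    Idempotent.  Raises :class:`EstimationError` if either arm empties.
    """
    kept = [
        p
        for p in ds.patients
        if p.has_complete_baseline()
        and p.visit(endpoint_week) is not None
        and p.visit(endpoint_week).uacr is not None
    ]
    out = TrialDataset(
        patients=kept,
        meta={
            **ds.meta,
            "filters": list(ds.meta.get("filters", []))
            + [f"analysis_set(endpoint_week={endpoint_week})"],
        },
    )
    for arm in (0, 1):
        if arm in ds.arms() and arm not in out.arms():
            raise EstimationError(
                f"analysis set at week {endpoint_week} has no patients in arm {arm}"
            )
    return out


def subgroup(ds: TrialDataset, attribute: str, level: str) -> TrialDataset:
    """Patients whose ``attribute`` equals ``level`` (may be empty)."""
    if not any(attribute in p.attributes for p in ds.patients):
        raise KeyError(f"unknown attribute {attribute!r}")
    kept = [p for p in ds.patients if p.attributes.get(attribute) == level]
    return TrialDataset(
        patients=kept,
        meta={
            **ds.meta,
            "filters": list(ds.meta.get("filters", []))
            + [f"subgroup({attribute}={level})"],
        },
    )


def copy_with_patients(ds: TrialDataset, patients: list[Patient]) -> TrialDataset:
    return replace(ds, patients=list(patients), meta=dict(ds.meta))
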