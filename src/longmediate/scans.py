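"""Repeat a mediation analysis across endpoint weeks or subgroups.

The longitudinal scan re-runs the whole pipeline — analysis-set
construction, mediator summarisation up to / just before the endpoint,
estimation, optional bootstrap — at each requested endpoint week, so the
per-week analysis sets may differ in size (only patients with a UACR value
at that week enter that cell).  The subgroup scan runs the same analysis
within each level of a categorical attribute.

Per-cell bootstrap seeds are ``master_seed + cell_index``, so a cell's
result does not depend on which other cells the scan contains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .errors import EstimationError, LongmediateError
from .inference import estimate_with_ci
from .mediation import AnalysisSpec, MediationEstimate, estimate_mediation
from .trial_data import TrialDataset, analysis_set, subgroup

__all__ = ["ScanCell", "ScanResult", "longitudinal_scan", "subgroup_scan"]


@dataclass
class ScanCell:
    label: str
    n_used: int
    estimate: MediationEstimate | None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.estimate is not None


@dataclass
class ScanResult:
    axis: str  # "week" or "subgroup"
    cells: list[ScanCell]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per cell × quantity, CIs alongside."""
        rows = []
        for cell in self.cells:
            if not cell.ok:
                rows.append(
                    {"cell": cell.label, "n_used": cell.n_used, "quantity": None,
                     "value": None, "lo95": None, "hi95": None, "error": cell.error}
                )
                continue
            cis = cell.estimate.cis or {}
            for q, v in cell.estimate.quantities().items():
                lo, hi = cis.get(q, (None, None))
                rows.append(
                    {"cell": cell.label, "n_used": cell.n_used, "quantity": q,
                     "value": v, "lo95": lo, "hi95": hi, "error": None}
                )
        return pd.DataFrame(rows)


def _run_cell(
    ds: TrialDataset, spec: AnalysisSpec, n_boot: int, seed: int
) -> tuple[MediationEstimate, int]:
    sub = analysis_set(ds, spec.endpoint_week)
    if n_boot > 0:
        est, _ = estimate_with_ci(sub, spec, n_replicates=n_boot, seed=seed)
    else:
        est = estimate_mediation(sub, spec)
    return est, est.n_used


def longitudinal_scan(
    ds: TrialDataset,
    spec: AnalysisSpec,
    weeks: list[int],
    *,
    n_boot: int = 0,
    seed: int = 0,
) -> ScanResult:
    """One mediation analysis per endpoint week; failed cells are flagged."""
    observed = set(ds.uacr_weeks())
    cells = []
    for i, w in enumerate(weeks):
        label = f"week {w}"
        if w not in observed:
            cells.append(ScanCell(label, 0, None, f"no UACR measurements at week {w}"))
            continue
        try:
            est, n = _run_cell(ds, replace(spec, endpoint_week=w), n_boot, seed + i)
        except LongmediateError as exc:
            cells.append(ScanCell(label, 0, None, str(exc)))
            continue
        cells.append(ScanCell(label, n, est))
    return ScanResult(axis="week", cells=cells)


def subgroup_scan(
    ds: TrialDataset,
    spec: AnalysisSpec,
    attribute: str,
    *,
    n_boot: int = 0,
    seed: int = 0,
) -> ScanResult:
    """One mediation analysis per level of ``attribute`` (same covariates)."""
    levels = ds.attribute_levels(attribute)
    if len(levels) < 2:
        raise EstimationError(
            f"attribute {attribute!r} has {len(levels)} level(s) in the data; "
            "a subgroup scan needs at least 2"
        )
    cells = []
    for i, level in enumerate(levels):
        label = f"{attribute}={level}"
        try:
            est, n = _run_cell(
                subgroup(ds, attribute, level),
                spec,
                n_boot,
                seed + i,
            )
        except LongmediateError as exc:
            cells.append(ScanCell(label, 0, None, str(exc)))
            continue
        cells.append(ScanCell(label, n, est))
    if not any(c.ok for c in cells):
        raise EstimationError(
            f"subgroup scan over {attribute!r} failed in every level: "
            + "; ".join(c.error or "" for c in cells)
        )
    return ScanResult(axis="subgroup", cells=cells)
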