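"""Scalar summaries of longitudinal mediator trajectories.

Two conventions reduce a patient's blood-pressure or eGFR trajectory to one
number per analysis, both defined on *changes from baseline*:

``cumulative_mean``
    the arithmetic mean change over all observed post-baseline visits up to
    and including the endpoint week — the cumulative-exposure hypothesis;

``achieved``
    the change at the latest non-missing visit *strictly before* the
    endpoint week — the acute-effect hypothesis.  When no pre-endpoint
    measurement exists the endpoint-week value is used and the fallback is
    flagged.  Setting ``strictly_before=False`` switches to the
    at-endpoint reading.

Mean arterial pressure (``map``) is derived per visit as
DBP + (SBP − DBP)/3 before differencing.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import EstimationError
from .trial_data import Patient, Visit

__all__ = [
    "MediatorSummary",
    "mediator_value",
    "change_from_baseline",
    "cumulative_mean_change",
    "achieved_change",
    "summarize",
]

MEDIATORS = ("sbp", "dbp", "egfr", "map")
CONVENTIONS = ("cumulative_mean", "achieved")


@dataclass(frozen=True)
class MediatorSummary:
    patient_id: str
    mediator: str
    convention: str
    value: float
    #: True when the achieved summary had to fall back to the endpoint visit
    fallback: bool = False


def mediator_value(visit: Visit, mediator: str) -> float | None:
    """Mediator measurement at one visit; MAP is composed from SBP and DBP."""
    if mediator == "map":
        if visit.sbp is None or visit.dbp is None:
            return None
        return visit.dbp + (visit.sbp - visit.dbp) / 3.0
    if mediator not in MEDIATORS:
        raise KeyError(f"unknown mediator {mediator!r}")
    return visit.value(mediator)


def _baseline_value(p: Patient, mediator: str) -> float:
    b = p.baseline
    v = None if b is None else mediator_value(b, mediator)
    if v is None:
        raise EstimationError(f"patient {p.id}: missing baseline {mediator}")
    return v


def change_from_baseline(p: Patient, mediator: str, week: int) -> float | None:
    """Visit-level change from baseline; ``None`` if the week is unmeasured."""
    base = _baseline_value(p, mediator)
    visit = p.visit(week)
    if visit is None:
        return None
    v = mediator_value(visit, mediator)
    return None if v is None else v - base


def cumulative_mean_change(
    p: Patient,
    mediator: str,
    endpoint_week: int,
    *,
    time_weighted: bool = False,
) -> MediatorSummary | None:
    """Mean change from baseline over post-baseline visits up to the endpoint.

    Missing visits are skipped (unweighted mean over observed values).  With
    ``time_weighted=True`` a trapezoid time average over the observed change
    trajectory (anchored at 0 change at week 0) is used instead.
    """
    base = _baseline_value(p, mediator)
    points = []
    for v in p.visits:
        if 0 < v.week <= endpoint_week:
            val = mediator_value(v, mediator)
            if val is not None:
                points.append((v.week, val - base))
    if not points:
        return None
    if time_weighted:
        knots = [(0, 0.0)] + points
        area = sum(
            (w1 - w0) * (c0 + c1) / 2.0
            for (w0, c0), (w1, c1) in zip(knots, knots[1:])
        )
        value = area / (points[-1][0] - 0)
    else:
        value = sum(c for _, c in points) / len(points)
    return MediatorSummary(p.id, mediator, "cumulative_mean", value)


def achieved_change(
    p: Patient,
    mediator: str,
    endpoint_week: int,
    *,
    strictly_before: bool = True,
) -> MediatorSummary | None:
    """Change at the latest non-missing visit just before the endpoint."""
    base = _baseline_value(p, mediator)
    latest: tuple[int, float] | None = None
    at_endpoint: float | None = None
    limit = endpoint_week if strictly_before else endpoint_week + 1
    for v in p.visits:
        if v.week <= 0:
            continue
        val = mediator_value(v, mediator)
        if val is None:
            continue
        if v.week < limit and (latest is None or v.week > latest[0]):
            latest = (v.week, val - base)
        if v.week == endpoint_week:
            at_endpoint = val - base
    if latest is not None:
        return MediatorSummary(p.id, mediator, "achieved", latest[1])
    if at_endpoint is not None:
        return MediatorSummary(p.id, mediator, "achieved", at_endpoint, fallback=True)
    return None


def summarize(
    p: Patient, mediator: str, convention: str, endpoint_week: int, **kwargs
) -> MediatorSummary | None:
    """Dispatch on convention name."""
    if convention == "cumulative_mean":
        return cumulative_mean_change(p, mediator, endpoint_week, **kwargs)
    if convention == "achieved":
        return achieved_change(p, mediator, endpoint_week, **kwargs)
    raise ValueError(f"unknown summary convention {convention!r}")
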