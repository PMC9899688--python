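"""Publication-style tables, machine-readable results files, and run logs.

Two renderings of the same estimates are provided: a full-precision tidy
CSV (one row per analysis × quantity with point estimate and 95% CI) for
machines, and an aligned text table for humans that rounds ratio-scale
effects to 3 decimal places and the proportion mediated to 1 — the
conventional presentation for geometric-mean-ratio decompositions.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import pandas as pd

from .mediation import MediationEstimate

__all__ = [
    "render_results_frame",
    "render_results_table",
    "write_results_csv",
    "read_results_csv",
    "RunConfig",
    "RunLog",
]

_EFFECT_ROWS = (("TE", "te_ratio"), ("NDE", "nde_ratio"), ("NIE", "nie_ratio"))


def render_results_frame(estimates: list[tuple[str, MediationEstimate]]) -> pd.DataFrame:
    """Full-precision tidy results: label × quantity with point, lo95, hi95."""
    rows = []
    for label, est in estimates:
        cis = est.cis or {}
        for q, v in est.quantities().items():
            lo, hi = cis.get(q, (None, None))
            rows.append(
                {"analysis": label, "n_used": est.n_used, "quantity": q,
                 "point": v, "lo95": lo, "hi95": hi}
            )
    return pd.DataFrame(rows)


def _fmt(v, nd, suffix=""):
    return "" if v is None else f"{v:.{nd}f}{suffix}"


def render_results_table(estimates: list[tuple[str, MediationEstimate]]) -> str:
    """Aligned text table: TE/NDE/NIE as ratios (3 d.p.), PM in % (1 d.p.)."""
    rows = []
    for label, est in estimates:
        cis = est.cis or {}
        for effect, q in _EFFECT_ROWS:
            v = est.quantities()[q]
            lo, hi = cis.get(q, (None, None))
            ci = f"({_fmt(lo, 3)}, {_fmt(hi, 3)})" if lo is not None else ""
            pm = ""
            if effect == "TE":
                plo, phi = cis.get("pm_pct", (None, None))
                pm = _fmt(est.pm_pct, 1, "%")
                if plo is not None:
                    pm += f" ({_fmt(plo, 1)}, {_fmt(phi, 1)})"
            rows.append(
                {"analysis": label, "effect": effect, "estimate": _fmt(v, 3),
                 "95% CI": ci, "PM": pm}
            )
    df = pd.DataFrame(rows)
    return df.to_string(index=False)


def write_results_csv(estimates: list[tuple[str, MediationEstimate]], path) -> None:
    render_results_frame(estimates).to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Everything needed to replay one CLI run byte-for-byte."""

    command: str
    options: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class RunLog:
    """Structured, timestamped event log for one run."""

    config: RunConfig
    events: list[dict] = field(default_factory=list)

    def record(self, event: str, **details) -> None:
        self.events.append({"time": time.time(), "event": event, **details})

    def to_json(self) -> str:
        return json.dumps(
            {"config": asdict(self.config), "events": self.events}, indent=2
        )
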