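"""Percentile-bootstrap confidence intervals for mediation estimates.

Whole patients are resampled with replacement (arms pooled by default, the
plain nonparametric bootstrap for a randomized trial; ``stratify_by_arm``
resamples within arms instead).  Each replicate refits both regressions on
the resampled rows — summaries and outcomes are computed once per dataset,
so a replicate costs two small least-squares solves.  Intervals are
empirical percentiles with linear interpolation between order statistics
(numpy's default), which makes them bit-reproducible for a fixed seed.

Proportion-mediated intervals are percentiles of the replicate PM draws
themselves, never back-computed from the effect intervals, so PM and effect
intervals stay mutually consistent replicate by replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, InferenceError
from .mediation import (
    AnalysisSpec,
    MediationEstimate,
    Rows,
    assemble_rows,
    estimate_from_rows,
)
from .trial_data import TrialDataset

__all__ = ["BootstrapResult", "bootstrap", "bootstrap_rows", "estimate_with_ci"]

QUANTITIES = ("te_log", "nde_log", "nie_log", "te_ratio", "nde_ratio", "nie_ratio", "pm_pct")


@dataclass
class BootstrapResult:
    n_replicates: int
    seed: int
    draws: dict[str, np.ndarray]
    n_failed: int = 0
    _level: float = 0.95

    def interval(self, quantity: str, level: float | None = None) -> tuple[float, float]:
        level = self._level if level is None else level
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        d = self.draws[quantity]
        return float(np.percentile(d, lo)), float(np.percentile(d, hi))

    @property
    def intervals(self) -> dict[str, tuple[float, float]]:
        return {q: self.interval(q) for q in self.draws}


def bootstrap_rows(
    rows: Rows,
    spec: AnalysisSpec,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    stratify_by_arm: bool = False,
    max_retry_factor: int = 10,
) -> BootstrapResult:
    """Bootstrap on pre-assembled per-patient rows (the fast path).

    Degenerate resamples (a single arm, or a rank-deficient refit) are
    redrawn, up to ``max_retry_factor * n_replicates`` redraws in total, and
    counted in ``n_failed``.
    """
    rng = np.random.default_rng(seed)
    n = rows.n
    idx0 = np.arange(n)
    arm1 = idx0[rows.a == 1.0]
    arm0 = idx0[rows.a == 0.0]
    draws: dict[str, list[float]] = {q: [] for q in QUANTITIES}
    n_failed = 0
    budget = max_retry_factor * n_replicates
    while len(draws["te_log"]) < n_replicates:
        if stratify_by_arm:
            idx = np.concatenate(
                [rng.choice(arm1, size=arm1.size), rng.choice(arm0, size=arm0.size)]
            )
        else:
            idx = rng.integers(0, n, size=n)
        try:
            est = estimate_from_rows(rows.take(idx), spec)
        except EstimationError:
            n_failed += 1
            if n_failed > budget:
                raise InferenceError(
                    f"bootstrap retry budget exhausted: {n_failed} degenerate "
                    f"resamples for {n_replicates} replicates"
                )
            continue
        for q, v in est.quantities().items():
            draws[q].append(v)
    return BootstrapResult(
        n_replicates=n_replicates,
        seed=seed,
        draws={q: np.asarray(v) for q, v in draws.items()},
        n_failed=n_failed,
    )


def bootstrap(
    ds: TrialDataset,
    spec: AnalysisSpec,
    n_replicates: int = 1000,
    seed: int = 0,
    **kwargs,
) -> BootstrapResult:
    """Patient-level percentile bootstrap of a mediation analysis."""
    rows = assemble_rows(ds, spec)
    estimate_from_rows(rows, spec)  # fail fast if the point estimate is impossible
    return bootstrap_rows(rows, spec, n_replicates, seed, **kwargs)


def estimate_with_ci(
    ds: TrialDataset,
    spec: AnalysisSpec,
    n_replicates: int = 1000,
    seed: int = 0,
    **kwargs,
) -> tuple[MediationEstimate, BootstrapResult]:
    """Point estimate plus bootstrap intervals attached to ``est.cis``."""
    rows = assemble_rows(ds, spec)
    est = estimate_from_rows(rows, spec)
    boot = bootstrap_rows(rows, spec, n_replicates, seed, **kwargs)
    est.cis = boot.intervals
    return est, boot
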