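"""Regression-based natural direct and indirect effects.

The outcome is the natural-log ratio of endpoint UACR to baseline UACR, so
additive effects on the analysis scale back-transform to geometric-mean
ratios versus placebo.  For treatment A ∈ {0, 1}, mediator summaries
M₁..M_K (change from baseline; see :mod:`longmediate.summaries`) and
baseline covariates C, two linear models are fitted by ordinary least
squares on the same analysis set:

    outcome:   Y  = θ₀ + θ_A·A + Σₖ (θ_Mk·Mₖ + θ_AMk·A·Mₖ) + θ_C'C
    mediator:  Mₖ = β₀ₖ + β_Aₖ·A + β_Cₖ'C            (one per mediator)

With c̄ the sample mean of the covariates over the analysis set and
m̄ₖ(a*) = β₀ₖ + β_Aₖ·a* + β_Cₖ'c̄ the model-implied mediator level under the
control condition, the counterfactual contrasts for a = 1 vs a* = 0 are

    NDE = [θ_A + Σₖ θ_AMk·m̄ₖ(a*)]·(a − a*)
    NIE = [Σₖ (θ_Mk + θ_AMk·a)·β_Aₖ]·(a − a*)
    TE  = NDE + NIE

on the log scale; exponentials give ratio-scale effects, and the proportion
mediated is 100·NIE/TE on the log (additive) scale.  With several mediators
the indirect effect is the *joint* effect through all of them, which does
not require specifying the causal ordering among the mediators.

Evaluating conditional effects at c̄ equals averaging patient-level
conditional effects because the models are linear, so the conditional and
marginal reports coincide.  Identification rests on the usual sequential
ignorability assumptions; randomization covers the exposure-outcome and
exposure-mediator parts, not the mediator-outcome part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .errors import EstimationError
from .summaries import summarize
from .trial_data import Patient, TrialDataset

__all__ = [
    "AnalysisSpec",
    "LinearFit",
    "MediationEstimate",
    "TotalEffectCheck",
    "build_outcome",
    "fit_least_squares",
    "assemble_rows",
    "estimate_mediation",
    "proportion_mediated",
    "proportion_mediated_from_ratios",
    "total_effect_check",
]

#: baseline covariate extractors, keyed by covariate name
_BASELINE_COVARIATES = {
    "bl_log_uacr": lambda b: None if b.uacr is None else math.log(b.uacr),
    "bl_sbp": lambda b: b.sbp,
    "bl_dbp": lambda b: b.dbp,
    "bl_egfr": lambda b: b.egfr,
    "bl_map": lambda b: None
    if b.sbp is None or b.dbp is None
    else b.dbp + (b.sbp - b.dbp) / 3.0,
}


@dataclass(frozen=True)
class AnalysisSpec:
    """Declarative description of one mediation run.

    ``mediators`` is an ordered tuple of (name, convention) pairs, e.g.
    ``(("sbp", "cumulative_mean"), ("egfr", "cumulative_mean"))``.
    ``covariates="auto"`` expands to the log baseline UACR plus the baseline
    value of every analyzed mediator.  ``interactions=False`` drops the
    exposure-mediator interaction terms (the product-of-coefficients /
    difference-method special case).
    """

    mediators: tuple[tuple[str, str], ...]
    endpoint_week: int = 52
    covariates: tuple[str, ...] | str = "auto"
    contrast: tuple[int, int] = (1, 0)
    interactions: bool = True

    def __post_init__(self) -> None:
        if not 1 <= len(self.mediators) <= 4:
            raise ValueError("between 1 and 4 mediators are supported")
        object.__setattr__(self, "mediators", tuple(tuple(m) for m in self.mediators))

    def resolved_covariates(self) -> tuple[str, ...]:
        if self.covariates != "auto":
            return tuple(self.covariates)
        cov = ["bl_log_uacr"]
        for name, _ in self.mediators:
            bl = f"bl_{name}"
            if bl not in cov:
                cov.append(bl)
        return tuple(cov)


@dataclass
class LinearFit:
    """An OLS fit: named coefficients, residual SD, size and rank."""

    names: list[str]
    coef: np.ndarray
    residual_sd: float
    n_used: int
    design_rank: int

    def __getitem__(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coef


@dataclass
class MediationEstimate:
    """TE/NDE/NIE on log and ratio scales, with proportion mediated (%).

    ``pm_pct`` is NaN when the total effect is exactly zero (undefined).
    ``cis`` optionally maps quantity names to (lo, hi) 95% intervals.
    """

    te_log: float
    nde_log: float
    nie_log: float
    n_used: int
    spec: AnalysisSpec
    outcome_fit: LinearFit | None = None
    mediator_fits: dict[str, LinearFit] = field(default_factory=dict)
    cis: dict[str, tuple[float, float]] | None = None

    @property
    def te_ratio(self) -> float:
        return math.exp(self.te_log)

    @property
    def nde_ratio(self) -> float:
        return math.exp(self.nde_log)

    @property
    def nie_ratio(self) -> float:
        return math.exp(self.nie_log)

    @property
    def pm_pct(self) -> float:
        return proportion_mediated(self.nie_log, self.te_log)

    def quantities(self) -> dict[str, float]:
        return {
            "te_log": self.te_log,
            "nde_log": self.nde_log,
            "nie_log": self.nie_log,
            "te_ratio": self.te_ratio,
            "nde_ratio": self.nde_ratio,
            "nie_ratio": self.nie_ratio,
            "pm_pct": self.pm_pct,
        }


def build_outcome(p: Patient, endpoint_week: int) -> float:
    """log(UACR at endpoint / UACR at baseline) — log geometric ratio."""
    b = p.baseline
    e = p.visit(endpoint_week)
    if b is None or b.uacr is None or e is None or e.uacr is None:
        raise EstimationError(
            f"patient {p.id}: UACR missing at baseline or week {endpoint_week}"
        )
    return math.log(e.uacr / b.uacr)


def fit_least_squares(y: np.ndarray, X: np.ndarray, names: list[str]) -> LinearFit:
    """OLS with a full-rank requirement.

    Rank deficiency is diagnosed with a pivoted QR factorization and reported
    by naming the columns whose pivoted R-diagonal is (numerically) zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise EstimationError(f"insufficient data: {n} rows for {k} regressors")
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, k) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < k:
        bad = sorted(names[piv[j]] for j in range(rank, k))
        raise EstimationError(
            f"rank-deficient design (rank {rank} of {k}); collinear column(s): "
            + ", ".join(bad)
        )
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - k
    residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    return LinearFit(list(names), coef, residual_sd, n, rank)


# ---------------------------------------------------------------------------
# Row assembly: one row per patient with outcome, summaries and covariates
# ---------------------------------------------------------------------------


@dataclass
class Rows:
    """Per-patient complete-case rows, ready for (re)fitting.

    Bootstrap resampling operates on these rows directly so that summaries
    are computed once per dataset, not once per replicate.
    """

    patient_ids: list[str]
    a: np.ndarray  # (n,) treatment indicator
    y: np.ndarray  # (n,) log outcome ratio
    m: np.ndarray  # (n, K) mediator summaries
    c: np.ndarray  # (n, p) baseline covariates
    mediator_labels: list[str]
    covariate_names: list[str]

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def take(self, idx: np.ndarray) -> "Rows":
        return Rows(
            [self.patient_ids[i] for i in idx],
            self.a[idx],
            self.y[idx],
            self.m[idx],
            self.c[idx],
            self.mediator_labels,
            self.covariate_names,
        )


def assemble_rows(ds: TrialDataset, spec: AnalysisSpec) -> Rows:
    """Build the complete-case per-patient row matrix for one analysis."""
    cov_names = list(spec.resolved_covariates())
    for c in cov_names:
        if c not in _BASELINE_COVARIATES:
            raise KeyError(f"unknown covariate {c!r}")
    labels = [f"{name}:{conv}" for name, conv in spec.mediators]
    ids, a, y, m, c = [], [], [], [], []
    for p in ds.patients:
        b = p.baseline
        if b is None or b.uacr is None:
            continue
        e = p.visit(spec.endpoint_week)
        if e is None or e.uacr is None:
            continue
        try:
            summaries = [
                summarize(p, name, conv, spec.endpoint_week)
                for name, conv in spec.mediators
            ]
        except EstimationError:
            continue  # missing mediator baseline
        if any(s is None for s in summaries):
            continue
        covs = [_BASELINE_COVARIATES[name](b) for name in cov_names]
        if any(v is None for v in covs):
            continue
        ids.append(p.id)
        a.append(float(p.arm))
        y.append(build_outcome(p, spec.endpoint_week))
        m.append([s.value for s in summaries])
        c.append(covs)
    return Rows(
        ids,
        np.asarray(a),
        np.asarray(y),
        np.asarray(m).reshape(len(ids), len(labels)),
        np.asarray(c).reshape(len(ids), len(cov_names)),
        labels,
        cov_names,
    )


def _check_rows(rows: Rows) -> None:
    if rows.n == 0:
        raise EstimationError("no analyzable patients (empty analysis set)")
    present = set(np.unique(rows.a))
    if present != {0.0, 1.0}:
        raise EstimationError(
            f"both arms required for estimation; arms present: {sorted(present)}"
        )


def _fit_models(rows: Rows, spec: AnalysisSpec) -> tuple[LinearFit, list[LinearFit]]:
    n, K = rows.m.shape
    one = np.ones(n)
    out_cols = [one, rows.a] + [rows.m[:, k] for k in range(K)]
    out_names = ["intercept", "arm"] + [f"m[{lab}]" for lab in rows.mediator_labels]
    if spec.interactions:
        out_cols += [rows.a * rows.m[:, k] for k in range(K)]
        out_names += [f"arm:m[{lab}]" for lab in rows.mediator_labels]
    out_cols += [rows.c[:, j] for j in range(rows.c.shape[1])]
    out_names += list(rows.covariate_names)
    outcome_fit = fit_least_squares(rows.y, np.column_stack(out_cols), out_names)

    med_X = np.column_stack([one, rows.a, rows.c])
    med_names = ["intercept", "arm"] + list(rows.covariate_names)
    mediator_fits = [
        fit_least_squares(rows.m[:, k], med_X, med_names) for k in range(K)
    ]
    return outcome_fit, mediator_fits


def estimate_from_rows(rows: Rows, spec: AnalysisSpec) -> MediationEstimate:
    """Closed-form NDE/NIE from fits on pre-assembled rows."""
    _check_rows(rows)
    outcome_fit, mediator_fits = _fit_models(rows, spec)
    a, a_star = spec.contrast
    cbar = rows.c.mean(axis=0)
    K = rows.m.shape[1]

    theta_a = outcome_fit["arm"]
    nde = theta_a
    nie = 0.0
    for k in range(K):
        lab = rows.mediator_labels[k]
        beta = mediator_fits[k]
        m_astar = beta["intercept"] + beta["arm"] * a_star + beta.coef[2:] @ cbar
        theta_m = outcome_fit[f"m[{lab}]"]
        theta_am = outcome_fit[f"arm:m[{lab}]"] if spec.interactions else 0.0
        nde += theta_am * m_astar
        nie += (theta_m + theta_am * a) * beta["arm"]
    nde_log = nde * (a - a_star)
    nie_log = nie * (a - a_star)
    return MediationEstimate(
        te_log=nde_log + nie_log,
        nde_log=nde_log,
        nie_log=nie_log,
        n_used=rows.n,
        spec=spec,
        outcome_fit=outcome_fit,
        mediator_fits={
            rows.mediator_labels[k]: mediator_fits[k] for k in range(K)
        },
    )


def estimate_mediation(ds: TrialDataset, spec: AnalysisSpec) -> MediationEstimate:
    """Fit both models on the dataset's complete cases and decompose TE."""
    return estimate_from_rows(assemble_rows(ds, spec), spec)


def proportion_mediated(nie_log: float, te_log: float) -> float:
    """100·NIE/TE on the additive (log) scale; NaN when TE = 0."""
    if te_log == 0:
        return float("nan")
    return 100.0 * nie_log / te_log


def proportion_mediated_from_ratios(nie_ratio: float, te_ratio: float) -> float:
    """Proportion mediated from ratio-scale (geometric mean ratio) effects."""
    return proportion_mediated(math.log(nie_ratio), math.log(te_ratio))


@dataclass
class TotalEffectCheck:
    """Decomposition TE versus the marginal intention-to-treat regression."""

    te_decomposition: float
    te_marginal: float

    @property
    def gap(self) -> float:
        return self.te_decomposition - self.te_marginal


def total_effect_check(ds: TrialDataset, spec: AnalysisSpec) -> TotalEffectCheck:
    """Compare the decomposition TE with the coefficient of treatment from a
    marginal regression of the outcome on treatment and covariates only.

    When the outcome model carries no exposure-mediator interaction and both
    models share rows and covariates, the two agree exactly (nested-OLS
    algebra); with interactions the gap is a finite-sample diagnostic that
    vanishes as n grows.
    """
    rows = assemble_rows(ds, spec)
    est = estimate_from_rows(rows, spec)
    X = np.column_stack([np.ones(rows.n), rows.a, rows.c])
    marginal = fit_least_squares(
        rows.y, X, ["intercept", "arm"] + list(rows.covariate_names)
    )
    a, a_star = spec.contrast
    return TotalEffectCheck(est.te_log, marginal["arm"] * (a - a_star))
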