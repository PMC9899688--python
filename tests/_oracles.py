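"""Independent oracles used by the test suite.

The Monte-Carlo counterfactual oracle re-derives natural direct/indirect
effects from the *fitted* models by brute-force simulation: draw mediator
values from the fitted mediator models under each treatment condition,
push them through the fitted outcome model at the covariate sample mean,
and average the counterfactual contrasts.  It shares the fitted
coefficients with the closed-form path but none of its algebra.
"""

import numpy as np


def mc_counterfactual(est, rows, n_draws=1_000_000, seed=0):
    """Simulate NDE/NIE from the fitted models; returns values and MC SEs."""
    rng = np.random.default_rng(seed)
    cbar = rows.c.mean(axis=0)
    K = rows.m.shape[1]
    theta = est.outcome_fit
    spec = est.spec

    def mediator_draws(a):
        cols = []
        for lab in rows.mediator_labels:
            beta = est.mediator_fits[lab]
            mean = beta["intercept"] + beta["arm"] * a + beta.coef[2:] @ cbar
            cols.append(rng.normal(mean, beta.residual_sd, size=n_draws))
        return np.column_stack(cols)

    def outcome(a, m):
        y = theta["intercept"] + theta["arm"] * a
        for k, lab in enumerate(rows.mediator_labels):
            coef = theta[f"m[{lab}]"]
            if spec.interactions:
                coef += theta[f"arm:m[{lab}]"] * a
            y = y + coef * m[:, k]
        return y + theta.coef[-rows.c.shape[1]:] @ cbar

    a, a_star = spec.contrast
    m_ctrl = mediator_draws(a_star)
    m_trt = mediator_draws(a)
    nde_draws = outcome(a, m_ctrl) - outcome(a_star, m_ctrl)
    nie_draws = outcome(a, m_trt) - outcome(a, m_ctrl)
    return (
        float(nde_draws.mean()),
        float(nie_draws.mean()),
        float(nde_draws.std(ddof=1) / np.sqrt(n_draws)),
        float(nie_draws.std(ddof=1) / np.sqrt(n_draws)),
    )
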