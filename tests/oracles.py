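"""Independent reference computations used to validate the package.

Everything here is deliberately written from first principles (scipy
distributions, direct quadrature, plain Monte-Carlo averaging) and shares no
code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats
from scipy.special import logsumexp


def mc_log_marginals(a_counts, b_counts, ab_counts, n_draws=200_000, seed=0,
                     rate_prior_shape=0.5, cap_multiplier=2.0):
    """Monte-Carlo marginal likelihoods of the AB counts under the four
    hypotheses, integrating the A/B rates over their conjugate Gamma
    posteriors and hypothesis parameters over their priors."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a_counts, float)
    b = np.asarray(b_counts, float)
    ab = np.asarray(ab_counts, float)

    lam_a = rng.gamma(rate_prior_shape + a.sum(), 1.0 / a.size, size=n_draws)
    lam_b = rng.gamma(rate_prior_shape + b.sum(), 1.0 / b.size, size=n_draws)
    alpha = rng.uniform(size=n_draws)

    # per-draw, per-trial log pmfs via scipy (independent of the package's
    # hand-written Poisson pmf)
    lp_a = stats.poisson.logpmf(ab[:, None], lam_a[None, :])
    lp_b = stats.poisson.logpmf(ab[:, None], lam_b[None, :])

    ll_mix = logsumexp(
        np.stack([np.log(alpha)[None, :] + lp_a, np.log1p(-alpha)[None, :] + lp_b]),
        axis=0).sum(axis=0)
    ll_int = stats.poisson.logpmf(
        ab[:, None], (alpha * lam_a + (1 - alpha) * lam_b)[None, :]).sum(axis=0)
    ll_single_a = lp_a.sum(axis=0)
    ll_single_b = lp_b.sum(axis=0)
    ll_single = logsumexp(np.stack([ll_single_a, ll_single_b]), axis=0) - np.log(2.0)

    low = np.minimum(lam_a, lam_b)
    high = np.maximum(lam_a, lam_b)
    cap = cap_multiplier * (lam_a + lam_b)
    below = rng.uniform(size=n_draws) < 0.5
    lam_star = np.where(below,
                        rng.uniform(size=n_draws) * low,
                        high + rng.uniform(size=n_draws) * (cap - high))
    ll_out = stats.poisson.logpmf(ab[:, None], lam_star[None, :]).sum(axis=0)

    def avg(ll):
        return float(logsumexp(ll) - np.log(n_draws))

    return {"mixture": avg(ll_mix), "intermediate": avg(ll_int),
            "single": avg(ll_single), "outside": avg(ll_out)}


def _quad_log_marginal(counts, prior_shape, prior_rate):
    """log integral of the Poisson likelihood against a proper Gamma prior,
    by adaptive quadrature on a shifted log scale."""
    counts = np.asarray(counts, float)
    peak = max((prior_shape + counts.sum() - 1) / (prior_rate + counts.size), 1e-6)

    def logf(lam):
        return (stats.poisson.logpmf(counts, lam).sum()
                + stats.gamma.logpdf(lam, prior_shape, scale=1.0 / prior_rate))

    shift = logf(peak)
    val, _ = integrate.quad(lambda lam: np.exp(logf(lam) - shift),
                            0, peak * 10 + 50, points=[peak], limit=200)
    return shift + np.log(val)


def quad_log_ibf(a_counts, b_counts, prior_shape=0.5, prior_rate=1e-8):
    """Arithmetic intrinsic Bayes factor for two distinct Poisson means over
    one shared mean, assembled from quadrature marginals with a proper
    Gamma(prior_shape, prior_rate) prior; prior_rate -> 0 recovers the
    improper-prior construction (the constants cancel across the ratio)."""
    a = np.asarray(a_counts, float)
    b = np.asarray(b_counts, float)
    m = lambda x: _quad_log_marginal(x, prior_shape, prior_rate)
    log_b10_full = m(a) + m(b) - m(np.concatenate([a, b]))
    parts = []
    for xa in a:
        for xb in b:
            parts.append(m([xa, xb]) - m([xa]) - m([xb]))
    return log_b10_full + logsumexp(parts) - np.log(len(parts))


def pearson_chi2(table):
    """Textbook Pearson chi-squared statistic for a 2x2 table."""
    table = np.asarray(table, float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
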