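"""Synthetic validation studies for the classification pipeline.

Each function runs one self-contained study on generated data with known
ground truth and returns plain numbers: analytic threshold identities,
quadrature-vs-Monte-Carlo agreement, classification recovery per generating
regime, the documented boundary caveats, Fano-screen rejection behaviour,
and mixing-weight recovery.  These back both the acceptance-style test
suite and the ``scripts/acceptance.py`` reporting script.

Study sizes default to the standard synthetic conditions: rates 20 vs 5
counts per 200 ms window, 15 trials per condition, 500 triplets per regime
category (the single and outside categories pool their two generator
variants 50/50), 40 trials per condition for the overdispersion screen and
the mixing-weight study.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .model import HYPOTHESES, ModelConfig, classify_triplet, classify_triplets
from .screening import (ScreeningConfig, screen_triplets, separability_posterior)
from .simulate import RegimeSpec, simulate_population

__all__ = [
    "threshold_identities",
    "oracle_agreement",
    "regime_recovery",
    "boundary_caveats",
    "screening_rejection",
    "alpha_recovery",
]


def threshold_identities() -> dict[str, float]:
    """Analytic identities behind the three decision thresholds.

    - with equal marginal likelihoods and equal priors every hypothesis has
      posterior 25%;
    - the "at least twice as likely as the rest combined" boundary for the
      fluctuating label sits at posterior 2/3 (printed as 0.67);
    - log intrinsic Bayes factor 3 under 1:1 prior odds corresponds to >95%
      posterior probability of distinct means.
    """
    from .model import posterior_probabilities

    equal = posterior_probabilities([0.0, 0.0, 0.0, 0.0])
    # posterior at which the winner is exactly twice as likely as the rest
    odds = 2.0
    twice_boundary = odds / (1.0 + odds)
    return {
        "equal_prior_posterior_pct": float(equal[0] * 100.0),
        "twice_as_likely_posterior_pct": float(twice_boundary * 100.0),
        "separability_posterior_pct_at_log_ibf_3": float(
            separability_posterior(3.0, prior_odds=1.0) * 100.0),
    }


def _random_small_specs(seed: int, n_triplets: int) -> list[RegimeSpec]:
    """Small random triplets (5 trials each, modest rates) across regimes."""
    rng = np.random.default_rng(seed)
    regimes = ("mixture", "intermediate", "single_A", "single_B",
               "outside_high", "outside_low")
    specs = []
    for i in range(n_triplets):
        lam_a = float(rng.uniform(3.0, 12.0))
        lam_b = float(rng.uniform(1.0, 6.0))
        specs.append(RegimeSpec(
            regime=regimes[i % len(regimes)], lambda_a=lam_a, lambda_b=lam_b,
            alpha=float(rng.uniform(0.2, 0.8)), n_a=5, n_b=5, n_ab=5,
            seed=int(rng.integers(2**31)),
        ))
    return specs


def oracle_agreement(seed: int, n_triplets: int = 24,
                     mc_draws: int = 300_000, n_batches: int = 10,
                     ) -> dict[str, float]:
    """Max |quadrature - Monte-Carlo| log marginal over random small triplets.

    The Monte-Carlo route draws rates from their Gamma posteriors and
    hypothesis parameters from their priors and averages likelihoods; it
    shares no quadrature machinery with the default path.  The Monte-Carlo
    estimate carries sampling noise of its own (importance weights are
    heavy-tailed when the AB data conflict with a hypothesis's prior
    support), so it is run in independent batches and the deviation is
    assessed only where the oracle's 3-standard-error resolution is finer
    than the 0.05-nat bound; the worst overall deviation is reported too.
    """
    from .model import hypothesis_log_marginals

    specs = _random_small_specs(seed, n_triplets)
    triplets = simulate_population(specs).triplets  # specs carry their own seeds
    max_dev_resolved = 0.0
    max_dev_any = 0.0
    n_resolved = 0
    for i, t in enumerate(triplets):
        quad = hypothesis_log_marginals(t, ModelConfig())
        batches = [
            hypothesis_log_marginals(
                t, ModelConfig(method="mc", mc_draws=mc_draws,
                               seed=seed + 1000 * i + b))
            for b in range(n_batches)
        ]
        for h in HYPOTHESES:
            vals = np.array([m[h] for m in batches])
            pooled = _pool_log_means(vals, mc_draws)
            se = float(vals.std(ddof=1) / np.sqrt(n_batches))
            dev = abs(quad[h] - pooled)
            max_dev_any = max(max_dev_any, dev)
            if 3.0 * se <= 0.05:
                n_resolved += 1
                max_dev_resolved = max(max_dev_resolved, dev)
    return {
        "max_abs_dev_nats": float(max_dev_resolved),
        "max_abs_dev_nats_unresolved": float(max_dev_any),
        "n_comparisons": n_resolved,
        "n": n_triplets,
    }


def _pool_log_means(batch_log_means: np.ndarray, draws_per_batch: int) -> float:
    """Combine equal-size batch log-mean estimates into the full-sample one."""
    from scipy.special import logsumexp

    return float(logsumexp(batch_log_means) - np.log(batch_log_means.size))


#: Regime-category composition for the recovery study: the single and
#: outside categories pool their two generator variants 50/50.
_CATEGORY_VARIANTS = {
    "mixture": ("mixture",),
    "intermediate": ("intermediate",),
    "single": ("single_A", "single_B"),
    "outside": ("outside_high", "outside_low"),
}


def _category_specs(category: str, n: int) -> list[RegimeSpec]:
    variants = _CATEGORY_VARIANTS[category]
    per = n // len(variants)
    specs = []
    for v in variants:
        specs += [RegimeSpec(regime=v) for _ in range(per)]
    return specs


def regime_recovery(seed: int, n_per_category: int = 500) -> dict[str, dict]:
    """Fraction of synthetic triplets whose modal classification matches the
    generating regime category, at the standard conditions."""
    out: dict[str, dict] = {}
    for k, category in enumerate(_CATEGORY_VARIANTS):
        specs = _category_specs(category, n_per_category)
        ds = simulate_population(specs, master_seed=seed + k)
        winners = [c.winner for c in classify_triplets(ds.triplets)]
        n = len(winners)
        out[category] = {
            "recovery_pct": 100.0 * winners.count(category) / n,
            "n": n,
        }
        if category == "mixture":
            out[category]["outside_pct"] = 100.0 * winners.count("outside") / n
    return out


def boundary_caveats(seed: int, n_triplets: int = 500) -> dict[str, dict]:
    """Classification of the two documented boundary cases at the standard
    conditions: mid-trial switching, and 90/10 trial-level mixing."""
    switch = simulate_population(
        [RegimeSpec(regime="mid_trial_switch") for _ in range(n_triplets)],
        master_seed=seed)
    switch_winners = [c.winner for c in classify_triplets(switch.triplets)]

    dominant = simulate_population(
        [RegimeSpec(regime="mixture", alpha=0.9) for _ in range(n_triplets)],
        master_seed=seed + 1)
    dominant_winners = [c.winner for c in classify_triplets(dominant.triplets)]

    return {
        "mid_trial_switch": {
            "intermediate_pct": 100.0 * switch_winners.count("intermediate") / n_triplets,
            "n": n_triplets,
        },
        "dominant_90_10_mixture": {
            "single_pct": 100.0 * dominant_winners.count("single") / n_triplets,
            "mixture_pct": 100.0 * dominant_winners.count("mixture") / n_triplets,
            "n": n_triplets,
        },
    }


def screening_rejection(seed: int, n_units: int = 500,
                        n_trials: int = 40) -> dict[str, dict]:
    """Fano-screen behaviour: rejection rate of overdispersed units
    (variance-to-mean 5) and the strict-variant subset property."""
    over = simulate_population(
        [RegimeSpec(regime="mixture", dispersion=5.0,
                    n_a=n_trials, n_b=n_trials, n_ab=n_trials)
         for _ in range(n_units)],
        master_seed=seed)
    reports = screen_triplets(over.triplets)
    rejected = sum(not r.included for r in reports)

    # mixed-dispersion dataset for the subset property (includes borderline
    # units that pass the default Fano cap 3 but fail the strict cap 2)
    mixed_specs = [RegimeSpec(regime="mixture", dispersion=d,
                              n_a=n_trials, n_b=n_trials, n_ab=n_trials)
                   for d in ([1.0] * 60 + [2.0] * 60 + [2.8] * 30 + [5.0] * 30)]
    mixed = simulate_population(mixed_specs, master_seed=seed + 1)
    default_in = {r.triplet.unit_id for r in screen_triplets(mixed.triplets)
                  if r.included}
    strict_in = {r.triplet.unit_id
                 for r in screen_triplets(mixed.triplets,
                                          ScreeningConfig(max_mean_fano=2.0))
                 if r.included}
    return {
        "overdispersed": {"rejection_pct": 100.0 * rejected / n_units, "n": n_units},
        "strict_screen": {
            "subset_violations": float(len(strict_in - default_in)),
            "is_proper_subset": float(strict_in < default_in),
            "n": len(mixed_specs),
        },
    }


def alpha_recovery(seed: int, alphas: Sequence[float] = (0.25, 0.5, 0.75),
                   n_per_alpha: int = 100, n_ab: int = 40) -> dict[str, float]:
    """Mean absolute error of the posterior-mean mixing weight on
    mixture-regime triplets with 40 AB trials."""
    errors = []
    for k, alpha in enumerate(alphas):
        specs = [RegimeSpec(regime="mixture", alpha=alpha, n_ab=n_ab)
                 for _ in range(n_per_alpha)]
        ds = simulate_population(specs, master_seed=seed + k)
        for c in classify_triplets(ds.triplets):
            errors.append(abs(c.alpha_posterior_mean - alpha))
    return {"mae": float(np.mean(errors)), "n": len(errors)}
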