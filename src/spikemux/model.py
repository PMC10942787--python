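"""Bayesian classification of combined-stimulus spike-count distributions.

Given a screened triplet — spike counts for stimulus A alone, B alone, and
both together (AB) — the question is how the AB response distribution
relates to the two single-stimulus Poisson response distributions.  Four
hypotheses are compared:

``mixture``
    Each AB trial is drawn from either the A or the B Poisson distribution,
    with a trial-level mixing weight ``alpha ~ Uniform(0, 1)`` — the
    signature of trial-to-trial fluctuation ("multiplexing").
``intermediate``
    All AB trials come from a single Poisson whose rate lies strictly
    between the A and B rates, ``alpha*lam_A + (1-alpha)*lam_B`` with
    ``alpha ~ Uniform(0, 1)`` — averaging, or switching faster than the
    counting window.
``single``
    All AB trials match exactly one of the single-stimulus distributions
    (winner-take-all with a constant winner); the A and B branches are
    averaged with equal weight.
``outside``
    All AB trials come from a Poisson rate below both or above both
    single-stimulus rates (suppression or summation).

The single-stimulus rates ``lam_A`` and ``lam_B`` are not plugged in as
point estimates: they are integrated under their conjugate Gamma posteriors
from the A-alone / B-alone trials, so that triplets with as few as five
trials are treated honestly.  All integrals use fixed-order Gauss
quadrature (deterministic); a Monte-Carlo integration path is available via
``ModelConfig(method="mc")``.  Posterior probabilities over the four
hypotheses use equal 25% priors by default; a triplet is flagged
*fluctuating* when the mixture hypothesis wins with posterior probability
above 0.67, i.e. when mixture is at least twice as likely as the other
three hypotheses combined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import Triplet

__all__ = [
    "HYPOTHESES",
    "ModelConfig",
    "RatePosterior",
    "TripletClassification",
    "PoissonTripletModel",
    "TripletResults",
    "fit_rate_posterior",
    "hypothesis_log_marginals",
    "posterior_probabilities",
    "classify_triplet",
    "classify_triplets",
    "classifications_to_frame",
]

#: Hypothesis labels in tie-break priority order (argmax over this order
#: resolves exact ties toward the earlier label).
HYPOTHESES = ("mixture", "intermediate", "single", "outside")


@dataclass(frozen=True)
class ModelConfig:
    """Priors, quadrature orders and decision thresholds."""

    hypothesis_priors: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    rate_prior_shape: float = 0.5
    rate_prior_rate: float = 0.0
    outside_cap_multiplier: float = 2.0
    n_rate_nodes: int = 31
    n_alpha_nodes: int = 63
    n_outside_nodes: int = 31
    fluctuation_threshold: float = 0.67
    method: str = "quadrature"  # or "mc"
    mc_draws: int = 200_000
    seed: int | None = 0  # only the Monte-Carlo path consumes this

    def __post_init__(self) -> None:
        priors = np.asarray(self.hypothesis_priors, dtype=float)
        if priors.shape != (4,) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-9:
            raise ValueError("hypothesis_priors must be four non-negative values summing to 1")
        if not 0.5 < self.fluctuation_threshold < 1.0:
            raise ValueError("fluctuation_threshold must lie in (0.5, 1)")
        if self.rate_prior_shape <= 0:
            raise ValueError("rate_prior_shape must be positive")
        if self.rate_prior_rate < 0:
            raise ValueError("rate_prior_rate must be non-negative")
        if self.outside_cap_multiplier <= 0:
            raise ValueError("outside_cap_multiplier must be positive")
        if min(self.n_rate_nodes, self.n_alpha_nodes, self.n_outside_nodes) < 3:
            raise ValueError("quadrature orders must be >= 3")
        if self.method not in ("quadrature", "mc"):
            raise ValueError("method must be 'quadrature' or 'mc'")


@dataclass(frozen=True)
class RatePosterior:
    """Gamma posterior over a Poisson mean (counts per window)."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        return self.shape / self.rate**2


def fit_rate_posterior(counts: Sequence[int], config: ModelConfig | None = None) -> RatePosterior:
    """Conjugate Gamma posterior for a Poisson rate from single-stimulus counts."""
    cfg = config or ModelConfig()
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("counts must be nonempty")
    return RatePosterior(shape=cfg.rate_prior_shape + float(arr.sum()),
                         rate=cfg.rate_prior_rate + float(arr.size))


@dataclass(frozen=True)
class TripletClassification:
    """Outcome of the four-way model comparison for one triplet."""

    triplet: Triplet
    log_marginal: Mapping[str, float]
    posterior: Mapping[str, float]
    winner: str
    winner_posterior: float
    fluctuating: bool
    alpha_posterior_mean: float
    single_branch: str  # "A" or "B": the branch dominating the single hypothesis


# ---------------------------------------------------------------------------
# Quadrature machinery
# ---------------------------------------------------------------------------

_LEGGAUSS_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _LEGGAUSS_CACHE:
        _LEGGAUSS_CACHE[n] = leggauss(n)
    return _LEGGAUSS_CACHE[n]


def _gamma_nodes(post: RatePosterior, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and normalised log-weights for integrating a function against a
    Gamma posterior: Gauss-Legendre nodes across the central
    (1e-10, 1 - 1e-10) quantile interval, weighted by the posterior density.

    This stays stable for the large posterior shapes routine here (shape ~
    sum of counts), where generalized Gauss-Laguerre weights overflow.
    """
    dist = stats.gamma(a=post.shape, scale=1.0 / post.rate)
    lo = max(float(dist.ppf(1e-10)), 1e-300)
    hi = float(dist.ppf(1.0 - 1e-10))
    x, w = _leggauss(n_nodes)
    nodes = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    logw = np.log(w) + dist.logpdf(nodes)
    logw -= logsumexp(logw)  # renormalise: removes interval truncation and scale
    return nodes, logw


def _alpha_nodes(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes for alpha ~ Uniform(0,1); strictly interior, so
    the intermediate hypothesis never touches the single-hypothesis endpoints."""
    x, w = _leggauss(n_nodes)
    return 0.5 * (x + 1.0), np.log(w / 2.0)


def _log_poisson_pmf(counts: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """log Poisson pmf on the outer product grid counts x rates."""
    c = counts[:, None]
    lam = rates[None, :]
    return c * np.log(lam) - lam - gammaln(c + 1.0)


# ---------------------------------------------------------------------------
# Marginal likelihoods (quadrature path)
# ---------------------------------------------------------------------------


def _marginals_quadrature(triplet: Triplet, cfg: ModelConfig) -> tuple[dict, dict]:
    ab = np.asarray(triplet.ab_counts, dtype=float)
    n_ab = ab.size
    s_ab = float(ab.sum())
    log_fact = float(gammaln(ab + 1.0).sum())

    post_a = fit_rate_posterior(triplet.a_counts, cfg)
    post_b = fit_rate_posterior(triplet.b_counts, cfg)
    la, lwa = _gamma_nodes(post_a, cfg.n_rate_nodes)
    lb, lwb = _gamma_nodes(post_b, cfg.n_rate_nodes)
    alpha, lwalpha = _alpha_nodes(cfg.n_alpha_nodes)

    lpa = _log_poisson_pmf(ab, la)  # (n_ab, nA)
    lpb = _log_poisson_pmf(ab, lb)  # (n_ab, nB)
    lw_ab = lwa[:, None] + lwb[None, :]  # (nA, nB)

    # --- mixture: per-trial alpha-coin between the two rates -------------
    mix_ll = np.empty((alpha.size, la.size, lb.size))
    la_term = lpa[:, :, None]  # (n_ab, nA, 1)
    lb_term = lpb[:, None, :]  # (n_ab, 1, nB)
    for k, a_k in enumerate(alpha):
        per_trial = np.logaddexp(np.log(a_k) + la_term, np.log1p(-a_k) + lb_term)
        mix_ll[k] = per_trial.sum(axis=0)
    mix_grid = mix_ll + lw_ab[None, :, :]
    log_m_mixture = float(logsumexp(mix_grid + lwalpha[:, None, None]))
    # posterior over alpha nodes, marginalising the rates
    mix_by_alpha = logsumexp(mix_grid, axis=(1, 2)) + lwalpha
    alpha_mean_mixture = float(np.exp(mix_by_alpha - logsumexp(mix_by_alpha)) @ alpha)

    # --- intermediate: one Poisson at alpha*lamA + (1-alpha)*lamB --------
    rate_grid = (alpha[:, None, None] * la[None, :, None]
                 + (1.0 - alpha)[:, None, None] * lb[None, None, :])
    int_ll = s_ab * np.log(rate_grid) - n_ab * rate_grid - log_fact
    int_grid = int_ll + lw_ab[None, :, :]
    log_m_intermediate = float(logsumexp(int_grid + lwalpha[:, None, None]))
    int_by_alpha = logsumexp(int_grid, axis=(1, 2)) + lwalpha
    alpha_mean_intermediate = float(np.exp(int_by_alpha - logsumexp(int_by_alpha)) @ alpha)

    # --- single: exact Gamma-Poisson (negative binomial) predictive ------
    def _branch_log_marginal(post: RatePosterior) -> float:
        return float(
            -log_fact
            + gammaln(post.shape + s_ab) - gammaln(post.shape)
            + post.shape * np.log(post.rate)
            - (post.shape + s_ab) * np.log(post.rate + n_ab)
        )

    log_m_single_a = _branch_log_marginal(post_a)
    log_m_single_b = _branch_log_marginal(post_b)
    log_m_single = float(np.logaddexp(log_m_single_a, log_m_single_b) - np.log(2.0))
    single_branch = "A" if log_m_single_a >= log_m_single_b else "B"

    # --- outside: rate below both or above both single-stimulus rates ----
    lam_lo = np.minimum(la[:, None], lb[None, :])  # (nA, nB)
    lam_hi = np.maximum(la[:, None], lb[None, :])
    cap = cfg.outside_cap_multiplier * (la[:, None] + lb[None, :])
    x, w = _leggauss(cfg.n_outside_nodes)
    half = 0.5 * (x + 1.0)  # nodes on (0, 1)
    logw_mean = np.log(w / 2.0)  # averaging weights on a unit interval

    def _segment_lse(seg_lo: np.ndarray, seg_hi: np.ndarray) -> np.ndarray:
        lam = seg_lo[:, :, None] + (seg_hi - seg_lo)[:, :, None] * half  # (nA,nB,Q)
        ll = s_ab * np.log(lam) - n_ab * lam - log_fact
        return logsumexp(ll + logw_mean, axis=2)

    seg_low = _segment_lse(np.zeros_like(lam_lo), lam_lo)
    seg_high = _segment_lse(lam_hi, cap)
    out_per_pair = np.logaddexp(seg_low, seg_high) - np.log(2.0)
    log_m_outside = float(logsumexp(out_per_pair + lw_ab))

    log_marginal = {
        "mixture": log_m_mixture,
        "intermediate": log_m_intermediate,
        "single": log_m_single,
        "outside": log_m_outside,
    }
    extras = {
        "alpha_mean_mixture": alpha_mean_mixture,
        "alpha_mean_intermediate": alpha_mean_intermediate,
        "single_branch": single_branch,
        "log_m_single_a": log_m_single_a,
        "log_m_single_b": log_m_single_b,
    }
    return log_marginal, extras


# ---------------------------------------------------------------------------
# Marginal likelihoods (Monte-Carlo path)
# ---------------------------------------------------------------------------


def _marginals_mc(triplet: Triplet, cfg: ModelConfig) -> tuple[dict, dict]:
    rng = np.random.default_rng(cfg.seed)
    ab = np.asarray(triplet.ab_counts, dtype=float)
    n_ab = ab.size
    s_ab = float(ab.sum())
    log_fact = float(gammaln(ab + 1.0).sum())
    n_draws = cfg.mc_draws

    post_a = fit_rate_posterior(triplet.a_counts, cfg)
    post_b = fit_rate_posterior(triplet.b_counts, cfg)
    la = rng.gamma(post_a.shape, 1.0 / post_a.rate, size=n_draws)
    lb = rng.gamma(post_b.shape, 1.0 / post_b.rate, size=n_draws)
    alpha = rng.uniform(0.0, 1.0, size=n_draws)

    lpa = ab[:, None] * np.log(la)[None, :] - la[None, :] - gammaln(ab + 1.0)[:, None]
    lpb = ab[:, None] * np.log(lb)[None, :] - lb[None, :] - gammaln(ab + 1.0)[:, None]

    mix_ll = np.logaddexp(np.log(alpha)[None, :] + lpa,
                          np.log1p(-alpha)[None, :] + lpb).sum(axis=0)
    log_m_mixture = float(logsumexp(mix_ll) - np.log(n_draws))
    w = np.exp(mix_ll - logsumexp(mix_ll))
    alpha_mean_mixture = float(w @ alpha)

    rate = alpha * la + (1.0 - alpha) * lb
    int_ll = s_ab * np.log(rate) - n_ab * rate - log_fact
    log_m_intermediate = float(logsumexp(int_ll) - np.log(n_draws))
    w = np.exp(int_ll - logsumexp(int_ll))
    alpha_mean_intermediate = float(w @ alpha)

    single_a_ll = lpa.sum(axis=0)
    single_b_ll = lpb.sum(axis=0)
    log_m_single_a = float(logsumexp(single_a_ll) - np.log(n_draws))
    log_m_single_b = float(logsumexp(single_b_ll) - np.log(n_draws))
    log_m_single = float(np.logaddexp(log_m_single_a, log_m_single_b) - np.log(2.0))
    single_branch = "A" if log_m_single_a >= log_m_single_b else "B"

    lam_lo = np.minimum(la, lb)
    lam_hi = np.maximum(la, lb)
    cap = cfg.outside_cap_multiplier * (la + lb)
    below = rng.random(n_draws) < 0.5
    u = rng.uniform(0.0, 1.0, size=n_draws)
    lam_star = np.where(below, u * lam_lo, lam_hi + u * (cap - lam_hi))
    out_ll = s_ab * np.log(lam_star) - n_ab * lam_star - log_fact
    log_m_outside = float(logsumexp(out_ll) - np.log(n_draws))

    log_marginal = {
        "mixture": log_m_mixture,
        "intermediate": log_m_intermediate,
        "single": log_m_single,
        "outside": log_m_outside,
    }
    extras = {
        "alpha_mean_mixture": alpha_mean_mixture,
        "alpha_mean_intermediate": alpha_mean_intermediate,
        "single_branch": single_branch,
        "log_m_single_a": log_m_single_a,
        "log_m_single_b": log_m_single_b,
    }
    return log_marginal, extras


# ---------------------------------------------------------------------------
# Public functional surface
# ---------------------------------------------------------------------------


def hypothesis_log_marginals(triplet: Triplet,
                             config: ModelConfig | None = None) -> dict[str, float]:
    """Log marginal likelihood of the AB counts under each hypothesis."""
    cfg = config or ModelConfig()
    compute = _marginals_mc if cfg.method == "mc" else _marginals_quadrature
    log_marginal, _ = compute(triplet, cfg)
    bad = [h for h, v in log_marginal.items() if not np.isfinite(v)]
    if bad:
        raise FloatingPointError(
            f"non-finite log marginal for {bad} on triplet "
            f"{triplet.unit_id}/{triplet.stimulus_pair_id}")
    return log_marginal


def posterior_probabilities(log_marginals: Sequence[float] | Mapping[str, float],
                            priors: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                            ) -> np.ndarray:
    """Posterior over hypotheses: softmax of log prior + log marginal."""
    if isinstance(log_marginals, Mapping):
        values = np.array([log_marginals[h] for h in HYPOTHESES], dtype=float)
    else:
        values = np.asarray(log_marginals, dtype=float)
    priors_arr = np.asarray(priors, dtype=float)
    if abs(priors_arr.sum() - 1.0) > 1e-9:
        raise ValueError("priors must sum to 1")
    with np.errstate(divide="ignore"):
        z = values + np.log(priors_arr)
    if not np.any(np.isfinite(z)):
        raise FloatingPointError("all hypotheses have -inf weight")
    z -= logsumexp(z)
    return np.exp(z)


class PoissonTripletModel:
    """Four-hypothesis Poisson model for one triplet's AB response.

    Parameters
    ----------
    triplet
        A screened :class:`~spikemux.io.Triplet`, or pass the three count
        vectors to :meth:`from_counts`.
    config
        :class:`ModelConfig`; defaults reproduce the standard analysis
        (equal 25% hypothesis priors, Jeffreys rate prior, 0.67 threshold).

    Examples
    --------
    >>> model = PoissonTripletModel.from_counts([21, 18, 23], [5, 4, 6],
    ...                                         [20, 6, 22, 4, 19])
    >>> res = model.fit()
    >>> res.winner
    'mixture'
    """

    def __init__(self, triplet: Triplet, config: ModelConfig | None = None):
        self.triplet = triplet
        self.config = config or ModelConfig()

    @classmethod
    def from_counts(cls, a_counts, b_counts, ab_counts,
                    config: ModelConfig | None = None,
                    unit_id: str = "unit", stimulus_pair_id: str = "A|B",
                    ) -> "PoissonTripletModel":
        return cls(Triplet(unit_id, stimulus_pair_id,
                           np.asarray(a_counts), np.asarray(b_counts),
                           np.asarray(ab_counts)), config)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config: ModelConfig | None = None,
                       condition_col: str = "condition", count_col: str = "spike_count",
                       unit_id: str = "unit", stimulus_pair_id: str = "A|B",
                       ) -> "PoissonTripletModel":
        """Build from a tidy per-trial frame with condition (A/B/AB) and count columns."""
        counts = {
            cond: frame.loc[frame[condition_col] == cond, count_col].to_numpy()
            for cond in ("A", "B", "AB")
        }
        return cls.from_counts(counts["A"], counts["B"], counts["AB"], config,
                               unit_id=unit_id, stimulus_pair_id=stimulus_pair_id)

    @property
    def rate_posterior_a(self) -> RatePosterior:
        return fit_rate_posterior(self.triplet.a_counts, self.config)

    @property
    def rate_posterior_b(self) -> RatePosterior:
        return fit_rate_posterior(self.triplet.b_counts, self.config)

    def fit(self) -> "TripletResults":
        cfg = self.config
        compute = _marginals_mc if cfg.method == "mc" else _marginals_quadrature
        log_marginal, extras = compute(self.triplet, cfg)
        bad = [h for h, v in log_marginal.items() if not np.isfinite(v)]
        if bad:
            raise FloatingPointError(
                f"non-finite log marginal for {bad} on triplet "
                f"{self.triplet.unit_id}/{self.triplet.stimulus_pair_id}")
        posterior = posterior_probabilities(log_marginal, cfg.hypothesis_priors)
        # argmax over the fixed priority order resolves exact ties toward
        # mixture > intermediate > single > outside
        winner_idx = int(np.argmax(posterior))
        winner = HYPOTHESES[winner_idx]
        winner_posterior = float(posterior[winner_idx])
        fluctuating = winner == "mixture" and winner_posterior > cfg.fluctuation_threshold
        if winner == "intermediate":
            alpha_mean = extras["alpha_mean_intermediate"]
        else:
            alpha_mean = extras["alpha_mean_mixture"]
        return TripletResults(
            model=self,
            log_marginal=dict(log_marginal),
            posterior=dict(zip(HYPOTHESES, posterior.tolist())),
            winner=winner,
            winner_posterior=winner_posterior,
            fluctuating=fluctuating,
            alpha_posterior_mean=float(alpha_mean),
            single_branch=extras["single_branch"],
            extras=extras,
        )


@dataclass(frozen=True)
class TripletResults:
    """Fitted four-way comparison; returned by :meth:`PoissonTripletModel.fit`."""

    model: PoissonTripletModel
    log_marginal: dict[str, float]
    posterior: dict[str, float]
    winner: str
    winner_posterior: float
    fluctuating: bool
    alpha_posterior_mean: float
    single_branch: str
    extras: dict = field(default_factory=dict, repr=False)

    @property
    def triplet(self) -> Triplet:
        return self.model.triplet

    def as_classification(self) -> TripletClassification:
        return TripletClassification(
            triplet=self.triplet,
            log_marginal=self.log_marginal,
            posterior=self.posterior,
            winner=self.winner,
            winner_posterior=self.winner_posterior,
            fluctuating=self.fluctuating,
            alpha_posterior_mean=self.alpha_posterior_mean,
            single_branch=self.single_branch,
        )

    def summary(self) -> str:
        t = self.triplet
        pa = self.model.rate_posterior_a
        pb = self.model.rate_posterior_b
        lines = [
            "Poisson triplet model comparison",
            "=" * 56,
            f"unit {t.unit_id}  pair {t.stimulus_pair_id}",
            f"trials: A={t.a_counts.size}  B={t.b_counts.size}  AB={t.ab_counts.size}",
            f"posterior rate means: A={pa.mean:.2f}  B={pb.mean:.2f}  (counts/window)",
            "-" * 56,
            f"{'hypothesis':<14}{'log marginal':>16}{'posterior':>12}",
        ]
        for h in HYPOTHESES:
            lines.append(f"{h:<14}{self.log_marginal[h]:>16.3f}{self.posterior[h]:>12.4f}")
        lines += [
            "-" * 56,
            f"winner: {self.winner} (p={self.winner_posterior:.4f})"
            f"{'  [fluctuating]' if self.fluctuating else ''}",
            f"alpha posterior mean: {self.alpha_posterior_mean:.3f}"
            f"   single branch: {self.single_branch}",
        ]
        return "\n".join(lines)


def classify_triplet(triplet: Triplet, config: ModelConfig | None = None,
                     ) -> TripletClassification:
    """Classify one triplet's AB distribution; functional wrapper over
    :class:`PoissonTripletModel`."""
    return PoissonTripletModel(triplet, config).fit().as_classification()


def classify_triplets(triplets: Iterable[Triplet], config: ModelConfig | None = None,
                      ) -> list[TripletClassification]:
    cfg = config or ModelConfig()
    return [classify_triplet(t, cfg) for t in triplets]


def classifications_to_frame(classifications: Iterable[TripletClassification]) -> pd.DataFrame:
    """Flatten classifications to a per-triplet report table."""
    rows = []
    for c in classifications:
        row = {
            "unit_id": c.triplet.unit_id,
            "stimulus_pair_id": c.triplet.stimulus_pair_id,
        }
        for h in HYPOTHESES:
            row[f"log_marginal_{h}"] = c.log_marginal[h]
        for h in HYPOTHESES:
            row[f"posterior_{h}"] = c.posterior[h]
        row.update({
            "winner": c.winner,
            "winner_posterior": c.winner_posterior,
            "fluctuating": c.fluctuating,
            "alpha_posterior_mean": c.alpha_posterior_mean,
            "single_branch": c.single_branch,
        })
        rows.append(row)
    return pd.DataFrame(rows)
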