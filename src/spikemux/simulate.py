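"""Synthetic triplet generation with known ground truth.

Generates A/B/AB spike-count triplets under each hypothesised response
regime so that the screening and classification stages can be validated
end-to-end.  Single-stimulus counts are Poisson at the specified rates (or
negative-binomial when ``dispersion > 1``, emulating the overdispersed units
the Fano screen must reject); AB counts follow the generating regime:

- ``mixture`` — each AB trial flips an alpha-coin between the A and B rates;
- ``intermediate`` — Poisson at ``alpha*lam_a + (1-alpha)*lam_b``;
- ``single_A`` / ``single_B`` — Poisson at that single rate;
- ``outside_high`` — Poisson at ``lam_a + lam_b`` (summation);
- ``outside_low`` — Poisson at ``0.25 * min(lam_a, lam_b)`` (suppression);
- ``mid_trial_switch`` — each trial sums a half-window draw at each rate,
  emulating a neuron that switches stimulus mid-presentation.

Default rates (20 vs 5 counts per 200 ms window, i.e. 100 vs 25 spikes/s)
and trial counts (15 per condition, within the 5-40 range typical of the
motivating datasets) give well-separated, screen-passing triplets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import Trial, Triplet

__all__ = [
    "REGIMES",
    "RegimeSpec",
    "GroundTruthDataset",
    "simulate_triplet",
    "simulate_population",
    "make_overdispersed_unit",
    "dataset_to_trials",
]

REGIMES = ("mixture", "intermediate", "single_A", "single_B",
           "outside_high", "outside_low", "mid_trial_switch")

#: Map from generating regime to the classification label it should recover.
REGIME_TO_CATEGORY = {
    "mixture": "mixture",
    "intermediate": "intermediate",
    "single_A": "single",
    "single_B": "single",
    "outside_high": "outside",
    "outside_low": "outside",
    "mid_trial_switch": "intermediate",  # known boundary behaviour
}


@dataclass(frozen=True)
class RegimeSpec:
    """Generative description of one synthetic triplet."""

    regime: str
    lambda_a: float = 20.0
    lambda_b: float = 5.0
    alpha: float = 0.5
    n_a: int = 15
    n_b: int = 15
    n_ab: int = 15
    dispersion: float = 1.0  # variance-to-mean of the single-stimulus counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.lambda_a <= 0 or self.lambda_b <= 0:
            raise ValueError("rates must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if min(self.n_a, self.n_b, self.n_ab) < 1:
            raise ValueError("trial counts must be >= 1")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1 (1 = Poisson)")


def _draw_counts(rng: np.random.Generator, lam: float, n: int,
                 dispersion: float) -> np.ndarray:
    """Counts with mean lam; Poisson at dispersion 1, else negative binomial
    moment-matched to mean lam and variance dispersion*lam."""
    if dispersion == 1.0:
        return rng.poisson(lam, size=n)
    r = lam / (dispersion - 1.0)
    p = 1.0 / dispersion
    return rng.negative_binomial(r, p, size=n)


def make_overdispersed_unit(lam: float, target_fano: float, n: int,
                            seed: int) -> np.ndarray:
    """Counts with mean ~lam and variance-to-mean ~target_fano."""
    if target_fano < 1.0:
        raise ValueError("target_fano must be >= 1")
    rng = np.random.default_rng(seed)
    return _draw_counts(rng, lam, n, target_fano)


def simulate_triplet(spec: RegimeSpec) -> Triplet:
    """Draw one triplet under the spec's regime; reproducible given its seed."""
    rng = np.random.default_rng(spec.seed)
    a = _draw_counts(rng, spec.lambda_a, spec.n_a, spec.dispersion)
    b = _draw_counts(rng, spec.lambda_b, spec.n_b, spec.dispersion)

    if spec.regime == "mixture":
        pick_a = rng.random(spec.n_ab) < spec.alpha
        rates = np.where(pick_a, spec.lambda_a, spec.lambda_b)
        ab = rng.poisson(rates)
    elif spec.regime == "intermediate":
        ab = rng.poisson(spec.alpha * spec.lambda_a + (1 - spec.alpha) * spec.lambda_b,
                         size=spec.n_ab)
    elif spec.regime == "single_A":
        ab = rng.poisson(spec.lambda_a, size=spec.n_ab)
    elif spec.regime == "single_B":
        ab = rng.poisson(spec.lambda_b, size=spec.n_ab)
    elif spec.regime == "outside_high":
        ab = rng.poisson(spec.lambda_a + spec.lambda_b, size=spec.n_ab)
    elif spec.regime == "outside_low":
        ab = rng.poisson(0.25 * min(spec.lambda_a, spec.lambda_b), size=spec.n_ab)
    elif spec.regime == "mid_trial_switch":
        ab = (rng.poisson(spec.lambda_a / 2.0, size=spec.n_ab)
              + rng.poisson(spec.lambda_b / 2.0, size=spec.n_ab))
    else:  # pragma: no cover - guarded in RegimeSpec
        raise ValueError(spec.regime)

    unit_id = f"sim-{spec.regime}-{spec.seed:010d}"
    return Triplet(unit_id, "A|B", a, b, ab)


@dataclass(frozen=True)
class GroundTruthDataset:
    """Simulated triplets paired with their generating specs."""

    pairs: tuple[tuple[Triplet, RegimeSpec], ...]

    @property
    def triplets(self) -> list[Triplet]:
        return [t for t, _ in self.pairs]

    @property
    def specs(self) -> list[RegimeSpec]:
        return [s for _, s in self.pairs]

    @property
    def composition(self) -> Counter:
        return Counter(s.regime for s in self.specs)

    def __len__(self) -> int:
        return len(self.pairs)


def child_seed(master_seed: int, index: int) -> int:
    """Stable per-spec seed: adding specs never perturbs earlier triplets."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
               % (2**31))


def simulate_population(specs: Sequence[RegimeSpec],
                        master_seed: int | None = None) -> GroundTruthDataset:
    """Simulate one triplet per spec.

    When ``master_seed`` is given, each spec's seed is replaced with a child
    seed derived from (master_seed, position), so whole populations are
    reproducible from one integer.
    """
    if not specs:
        raise ValueError("specs must be nonempty")
    pairs = []
    for i, spec in enumerate(specs):
        if master_seed is not None:
            spec = replace(spec, seed=child_seed(master_seed, i))
        triplet = simulate_triplet(spec)
        # each population member gets a unique unit id
        triplet = Triplet(f"u{i:05d}-{spec.regime}", triplet.stimulus_pair_id,
                          triplet.a_counts, triplet.b_counts, triplet.ab_counts)
        pairs.append((triplet, spec))
    return GroundTruthDataset(tuple(pairs))


def dataset_to_trials(dataset: GroundTruthDataset) -> list[Trial]:
    """Expand a simulated dataset to trial rows in the tabular dialect
    ``spikemux.io`` reads, so synthetic data can exercise the full pipeline."""
    trials = []
    for triplet, _spec in dataset.pairs:
        counter = 0
        for cond, counts in (("A", triplet.a_counts), ("B", triplet.b_counts),
                             ("AB", triplet.ab_counts)):
            for c in counts:
                trials.append(Trial(
                    trial_id=f"{triplet.unit_id}-t{counter:04d}",
                    unit_id=triplet.unit_id,
                    condition=cond,
                    stimulus_a_id="sA" if cond in ("A", "AB") else None,
                    stimulus_b_id="sB" if cond in ("B", "AB") else None,
                    spike_count=int(c),
                ))
                counter += 1
    return trials
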