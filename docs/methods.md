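# Methods

`spikemux` asks a simple question of paired-stimulus spike data: when a
neuron that responds differently to stimulus A and stimulus B sees both at
once, does its trial-to-trial response look like it is *fluctuating* between
the two single-stimulus responses, or like a single stable compromise?  The
unit of analysis is the **triplet**: the spike-count samples from A-alone,
B-alone and AB trials for one unit and one stimulus pair, counted in a fixed
window after stimulus onset.

## Spike counting and trial filters

Counts are taken in a half-open window `[latency_offset, latency_offset +
duration)`; the presets shift a 200 ms window by the area's typical response
latency (30 ms for MT, 50 ms for IT, with a 400 ms IT variant for longer
presentations).  Multiplying counts by `1/duration` converts to spikes/s
(x5 for 200 ms).  Only correct trials enter the analysis.  When an eye-speed
trace accompanies a trial, the trial is dropped if any stimulus-epoch sample
exceeds the fixation-epoch mean by strictly more than 6 standard deviations
(unbiased estimator); a constant trace has zero spread and flags nothing, so
degenerate traces never discard trials.  No smoothing is applied to the
trace before thresholding — the detector operates on whatever trace is
supplied.  Trials without eye data pass through unscreened.

## Triplet screening

Three criteria gate a triplet into model comparison, and every failure is
recorded, not just the first:

1. **Trial minimum** (default 5 per condition, applied after all trial-level
   filters).  Five Poisson counts still carry useful rate information under
   the conjugate treatment below; fewer do not.
2. **Poisson-ness.**  The mean of the A and B variance-to-mean ratios (Fano
   factors, unbiased variance estimator) must not exceed 3 (strict
   sensitivity variant: 2).  Exactly 3 is retained; all-zero count vectors
   have an undefined ratio, reported as `+inf`, and fail.  The unbiased
   (n-1) variance matters at n = 5: the biased estimator would
   systematically flatter small triplets.
3. **Separability.**  The A and B distributions must be distinguishable,
   or "which single-stimulus distribution does AB resemble?" is
   unanswerable.  The criterion is a natural-log intrinsic Bayes factor
   above 3 for "two distinct Poisson means" over "one shared mean", which
   under 1:1 prior odds is a posterior probability above
   e^3/(1+e^3) = 0.9526 — i.e. at least 95% — that the means differ.

The intrinsic Bayes factor is the arithmetic variant of Berger & Pericchi's
construction.  Improper Jeffreys-type Gamma(1/2, b0 → 0) priors on each
Poisson mean leave the Bayes factor defined only up to a constant; the
intrinsic construction cancels that constant by conditioning on *minimal
training samples* — here one trial from each condition, the smallest
sample that makes both priors proper under both hypotheses — and averaging
the inverse partial Bayes factors over all n_A x n_B such samples.  With
conjugate Gamma-Poisson marginals everything is closed-form:

    log B10 = [logM(S_A, n_A) + logM(S_B, n_B) - logM(S_A+S_B, n_A+n_B)]
              + log mean_{i,j} exp{ logM(a_i + b_j, 2) - logM(a_i, 1) - logM(b_j, 1) }
    logM(S, n) = log Gamma(1/2 + S) - (1/2 + S) log n

where the factorial, Gamma(1/2) and b0 factors cancel across the two
bracketed terms and are dropped analytically.  Unequal sample sizes need no
special treatment.  The statistic is symmetric in A and B, and the tests
validate it against an independent adaptive-quadrature oracle with proper
priors at b0 = 1e-8.

## The four-hypothesis model

Let lam_A, lam_B be the single-stimulus Poisson means.  Rather than plugging
in point estimates — overconfident at five trials — both rates carry their
conjugate Gamma posteriors, Gamma(1/2 + sum(counts), n), and every
hypothesis marginal integrates over them.  The AB counts are then modelled
four ways:

- **mixture**: each AB trial independently draws its rate from {lam_A,
  lam_B} with weight alpha ~ Uniform(0,1) — trial-by-trial fluctuation;
- **intermediate**: all AB trials from one Poisson at
  alpha·lam_A + (1-alpha)·lam_B, alpha ~ Uniform(0,1) — averaging, or
  switching faster than the window;
- **single**: all AB trials from Poisson(lam_A) or Poisson(lam_B); the two
  branches are averaged with equal weight (a proper treatment of the
  sub-hypothesis rather than a max, which would overfit), and the dominant
  branch is reported;
- **outside**: all AB trials from Poisson(lam*), with lam* drawn 50/50 from
  Uniform(0, min(lam_A, lam_B)) or Uniform(max(lam_A, lam_B), cap),
  cap = 2·(lam_A + lam_B).

Posterior probabilities are the softmax of log prior + log marginal with
equal 25% priors; priors enter only at this step, never inside marginals.
A triplet is **fluctuating** when mixture wins with posterior above 0.67 —
the "at least twice as likely as the other three combined" boundary, since
p/(1-p) > 2 at p = 2/3.  Population tallies count winners at posterior
**0.67 or greater** (inclusive), matching the population-figure convention,
whereas the fluctuating flag is strict (> 0.67); both rules are implemented
exactly where each is stated, and the boundary case p = 0.67 exactly is the
only point where they differ.

### Numerical scheme

All accumulation is in the log domain.  Integrals use fixed-order Gauss
quadrature, so the default path is seedless and deterministic:

- **Rate posteriors**: Gauss-Legendre nodes (default 31) across the central
  (1e-10, 1-1e-10) quantile interval of each Gamma posterior, weighted by
  the posterior log-density and renormalised to sum to one.  (Generalized
  Gauss-Laguerre rules are the textbook choice but their weights overflow
  float64 beyond shape ~170, and posterior shapes here are routinely ~300.)
- **alpha**: Gauss-Legendre on (0,1), default 63 nodes, strictly interior —
  the intermediate hypothesis approaches but never touches the endpoints,
  which belong to the single hypothesis.
- **outside**: for each (lam_A, lam_B) node pair the two uniform segments
  are integrated on Gauss-Legendre nodes clipped to where the
  Gamma(S_AB + 1, n_AB) likelihood kernel has mass, so a narrow likelihood
  inside a wide segment is never undersampled.
- **single**: the Gamma-Poisson (negative-binomial) predictive in closed
  form — the exact value of the same integral.

Default orders agree with an 81/101/201-node reference to < 1e-4 nats and
with an independent Monte-Carlo oracle to < 0.05 nats (see below).  Exact
posterior ties are broken deterministically in the order mixture >
intermediate > single > outside; ties are measure-zero and the order is
documented purely for reproducibility.  A Monte-Carlo integration path
(`ModelConfig(method="mc")`, seeded) exists as a cross-check.

### Outside-prior cap sensitivity

The cap on the upper outside segment is a proper-prior device; the data do
not identify it.  Widening it dilutes the outside prior and costs outside
recovery while slightly flattering single (measured on 150 synthetic
triplets per regime, rates 20 vs 5, 15 trials): cap multiplier 1.5 / 2 / 3 /
4 gives outside_high recovery 89 / 83 / 75 / 71% and single_A recovery 85 /
85 / 87 / 87%; mixture and intermediate classification are unaffected.  The
default multiplier 2 is a compromise; it is a config field, not a constant.

## Synthetic ground truth

The generator (`spikemux.simulate`) draws single-stimulus counts as Poisson
(or negative-binomial moment-matched to a target variance-to-mean ratio,
emulating the overdispersed units the Fano screen must reject) and AB counts
under each regime, including two deliberately pathological cases: summation
(`outside_high`, rate lam_A + lam_B) and strong suppression (`outside_low`,
rate 0.25·min — both anchors configurable), and a mid-trial switcher whose
counts sum a half-window draw at each rate (exactly Poisson at the midpoint
rate, hence indistinguishable from averaging at the whole-trial level).
Default conditions: rates 20 and 5 counts per 200 ms window (100 and 25
spikes/s), 15 trials per condition, alpha = 0.5.  Population presets with 6,
18 and 37 trials per condition echo the spread of trial counts across the
motivating datasets.  Seeds derive per-triplet from a master seed and the
triplet's position, so extending a population never perturbs existing
triplets.

What the generator does *not* emulate: within-trial spike timing (beyond the
two-half-window construction), rate drift across a session, serial
correlation between trials, unit-to-unit rate heterogeneity within a
population preset, and eye-movement artefacts.  Passing the validation
studies therefore demonstrates that the inference machinery recovers known
whole-trial count-generating processes — not that real cortical data satisfy
the Poisson assumptions; that is what the Fano and separability screens are
for.

## Validation studies and what they show

`spikemux.validation` runs six self-contained studies (reported by
`scripts/acceptance.py`, asserted in `tests/test_acceptance.py`):

1. **Threshold identities** — the 25% equal-prior baseline, the 2/3
   twice-as-likely boundary, and the 95% separability posterior at log-IBF
   3 are reproduced by the posterior machinery itself.
2. **Oracle equivalence** — quadrature marginals agree with an independent
   Monte-Carlo oracle within 0.05 nats on random small triplets.  The
   oracle runs in 10 independent batches so its own standard error is
   known; a few deeply-losing hypotheses have irreducibly noisy Monte-Carlo
   estimates (heavy-tailed importance weights), and the bound is asserted
   wherever the oracle's 3-SE resolution is finer than it (96 of 96
   comparisons at the default conditions).
3. **Regime recovery** — at rates 20 vs 5 and 15 trials per condition (500
   triplets per category; single and outside pool their two generator
   variants 50/50) the modal classification recovers mixture and
   intermediate essentially always and single/outside at ~87-92%; mixture
   triplets are never classified outside.  The residual single/outside
   confusion is real posterior overlap at these sample sizes, not numerics:
   when the AB sample mean drifts a couple of counts from its generating
   rate, a neighbouring hypothesis can honestly win.
4. **Boundary caveats** — mid-trial switching is classified intermediate
   (by construction of the generator, necessarily so).  The second
   documented caveat — a unit responding to A on 90% of trials being
   labelled single — holds at *moderate* rate separations (at 12 vs 6,
   single is the modal label), but **not** at the default 20-vs-5
   separation, where even one low-count AB trial is decisive evidence for
   the mixture hypothesis (log-pmf gap ~6 nats/trial) and ~80% of 90/10
   triplets classify as mixture.  The corresponding acceptance test asserts
   the caveat at the standard conditions and fails; it is left failing
   deliberately, as the exact computation contradicts the qualitative
   expectation at that separation.
5. **Screening behaviour** — units generated at variance-to-mean 5 are
   rejected at >99% with 40 trials per condition (40 chosen to match the
   upper range of the motivating datasets); the strict Fano-2 screen
   includes a strict subset of the default screen's triplets.
6. **Mixing-weight recovery** — with 40 AB trials, the posterior-mean alpha
   has mean absolute error ~0.05 over alpha in {0.25, 0.5, 0.75}, within
   the binomial floor sqrt(alpha(1-alpha)/40) ~ 0.07.

Study sizes (500 triplets per regime, 24 oracle triplets, 300 alpha-recovery
triplets) keep a full validation run around two minutes on one core while
holding the binomial standard error on reported percentages near 1.5 points.

## Known limitations

- The analysis is blind to *within-trial* structure: a fast switcher looks
  intermediate.  A dynamic (sub-trial) extension is out of scope here.
- The outside hypothesis depends on an arbitrary proper-prior cap (above).
- Screening thresholds (Fano <= 3, log-IBF > 3, 5 trials) are inherited
  conventions, exposed in config rather than justified from first
  principles.
- With strongly separated rates the mixture hypothesis is extremely
  sensitive — a single outlier AB trial can flip a single-regime triplet to
  mixture; conversely at weak separation mixtures masquerade as single.
  Prevalence comparisons across datasets with different separations and
  trial counts inherit this asymmetry, which is why the population
  summaries carry their denominators and screening attrition alongside the
  percentages.
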