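# Methods

This note defines the models, scores, and synthetic benchmark implemented
by `vaemil`, and records the numerical and experimental choices the
package makes.

## Problem setting

A *bag* is a set of instance feature vectors `X = {x_1, ..., x_N}`,
`x_i ∈ R^P`, with a single binary label `y` under the standard
multiple-instance assumption: the bag is positive iff at least one
instance is positive (`y = max_i y_i`). Instance labels are never used
for training. The motivating application is whole-slide-image analysis,
where a slide is a bag of patch feature vectors produced by a frozen
extractor; the same structure arises in any set-valued weak-labelling
problem.

Beyond classification, the package addresses *out-of-distribution (OOD)
detection*: at test time, bags may come from a different distribution
(different tissue, acquisition artifacts), and the model should flag
them rather than silently classify them.

## Attention-based MIL (the shared head)

Instances are embedded to latent codes `z_i ∈ R^D` (see below), and the
bag representation is a gated-free attention pool:

    f_i = w^T tanh(W z_i)          attention score, W ∈ R^{L×D}, w ∈ R^L
    a_i = softmax(f)_i             attention weights (sum to 1)
    B   = Σ_i a_i z_i              bag representation

followed by a linear classifier `p(y=1|X) = σ(c^T B + b)`. The pool is
permutation-invariant by construction; softmax is computed with the
max-shift trick.

## VAEABMIL (probabilistic embedding)

Each instance gets a Gaussian variational posterior
`q(z|x) = N(m_φ(x), s_φ(x)² I)` with a **single scale shared across the
latent dimensions**, a standard-normal prior, and a Gaussian decoder
`p(x|z) = N(m_θ(z), σ_θ(z)² I)` (one variance per instance). Encoder
and decoder are three-layer ReLU networks (default sizes
`[512, 256, 128]`; the last entry is the latent dimension `D`); the
scale/variance heads go through a softplus with a `1e-6` floor.

Training minimizes the negative evidence lower bound of the joint model
`p(X, y) = p(y|Z) Π_i p(x_i|z_i) p(z_i)`:

    L = E_q[-log p(y|Z)] + Σ_i E_q[-log p(x_i|z_i)] + Σ_i KL(q(z_i|x_i) || N(0, I))

with the KL in closed form and the expectations estimated with `S`
reparameterized samples (default `S = 1`); crucially, the bag logit is
computed from a *joint* sample `Z_s` of all instances. Prediction uses
the Monte-Carlo average `p(y|X) ≈ (1/S) Σ_s σ(logit(Z_s))`, or the
posterior means (`use_posterior_mean=True`) for a deterministic output.

## DAEABMIL (deterministic embedding)

The deterministic variant uses `z_i = m_φ(x_i)` and the loss

    L = μ · NLL(y) + α · Σ_i ||x_i − m_θ(z_i)||² + β · Σ_i ||z_i||²

with defaults `μ = 1, α = β = 0.3`. At `α = β = 0` this is *exactly*
classical attention-based MIL — the reduction is checked to `1e-7` in
the test suite.

## OOD scores

All scores are oriented so that **higher = more OOD**, and bag scores
aggregate per-instance scores by mean (default) or max.

- **logpx** (tailored, VAEABMIL): per-instance negative log marginal
  likelihood estimated by importance sampling with the variational
  posterior as proposal,
  `log p(x) ≈ logsumexp_s[log p(x|z_s) + log p(z_s) − log q(z_s|x)] − log S`.
  The `S` standard-normal draws are shared across the instances of a
  bag (common random numbers): each estimate remains a valid
  importance-sampling estimate and the bag score becomes exactly
  invariant to instance order.
- **recerr** (tailored, DAEABMIL): per-instance squared reconstruction
  error `||x − m_θ(m_φ(x))||²`.
- **entropy** (post hoc): Shannon entropy of the predicted bag
  probability.
- **mls** (post hoc): negative absolute bag logit (the binary
  single-logit analogue of a max-logit score).

Detection quality is the AUC of the score at separating OOD (label 1)
from in-distribution test bags (label 0); `auc` delegates to
`sklearn.metrics.roc_auc_score` and is verified against a brute-force
all-pairs Mann-Whitney count in the tests.

## Training procedure

One bag per Adam step (default learning rate `1e-4`), shuffled epochs,
no early stopping; 20% of the training bags are held out as a
stratified validation split and the epoch with the highest validation
AUC is kept (earliest on ties). `TrainConfig.n_restarts` repeats the
whole run from independent initializations on the same split and keeps
the restart with the best validation AUC: the joint loss has a local
optimum in which attention pooling destroys the class signal (roughly 1
in 8 runs on the synthetic benchmark), and restart selection by the
same validation criterion removes it without touching the loss. All
randomness flows from `numpy.random.SeedSequence` spawning, so fits are
bit-reproducible.

## Synthetic feature-bag generator

`vaemil.simulate` generates bags whose instances live near a low-rank
linear manifold: latent factors `h ∈ R^r` are standard normal (positive
instances shifted by `class_separation` along a fixed unit direction),
mixed as `x = A h + noise` with a seed-fixed map `A ∈ R^{P×r}`.
Positive bags contain `ceil(witness_rate · N)` positive instances.
OOD sets displace the latent factors before mixing:

| preset     | shift                                        | emulates            |
|------------|----------------------------------------------|---------------------|
| `near`     | whole bag, magnitude 2                       | similar domain      |
| `far`      | whole bag, magnitude 8                       | different domain    |
| `artifact` | 15% of instances, magnitude 8                | partial artifacts   |

A magnitude-0 shift reproduces the in-distribution process exactly and
serves as the null control.

**Scope note.** Because the shifts act in latent space, shifted
features remain in the column space of `A` — they are *on-manifold*
shifts. A deterministic autoencoder can partially reconstruct such
points, so `recerr`'s detection power on the `far` preset relies on
limited encoder extrapolation and is seed-dependent (observed far-OOD
AUC 1.0, 1.0, 0.968 across the three benchmark seeds, mean 0.989). The
probabilistic `logpx` score is unaffected (AUC 1.0 on all seeds): its
prior term penalizes the large latent norm regardless of reconstruction
quality. This asymmetry is itself the central argument for the
variational model. Off-manifold corruption modes are deliberately out
of scope for the generator.

## Benchmark recipe

The desk-scale benchmark (`vaemil.benchmark`) uses 200 training /
100 test / 100 OOD bags with `P = 64`, latent rank 8, witness rate 0.2,
class separation 4, and trains both models with a `(64, 32, 16)`
encoder (a scaled-down analogue of the default `[512, 256, 128]` sized
for 512/1024-dim extractor features), attention width 32, learning rate
`1e-3`, 30 epochs, 2 restarts. On this benchmark, averaged over three
seeds: both models exceed 0.95 test classification AUC, `logpx`
separates far-OOD perfectly, tailored scores beat the entropy baseline
on near-OOD, null controls sit at chance level, and attention scores
rank true-positive instances within positive bags with instance-level
AUC above 0.95. `scripts/acceptance.py` recomputes all of these from
scratch.

## Numerical choices

- Stable primitives throughout: max-shift softmax, `logaddexp`-based
  binary cross-entropy, `logsumexp` for importance sampling (scores
  stay finite even when all log-weights are below −10⁴).
- Softplus floors (`1e-6`) keep posterior scales and decoder variances
  positive; degenerate posteriors collapse cleanly to point masses.
- The autodiff engine (`vaemil.autodiff`) is a minimal NumPy
  reverse-mode implementation (broadcast-aware, topologically ordered
  backward pass) and is verified against central finite differences.
- All derived seeds stay below 2³¹.
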