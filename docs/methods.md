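# Methods

## The model

A system receives an input vector **x** drawn from P(**x**) and produces a
binary output y ∈ {0,1}. Its computation is summarized by the response
function P(y=1|**x**). When only a finite list of input/output moments
⟨y f_μ(**x**)⟩ is known — for a neuron, the mean firing rate, the
spike-triggered average, the spike-triggered covariance — infinitely many
response functions agree with those measurements. The maximum-noise-entropy
(MNE) model is the one that maximizes the average conditional entropy

    S_noise = − Σ_x P(x) Σ_y P(y|x) log₂ P(y|x)

subject to the moment constraints: it reproduces what was measured and is
maximally uncommitted about everything else. For binary outputs the solution
is a logistic function of a polynomial in the inputs, with one Lagrange
multiplier per constrained monomial:

    P(y=1|x) = 1 / (1 + exp(z)),
    z = a + Σᵢ hᵢ xᵢ + Σ_{i≤j} J_ij xᵢ xⱼ + …   (up to the constrained order)

Because the mean output is always among the constraints, the response
entropy H₂(⟨y⟩) is pinned, so maximizing the noise entropy simultaneously
*minimizes* the mutual information I = H₂(⟨y⟩) − S_noise. The model's
information is therefore exactly the information content of the constraint
set, and the ratio I_model / I_empirical is the fraction of the system's
information explained by those constraints. Augmenting the constraint order
until the ratio is high enough identifies which input statistics the system
encodes.

**Sign convention.** The exponent sign is arbitrary (negating all
coefficients gives the mirrored convention). This package fixes
P = 1/(1+exp(z)) — negative coefficients excite — records the convention in
every serialized model, and coefficients must not be compared with other
software without mapping.

**Encoding.** Binary inputs are encoded {0,1}, so first-order moments read
directly as spike-triggered averages and repeated-index monomials are
redundant (x² = x) and excluded. `recode_pm1` converts to ±1 when an
Ising-style parameterization is wanted.

## Fitting

Matching model moments to empirical moments is equivalent to maximizing the
average Bernoulli log-likelihood of the logistic model: the gradient of the
negative average log-likelihood with respect to the coefficients is exactly
(empirical − model) moments. `fit_mne` minimizes that convex objective with
L-BFGS-B from the all-zero vector (the constant-1/2 model), so the default
path is deterministic with no seed sensitivity. Convergence is declared when
the max-norm moment mismatch is below `tolerance` (default 1e-6);
non-convergence is flagged, never silent.

Deterministic systems (exact logic gates) push coefficients to ±∞. Two
guards keep fits finite: a box bound `coefficient_cap` (default 50) and an
L2 penalty `l2_penalty` (default 1e-8, the constant term unpenalized). The
penalty biases the matched moments by 2λ|c|, so exact-gate analyses use
λ=1e-10 with cap 500: order-3 deterministic gates need coefficients up to
~120 (the Möbius inversion of the target exponents), and a cap of 50 would
leave the information ratio visibly short of its limit, while λ=1e-10 keeps
the moment bias near 1e-8, far below tolerance.

`maxent_oracle` is the independent check: it maximizes Σ P(x) H₂(q_x)
directly over the per-state conditional table with SLSQP under the linear
moment constraints — no logistic parameterization — and raises an
infeasibility error naming the worst-violated constraint when the residual
exceeds 1e-8. Tests verify state-by-state agreement (≤1e-6) between the
fitted logistic table and the oracle on enumerable ensembles (guard: 4096
distinct states).

## Information accounting

All user-facing entropies are in bits. H₂ is defined to be exactly 0 at
p ∈ {0,1}; model probabilities are clamped to [1e-12, 1−1e-12] inside
logarithms, so deterministic tables have exactly zero noise entropy. The
empirical reference information is the plug-in (maximum-likelihood) mutual
information between a discretized input state and the response, with no
bias correction: on exact gate ensembles the plug-in value is exact, which
is where the quantitative acceptance checks live. Ratios are clipped to 1
(with a warning) when numerical noise or reference discretization pushes
them above; a positive model information against a zero reference raises,
since it signals inconsistent inputs.

On exact ensembles the minimum-information chain 0 ≤ I(order 1) ≤
I(order 2) ≤ … ≤ I_emp ≤ H₂(rate) holds to numerical tolerance, and for N
binary inputs the order-N model always reaches I_emp (all higher moments of
0/1 variables are redundant) — verified exhaustively over all 256
three-input truth tables.

## Neural pipeline

Spike trains are binned at dt = 4 ms (half-open bins, multi-spike bins
clipped to 1 and tallied), which keeps the response binary at these firing
rates. The input for response bin t is the 50-bin (200 ms) stimulus window
ending at and including bin t, stored oldest-first; the paper-style
"preceding window" is ambiguous about inclusivity, so the inclusive
convention is fixed here and pinned by a delta-stimulus alignment test. Two
temporal filters (externally obtained, e.g. by maximally informative
dimensions — an input to this package, not part of it) project each window
onto reduced inputs s₁, s₂, each divided by its maximum absolute value over
the dataset so the range is [−1,1]; the divisors are returned so held-out
data can be mapped into the same coordinates (out-of-range values are
clipped for binning and tallied).

MNE models are fitted on the *continuous* reduced inputs; the 14×14 grid
over [−1,1]² is used only for the empirical reference information and for
visualization. Unsampled bins are NaN, distinct from sampled bins with zero
spike probability. Because binning discards some information, a
well-matched continuous model can slightly exceed the binned reference
(ratio clipped at 1); on gate ensembles, where the reference is exact, no
clipping occurs. No spike-history terms are modeled: bins are conditionally
independent Bernoulli given the reduced inputs.

Two diagnostics probe sufficiency of a fitted order: predicted vs observed
*unconstrained* moments (default: all third-order monomials of s₁,s₂ —
the constrained ones match by construction), and the nested comparison of
second-order fits with and without the mixed s₁s₂ constraint, whose
information gain is nonnegative by nesting and measures how far the
response function's symmetry axes are from the filter basis.

## Synthetic data

The generator plays the role of the experiment so every stage runs without
recordings. Its defaults are fixed study conditions, not tuning knobs:

- **Stimulus**: exponentiated mean-reverting AR(1) Gaussian process,
  standardized to zero mean, unit variance; correlation time 10 bins
  (40 ms), log-sigma 0.5. This gives positive skew (~1.8) and excess
  kurtosis (~6) — temporally correlated and non-Gaussian like naturalistic
  luminance flicker. It is a generic stand-in, not a fit to any photometric
  dataset: the exponentiated-AR(1) autocorrelation at one correlation time
  is (e^{σ²/e}−1)/(e^{σ²}−1) ≈ 0.34, slightly below the backbone's 1/e.
- **Filters**: two biphasic difference-of-Gaussians time courses with
  seeded latency jitter, Gram-Schmidt orthonormalized — the canonical shape
  of early-visual temporal receptive fields.
- **Planted model**: second order over the normalized (s₁,s₂),
  coefficients (a, h₁, h₂, J₁₁, J₁₂, J₂₂) = (1.5, −0.5, 0.3, −6, 0, −4):
  predominantly quadratic (suppressive curvature both dimensions), zero
  mixed term so the cross-term diagnostic has a known null, mean rate ≈0.21
  per 4 ms bin and ≈0.015 bits/bin — weak per-bin information, as is
  realistic at this bin size. Spiking is Bernoulli per bin from the planted
  model evaluated on pipeline-normalized coordinates, so planted and
  recovered coefficients are directly comparable. A warning fires if the
  planted rate leaves (0.005, 0.5), where recovery degrades.

What the synthetic data does *not* emulate: refractoriness and spike-history
dependence, adaptation/nonstationarity, the actual naturalistic luminance
statistics, and filter estimation error (filters are known exactly). Passing
recovery tests therefore demonstrate correctness of the estimator under the
model's own assumptions, not robustness to their violation on real
recordings.

**Problem sizes.** Recovery and diagnostic tests use T = 2×10⁵ bins
(≈13 min of recording at 4 ms), with a T = 2×10⁴ contrast to show error
shrinking with duration; the stimulus-statistics checks use 10⁶ bins. At
T = 2×10⁵, seed 7, the order-2 fit recovers the planted coefficient vector
to 3.5% relative error (norm), the matched-order information ratio exceeds
95%, and the order-1 model captures ~21%.

## Numerical choices and limitations

- Probabilities clamped at 1e-12 inside logs; H₂ exactly 0 at {0,1}.
- Moments matched on their natural scale (no standardization): gate
  ensembles are exact and reduced neural inputs are already in [−1,1].
- Oracle infeasibility threshold 1e-8 on constraint residuals.
- Ties/degenerate inputs: a dataset with mean output 0 or 1 returns the
  clamped constant model with a warning rather than diverging.
- Only binary outputs are supported; the general multinomial
  partition-function form and the iterative general-MinMI solution are out
  of scope, as are debiased MI estimators and the search for the filters
  themselves.
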