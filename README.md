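# mnemodels

Maximum-noise-entropy (MNE) response-function models for binary-output
systems — neurons encoding sensory stimuli, on/off gene regulation, logic
gates — built from limited knowledge of input/output moments.

Given constraints ⟨y f_μ(**x**)⟩ (for a neuron: the mean firing rate, the
spike-triggered average, the spike-triggered covariance), the MNE model is
the conditional distribution P(y=1|**x**) that reproduces those moments
while maximizing the noise entropy Σ_x P(x) H₂(P(1|x)) — the least biased
response function consistent with the measurements. For a binary output it
is a logistic function of a polynomial in the inputs,

    P(y=1|x) = 1 / (1 + exp(a + Σᵢ hᵢxᵢ + Σ_{i≤j} J_ij xᵢxⱼ + …)),

with one Lagrange multiplier per constrained monomial, fitted by moment
matching (equivalently, maximum likelihood). Because the mean rate pins the
response entropy H₂(⟨y⟩), the MNE model is simultaneously the
minimum-mutual-information model: its information
I_model = H₂(⟨y⟩) − S_noise is exactly the information content of the
constraints, and the ratio I_model / I_empirical says what fraction of the
system's computation the constraints explain. Raising the interaction order
until that ratio saturates identifies which input statistics the output
encodes.

The package provides:

- feature maps and logistic MNE models of arbitrary order, with JSON
  serialization (`mnemodels.core`);
- deterministic moment-matching fits plus an independent brute-force
  constrained entropy maximizer used as a test oracle (`mnemodels.fitting`);
- entropies, plug-in mutual information, information ratios and the
  incremental order-selection scan (`mnemodels.information`);
- exact Boolean gate ensembles, exhaustively enumerable (`mnemodels.gates`);
- a spike-train pipeline — 4 ms binning, 50-bin stimulus histories,
  projection onto two receptive-field filters normalized to [−1,1], 14×14
  binned response functions, order-1/2 fits, unconstrained-moment and
  cross-term diagnostics (`mnemodels.neural`);
- a synthetic-data generator with naturalistic-like stimuli and planted
  models for end-to-end parameter-recovery checks (`mnemodels.synthetic`);
- a `mnemodels` CLI with `gates`, `fit`, `simulate` and `scan` subcommands.

## Worked example: what does a logic gate encode?

```bash
$ mnemodels gates --name XOR
...
order 1: 0.0% of 1.000000 bits
order 2: 100.0% of 1.000000 bits
```

XOR on two uniform binary inputs transmits exactly 1 bit. The first-order
model — constrained by the mean output and the two single-input moments —
captures 0.0% of it: XOR has no first-order structure, and the fitted model
is the uniform coin flip. Adding the single pairwise constraint ⟨y x₁x₂⟩
jumps to 100.0%: XOR is a purely second-order computation. Running the same
command with `--name AND` gives 100% already at first order — AND is fully
described by its spike-triggered average.

The same loop on a simulated neuron (stimulus → spikes from a planted
second-order model, T = 2×10⁵ bins of 4 ms):

```python
from mnemodels import SyntheticSpec, simulate_neuron, fit_reduced_models

spec = SyntheticSpec(seed=7, duration_bins=200_000)
data, truth = simulate_neuron(spec)
reports, fits = fit_reduced_models(truth["s1"], truth["s2"], data.responses)
```

prints, via the reports:

```
mean rate: 0.214
order 1:  21.2%  I_model=0.00302  I_emp=0.01427 bits
order 2: 100.0%  I_model=0.01485  I_emp=0.01427 bits
planted : (1.5, -0.5, 0.3, -6.0, 0.0, -4.0)
fitted  : (1.499, -0.554, 0.306, -6.082, -0.196, -3.868)
```

The first-order (spike-triggered-average) model explains ~21% of the
information; the second-order model recovers the planted coefficients to
3.5% (vector norm) and saturates the empirical reference — the slight
overshoot relative to the 14×14-binned reference is the information lost to
binning, and the ratio is clipped at 100%. See `docs/methods.md` for the
model, conventions and numerical details.

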