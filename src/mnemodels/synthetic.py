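"""Synthetic stimuli, filters and spiking from planted MNE models.

Every pipeline stage can be exercised without recordings: a temporally
correlated, non-Gaussian luminance trace stands in for a naturalistic
flicker stimulus, two orthonormal biphasic temporal filters stand in for
the receptive-field dimensions, and spikes are drawn from a planted
first- or second-order logistic model applied to the normalized reduced
inputs — so the planted coefficients are directly comparable to the
recovered ones.

The stimulus is an exponentiated mean-reverting (AR(1)) Gaussian
process, standardized to zero mean and unit variance: positively skewed
and heavy-tailed like natural light-intensity fluctuations, with an
exponential autocorrelation set by ``corr_time_bins``.  It is a
generic non-Gaussian correlated process, not a fit to any particular
photometric dataset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MNEModel, ResponseDataset, build_feature_map
from .neural import (
    DEFAULT_DT,
    DEFAULT_WINDOW_BINS,
    FilterPair,
    StimulusTrace,
    build_lagged_inputs,
    project_and_normalize,
    trim_responses,
)

# Planted second-order model used as the default ground truth.  Strong
# diagonal quadratic terms (suppressive in s1, weaker in s2) on top of a
# low baseline rate; no mixed term by default, so the cross-term
# diagnostic has a known null.  Coefficients follow the package sign
# convention P(1|s) = 1/(1+exp(z)).
DEFAULT_PLANTED_COEFFS = (1.5, -0.5, 0.3, -6.0, 0.0, -4.0)


def default_planted_model(coefficients=DEFAULT_PLANTED_COEFFS) -> MNEModel:
    """Second-order planted model over (s1, s2); coefficients (a, h1, h2, J11, J12, J22)."""
    fm = build_feature_map(2, 2, binary_inputs=False, include_cross_terms=True)
    return MNEModel(feature_map=fm, coefficients=tuple(coefficients))


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one synthetic experiment; the seed is mandatory."""

    seed: int
    duration_bins: int = 200_000
    dt: float = DEFAULT_DT
    corr_time_bins: float = 10.0
    log_sigma: float = 0.5
    window_bins: int = DEFAULT_WINDOW_BINS
    planted_model: MNEModel = field(default_factory=default_planted_model)

    def __post_init__(self) -> None:
        if self.duration_bins < 1:
            raise ValueError("duration_bins must be positive")
        if self.planted_model.feature_map.n_inputs != 2:
            raise ValueError("planted model must act on 2 reduced dimensions")
        if self.planted_model.feature_map.order not in (1, 2):
            raise ValueError("planted model order must be 1 or 2")


def generate_stimulus(spec: SyntheticSpec) -> StimulusTrace:
    """Exponentiated AR(1) luminance trace, standardized; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.duration_bins
    rho = float(np.exp(-1.0 / spec.corr_time_bins))
    g = np.empty(n)
    g[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho * rho) if n > 1 else None
    for t in range(1, n):
        g[t] = rho * g[t - 1] + innov[t - 1]
    s = np.exp(spec.log_sigma * g)
    s = (s - s.mean()) / s.std()
    return StimulusTrace(values=s, dt=spec.dt)


def generate_filters(window_bins: int = DEFAULT_WINDOW_BINS, seed: int = 0) -> FilterPair:
    """Two orthonormal biphasic temporal filters over the stimulus window.

    Each is a difference of Gaussians in time (an excitatory lobe
    followed by a delayed suppressive lobe), the second lagged relative
    to the first; the seed jitters the lobe latencies slightly so
    distinct synthetic cells get distinct receptive fields.  The pair is
    orthonormalized by Gram-Schmidt.
    """
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(window_bins, dtype=float)
    w = float(window_bins)

    def biphasic(center: float, lag: float, width: float) -> np.ndarray:
        a = np.exp(-0.5 * ((t - center) / width) ** 2)
        b = np.exp(-0.5 * ((t - center - lag) / (1.4 * width)) ** 2)
        return a - 0.65 * b

    jit = rng.uniform(-0.02, 0.02, size=2) * w
    f1 = biphasic(0.70 * w + jit[0], 0.12 * w, 0.06 * w)
    f2 = biphasic(0.55 * w + jit[1], 0.15 * w, 0.08 * w)
    f1 = f1 / np.linalg.norm(f1)
    f2 = f2 - (f2 @ f1) * f1
    f2 = f2 / np.linalg.norm(f2)
    return FilterPair(v1=f1, v2=f2)


def simulate_neuron(
    spec: SyntheticSpec, filters: FilterPair | None = None
) -> tuple[ResponseDataset, dict]:
    """Bernoulli spiking from the planted model on pipeline-built inputs.

    The reduced inputs are built exactly as the analysis pipeline builds
    them (lag -> project -> per-dimension max-abs normalization), the
    planted model is evaluated on the *normalized* coordinates, and each
    bin spikes independently with that probability.  Returns the dataset
    (inputs are the normalized s1, s2 columns) and a ground-truth dict
    with the planted model, the reduced inputs, the per-bin spike
    probabilities and the filters.
    """
    if filters is None:
        filters = generate_filters(spec.window_bins, seed=spec.seed)
    stim = generate_stimulus(spec)
    lagged = build_lagged_inputs(stim, spec.window_bins)
    s1, s2, scales = project_and_normalize(lagged, filters)
    X = np.column_stack([s1, s2])
    p = spec.planted_model.predict(X)
    rate = float(np.mean(p))
    if not 0.005 < rate < 0.5:
        warnings.warn(
            f"planted mean rate {rate:.4f} outside (0.005, 0.5); "
            "sparse or saturated regimes degrade parameter recovery",
            RuntimeWarning,
        )
    rng = np.random.default_rng(spec.seed + 1)  # distinct stream from the stimulus
    y = rng.binomial(1, p).astype(float)
    data = ResponseDataset.from_arrays(X, y)
    truth = {
        "model": spec.planted_model,
        "stimulus": stim,
        "filters": filters,
        "s1": s1,
        "s2": s2,
        "scales": scales,
        "spike_probabilities": p,
        "mean_rate": rate,
    }
    return data, truth


def write_simulation(spec: SyntheticSpec, prefix: str) -> dict:
    """Write stimulus, binary responses, filters and truth JSON to text files.

    Produces ``<prefix>_stimulus.csv`` (one value per line),
    ``<prefix>_responses.csv`` (0/1 per retained bin),
    ``<prefix>_filters.tsv`` (two columns) and ``<prefix>_truth.json``
    (planted coefficients and simulation conditions) — directly
    consumable by the ``fit`` CLI subcommand.
    """
    from .neural import save_filters

    data, truth = simulate_neuron(spec)
    paths = {
        "stimulus": f"{prefix}_stimulus.csv",
        "responses": f"{prefix}_responses.csv",
        "filters": f"{prefix}_filters.tsv",
        "truth": f"{prefix}_truth.json",
    }
    np.savetxt(paths["stimulus"], truth["stimulus"].values, fmt="%.10g")
    np.savetxt(paths["responses"], data.responses, fmt="%d")
    save_filters(truth["filters"], paths["filters"])
    with open(paths["truth"], "w") as fh:
        fh.write(
            json.dumps(
                {
                    "planted_model": json.loads(truth["model"].to_json()),
                    "seed": spec.seed,
                    "duration_bins": spec.duration_bins,
                    "dt": spec.dt,
                    "corr_time_bins": spec.corr_time_bins,
                    "log_sigma": spec.log_sigma,
                    "window_bins": spec.window_bins,
                    "mean_rate": truth["mean_rate"],
                }
            )
        )
    return paths
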