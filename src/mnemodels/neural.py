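"""Spike-train analysis in a reduced two-dimensional stimulus space.

The pipeline mirrors the standard receptive-field workflow for early
visual neurons driven by a flickering luminance stimulus: spikes are
binned at 4 ms (making the response binary), the stimulus history over a
200 ms window (50 bins) forms the raw input vector, and two temporal
filters — found externally, e.g. by maximally informative dimensions —
project that history onto reduced inputs s1, s2, each normalized to
[-1, 1].  MNE models of first and second order are then fitted on the
continuous reduced inputs; a 14x14 binned response function provides the
empirical reference mutual information and the visualization surface.

Alignment convention: the input for response bin t is the window of
stimulus bins ending at and *including* t, stored oldest-first, so the
last filter tap multiplies the current stimulus bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    FeatureMap,
    InputEnsemble,
    MNEModel,
    MomentVector,
    ResponseDataset,
    build_feature_map,
    model_moments,
)
from .fitting import FitOptions, FitResult, empirical_moments, fit_mne
from .information import InfoReport, empirical_information, report_for_model

DEFAULT_DT = 0.004          # 4 ms bins keep the response binary
DEFAULT_WINDOW_BINS = 50    # 200 ms of stimulus history
DEFAULT_N_BINS = 14         # display / reference-MI grid per dimension


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times in seconds over a recording of given duration."""

    spike_times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", t)
        if np.any(np.diff(t) < 0):
            raise ValueError("spike times must be nondecreasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")


@dataclass(frozen=True)
class StimulusTrace:
    """Uniformly sampled scalar stimulus (normalized luminance)."""

    values: np.ndarray
    dt: float = DEFAULT_DT

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("stimulus values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FilterPair:
    """Two temporal receptive-field filters over the stimulus window."""

    v1: np.ndarray
    v2: np.ndarray

    def __post_init__(self) -> None:
        v1 = np.asarray(self.v1, dtype=float)
        v2 = np.asarray(self.v2, dtype=float)
        object.__setattr__(self, "v1", v1)
        object.__setattr__(self, "v2", v2)
        if v1.shape != v2.shape or v1.ndim != 1:
            raise ValueError("filters must be 1-D vectors of equal length")
        if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
            raise ValueError("filters must be finite")

    @property
    def window_bins(self) -> int:
        return len(self.v1)


@dataclass(frozen=True)
class BinnedResponseFunction:
    """Occupancy, spike counts and spike probability on a 2-D grid.

    ``probability`` is NaN where a bin is unsampled — distinct from an
    observed probability of zero (sampled, but no spikes).
    """

    n_bins: int
    occupancy: np.ndarray
    spike_counts: np.ndarray
    clipped_samples: int = 0

    def __post_init__(self) -> None:
        if np.any(self.spike_counts > self.occupancy):
            raise ValueError("spike counts cannot exceed occupancy")

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.spike_counts / self.occupancy
        return np.where(self.occupancy > 0, p, np.nan)

    def to_frame(self) -> pd.DataFrame:
        i, j = np.meshgrid(range(self.n_bins), range(self.n_bins), indexing="ij")
        return pd.DataFrame(
            {
                "bin_s1": i.ravel(),
                "bin_s2": j.ravel(),
                "occupancy": self.occupancy.ravel(),
                "spikes": self.spike_counts.ravel(),
                "probability": self.probability.ravel(),
            }
        )


def bin_spikes(train: SpikeTrain, dt: float = DEFAULT_DT) -> np.ndarray:
    """Binary response sequence: y_t = 1 iff >= 1 spike in [t*dt, (t+1)*dt).

    Bins containing more than one spike are clipped to 1; the clip count
    is reported in a warning so refractory violations are visible.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_bins = int(np.floor(train.duration / dt + 1e-9))
    t = train.spike_times
    if t.size and t[-1] > n_bins * dt + 1e-12:
        raise ValueError("spike beyond the binned duration")
    idx = np.minimum(np.floor(t / dt).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins) if t.size else np.zeros(n_bins, dtype=int)
    n_clipped = int(np.sum(np.maximum(counts - 1, 0)))
    if n_clipped:
        warnings.warn(f"{n_clipped} extra spikes clipped to binary bins", RuntimeWarning)
    return (counts > 0).astype(float)


def build_lagged_inputs(stim: StimulusTrace, window_bins: int = DEFAULT_WINDOW_BINS) -> np.ndarray:
    """Stimulus-history matrix: row t-(window-1) holds bins t-window+1..t, oldest first.

    The first window-1 response bins have incomplete histories and are
    dropped; trim the response series with ``trim_responses`` to match.
    """
    v = stim.values
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if len(v) < window_bins:
        raise ValueError(f"series length {len(v)} shorter than window {window_bins}")
    return np.lib.stride_tricks.sliding_window_view(v, window_bins).copy()


def trim_responses(y: np.ndarray, window_bins: int = DEFAULT_WINDOW_BINS) -> np.ndarray:
    """Drop the first window-1 responses to align with ``build_lagged_inputs``."""
    return np.asarray(y, dtype=float)[window_bins - 1 :]


def project_and_normalize(
    lagged: np.ndarray, filters: FilterPair
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Project stimulus histories onto the two filters; scale each to [-1, 1].

    Each dimension is divided by its own maximum absolute value over the
    dataset, so |s| attains 1 somewhere.  Returns (s1, s2, scales) where
    ``scales`` are the divisors, needed to map held-out data into the
    same coordinates.
    """
    lagged = np.atleast_2d(np.asarray(lagged, dtype=float))
    if lagged.shape[1] != filters.window_bins:
        raise ValueError("filter length must equal the stimulus window")
    if not np.any(filters.v1) or not np.any(filters.v2):
        raise ValueError("zero-norm filter")
    raw1 = lagged @ filters.v1
    raw2 = lagged @ filters.v2
    m1 = float(np.max(np.abs(raw1)))
    m2 = float(np.max(np.abs(raw2)))
    s1 = raw1 / m1 if m1 > 0 else raw1
    s2 = raw2 / m2 if m2 > 0 else raw2
    return s1, s2, (m1 if m1 > 0 else 1.0, m2 if m2 > 0 else 1.0)


def bin_index(s: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniform bin index over [-1, 1]; half-open bins, last bin closed."""
    idx = np.floor((np.asarray(s) + 1.0) / 2.0 * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def bin_response_2d(
    s1: np.ndarray, s2: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> BinnedResponseFunction:
    """Discretize the reduced inputs onto an n_bins x n_bins grid.

    Values outside [-1, 1] (possible when trained scales are applied to
    held-out data) are clipped into the edge bins and tallied.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(s1) == len(s2) == len(y)):
        raise ValueError("s1, s2 and y must have equal lengths")
    out_of_range = int(np.sum((np.abs(s1) > 1.0) | (np.abs(s2) > 1.0)))
    if out_of_range:
        warnings.warn(f"{out_of_range} samples outside [-1,1] clipped for binning", RuntimeWarning)
    i = bin_index(np.clip(s1, -1.0, 1.0), n_bins)
    j = bin_index(np.clip(s2, -1.0, 1.0), n_bins)
    flat = i * n_bins + j
    occ = np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    spk = np.bincount(flat, weights=y, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    return BinnedResponseFunction(
        n_bins=n_bins,
        occupancy=occ,
        spike_counts=spk,
        clipped_samples=out_of_range,
    )


def binned_reference_information(
    s1: np.ndarray, s2: np.ndarray, y: np.ndarray, n_bins: int = DEFAULT_N_BINS
) -> float:
    """Empirical MI between the binned (s1, s2) state and the response, bits."""
    i = bin_index(np.clip(s1, -1.0, 1.0), n_bins)
    j = bin_index(np.clip(s2, -1.0, 1.0), n_bins)
    data = ResponseDataset.from_arrays(np.column_stack([i, j]).astype(float), y)
    return empirical_information(data)


def _reduced_dataset(s1: np.ndarray, s2: np.ndarray, y: np.ndarray) -> ResponseDataset:
    return ResponseDataset.from_arrays(np.column_stack([s1, s2]), y)


def fit_reduced_models(
    s1: np.ndarray,
    s2: np.ndarray,
    y: np.ndarray,
    orders: Sequence[int] = (1, 2),
    include_cross_terms: bool = True,
    opts: FitOptions | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[list[InfoReport], list[FitResult]]:
    """Fit MNE models of the requested orders on the continuous reduced inputs.

    The binned response function supplies the empirical reference
    information; the fits themselves use the continuous s1, s2 values.
    """
    if len(y) == 0:
        raise ValueError("empty dataset")
    data = _reduced_dataset(s1, s2, y)
    ref = binned_reference_information(s1, s2, y, n_bins)
    reports, fits = [], []
    for order in orders:
        fm = build_feature_map(2, order, binary_inputs=False, include_cross_terms=include_cross_terms)
        fit = fit_mne(data, fm, opts)
        reports.append(report_for_model(fit, data, ref))
        fits.append(fit)
    return reports, fits


def predict_unconstrained_moments(
    model: MNEModel,
    data: ResponseDataset,
    monomials: Sequence[tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Model-predicted vs observed values of moments *not* in the constraint set.

    Constrained moments match by construction; comparing the unconstrained
    ones (by default, all third-order monomials of the two reduced inputs)
    diagnoses whether the fitted order suffices.  Returns a table with one
    row per monomial: predicted, observed, and whether it was constrained.
    """
    D = model.feature_map.n_inputs
    if monomials is None:
        import itertools as _it

        monomials = list(_it.combinations_with_replacement(range(D), 3))
    constrained = set(model.feature_map.monomials)
    probe = [tuple(sorted(m)) for m in monomials]
    for m in probe:
        if m in constrained:
            warnings.warn(
                f"monomial {m} is in the constraint set; its comparison is trivially exact",
                RuntimeWarning,
            )
    fm_probe = FeatureMap(
        n_inputs=D,
        order=max((len(m) for m in probe), default=1),
        monomials=((),) + tuple(m for m in probe if m != ()),
    )
    F = fm_probe.design_matrix(data.ensemble.inputs)
    w = data.ensemble.weights
    p = model.predict(data.ensemble.inputs)
    predicted = F.T @ (w * p)
    observed = F.T @ (w * data.responses)
    rows = []
    for k, m in enumerate(fm_probe.monomials):
        if m == () and () not in probe:
            continue
        rows.append(
            {
                "monomial": m,
                "predicted": predicted[k],
                "observed": observed[k],
                "constrained": m in constrained,
            }
        )
    return pd.DataFrame(rows)


def compare_cross_term(
    s1: np.ndarray,
    s2: np.ndarray,
    y: np.ndarray,
    opts: FitOptions | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> dict:
    """Second-order fits with and without the mixed s1*s2 coefficient.

    The mixed coefficient measures how far the symmetry axes of the
    conic-section probability contours are from the coordinate axes; the
    information gain from constraining it is never negative (the models
    are nested).  Returns both reports, the gain in bits, and the fitted
    mixed coefficient.
    """
    reports_with, fits_with = fit_reduced_models(
        s1, s2, y, orders=(2,), include_cross_terms=True, opts=opts, n_bins=n_bins
    )
    reports_wo, fits_wo = fit_reduced_models(
        s1, s2, y, orders=(2,), include_cross_terms=False, opts=opts, n_bins=n_bins
    )
    model = fits_with[0].model
    mixed_idx = model.feature_map.monomials.index((0, 1))
    return {
        "with_cross": reports_with[0],
        "without_cross": reports_wo[0],
        "gain_bits": reports_with[0].model_information_bits
        - reports_wo[0].model_information_bits,
        "mixed_coefficient": model.coefficients[mixed_idx],
        "fit_with": fits_with[0],
        "fit_without": fits_wo[0],
    }


# ---------------------------------------------------------------------------
# plain-text I/O


def load_stimulus(path, dt: float = DEFAULT_DT) -> StimulusTrace:
    """Stimulus CSV/text: one luminance value per line."""
    return StimulusTrace(values=np.loadtxt(path, ndmin=1), dt=dt)


def load_spike_times(path, duration: float) -> SpikeTrain:
    """Spike times text: one float per line, seconds."""
    t = np.loadtxt(path, ndmin=1)
    return SpikeTrain(spike_times=np.sort(t), duration=duration)


def load_binary_responses(path) -> np.ndarray:
    y = np.loadtxt(path, ndmin=1)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("binary response file must contain only 0/1")
    return y


def load_filters(path) -> FilterPair:
    """Two-column delimited text, one row per window bin, oldest first."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError(f"expected 2 filter columns, got {arr.shape[1]}")
    return FilterPair(v1=arr[:, 0], v2=arr[:, 1])


def save_filters(filters: FilterPair, path) -> None:
    np.savetxt(path, np.column_stack([filters.v1, filters.v2]))
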