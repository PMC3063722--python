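"""Entropies, mutual information and the constraint-selection loop.

For a binary output y with mean rate r, the response entropy is the
binary entropy H2(r) and the mutual information of a model is

    I_model = H2(r) - sum_x P(x) H2(P(1|x)),

the response entropy minus the noise entropy.  Because the mean rate is
always among the constraints, the MNE model is also the *minimum* mutual
information model consistent with the constraints: I_model quantifies
the information content of the constraint set, and the ratio of I_model
to an empirical estimate of the true mutual information is the percent
of the information the constraints capture.

All user-facing entropies are in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np
import pandas as pd

from .core import InputEnsemble, MNEModel, ResponseDataset, model_moments
from .fitting import FitOptions, FitResult, empirical_moments, fit_mne


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """H2(p) in bits; exactly 0 at p=0 and p=1."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    interior = (p > 0.0) & (p < 1.0)
    pi = p[interior]
    out[interior] = -(pi * np.log2(pi) + (1.0 - pi) * np.log2(1.0 - pi))
    return float(out) if out.ndim == 0 else out


def noise_entropy(model_or_table: MNEModel | np.ndarray, ensemble: InputEnsemble) -> float:
    """Average conditional output entropy sum_x P(x) H2(P(1|x)), in bits.

    Accepts either a fitted model or an explicit conditional probability
    table aligned with the ensemble rows.
    """
    if isinstance(model_or_table, MNEModel):
        p = model_or_table.predict(ensemble.inputs)
    else:
        p = np.asarray(model_or_table, dtype=float)
        if p.shape != (len(ensemble),):
            raise ValueError("conditional table must align with ensemble rows")
    return float(ensemble.weights @ binary_entropy(p))


def response_entropy(mean_output: float) -> float:
    """Entropy of the marginal binary output: H2(mean rate), in bits."""
    if not 0.0 <= mean_output <= 1.0:
        raise ValueError(f"mean output {mean_output} outside [0, 1]")
    return float(binary_entropy(mean_output))


def model_information(model_or_table: MNEModel | np.ndarray, ensemble: InputEnsemble) -> float:
    """Mutual information of a model: response entropy minus noise entropy."""
    if isinstance(model_or_table, MNEModel):
        p = model_or_table.predict(ensemble.inputs)
    else:
        p = np.asarray(model_or_table, dtype=float)
    rate = float(ensemble.weights @ p)
    return response_entropy(rate) - float(ensemble.weights @ binary_entropy(p))


def empirical_information(
    data: ResponseDataset,
    state_key: Callable[[np.ndarray], Hashable] | None = None,
) -> float:
    """Plug-in mutual information between discretized input state and output.

    ``state_key`` maps each input row to a hashable state (default: the
    exact tuple of coordinates, appropriate for discrete ensembles; pass
    a binning rule for continuous data).  Weighted counts give the joint
    distribution; the estimator is the maximum-likelihood plug-in with no
    bias correction.
    """
    if state_key is None:
        state_key = lambda row: tuple(row)
    joint: dict[Hashable, np.ndarray] = {}
    for row, w, y in zip(data.ensemble.inputs, data.ensemble.weights, data.responses):
        k = state_key(row)
        if k not in joint:
            joint[k] = np.zeros(2)
        joint[k][int(y)] += w
    if len(joint) < 2:
        warnings.warn("fewer than 2 distinct input states; information is 0", RuntimeWarning)
        return 0.0
    P = np.array(list(joint.values()))          # (S, 2)
    P = P / P.sum()
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mask = P > 0
    mi = float(np.sum(P[mask] * np.log2(P[mask] / (px[:, None] * py[None, :])[mask])))
    return max(mi, 0.0)


def info_ratio(model_info_bits: float, reference_info_bits: float) -> float:
    """Fraction of the reference information captured by the model, in [0, 1].

    Values slightly above 1 from numerical noise are clipped with a
    warning; a positive model information with a zero reference signals
    inconsistent inputs and raises.
    """
    if reference_info_bits < 0:
        raise ValueError("reference information must be nonnegative")
    if reference_info_bits == 0.0 or reference_info_bits < 1e-12:
        if model_info_bits > 1e-9:
            raise ValueError(
                f"model information {model_info_bits} with zero reference information"
            )
        return 0.0
    r = model_info_bits / reference_info_bits
    if r > 1.0:
        if r > 1.0 + 1e-6:
            warnings.warn(f"information ratio {r:.8f} > 1 clipped", RuntimeWarning)
        r = 1.0
    return r


@dataclass(frozen=True)
class InfoReport:
    """Entropy/information summary for one fitted model."""

    order: int
    constraint_count: int
    noise_entropy_bits: float
    response_entropy_bits: float
    model_information_bits: float
    reference_information_bits: float
    ratio: float
    converged: bool = True

    @property
    def percent(self) -> float:
        return 100.0 * self.ratio


def report_for_model(
    fit: FitResult,
    data: ResponseDataset,
    reference_info_bits: float,
) -> InfoReport:
    """Assemble an InfoReport for a fitted model against a reference MI."""
    model = fit.model
    ens = data.ensemble
    p = model.predict(ens.inputs)
    rate = float(ens.weights @ p)
    s_noise = float(ens.weights @ binary_entropy(p))
    s_resp = response_entropy(rate)
    i_model = s_resp - s_noise
    return InfoReport(
        order=model.feature_map.order,
        constraint_count=model.feature_map.n_features,
        noise_entropy_bits=s_noise,
        response_entropy_bits=s_resp,
        model_information_bits=i_model,
        reference_information_bits=reference_info_bits,
        ratio=info_ratio(i_model, reference_info_bits),
        converged=fit.converged,
    )


def scan_orders(
    data: ResponseDataset,
    max_order: int,
    threshold_percent: float = 90.0,
    opts: FitOptions | None = None,
    binary_inputs: bool = True,
    reference_info_bits: float | None = None,
    state_key: Callable[[np.ndarray], Hashable] | None = None,
) -> tuple[list[InfoReport], int]:
    """Incremental constraint selection: fit orders 1..max_order in turn.

    Stops at the first order whose information ratio reaches
    ``threshold_percent``; returns all reports computed plus the selected
    order (the last fitted order if the threshold is never reached).
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    from .core import build_feature_map  # local import to avoid cycle noise

    if reference_info_bits is None:
        reference_info_bits = empirical_information(data, state_key)
    reports: list[InfoReport] = []
    selected = 1
    for order in range(1, max_order + 1):
        fm = build_feature_map(data.ensemble.n_inputs, order, binary_inputs=binary_inputs)
        fit = fit_mne(data, fm, opts)
        rep = report_for_model(fit, data, reference_info_bits)
        reports.append(rep)
        selected = order
        if rep.percent >= threshold_percent:
            break
    return reports, selected


def reports_to_frame(reports: Sequence[InfoReport]) -> pd.DataFrame:
    """One row per order: entropies, information, ratio, convergence flag."""
    return pd.DataFrame(
        {
            "order": [r.order for r in reports],
            "constraint_count": [r.constraint_count for r in reports],
            "noise_entropy_bits": [r.noise_entropy_bits for r in reports],
            "response_entropy_bits": [r.response_entropy_bits for r in reports],
            "model_information_bits": [r.model_information_bits for r in reports],
            "reference_information_bits": [r.reference_information_bits for r in reports],
            "percent_information": [r.percent for r in reports],
            "converged": [r.converged for r in reports],
        }
    )
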