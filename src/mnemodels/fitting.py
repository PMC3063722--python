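"""Fitting MNE models by moment matching, and a brute-force oracle.

Matching the model moments to the empirical moments (the Lagrange
condition of the constrained entropy maximization) is equivalent to
maximizing the average Bernoulli log-likelihood of the logistic model:
the likelihood gradient with respect to each coefficient equals the
empirical-minus-model moment mismatch for that monomial.  We therefore
fit with a deterministic quasi-Newton method (L-BFGS-B) on the penalized
negative average log-likelihood, initialized at the all-zero coefficient
vector (the constant-1/2 model).  The objective is convex, so the default
path has no seed sensitivity.

Deterministic systems (e.g. exact logic gates) drive coefficients to
infinity; a box bound (``coefficient_cap``) and an optional tiny L2
penalty keep the fit finite while the information converges to its
limit.

``maxent_oracle`` is an independent check: it maximizes the noise
entropy directly over the per-state conditional probability table with a
generic constrained optimizer — no logistic parameterization — and is
used in tests to verify that the logistic form attains the constrained
maximum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize
from scipy.special import expit

from .core import (
    PROB_FLOOR,
    FeatureMap,
    InputEnsemble,
    MNEModel,
    MomentVector,
    ResponseDataset,
    model_moments,
)


@dataclass(frozen=True)
class FitOptions:
    """Numerical options for ``fit_mne``.

    tolerance: maximum absolute moment mismatch accepted as converged.
    l2_penalty: coefficient shrinkage strength (per squared coefficient,
        constant term excluded); keeps deterministic fits finite.
    coefficient_cap: box bound on each coefficient's absolute value.
    seed: reserved for randomized initializations; the default
        deterministic path ignores it.
    """

    tolerance: float = 1e-6
    max_iterations: int = 1000
    l2_penalty: float = 1e-8
    coefficient_cap: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.coefficient_cap <= 0:
            raise ValueError("coefficient_cap must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    model: MNEModel
    converged: bool
    final_mismatch: float
    n_iterations: int
    options: FitOptions
    log: str = ""

    def to_json(self) -> str:
        d = json.loads(self.model.to_json())
        d.update(
            converged=self.converged,
            final_mismatch=self.final_mismatch,
            n_iterations=self.n_iterations,
            options=asdict(self.options),
        )
        return json.dumps(d)


def empirical_moments(data: ResponseDataset, fm: FeatureMap) -> MomentVector:
    """Weighted empirical moments <y f_mu(x)> of a response dataset."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    F = fm.design_matrix(data.ensemble.inputs)
    vals = F.T @ (data.ensemble.weights * data.responses)
    return MomentVector(feature_map=fm, values=vals)


def _neg_avg_loglik_and_grad(
    coef: np.ndarray, F: np.ndarray, y: np.ndarray, w: np.ndarray, l2: float
) -> tuple[float, np.ndarray]:
    """Penalized negative average log-likelihood and its gradient.

    With p = sigmoid(-z), z = F @ coef, the per-sample log-likelihood is
    -y*log(1+e^z) - (1-y)*log(1+e^{-z}); the gradient of the *negative*
    average log-likelihood is F.T @ (w*(y - p)) = empirical - model
    moments, so the stationarity condition is exactly moment matching.
    """
    z = F @ coef
    # log(1 + e^z) computed stably for both signs of z
    log1pez = np.logaddexp(0.0, z)
    nll = float(w @ (y * log1pez + (1.0 - y) * (log1pez - z)))
    p = expit(-z)
    grad = F.T @ (w * (y - p))
    if l2 > 0:
        pen = coef.copy()
        pen[0] = 0.0  # the mean-rate multiplier is not shrunk
        nll += l2 * float(pen @ pen)
        grad = grad + 2.0 * l2 * pen
    return nll, grad


def fit_mne(data: ResponseDataset, fm: FeatureMap, opts: FitOptions | None = None) -> FitResult:
    """Fit the Lagrange multipliers so model moments match empirical moments.

    Returns a ``FitResult``; ``converged`` is True when the max-norm
    moment mismatch (which equals the unpenalized likelihood gradient) is
    below ``opts.tolerance``.  Deterministic given data, feature map and
    options.
    """
    opts = opts or FitOptions()
    if len(data) == 0:
        raise ValueError("empty dataset")
    y = data.responses
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("responses must be binary")
    w = data.ensemble.weights
    rate = data.mean_output

    F = fm.design_matrix(data.ensemble.inputs)

    if rate <= 0.0 or rate >= 1.0:
        warnings.warn(
            f"degenerate mean output {rate}; returning the constant model",
            RuntimeWarning,
        )
        p = min(max(rate, PROB_FLOOR), 1.0 - PROB_FLOOR)
        a = min(max(np.log((1.0 - p) / p), -opts.coefficient_cap), opts.coefficient_cap)
        coef = np.zeros(fm.n_features)
        coef[0] = a
        model = MNEModel(feature_map=fm, coefficients=tuple(coef))
        mm = model_moments(model, data.ensemble).values
        em = empirical_moments(data, fm).values
        mis = float(np.max(np.abs(em - mm)))
        return FitResult(model, mis <= opts.tolerance, mis, 0, opts, "degenerate rate")

    x0 = np.zeros(fm.n_features)
    bounds = [(-opts.coefficient_cap, opts.coefficient_cap)] * fm.n_features
    res = optimize.minimize(
        _neg_avg_loglik_and_grad,
        x0,
        args=(F, y, w, opts.l2_penalty),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": opts.max_iterations,
            "maxfun": 20 * opts.max_iterations,
            "ftol": 1e-16,
            "gtol": min(opts.tolerance * 0.1, 1e-9),
        },
    )
    coef = res.x
    p = expit(-(F @ coef))
    mismatch = float(np.max(np.abs(F.T @ (w * (y - p)))))
    model = MNEModel(feature_map=fm, coefficients=tuple(coef))
    converged = bool(mismatch <= opts.tolerance)
    if not converged:
        warnings.warn(
            f"fit did not reach moment tolerance: mismatch {mismatch:.3g} "
            f"> {opts.tolerance:.3g} after {res.nit} iterations",
            RuntimeWarning,
        )
    return FitResult(
        model=model,
        converged=converged,
        final_mismatch=mismatch,
        n_iterations=int(res.nit),
        options=opts,
        log=str(res.message),
    )


class InfeasibleMomentsError(ValueError):
    """Raised when no conditional probability table satisfies the moments."""


_ORACLE_STATE_GUARD = 4096


def maxent_oracle(
    moments: MomentVector, ensemble: InputEnsemble, residual_tol: float = 1e-8
) -> np.ndarray:
    """Directly maximize the noise entropy over a conditional table.

    Enumerates the distinct input states of the ensemble (guard: at most
    4096) and maximizes sum_x P(x) H2(q_x) over the per-state spike
    probabilities q subject to the linear moment constraints
    sum_x P(x) q_x f_mu(x) = m_mu, using SLSQP — no logistic
    parameterization, so this is an independent check of ``fit_mne``.

    Returns q aligned with the deduplicated state list, as the pair
    (states, q) collapsed onto the original ensemble row order: the
    returned array has one entry per ensemble row (duplicate rows get the
    shared state's probability).
    """
    fm = moments.feature_map
    X = ensemble.inputs
    # aggregate duplicate states and their weights
    keys = [tuple(row) for row in X]
    uniq: dict[tuple, int] = {}
    for k in keys:
        if k not in uniq:
            uniq[k] = len(uniq)
    S = len(uniq)
    if S > _ORACLE_STATE_GUARD:
        raise ValueError(f"{S} distinct states exceeds the oracle guard of {_ORACLE_STATE_GUARD}")
    Xs = np.array(list(uniq.keys()), dtype=float)
    Pw = np.zeros(S)
    for k, w in zip(keys, ensemble.weights):
        Pw[uniq[k]] += w

    Fs = fm.design_matrix(Xs)          # (S, M)
    A = (Fs * Pw[:, None]).T           # (M, S): A @ q = moments
    m = moments.values

    eps = PROB_FLOOR

    def neg_entropy(q: np.ndarray) -> float:
        qc = np.clip(q, eps, 1.0 - eps)
        h = -(qc * np.log2(qc) + (1.0 - qc) * np.log2(1.0 - qc))
        return -float(Pw @ h)

    def neg_entropy_grad(q: np.ndarray) -> np.ndarray:
        qc = np.clip(q, eps, 1.0 - eps)
        return -Pw * np.log2((1.0 - qc) / qc)

    # feasible-ish start: the mean rate everywhere (satisfies the constant
    # constraint whenever the moments came from real data)
    q0 = np.full(S, min(max(m[0], 0.01), 0.99))
    cons = [
        {
            "type": "eq",
            "fun": lambda q, A=A, m=m: A @ q - m,
            "jac": lambda q, A=A: A,
        }
    ]
    res = optimize.minimize(
        neg_entropy,
        q0,
        jac=neg_entropy_grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * S,
        constraints=cons,
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    q = np.clip(res.x, 0.0, 1.0)
    resid = np.abs(A @ q - m)
    if np.max(resid) > residual_tol:
        mu = int(np.argmax(resid))
        raise InfeasibleMomentsError(
            f"moment constraint for monomial {fm.monomials[mu]} violated by "
            f"{resid[mu]:.3g} (> {residual_tol:.1g}); constraints may be infeasible"
        )
    # broadcast back to the original row order
    idx = np.array([uniq[k] for k in keys])
    return q[idx]
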