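"""Core objects: feature maps, the MNE model, input ensembles and moments.

A maximum-noise-entropy (MNE) model of a binary-output system is the
conditional distribution :math:`P(y=1\\mid\\mathbf{x})` that maximizes the
average conditional entropy of the output subject to a set of moment
constraints :math:`\\langle y\\,f_\\mu(\\mathbf{x})\\rangle`.  For a binary
output the solution is a logistic function of a polynomial in the inputs;
the polynomial terms (monomials) are the constraint functions and the
Lagrange multipliers are the model coefficients.

Sign convention used throughout this package::

    P(y=1 | x) = 1 / (1 + exp(z)),   z = a + sum_i h_i x_i + sum_{i<=j} J_ij x_i x_j + ...

so *negative* coefficients increase the output probability.  The
convention is arbitrary (negating every coefficient gives the mirrored
convention) but is fixed and recorded in serialized models.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit

SIGN_CONVENTION = "P(y=1|x) = 1/(1+exp(a + sum h_i x_i + sum_{i<=j} J_ij x_i x_j + ...))"

#: probabilities are clamped to this range inside logarithms so entropies
#: stay finite near the deterministic limit
PROB_FLOOR = 1e-12


Monomial = tuple[int, ...]


@dataclass(frozen=True)
class FeatureMap:
    """Ordered set of monomial constraint functions ``f_mu(x)``.

    ``monomials`` is a tuple of index multisets (sorted tuples); the empty
    tuple denotes the constant feature enforcing the mean-output
    constraint.  Canonical order: constant, singletons ascending, pairs
    lexicographic, triples lexicographic, ...
    """

    n_inputs: int
    order: int
    monomials: tuple[Monomial, ...]
    binary_inputs: bool = False
    include_cross_terms: bool = True

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError(f"n_inputs must be >= 1, got {self.n_inputs}")
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")
        if not self.monomials or self.monomials[0] != ():
            raise ValueError("the constant feature () must be present and first")
        seen = set()
        for mono in self.monomials:
            if mono in seen:
                raise ValueError(f"duplicate monomial {mono}")
            seen.add(mono)
            if any(i < 0 or i >= self.n_inputs for i in mono):
                raise ValueError(f"monomial {mono} has indices outside [0, {self.n_inputs})")
            if tuple(sorted(mono)) != mono:
                raise ValueError(f"monomial {mono} is not a sorted index tuple")
            if self.binary_inputs and len(set(mono)) != len(mono):
                # for x in {0,1}, x^k = x: higher powers are redundant
                raise ValueError(f"repeated index in {mono} is redundant for binary inputs")

    @property
    def n_features(self) -> int:
        return len(self.monomials)

    def evaluate(self, x: Sequence[float]) -> np.ndarray:
        """Evaluate every monomial at a single input vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_inputs,):
            raise ValueError(f"expected input of length {self.n_inputs}, got shape {x.shape}")
        return self.design_matrix(x[None, :])[0]

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        """(T, n_features) matrix of monomial values for rows of ``X``."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} input columns, got {X.shape[1]}"
            )
        cols = np.empty((X.shape[0], self.n_features))
        for j, mono in enumerate(self.monomials):
            col = np.ones(X.shape[0])
            for i in mono:
                col = col * X[:, i]
            cols[:, j] = col
        return cols


def build_feature_map(
    n_inputs: int,
    order: int,
    binary_inputs: bool = False,
    include_cross_terms: bool = True,
) -> FeatureMap:
    """Enumerate monomials up to ``order`` in canonical order.

    The constant feature comes first, then all monomials of total degree
    1, 2, ... ``order``, each degree in lexicographic order of index
    multisets.  For binary inputs, monomials with a repeated index are
    skipped (powers of a 0/1 variable are redundant).  With
    ``include_cross_terms=False``, monomials involving more than one
    distinct input are dropped — each input then only interacts with
    itself, e.g. the diagonal-only second-order model.
    """
    if n_inputs < 1:
        raise ValueError(f"n_inputs must be >= 1, got {n_inputs}")
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    monomials: list[Monomial] = [()]
    for k in range(1, order + 1):
        for combo in itertools.combinations_with_replacement(range(n_inputs), k):
            if binary_inputs and len(set(combo)) != len(combo):
                continue
            if not include_cross_terms and len(set(combo)) > 1:
                continue
            monomials.append(combo)
    return FeatureMap(
        n_inputs=n_inputs,
        order=order,
        monomials=tuple(monomials),
        binary_inputs=binary_inputs,
        include_cross_terms=include_cross_terms,
    )


@dataclass(frozen=True)
class MNEModel:
    """Logistic response function with one Lagrange multiplier per monomial."""

    feature_map: FeatureMap
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        coef = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coef)
        if len(coef) != self.feature_map.n_features:
            raise ValueError(
                f"{len(coef)} coefficients for {self.feature_map.n_features} monomials"
            )
        if not np.all(np.isfinite(coef)):
            raise ValueError("coefficients must be finite")

    def transformed_input(self, X: np.ndarray) -> np.ndarray:
        """The exponent z(x): the polynomial combination of the features."""
        F = self.feature_map.design_matrix(X)
        return F @ np.asarray(self.coefficients)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """P(y=1|x) for each row of X; scalar input vectors are promoted."""
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        p = expit(-self.transformed_input(np.atleast_2d(X)))
        return float(p[0]) if single else p

    def to_json(self) -> str:
        return json.dumps(
            {
                "convention": SIGN_CONVENTION,
                "n_inputs": self.feature_map.n_inputs,
                "order": self.feature_map.order,
                "binary_inputs": self.feature_map.binary_inputs,
                "include_cross_terms": self.feature_map.include_cross_terms,
                "monomials": [list(m) for m in self.feature_map.monomials],
                "coefficients": list(self.coefficients),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MNEModel":
        d = json.loads(text)
        fm = FeatureMap(
            n_inputs=d["n_inputs"],
            order=d["order"],
            monomials=tuple(tuple(m) for m in d["monomials"]),
            binary_inputs=d.get("binary_inputs", False),
            include_cross_terms=d.get("include_cross_terms", True),
        )
        return cls(feature_map=fm, coefficients=tuple(d["coefficients"]))


@dataclass(frozen=True)
class InputEnsemble:
    """Discrete inputs with probability weights.

    Exact ensembles (e.g. the uniform distribution over the 2^N states of
    a logic gate) carry analytic weights; empirical samples carry uniform
    weights 1/T.
    """

    inputs: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "weights", weights)
        if len(weights) != inputs.shape[0]:
            raise ValueError("one weight per input row required")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {weights.sum()!r}")

    @classmethod
    def from_samples(cls, X: np.ndarray) -> "InputEnsemble":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return cls(inputs=X, weights=np.full(X.shape[0], 1.0 / X.shape[0]))

    @property
    def n_inputs(self) -> int:
        return self.inputs.shape[1]

    def __len__(self) -> int:
        return self.inputs.shape[0]


@dataclass(frozen=True)
class ResponseDataset:
    """Paired (input vector, binary output) observations."""

    ensemble: InputEnsemble
    responses: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", y)
        if len(y) != len(self.ensemble):
            raise ValueError("responses must align with ensemble inputs")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("responses must be binary 0/1")

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray) -> "ResponseDataset":
        return cls(ensemble=InputEnsemble.from_samples(X), responses=np.asarray(y))

    @property
    def mean_output(self) -> float:
        return float(self.ensemble.weights @ self.responses)

    def __len__(self) -> int:
        return len(self.ensemble)


@dataclass(frozen=True)
class MomentVector:
    """Values of <y f_mu(x)>, one per monomial of a feature map.

    The first entry (constant feature) is the mean output rate; for
    neural data the singleton entries are the spike-triggered average and
    the pair entries the spike-triggered second moments.
    """

    feature_map: FeatureMap
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if len(v) != self.feature_map.n_features:
            raise ValueError("one moment per monomial required")
        if not (-1e-12 <= v[0] <= 1.0 + 1e-12):
            raise ValueError(f"mean output {v[0]} outside [0, 1]")


def model_moments(model: MNEModel, ensemble: InputEnsemble) -> MomentVector:
    """Model-implied moments <y f_mu(x)> = sum_x P(x) P(1|x) f_mu(x).

    Computed by direct expectation over the ensemble, which for binary
    outputs coincides with the free-energy derivative of the partition
    function.
    """
    F = model.feature_map.design_matrix(ensemble.inputs)
    p = model.predict(ensemble.inputs)
    vals = F.T @ (ensemble.weights * p)
    return MomentVector(feature_map=model.feature_map, values=vals)
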