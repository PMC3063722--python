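"""Exact Boolean input/output ensembles (logic gates).

Logic gates are exactly solvable test systems for the MNE method: with N
binary inputs under a uniform input distribution, every moment is an
exact rational number, the empirical mutual information is exact, and
the order-N model is guaranteed to capture all of the information (every
higher power of a 0/1 variable is redundant).  Inputs are encoded as
{0,1}, matching the spike-triggered-average reading of the first-order
moments; ``recode_pm1`` converts a dataset to the ±1 convention when
comparison with Ising-style parameterizations is needed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np

from .core import InputEnsemble, ResponseDataset

State = tuple[int, ...]


@dataclass(frozen=True)
class TruthGate:
    """Map from each binary input state to P(y=1 | state)."""

    n_inputs: int
    table: Mapping[State, float]

    def __post_init__(self) -> None:
        states = set(itertools.product((0, 1), repeat=self.n_inputs))
        if set(self.table) != states:
            raise ValueError(f"table must cover all {2 ** self.n_inputs} states")
        for s, p in self.table.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"P(y=1|{s}) = {p} outside [0, 1]")

    @property
    def is_deterministic(self) -> bool:
        return all(p in (0.0, 1.0) for p in self.table.values())


_GATE_RULES = {
    "AND": lambda bits: int(all(bits)),
    "OR": lambda bits: int(any(bits)),
    "XOR": lambda bits: int(sum(bits) % 2),          # parity for >2 inputs
    "NAND": lambda bits: int(not all(bits)),
    "NOR": lambda bits: int(not any(bits)),
    "XNOR": lambda bits: int((sum(bits) + 1) % 2),
}


def named_gate(name: str, n_inputs: int = 2) -> TruthGate:
    """Standard Boolean gate on {0,1} inputs (XOR/XNOR are parity for N>2)."""
    key = name.upper()
    if key not in _GATE_RULES:
        raise ValueError(f"unknown gate {name!r}; supported: {sorted(_GATE_RULES)}")
    if n_inputs < 2:
        raise ValueError("gates require at least 2 inputs")
    rule = _GATE_RULES[key]
    table = {
        bits: float(rule(bits)) for bits in itertools.product((0, 1), repeat=n_inputs)
    }
    return TruthGate(n_inputs=n_inputs, table=table)


def gate_from_outputs(outputs, n_inputs: int) -> TruthGate:
    """Gate from a flat output list over states in lexicographic order."""
    states = list(itertools.product((0, 1), repeat=n_inputs))
    if len(outputs) != len(states):
        raise ValueError(f"need {len(states)} outputs, got {len(outputs)}")
    return TruthGate(n_inputs=n_inputs, table=dict(zip(states, map(float, outputs))))


def gate_dataset(gate: TruthGate) -> ResponseDataset:
    """Exact uniform-ensemble dataset for a gate.

    Each of the 2^N states carries weight 2^-N.  Deterministic states
    contribute one row; stochastic states expand into a spike and a
    no-spike row with weights split by the state's spike probability.
    """
    rows, weights, ys = [], [], []
    w0 = 2.0 ** (-gate.n_inputs)
    for state in sorted(gate.table):
        p = gate.table[state]
        if p in (0.0, 1.0):
            rows.append(state)
            weights.append(w0)
            ys.append(p)
        else:
            rows.append(state); weights.append(w0 * p); ys.append(1.0)
            rows.append(state); weights.append(w0 * (1.0 - p)); ys.append(0.0)
    ens = InputEnsemble(inputs=np.array(rows, dtype=float), weights=np.array(weights))
    return ResponseDataset(ensemble=ens, responses=np.array(ys))


def enumerate_gates(n_inputs: int) -> Iterator[TruthGate]:
    """All 2^(2^N) deterministic truth tables, in deterministic order."""
    if n_inputs > 4:
        raise ValueError("enumeration is guarded to n_inputs <= 4")
    if n_inputs < 1:
        raise ValueError("n_inputs must be >= 1")
    states = list(itertools.product((0, 1), repeat=n_inputs))
    for outputs in itertools.product((0.0, 1.0), repeat=len(states)):
        yield TruthGate(n_inputs=n_inputs, table=dict(zip(states, outputs)))


def recode_pm1(data: ResponseDataset) -> ResponseDataset:
    """Re-encode {0,1} inputs as {-1,+1} (x -> 2x - 1); responses unchanged."""
    ens = data.ensemble
    return ResponseDataset(
        ensemble=InputEnsemble(inputs=2.0 * ens.inputs - 1.0, weights=ens.weights),
        responses=data.responses,
    )


def write_truth_table(gate: TruthGate, path) -> None:
    """One line per state: space-separated bits then output probability."""
    with open(path, "w") as fh:
        for state in sorted(gate.table):
            bits = " ".join(str(b) for b in state)
            fh.write(f"{bits} {gate.table[state]:g}\n")


def read_truth_table(path) -> TruthGate:
    table: dict[State, float] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            *bits, p = parts
            table[tuple(int(b) for b in bits)] = float(p)
    n = len(next(iter(table)))
    return TruthGate(n_inputs=n, table=table)
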