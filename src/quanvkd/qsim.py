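"""Dense statevector simulation of small qubit registers.

This module implements the quantum half of the quanvolution operator: RY
rotations, CNOT entanglers, seeded parameterized circuits ("random layers"),
Pauli-Z expectation values, and exact gradients via the parameter-shift rule.

Conventions
-----------
* Qubit 0 is the **most significant bit** of the computational-basis index:
  for 2 qubits the amplitudes are ordered |00>, |01>, |10>, |11> with the
  first bit belonging to qubit 0.
* Gates act on :class:`StateVector` objects and return new objects; the
  input state is never mutated.
* RY(theta) = [[cos(theta/2), -sin(theta/2)], [sin(theta/2), cos(theta/2)]].
* CNOT maps |c, t> -> |c, c XOR t>.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

__all__ = [
    "StateVector",
    "GateOp",
    "PQCParams",
    "init_state",
    "apply_gate",
    "apply_ry",
    "apply_cnot",
    "run_circuit",
    "expect_z",
    "build_pqc",
    "circuit_unitary",
    "parameter_shift_grad",
]

_NORM_ATOL = 1e-10


@dataclass(frozen=True)
class StateVector:
    """Pure state of an ``n_qubits`` register as a complex amplitude vector."""

    amplitudes: np.ndarray
    n_qubits: int

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=np.complex128)
        object.__setattr__(self, "amplitudes", amps)
        if self.n_qubits < 1:
            raise ValueError(f"n_qubits must be >= 1, got {self.n_qubits}")
        if amps.shape != (2**self.n_qubits,):
            raise ValueError(
                f"amplitude vector of length {amps.shape} does not match "
                f"{self.n_qubits} qubits (expected {2**self.n_qubits})"
            )
        norm = float(np.sum(np.abs(amps) ** 2))
        if abs(norm - 1.0) > 1e-8:
            raise ValueError(f"state norm^2 = {norm!r}, expected 1")

    @property
    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2


@dataclass(frozen=True)
class GateOp:
    """A single RY or CNOT gate.

    ``angle`` is meaningful only for RY; ``control`` only for CNOT.
    """

    kind: str
    target: int
    angle: float = 0.0
    control: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("RY", "CNOT"):
            raise ValueError(f"unknown gate kind {self.kind!r}")
        if self.kind == "CNOT":
            if self.control is None:
                raise ValueError("CNOT requires a control qubit")
            if self.control == self.target:
                raise ValueError("CNOT control and target must differ")


def _check_qubit(qubit: int, n_qubits: int) -> None:
    if not 0 <= qubit < n_qubits:
        raise ValueError(f"qubit index {qubit} out of range for {n_qubits} qubits")


def init_state(n_qubits: int) -> StateVector:
    """All-zeros register |0...0>: amplitude 1 at basis index 0."""
    if n_qubits < 1:
        raise ValueError(f"n_qubits must be >= 1, got {n_qubits}")
    amps = np.zeros(2**n_qubits, dtype=np.complex128)
    amps[0] = 1.0
    return StateVector(amps, n_qubits)


def _apply_ry_raw(amps: np.ndarray, theta: float, qubit: int, n_qubits: int) -> np.ndarray:
    # Reshape so the addressed qubit is the middle axis; qubit 0 is the MSB,
    # hence `qubit` leading axes of size 2 come before it.
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    shaped = amps.reshape(2**qubit, 2, -1)
    a0, a1 = shaped[:, 0, :], shaped[:, 1, :]
    out = np.empty_like(shaped)
    out[:, 0, :] = c * a0 - s * a1
    out[:, 1, :] = s * a0 + c * a1
    return out.reshape(-1)


def _apply_cnot_raw(amps: np.ndarray, control: int, target: int, n_qubits: int) -> np.ndarray:
    idx = np.arange(2**n_qubits)
    control_bit = (idx >> (n_qubits - 1 - control)) & 1
    source = idx ^ (control_bit << (n_qubits - 1 - target))
    return amps[source]


def apply_ry(state: StateVector, theta: float, qubit: int) -> StateVector:
    """Rotate one qubit about Y by ``theta`` radians."""
    _check_qubit(qubit, state.n_qubits)
    amps = _apply_ry_raw(state.amplitudes, theta, qubit, state.n_qubits)
    return StateVector(amps, state.n_qubits)


def apply_cnot(state: StateVector, control: int, target: int) -> StateVector:
    """Flip ``target`` on the basis states where ``control`` is 1."""
    _check_qubit(control, state.n_qubits)
    _check_qubit(target, state.n_qubits)
    if control == target:
        raise ValueError("CNOT control and target must differ")
    amps = _apply_cnot_raw(state.amplitudes, control, target, state.n_qubits)
    return StateVector(amps, state.n_qubits)


def apply_gate(state: StateVector, gate: GateOp) -> StateVector:
    if gate.kind == "RY":
        return apply_ry(state, gate.angle, gate.target)
    return apply_cnot(state, gate.control, gate.target)


def run_circuit(gates: Sequence[GateOp], n_qubits: int,
                initial: StateVector | None = None) -> StateVector:
    """Apply ``gates`` left-to-right, starting from |0...0> by default."""
    state = init_state(n_qubits) if initial is None else initial
    for gate in gates:
        state = apply_gate(state, gate)
    return state


def expect_z(state: StateVector, qubit: int) -> float:
    """Pauli-Z expectation of one qubit: +1 for |0>, -1 for |1>."""
    _check_qubit(qubit, state.n_qubits)
    idx = np.arange(2**state.n_qubits)
    bit = (idx >> (state.n_qubits - 1 - qubit)) & 1
    signs = 1.0 - 2.0 * bit
    return float(np.sum(signs * state.probabilities))


def circuit_unitary(gates: Sequence[GateOp], n_qubits: int) -> np.ndarray:
    """Full unitary of a gate list, built column by column.

    Column ``b`` is the circuit applied to the computational basis state
    ``|b>``.  Used by the quanvolution fast path to collapse a fixed
    parameterized block into one matrix; independent tests compare against an
    explicit Kronecker-product construction.
    """
    dim = 2**n_qubits
    unitary = np.empty((dim, dim), dtype=np.complex128)
    for b in range(dim):
        amps = np.zeros(dim, dtype=np.complex128)
        amps[b] = 1.0
        basis = StateVector(amps, n_qubits)
        unitary[:, b] = run_circuit(gates, n_qubits, initial=basis).amplitudes
    return unitary


@dataclass
class PQCParams:
    """Parameters of the entangling block ("random layers").

    Each layer applies an RY rotation on every qubit followed by a linear
    CNOT chain (qubit q controls qubit q+1); for 2 qubits that is a single
    CNOT 0->1.  Angles default to uniform draws on [0, 2*pi) from ``seed``.

    ``trainable`` marks whether the angles are meant to be optimized with the
    parameter-shift rule; frozen (False) is the default, in which case feature
    maps computed from this block may be cached.
    """

    n_layers: int = 2
    n_qubits: int = 2
    seed: int = 0
    thetas: np.ndarray | None = None
    trainable: bool = False

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")
        if self.thetas is None:
            rng = np.random.default_rng(self.seed)
            self.thetas = rng.uniform(0.0, 2.0 * np.pi, size=(self.n_layers, self.n_qubits))
        else:
            self.thetas = np.asarray(self.thetas, dtype=float)
            if self.thetas.shape != (self.n_layers, self.n_qubits):
                raise ValueError(
                    f"thetas shape {self.thetas.shape} does not match "
                    f"(n_layers, n_qubits) = {(self.n_layers, self.n_qubits)}"
                )

    def replace_theta(self, layer: int, qubit: int, value: float) -> "PQCParams":
        thetas = self.thetas.copy()
        thetas[layer, qubit] = value
        return PQCParams(self.n_layers, self.n_qubits, self.seed, thetas, self.trainable)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_layers": self.n_layers,
            "n_qubits": self.n_qubits,
            "seed": self.seed,
            "thetas": self.thetas.tolist(),
            "trainable": self.trainable,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PQCParams":
        thetas = d.get("thetas")
        return cls(
            n_layers=d["n_layers"],
            n_qubits=d.get("n_qubits", 2),
            seed=d.get("seed", 0),
            thetas=None if thetas is None else np.asarray(thetas, dtype=float),
            trainable=d.get("trainable", False),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PQCParams":
        path = Path(path)
        text = path.read_text()
        payload = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(payload)


def build_pqc(params: PQCParams) -> list[GateOp]:
    """Gate list of the parameterized block: per layer, RY on every qubit
    then the linear CNOT chain."""
    gates: list[GateOp] = []
    for layer in range(params.n_layers):
        for q in range(params.n_qubits):
            gates.append(GateOp("RY", target=q, angle=float(params.thetas[layer, q])))
        for q in range(params.n_qubits - 1):
            gates.append(GateOp("CNOT", target=q + 1, control=q))
    return gates


def parameter_shift_grad(
    circuit_builder: Callable[[PQCParams], Sequence[GateOp]],
    params: PQCParams,
    observable_qubit: int,
    theta_index: tuple[int, int],
) -> float:
    """Exact gradient d<Z_q>/d(theta) by the parameter-shift rule.

    The gradient of a Pauli expectation with respect to a rotation angle is
    ``[f(theta + pi/2) - f(theta - pi/2)] / 2`` where ``f`` evaluates the
    circuit built by ``circuit_builder`` at the shifted parameter set.
    """
    layer, qubit = theta_index
    if not (0 <= layer < params.n_layers and 0 <= qubit < params.n_qubits):
        raise ValueError(f"theta index {theta_index} out of range "
                         f"for shape {(params.n_layers, params.n_qubits)}")

    def f(theta_value: float) -> float:
        shifted = params.replace_theta(layer, qubit, theta_value)
        state = run_circuit(circuit_builder(shifted), params.n_qubits)
        return expect_z(state, observable_qubit)

    theta = float(params.thetas[layer, qubit])
    return (f(theta + np.pi / 2.0) - f(theta - np.pi / 2.0)) / 2.0
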