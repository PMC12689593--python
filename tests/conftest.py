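"""Shared fixtures and the independent dense-matrix circuit oracle."""

import numpy as np
import pytest

from quanvkd.qsim import GateOp

I2 = np.eye(2)
P0 = np.diag([1.0, 0.0])
P1 = np.diag([0.0, 1.0])
X = np.array([[0.0, 1.0], [1.0, 0.0]])


def ry_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    return np.array([[c, -s], [s, c]])


def kron_chain(factors) -> np.ndarray:
    out = np.eye(1)
    for f in factors:
        out = np.kron(out, f)
    return out


def gate_matrix_oracle(gate: GateOp, n_qubits: int) -> np.ndarray:
    """Dense matrix of a single gate by explicit Kronecker expansion.

    Qubit 0 is the most significant bit, so it is the *first* Kronecker
    factor.  CNOT uses the projector decomposition
    P0(control) x I + P1(control) x X(target).
    """
    if gate.kind == "RY":
        return kron_chain(ry_matrix(gate.angle) if q == gate.target else I2
                          for q in range(n_qubits))
    term0 = kron_chain(P0 if q == gate.control else I2 for q in range(n_qubits))
    term1 = kron_chain(
        P1 if q == gate.control else (X if q == gate.target else I2)
        for q in range(n_qubits))
    return term0 + term1


def circuit_matrix_oracle(gates, n_qubits: int) -> np.ndarray:
    """Product of gate matrices, applied left to right."""
    mat = np.eye(2**n_qubits)
    for gate in gates:
        mat = gate_matrix_oracle(gate, n_qubits) @ mat
    return mat


def random_circuit(rng: np.random.Generator, n_qubits: int,
                   n_gates: int) -> list[GateOp]:
    gates = []
    for _ in range(n_gates):
        if n_qubits > 1 and rng.uniform() < 0.4:
            control, target = rng.choice(n_qubits, size=2, replace=False)
            gates.append(GateOp("CNOT", target=int(target), control=int(control)))
        else:
            gates.append(GateOp("RY", target=int(rng.integers(n_qubits)),
                                angle=float(rng.uniform(0, 2 * np.pi))))
    return gates


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
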