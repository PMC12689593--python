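"""Quantum convolution: patch-wise 2-qubit circuits over an image ROI.

Each non-overlapping 2x2 patch is reduced to two scalars, the scalars are
encoded as RY rotation angles (scale pi, so the encoding is injective on
[0, 1]), the parameterized entangling block runs, and both qubits' Pauli-Z
expectations are measured.  Patch (i, j) of the grid lands at position
(i, j) of the output map, whose channel c holds qubit c's expectation; for a
14x14 ROI the result is the 7x7x2 quantum feature map with every entry in
[-1, 1].

With a frozen parameter block the map of a dataset is precomputed once and
cached (the block's unitary is collapsed to a single 4x4 matrix, so a whole
dataset batches into one matrix product).  For trainable parameters, exact
gradients of every map entry flow through the parameter-shift rule.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import qsim
from .preprocess import PreprocessConfig, extract_patches, reduce_patches
from .synthetic import LabeledDataset

__all__ = [
    "QuantumFeatureMap",
    "StaleCacheError",
    "encode_angles",
    "quanv_patch",
    "quanvolve",
    "quanvolve_dataset",
    "quanv_grad_thetas",
    "load_feature_archive",
]

logger = logging.getLogger(__name__)

DEFAULT_ANGLE_SCALE = np.pi


class StaleCacheError(RuntimeError):
    """A cached feature archive was produced under a different configuration."""


@dataclass(frozen=True)
class QuantumFeatureMap:
    """Per-image tensor of Pauli-Z expectations, shape (grid, grid, 2)."""

    values: np.ndarray
    source_id: int = -1
    pqc_seed: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError("feature map must be (grid, grid, channels)")
        if values.min() < -1.0 - 1e-9 or values.max() > 1.0 + 1e-9:
            raise ValueError("feature map entries must lie in [-1, 1]")


def encode_angles(values, scale: float = DEFAULT_ANGLE_SCALE) -> np.ndarray:
    """Map reduced patch values in [0, 1] to RY angles ``scale * value``.

    Out-of-range inputs are clipped with a warning rather than rejected, so a
    marginally out-of-range float from resampling cannot abort a run.
    """
    values = np.asarray(values, dtype=float)
    if values.min() < 0.0 or values.max() > 1.0:
        warnings.warn("encoder inputs outside [0, 1]; clipping", stacklevel=2)
        values = np.clip(values, 0.0, 1.0)
    return scale * values


def _encoded_states(angles: np.ndarray) -> np.ndarray:
    """Statevectors of RY(a0) x RY(a1) applied to |00>, batched.

    ``angles`` has shape (n, 2); the output is (n, 4) with qubit 0 as the
    most significant bit, matching the simulator's convention.
    """
    half = angles / 2.0
    c0, s0 = np.cos(half[:, 0]), np.sin(half[:, 0])
    c1, s1 = np.cos(half[:, 1]), np.sin(half[:, 1])
    return np.stack([c0 * c1, c0 * s1, s0 * c1, s0 * s1], axis=1).astype(np.complex128)


_Z_SIGNS = {
    0: np.array([1.0, 1.0, -1.0, -1.0]),  # qubit 0 = MSB
    1: np.array([1.0, -1.0, 1.0, -1.0]),
}


def quanv_patch(values, pqc: qsim.PQCParams,
                scale: float = DEFAULT_ANGLE_SCALE) -> tuple[float, float]:
    """Run one patch through the 2-qubit circuit; return (<Z0>, <Z1>).

    The circuit is the two encoding rotations followed by the parameterized
    block; the result is deterministic given ``pqc``.
    """
    angles = encode_angles(values, scale)
    gates = [qsim.GateOp("RY", target=0, angle=float(angles[0])),
             qsim.GateOp("RY", target=1, angle=float(angles[1]))]
    gates += qsim.build_pqc(pqc)
    state = qsim.run_circuit(gates, 2)
    return (qsim.expect_z(state, 0), qsim.expect_z(state, 1))


def _quanv_values(reduced: np.ndarray, pqc: qsim.PQCParams,
                  scale: float = DEFAULT_ANGLE_SCALE) -> np.ndarray:
    """Batched circuit evaluation: (n, 2) reduced values -> (n, 2) expectations.

    The fixed parameter block collapses to one 4x4 unitary (built from the
    simulator itself, column by column), so the batch is a single product.
    """
    angles = encode_angles(reduced, scale)
    states = _encoded_states(angles)
    if pqc.n_layers > 0:
        unitary = qsim.circuit_unitary(qsim.build_pqc(pqc), 2)
        states = states @ unitary.T
    probs = np.abs(states) ** 2
    return np.stack([probs @ _Z_SIGNS[0], probs @ _Z_SIGNS[1]], axis=1)


def quanvolve(roi: np.ndarray, pqc: qsim.PQCParams,
              reduction: str = "row_mean",
              scale: float = DEFAULT_ANGLE_SCALE) -> QuantumFeatureMap:
    """Quantum-convolve one ROI into its feature map.

    Patch (i, j) maps to output position (i, j); channel c is qubit c's
    Pauli-Z expectation.  Requires an even ROI side.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.shape[0] % 2 != 0 or roi.shape[0] != roi.shape[1]:
        raise ValueError(f"ROI must be square with even side, got {roi.shape}")
    grid = roi.shape[0] // 2
    patches = extract_patches(roi, 2)
    reduced = reduce_patches(patches, reduction)
    expectations = _quanv_values(reduced, pqc, scale)
    values = expectations.reshape(grid, grid, 2)
    return QuantumFeatureMap(values, pqc_seed=pqc.seed)


def quanvolve_images(rois: np.ndarray, pqc: qsim.PQCParams,
                     reduction: str = "row_mean",
                     scale: float = DEFAULT_ANGLE_SCALE) -> np.ndarray:
    """Vectorized :func:`quanvolve` over a stack of ROIs -> (n, g, g, 2)."""
    rois = np.asarray(rois, dtype=float)
    n, side, _ = rois.shape
    grid = side // 2
    tiled = rois.reshape(n, grid, 2, grid, 2).transpose(0, 1, 3, 2, 4)
    patches = tiled.reshape(n * grid * grid, 2, 2)
    reduced = reduce_patches(patches, reduction)
    expectations = _quanv_values(reduced, pqc, scale)
    return expectations.reshape(n, grid, grid, 2)


def _config_hash(pqc: qsim.PQCParams, config: PreprocessConfig, scale: float) -> str:
    payload = {
        "pqc": pqc.to_dict(),
        "roi_side": config.roi_side,
        "patch_side": config.patch_side,
        "reduction": config.reduction,
        "scale": scale,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def quanvolve_dataset(dataset: LabeledDataset, pqc: qsim.PQCParams,
                      config: PreprocessConfig,
                      cache_path: str | Path | None = None,
                      scale: float = DEFAULT_ANGLE_SCALE) -> np.ndarray:
    """Feature maps for a whole dataset, optionally cached on disk.

    Images are pushed through the deterministic front end (resize, center
    crop to the ROI) and the batched circuit.  The archive embeds the
    configuration hash (parameter-block seed and angles, reduction, geometry)
    so a stale cache is detected rather than silently reused; caching is
    refused for trainable parameter blocks, whose angles change under
    optimization.
    """
    from .preprocess import prepare_roi

    want_hash = _config_hash(pqc, config, scale)
    if cache_path is not None and pqc.trainable:
        raise ValueError("caching is disabled for trainable parameter blocks")
    if cache_path is not None and Path(cache_path).exists():
        maps, got_hash = _read_archive(cache_path)
        if got_hash != want_hash:
            raise StaleCacheError(
                f"cached archive hash {got_hash} != current config hash {want_hash}"
            )
        if len(maps) == len(dataset):
            logger.info("reusing cached feature maps from %s", cache_path)
            return maps

    rois = np.stack([prepare_roi(img, config) for img in dataset.images])
    maps = quanvolve_images(rois, pqc, config.reduction, scale)
    if cache_path is not None:
        meta = json.dumps({"config_hash": want_hash, "pqc": pqc.to_dict(),
                           "reduction": config.reduction,
                           "roi_side": config.roi_side})
        np.savez_compressed(Path(cache_path), maps=maps,
                            meta=np.asarray(meta))
    return maps


def _read_archive(path: str | Path) -> tuple[np.ndarray, str]:
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return z["maps"], meta["config_hash"]


def load_feature_archive(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a cached feature-map archive and its embedded metadata."""
    with np.load(Path(path), allow_pickle=False) as z:
        return z["maps"], json.loads(str(z["meta"]))


def quanv_grad_thetas(roi: np.ndarray, pqc: qsim.PQCParams,
                      reduction: str = "row_mean",
                      scale: float = DEFAULT_ANGLE_SCALE) -> np.ndarray:
    """Parameter-shift gradients of every map entry w.r.t. every block angle.

    Returns shape (n_layers, n_qubits, grid, grid, 2): exact derivatives
    d<Z_c>(patch i, j) / d theta[l, q], the quantities a joint
    quantum-classical optimizer feeds the chain rule in trainable mode.
    """
    roi = np.asarray(roi, dtype=float)
    grid = roi.shape[0] // 2
    patches = extract_patches(roi, 2)
    reduced = reduce_patches(patches, reduction)
    grads = np.zeros((pqc.n_layers, pqc.n_qubits, grid, grid, 2))
    shift = np.pi / 2.0
    for layer in range(pqc.n_layers):
        for qubit in range(pqc.n_qubits):
            theta = float(pqc.thetas[layer, qubit])
            plus = _quanv_values(reduced, pqc.replace_theta(layer, qubit, theta + shift), scale)
            minus = _quanv_values(reduced, pqc.replace_theta(layer, qubit, theta - shift), scale)
            grads[layer, qubit] = ((plus - minus) / 2.0).reshape(grid, grid, 2)
    return grads
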