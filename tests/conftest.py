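"""Shared fixtures: small phantoms, toy datasets, brute-force oracles.

The oracles here deliberately re-derive every statistic with naive
explicit loops, independent of the vectorized implementation paths they
are used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import sliceqc as sq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def brute_force_deviation(means: np.ndarray, directions: np.ndarray,
                          antipodal: bool = True, normalize: bool = True,
                          floor: float = 0.0) -> np.ndarray:
    """Naive double-loop evaluation of the pairwise deviation average."""
    V, Z = means.shape
    delta = np.full((V, Z), np.nan)
    background = [
        z for z in range(Z)
        if any(np.isnan(means[i, z]) or means[i, z] < floor for i in range(V))
    ]
    for j in range(V):
        for z in range(Z):
            if z in background:
                continue
            num = 0.0
            wsum = 0.0
            for i in range(V):
                if i == j:
                    continue
                dot = float(np.dot(directions[i], directions[j]))
                w = abs(dot) if antipodal else max(dot, 0.0)
                s = means[i, z] + means[j, z]
                dev = abs(means[i, z] - means[j, z]) / s if s > 0 else 0.0
                num += w * dev
                wsum += w
            delta[j, z] = num / wsum if normalize else num / (V - 1)
    return delta


def brute_force_outlier_counts(data: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Naive per-voxel weighted mean/SD outlier counting."""
    X, Y, Z, V = data.shape
    counts = np.zeros((V, Z), dtype=int)
    for j in range(V):
        w = np.array([
            0.0 if i == j else abs(float(np.dot(directions[i], directions[j])))
            for i in range(V)
        ])
        w = w / w.sum()
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    s = data[x, y, z]
                    m = float(np.dot(w, s))
                    var = float(np.dot(w, (s - m) ** 2))
                    if abs(s[j] - m) > 2.0 * np.sqrt(max(var, 0.0)):
                        counts[j, z] += 1
    return counts


def brute_force_tensor_fit(data: np.ndarray, gradients: sq.GradientTable):
    """Per-voxel normal-equations solve of the log-linear tensor model."""
    g = gradients.directions
    b = gradients.bvalues
    V = len(gradients)
    X = np.zeros((V, 7))
    for v in range(V):
        gx, gy, gz = g[v]
        X[v] = [-b[v] * gx * gx, -b[v] * gy * gy, -b[v] * gz * gz,
                -2 * b[v] * gx * gy, -2 * b[v] * gx * gz, -2 * b[v] * gy * gz, 1.0]
    XtX_inv_Xt = np.linalg.inv(X.T @ X) @ X.T
    spatial = data.shape[:3]
    tensor = np.zeros(spatial + (6,))
    s0 = np.zeros(spatial)
    for idx in np.ndindex(spatial):
        beta = XtX_inv_Xt @ np.log(data[idx])
        tensor[idx] = beta[:6]
        s0[idx] = np.exp(beta[6])
    return tensor, s0


def random_spd_tensor(rng: np.random.Generator) -> np.ndarray:
    """Random SPD tensor with eigenvalues in the physiological range.

    The largest eigenvalue is drawn from [1.0, 2.5]·10⁻³ mm²/s so that
    b·λ stays ≤ ~2.5 and the simulated signal never falls near the
    log-transform clamp floor.
    """
    A = rng.normal(size=(3, 3))
    M = A @ A.T + 0.1 * np.eye(3)
    lam_max = np.linalg.eigvalsh(M)[-1]
    return M * (rng.uniform(1.0e-3, 2.5e-3) / lam_max)


@pytest.fixture(scope="session")
def small_scheme() -> sq.GradientTable:
    """12 high-b directions + 2 low-b anchors; rank-7 design."""
    return sq.default_gradient_scheme(n_high=12, n_low=2, b_high=1000.0, b_low=100.0)


@pytest.fixture(scope="session")
def small_phantom_truth():
    spec = sq.default_phantom_spec(grid_shape=(16, 16, 12))
    return sq.build_phantom(spec)


@pytest.fixture(scope="session")
def noisefree_small_dataset(small_phantom_truth, small_scheme) -> sq.DWIDataset:
    return sq.simulate_signal(small_phantom_truth, small_scheme, snr=None)


@pytest.fixture()
def toy_dataset() -> sq.DWIDataset:
    """Deterministic 4×4×4 dataset with 6 directional volumes."""
    rng = np.random.default_rng(7)
    dirs = random_unit_vectors(6, rng)
    gt = sq.GradientTable(dirs, np.full(6, 1000.0))
    data = 100.0 + 10.0 * rng.random((4, 4, 4, 6))
    return sq.DWIDataset(data, np.array([2.3, 2.3, 2.3]), gt)
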