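"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths they check: the SASA oracle uses a
random (seeded) dense point cloud and an all-pairs occlusion loop instead
of the golden-spiral set with a KD-tree; the superposition oracle minimises
RMSD numerically over rotation parameters instead of using the SVD.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def sasa_dense_grid(coords: np.ndarray, radii: np.ndarray,
                    probe: float = 1.4, n_points: int = 100_000,
                    seed: int = 0) -> float:
    """Total SASA by Monte-Carlo integration with a dense random point set."""
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    radii = np.asarray(radii, dtype=np.float64).reshape(-1)
    rng = np.random.default_rng(seed)
    total = 0.0
    expanded = radii + probe
    for i in range(coords.shape[0]):
        raw = rng.normal(size=(n_points, 3))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * raw
        exposed = np.ones(n_points, dtype=bool)
        for j in range(coords.shape[0]):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= expanded[j] ** 2
        total += 4.0 * np.pi * expanded[i] ** 2 * exposed.mean()
    return total


def buried_surface_dense_grid(coords_a, radii_a, coords_b, radii_b,
                              probe: float = 1.4, n_points: int = 100_000,
                              seed: int = 0) -> float:
    """Per-side buried area via the dense-grid SASA integrator."""
    a = sasa_dense_grid(coords_a, radii_a, probe, n_points, seed)
    b = sasa_dense_grid(coords_b, radii_b, probe, n_points, seed + 1)
    ab = sasa_dense_grid(np.concatenate([coords_a, coords_b]),
                         np.concatenate([radii_a, radii_b]),
                         probe, n_points, seed + 2)
    return max(0.0, 0.5 * (a + b - ab))


def min_rmsd_numeric(mobile: np.ndarray, reference: np.ndarray,
                     n_starts: int = 8, seed: int = 0) -> float:
    """Minimum RMSD over all proper rigid motions, by numerical optimisation.

    The optimal translation matches centroids, so only the rotation (as a
    rotation vector) is optimised, from several starting points.
    """
    X = np.asarray(mobile, dtype=np.float64)
    Y = np.asarray(reference, dtype=np.float64)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec)
        diff = R.apply(Xc) - Yc
        return np.mean(np.sum(diff * diff, axis=1))

    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [np.zeros(3)] + [rng.normal(size=3) * np.pi
                              for _ in range(n_starts - 1)]
    for x0 in starts:
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 20_000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix from a seeded generator."""
    quat = rng.normal(size=4)
    quat /= np.linalg.norm(quat)
    return Rotation.from_quat(quat).as_matrix()


def random_rigid_motion(rng: np.random.Generator,
                        shift_scale: float = 20.0):
    """(R, t) with uniform rotation and Gaussian translation."""
    return random_rotation(rng), rng.normal(scale=shift_scale, size=3)
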