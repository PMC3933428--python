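"""Solvent-accessible and buried surface areas (Shrake–Rupley).

SASA is computed by counting unoccluded test points on a deterministic
golden-section-spiral point set placed on each atom's solvent-accessible
sphere of radius ``r_atom + probe``.  Buried surface between two disjoint
groups is the per-side interface area

    BSA = (SASA(A alone) + SASA(B alone) - SASA(A ∪ B)) / 2 .

The implementation subtracts per-atom areas pairwise before summing, so two
groups that cannot occlude each other (every cross-group pair farther apart
than ``r_i + r_j + 2·probe``) yield a buried area of exactly 0.0 — the
zero-vs-nonzero distinction is what the valency classifier rests on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateGeometryWarning, EmptySelectionError

DEFAULT_PROBE_RADIUS = 1.4   # Å, water
DEFAULT_N_POINTS = 960


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors from the golden-section spiral.

    Deterministic: the same ``n`` always yields bit-identical points.
    """
    if n < 32:
        raise ValueError("need at least 32 sphere points")
    k = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class SasaResult:
    """Per-atom and total solvent-accessible surface area (Å²)."""

    per_atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class BuriedSurface:
    """Per-side buried area between two atom groups (Å²)."""

    value: float
    group_a_area: float
    group_b_area: float
    complex_area: float


def _check_geometry(coords: np.ndarray) -> None:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(1e-9)
    if pairs:
        i, j = next(iter(pairs))
        warnings.warn(
            f"atoms {i} and {j} share identical coordinates; "
            "areas remain defined", DegenerateGeometryWarning)


def _per_atom_sasa(coords: np.ndarray, radii: np.ndarray, probe: float,
                   points: np.ndarray) -> np.ndarray:
    """Exposed-point-fraction areas for each atom against all others."""
    n_atoms = coords.shape[0]
    n_pts = points.shape[0]
    expanded = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n_atoms, dtype=np.float64)
    for i in range(n_atoms):
        neighbors = tree.query_ball_point(coords[i], expanded[i] + expanded.max())
        neighbors = [j for j in neighbors
                     if j != i
                     and np.linalg.norm(coords[j] - coords[i])
                     < expanded[i] + expanded[j]]
        sphere_area = 4.0 * np.pi * expanded[i] ** 2
        if not neighbors:
            areas[i] = sphere_area
            continue
        test = coords[i] + expanded[i] * points          # (n_pts, 3)
        exposed = np.ones(n_pts, dtype=bool)
        nb_coords = coords[neighbors]                    # (m, 3)
        nb_cut2 = expanded[neighbors] ** 2               # (m,)
        # occlusion: test point inside any neighbour's expanded sphere
        d2 = np.sum((test[:, None, :] - nb_coords[None, :, :]) ** 2, axis=2)
        exposed = ~np.any(d2 < nb_cut2[None, :] - 1e-12, axis=1)
        areas[i] = sphere_area * np.count_nonzero(exposed) / n_pts
    return areas


def sasa(coords: np.ndarray, radii: np.ndarray,
         probe_radius: float = DEFAULT_PROBE_RADIUS,
         n_sphere_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Shrake–Rupley SASA of a set of spheres.

    Parameters
    ----------
    coords : (N, 3) array, Å
    radii : (N,) array of van der Waals radii, Å, all positive
    probe_radius : probe sphere radius, Å (1.4 = water)
    n_sphere_points : test points per atom (≥ 32); the point set is the
        deterministic golden-section spiral, so results are reproducible.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 3)
    radii = np.asarray(radii, dtype=np.float64).reshape(-1)
    if coords.shape[0] == 0:
        raise EmptySelectionError("SASA of an empty atom set")
    if coords.shape[0] != radii.shape[0]:
        raise ValueError("coords and radii length mismatch")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    _check_geometry(coords)
    points = sphere_points(n_sphere_points)
    areas = _per_atom_sasa(coords, radii, float(probe_radius), points)
    return SasaResult(per_atom_area=areas, probe_radius=float(probe_radius),
                      n_sphere_points=int(n_sphere_points))


def buried_surface(coords_a: np.ndarray, radii_a: np.ndarray,
                   coords_b: np.ndarray, radii_b: np.ndarray,
                   probe_radius: float = DEFAULT_PROBE_RADIUS,
                   n_sphere_points: int = DEFAULT_N_POINTS) -> BuriedSurface:
    """Per-side buried surface area between two disjoint atom groups.

    Symmetric in (A, B).  Exactly 0.0 when no cross-group atom pair is
    within occlusion range; tiny negative round-off is clamped to 0.
    """
    ca = np.asarray(coords_a, dtype=np.float64).reshape(-1, 3)
    cb = np.asarray(coords_b, dtype=np.float64).reshape(-1, 3)
    ra = np.asarray(radii_a, dtype=np.float64).reshape(-1)
    rb = np.asarray(radii_b, dtype=np.float64).reshape(-1)
    if ca.shape[0] == 0 or cb.shape[0] == 0:
        raise EmptySelectionError("buried surface of an empty group")
    points = sphere_points(n_sphere_points)
    probe = float(probe_radius)
    iso_a = _per_atom_sasa(ca, ra, probe, points)
    iso_b = _per_atom_sasa(cb, rb, probe, points)
    coords = np.concatenate([ca, cb])
    radii = np.concatenate([ra, rb])
    _check_geometry(coords)
    cplx = _per_atom_sasa(coords, radii, probe, points)
    na = ca.shape[0]
    # pairwise per-atom differences: exactly zero when occlusion is unchanged
    lost = float(np.sum(iso_a - cplx[:na]) + np.sum(iso_b - cplx[na:]))
    value = max(0.0, 0.5 * lost)
    return BuriedSurface(value=value,
                         group_a_area=float(iso_a.sum()),
                         group_b_area=float(iso_b.sum()),
                         complex_area=float(cplx.sum()))
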