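"""Least-squares rigid superposition (Kabsch) and selection-based RMSD.

The rotation is obtained from the SVD of the coordinate covariance matrix
with the usual reflection correction (the sign of the smallest singular
vector is flipped when the raw solution has determinant -1), so every
returned rotation is proper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, PairingError
from .structure_io import Ensemble, Selection, Structure

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rotation plus translation: ``x -> R @ x + t`` (Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 1.0 - 1e-6:
            raise ValueError("rotation matrix is not proper (det != +1)")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=np.float64)
        return c @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` then self."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation
                              + self.translation)

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Å) against a fixed reference frame."""

    values: np.ndarray
    frame_times: np.ndarray
    selection_used: Selection

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times length mismatch")
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be nonnegative")

    def to_csv(self, sink) -> None:
        import pandas as pd
        df = pd.DataFrame({
            "frame": np.arange(len(self.values)),
            "time_ns": self.frame_times,
            "rmsd_A": self.values,
        })
        df.to_csv(sink, index=False, float_format="%.6f")


def kabsch_fit(mobile: np.ndarray,
               reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Point sets are paired index-to-index.  Returns the minimising proper
    transform and the residual RMSD (Å) after applying it.
    """
    X = np.asarray(mobile, dtype=np.float64)
    Y = np.asarray(reference, dtype=np.float64)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise PairingError("mobile and reference must be matching N×3 arrays")
    n = X.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xc, Y - yc
    # collinear (rank < 2) point sets leave the rotation underdetermined
    scale = max(np.abs(Xc).max(), np.abs(Yc).max(), 1e-12)
    if (np.linalg.matrix_rank(Xc, tol=1e-8 * scale * np.sqrt(n)) < 2
            or np.linalg.matrix_rank(Yc, tol=1e-8 * scale * np.sqrt(n)) < 2):
        raise DegenerateGeometryError(
            "point set is collinear; rotation is not uniquely determined"
        )
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    transform = RigidTransform(R, t)
    resid = transform.apply(X) - Y
    rmsd = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    return transform, rmsd


def rmsd_after_fit(a: Structure, b: Structure, selection: Selection) -> float:
    """RMSD between ``a`` and ``b`` after superposing on ``selection``.

    The selection must resolve to identical atom identity lists in both
    structures; the fit and the reported RMSD use the same atoms.
    """
    ia = selection.resolve(a)
    ib = selection.resolve(b)
    ident_a = [a.identity()[i] for i in ia]
    ident_b = [b.identity()[i] for i in ib]
    if ident_a != ident_b:
        raise PairingError(
            "selection resolves to different atom identity lists in a and b"
        )
    _, rmsd = kabsch_fit(a.coord[ia], b.coord[ib])
    return rmsd


def rmsd_vs_initial(ensemble: Ensemble, selection: Selection) -> RmsdSeries:
    """RMSD of every frame against frame 0 over ``selection``.

    The reference is the first frame of the trajectory (the initial
    conformation), not a running average.  ``values[0]`` is exactly zero.
    """
    ref = ensemble.frames[0]
    values = np.empty(len(ensemble), dtype=np.float64)
    values[0] = 0.0
    for k in range(1, len(ensemble)):
        values[k] = rmsd_after_fit(ensemble.frames[k], ref, selection)
    times = (ensemble.frame_times if ensemble.frame_times is not None
             else np.arange(len(ensemble), dtype=np.float64))
    return RmsdSeries(values=values, frame_times=times,
                      selection_used=selection)
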