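"""Elementary geometric kernels: ring planes, angles, superposition, RMSD.

All coordinates are in Angstrom, all angles in degrees. The kernels are
deliberately free of any trajectory or interaction semantics; the detectors
in :mod:`ifpkit.interactions` compose them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ifpkit.errors import GeometryError

__all__ = [
    "RingGeometry",
    "ring_geometry",
    "angle_vector_to_normal",
    "kabsch_superpose",
    "rmsd",
]

#: out-of-plane RMS above which a declared aromatic ring is suspicious
PLANARITY_WARN_RMS = 0.3


@dataclass(frozen=True)
class RingGeometry:
    """Best-fit plane of an aromatic ring.

    Attributes
    ----------
    centroid : (3,) ndarray
        Unweighted mean of the ring atom positions (Angstrom).
    normal : (3,) ndarray
        Unit normal of the least-squares ring plane. The sign is
        canonicalized (positive component on the axis of largest absolute
        value; ties broken x before y before z) so results are reproducible;
        detectors only ever use the fold-invariant angle, so the sign never
        affects detection.
    planarity_rms : float
        RMS out-of-plane deviation of the ring atoms (Angstrom).
    """

    centroid: np.ndarray
    normal: np.ndarray
    planarity_rms: float


def ring_geometry(ring_coords) -> RingGeometry:
    """Centroid, unit plane normal and planarity RMS of a ring atom set.

    The normal is the principal axis of least variance of the centered
    coordinates (eigenvector of the smallest eigenvalue of the 3x3
    covariance), which is robust to ring puckering.

    Parameters
    ----------
    ring_coords : array-like, shape (n, 3) with n >= 3
        Ring atom positions in Angstrom; must not be collinear.

    Raises
    ------
    GeometryError
        For fewer than 3 points or (near-)collinear points.
    """
    coords = np.asarray(ring_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 3:
        raise GeometryError(
            f"ring needs >=3 points of dimension 3, got shape {coords.shape}"
        )
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    # collinear points: two vanishing eigenvalues (only one spread direction)
    scale = max(evals[-1], 1e-30)
    if evals[1] / scale < 1e-12:
        raise GeometryError("ring atoms are collinear or coincident")
    normal = evecs[:, 0]
    normal = _canonical_sign(normal)
    planarity_rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    if planarity_rms > PLANARITY_WARN_RMS:
        warnings.warn(
            f"declared aromatic ring has planarity RMS {planarity_rms:.2f} A "
            f"(> {PLANARITY_WARN_RMS} A)",
            stacklevel=2,
        )
    return RingGeometry(centroid=centroid, normal=normal,
                        planarity_rms=planarity_rms)


def _canonical_sign(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its largest-magnitude component is positive (tie: x<y<z)."""
    idx = int(np.argmax(np.abs(v)))
    # resolve near-ties deterministically toward the lowest axis index
    for i in range(3):
        if abs(abs(v[i]) - abs(v[idx])) < 1e-12:
            idx = i
            break
    if v[idx] < 0:
        return -v
    return v.copy()


def angle_vector_to_normal(normal, v) -> float:
    """Folded angle in degrees, in [0, 90], between a plane normal and a vector.

    Computed as ``arccos(|n . v/|v||)`` so the result is independent of the
    normal's sign convention.
    """
    normal = np.asarray(normal, dtype=float)
    v = np.asarray(v, dtype=float)
    nv = np.linalg.norm(v)
    if nv <= 0.0:
        raise GeometryError("zero-length vector has no angle to a plane normal")
    nn = np.linalg.norm(normal)
    cosang = abs(float(np.dot(normal, v)) / (nn * nv))
    return float(np.degrees(np.arccos(min(cosang, 1.0))))


def kabsch_superpose(mobile, reference):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, fitted_rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    least-squares sense, with ``rotation`` a proper rotation (det = +1).

    Parameters
    ----------
    mobile, reference : array-like, shape (n, 3), n >= 3
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(
            f"point count mismatch: mobile {P.shape} vs reference {Q.shape}"
        )
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise GeometryError("superposition needs >=3 points of dimension 3")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    fitted = P @ R.T + t
    return R, t, rmsd(fitted, Q)


def rmsd(coords_a, coords_b) -> float:
    """Root-mean-square deviation between two equally sized point sets.

    No superposition is performed; use :func:`kabsch_superpose` first if a
    best-fit alignment is wanted.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3 or A.shape[0] < 1:
        raise GeometryError(
            f"RMSD needs two equal (n,3) coordinate sets, got {A.shape} vs {B.shape}"
        )
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
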