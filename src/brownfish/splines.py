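"""Low-rank thin-plate regression spline basis for a 2-D spatial trend.

Large-scale spatial gradients in lake surveys (productivity, climate) are
absorbed by a smooth trend surface f(u, v) over easting/northing.  The
basis is the classic thin-plate construction: a degree-1 polynomial null
space {1, u, v} plus radial kernel columns eta(r) = r^2 log r about a
space-filling subset of knots, reparameterized so the kernel coefficients
are orthogonal to the polynomial space at the knots.  On that subspace the
bending-energy matrix is positive semi-definite, giving a valid wiggliness
penalty.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import null_space
from scipy.spatial.distance import cdist


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """Thin-plate radial kernel r^2 * log(r), with eta(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    pos = r > 0
    out[pos] = r[pos] ** 2 * np.log(r[pos])
    return out


def farthest_point_knots(coords: np.ndarray, k: int) -> np.ndarray:
    """Deterministic space-filling knot selection.

    Starts from the point nearest the centroid and greedily adds the point
    farthest from the current knot set (maximin design).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    centroid = coords.mean(axis=0)
    start = int(np.argmin(((coords - centroid) ** 2).sum(axis=1)))
    chosen = [start]
    d = np.linalg.norm(coords - coords[start], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return coords[chosen]


def build_thinplate_basis(
    coords: np.ndarray, n_basis: int = 20
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Design matrix and penalty for a rank-``n_basis`` thin-plate smooth.

    Parameters
    ----------
    coords : (n, 2) array
        Planar easting/northing pairs; duplicates are removed (with a
        warning) before knot selection.
    n_basis : int
        Total basis dimension including the {1, u, v} null space, so
        ``n_basis >= 3``; ``n_basis = 3`` yields exactly the plane.

    Returns
    -------
    design : (n, n_basis) array
        Columns ``[1, u, v, smooth...]``.
    penalty : (n_basis, n_basis) array
        Zero on the polynomial block; the reduced bending-energy matrix
        Z' E Z on the smooth block.  Symmetric PSD.
    info : dict
        Knots and the reparameterization matrix, needed to evaluate the
        fitted surface at new locations.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    if n_basis < 3:
        raise ValueError("n_basis must be at least 3 (the {1,u,v} null space)")
    uniq = np.unique(coords, axis=0)
    if uniq.shape[0] < coords.shape[0]:
        warnings.warn("duplicate coordinates removed before knot selection")
    if uniq.shape[0] < n_basis:
        raise ValueError("need at least n_basis distinct coordinate pairs")

    k = n_basis - 3  # kernel columns after reparameterization
    n = coords.shape[0]
    poly = np.column_stack([np.ones(n), coords])
    if k == 0:
        return poly, np.zeros((3, 3)), {"knots": np.empty((0, 2)), "Z": np.empty((0, 0))}

    # one extra knot per polynomial constraint keeps k kernel columns
    knots = farthest_point_knots(uniq, k + 3)
    E = tps_kernel(cdist(knots, knots))
    T = np.column_stack([np.ones(len(knots)), knots])
    Z = null_space(T.T)  # (k+3, k): kernel coefs orthogonal to the plane
    smooth = tps_kernel(cdist(coords, knots)) @ Z
    design = np.column_stack([poly, smooth])

    S = Z.T @ E @ Z
    S = 0.5 * (S + S.T)
    # bending energy is PSD on the constrained subspace; clear numerical noise
    w, V = np.linalg.eigh(S)
    S = (V * np.clip(w, 0.0, None)) @ V.T
    penalty = np.zeros((n_basis, n_basis))
    penalty[3:, 3:] = 0.5 * (S + S.T)
    return design, penalty, {"knots": knots, "Z": Z}


def evaluate_thinplate(coords_new: np.ndarray, info: dict) -> np.ndarray:
    """Evaluate the basis (same column layout) at new coordinates."""
    coords_new = np.asarray(coords_new, dtype=float)
    poly = np.column_stack([np.ones(len(coords_new)), coords_new])
    Z = info["Z"]
    if Z.size == 0:
        return poly
    smooth = tps_kernel(cdist(coords_new, info["knots"])) @ Z
    return np.column_stack([poly, smooth])
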