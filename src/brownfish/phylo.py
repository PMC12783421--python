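"""Phylogenetic and spatial covariance structures for the community model.

Under Brownian trait evolution the covariance between two species equals
the branch length shared from the root to their most recent common
ancestor; for an ultrametric tree the diagonal (root-to-tip depth) is
constant.  Spatial dependence between lakes decays exponentially with
distance, using great-circle distance for geographic coordinates and
Euclidean distance for planar synthetic ones.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np
from scipy.spatial.distance import cdist


def phylo_vcv(tree: "dendropy.Tree | str", taxa: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion variance-covariance matrix of a rooted tree.

    Entry (s, t) is the root depth of MRCA(s, t), computed as
    ``(depth_s + depth_t - patristic(s, t)) / 2``; the diagonal is each
    tip's root-to-tip distance.  Accepts a dendropy tree or a newick
    string.  Returns the matrix and the tip-label order used.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    lengths = [e.length for e in tree.preorder_edge_iter() if e.head_node.parent_node]
    if any(l is None for l in lengths):
        raise ValueError("tree must have branch lengths on all edges")
    if sum(lengths) == 0:
        raise ValueError("tree has zero total branch length")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if taxa is not None:
        if set(taxa) != set(labels):
            raise ValueError("taxa do not match tree tip labels")
        labels = list(taxa)
    depth = {lf.taxon.label: lf.root_distance for lf in tree.leaf_node_iter()}
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        V[i, i] = depth[a]
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(tx[a], tx[b])
            V[i, j] = V[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return V, labels


def blended_species_cov(V: np.ndarray, rho: float) -> np.ndarray:
    """``rho * phylogeny + (1 - rho) * identity`` correlation blend.

    V is first scaled to unit diagonal (a correlation-like structure) so
    rho in [0, 1] interpolates between full phylogenetic signal and
    independence.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    d = np.sqrt(np.diag(V))
    C = V / np.outer(d, d)
    return rho * C + (1.0 - rho) * np.eye(V.shape[0])


_EARTH_RADIUS_KM = 6371.0


def haversine_distances(latlon: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) from (lat, lon) degrees."""
    ll = np.radians(np.asarray(latlon, dtype=float))
    lat = ll[:, 0][:, None]
    lon = ll[:, 1][:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def spatial_correlation(coords: np.ndarray, range_param: float,
                        geodesic: bool = False, jitter: float = 1e-8) -> np.ndarray:
    """Exponential-decay spatial correlation ``exp(-d / range)``.

    ``geodesic=True`` treats ``coords`` as (lat, lon) in degrees and uses
    great-circle distance; otherwise planar Euclidean distance.  Duplicate
    points make the matrix singular; a small diagonal jitter is added with
    a warning in that case.  The diagonal is exactly 1 on return (jitter is
    folded in multiplicatively).
    """
    if range_param <= 0:
        raise ValueError("range_param must be positive")
    coords = np.asarray(coords, dtype=float)
    d = haversine_distances(coords) if geodesic else cdist(coords, coords)
    C = np.exp(-d / range_param)
    off = ~np.eye(len(C), dtype=bool)
    if np.any(np.isclose(C[off], 1.0)):
        warnings.warn("duplicate or near-duplicate coordinates; jittering "
                      "the correlation matrix")
        C = C * (1.0 - jitter)
    np.fill_diagonal(C, 1.0)
    return C
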