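"""High-order connectivity via kNN hypergraphs and hypergraph Laplacians.

A hypergraph G = {V, E, W} over the M ROIs is built by treating every ROI
as the center of one hyperedge containing the center plus its k nearest
other ROIs under Euclidean distance in a chosen feature space (by default
each ROI's connectivity profile, i.e. its row of the subject's low-order
FCN). With the center included every hyperedge has exactly k+1 members, so
the incidence matrix H is M x M with column sums k+1.

From H, the hyperedge weights W (all 1 by default) and the diagonal degree
matrices D_v (vertex degrees d(v_i) = sum_e w_e H_ie) and D_e (hyperedge
degrees delta(e_j) = sum_v H_vj), the hypergraph Laplacian is

    L      = D_v - H W D_e^{-1} H^T
    L_norm = I - D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}

and the normalized high-order association matrix

    S = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}   (so L_norm = I - S)

is the bounded, symmetric operator whose strict upper triangle serves as
the subject's high-order feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .connectivity import FcnMatrix, FeatureVector, vectorize_upper
from .exceptions import ValidationError

__all__ = [
    "Hypergraph",
    "HoFcn",
    "build_knn_hypergraph",
    "degrees",
    "hypergraph_laplacian",
    "ho_features",
]


@dataclass
class Hypergraph:
    """Vertices = ROIs; one hyperedge per ROI (center + k nearest)."""

    incidence: np.ndarray  # binary M x M_e
    weights: np.ndarray  # positive, length M_e
    k: int

    def __post_init__(self) -> None:
        h = np.asarray(self.incidence, dtype=np.float64)
        if h.ndim != 2:
            raise ValidationError("incidence matrix must be 2-D")
        if not np.all((h == 0) | (h == 1)):
            raise ValidationError("incidence matrix must be binary")
        if np.any(h.sum(axis=1) < 1):
            raise ValidationError("every vertex must belong to at least one hyperedge")
        col = h.sum(axis=0)
        if np.any(col != self.k + 1):
            raise ValidationError(
                f"every hyperedge must contain exactly k+1={self.k + 1} vertices"
            )
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (h.shape[1],) or np.any(w <= 0):
            raise ValidationError("weights must be strictly positive, one per hyperedge")
        self.incidence = h
        self.weights = w

    @property
    def n_vertices(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_hyperedges(self) -> int:
        return self.incidence.shape[1]

    def to_coo_text(self, path) -> None:
        """Export H as sparse coordinate text: row col value."""
        rows, cols = np.nonzero(self.incidence)
        lines = [f"{r} {c} 1" for r, c in zip(rows, cols)]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class HoFcn:
    """High-order connectivity: association matrix and Laplacians."""

    assoc: np.ndarray  # S, normalized association
    laplacian: np.ndarray  # L = D_v - H W D_e^{-1} H^T
    laplacian_norm: np.ndarray  # I - S
    degrees_v: np.ndarray
    degrees_e: np.ndarray

    @property
    def n_rois(self) -> int:
        return self.assoc.shape[0]


def build_knn_hypergraph(features: np.ndarray, k: int) -> Hypergraph:
    """Build the kNN hypergraph over ROIs.

    ``features`` row i is ROI i's representation (connectivity profile or
    raw time course); hyperedge i contains ROI i plus its k nearest other
    ROIs by Euclidean distance. Ties are broken toward the lowest vertex
    index; all hyperedge weights are 1.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValidationError("feature matrix must be 2-D (one row per ROI)")
    if not np.all(np.isfinite(x)):
        raise ValidationError("feature matrix contains non-finite entries")
    m = x.shape[0]
    if not 1 <= k <= m - 1:
        raise ValidationError(f"k must be in [1, M-1]=[1, {m - 1}], got {k}")
    dist = cdist(x, x, metric="euclidean")
    np.fill_diagonal(dist, np.inf)  # self excluded from the neighbor scan
    incidence = np.zeros((m, m), dtype=np.float64)
    for center in range(m):
        # stable sort => equal distances resolve to the lowest index
        order = np.argsort(dist[center], kind="stable")
        incidence[order[:k], center] = 1.0
        incidence[center, center] = 1.0
    return Hypergraph(incidence=incidence, weights=np.ones(m), k=k)


def degrees(hg: Hypergraph) -> tuple[np.ndarray, np.ndarray]:
    """Vertex degrees d(v_i) = sum_j W_j H_ij and hyperedge degrees
    delta(e_j) = sum_i H_ij."""
    d_v = hg.incidence @ hg.weights
    d_e = hg.incidence.sum(axis=0)
    return d_v, d_e


def hypergraph_laplacian(hg: Hypergraph) -> HoFcn:
    """Compute L, the normalized Laplacian and the association matrix S.

    Requires every vertex and hyperedge degree to be positive (guaranteed
    by center-in-own-hyperedge construction; checked anyway).
    """
    d_v, d_e = degrees(hg)
    if np.any(d_v <= 0):
        raise ValidationError(
            f"isolated vertex (zero degree) at index {int(np.flatnonzero(d_v <= 0)[0])}"
        )
    if np.any(d_e <= 0):
        raise ValidationError("empty hyperedge (zero degree)")
    h = hg.incidence
    # Theta = H W D_e^{-1} H^T
    theta = (h * hg.weights / d_e) @ h.T
    lap = np.diag(d_v) - theta
    inv_sqrt = 1.0 / np.sqrt(d_v)
    assoc = inv_sqrt[:, None] * theta * inv_sqrt[None, :]
    assoc = (assoc + assoc.T) / 2.0  # kill fp drift
    lap = (lap + lap.T) / 2.0
    lap_norm = np.eye(hg.n_vertices) - assoc
    return HoFcn(
        assoc=assoc,
        laplacian=lap,
        laplacian_norm=lap_norm,
        degrees_v=d_v,
        degrees_e=d_e,
    )


def ho_features(ho: HoFcn) -> FeatureVector:
    """Vectorize the high-order association matrix S (strict upper triangle)."""
    return vectorize_upper(FcnMatrix(values=ho.assoc, kind="high_order"))
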