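"""Low-order functional connectivity: Pearson correlation networks.

The low-order functional connectivity network (Lo-FCN) of a subject is the
M x M matrix of Pearson correlation coefficients between every pair of ROI
BOLD time courses,

    rho_uv = sum_t (u_t - ubar)(v_t - vbar)
             / sqrt(sum_t (u_t - ubar)^2  sum_t (v_t - vbar)^2).

No Fisher z-transform and no thresholding are applied: raw rho values flow
downstream. The stored time series are never modified; mean-centering and
scaling happen only inside the correlation computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import RoiTimeSeries

__all__ = ["FcnMatrix", "FeatureVector", "pearson_fcn", "vectorize_upper", "devectorize"]

_SYM_TOL = 1e-10


@dataclass
class FcnMatrix:
    """Symmetric M x M connectivity matrix.

    ``kind`` distinguishes the pairwise-Pearson low-order network
    (diagonal exactly 1, entries in [-1, 1]) from the hypergraph-derived
    high-order association matrix (entries bounded but diagonal free).
    """

    values: np.ndarray
    kind: str  # "low_order" | "high_order"
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.kind not in ("low_order", "high_order"):
            raise ValidationError(f"unknown FCN kind {self.kind!r}")
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if np.max(np.abs(v - v.T)) > _SYM_TOL:
            raise ValidationError("connectivity matrix not symmetric within 1e-10")
        if self.kind == "low_order":
            if not np.all(np.diag(v) == 1.0):
                raise ValidationError("low-order FCN diagonal must be exactly 1")
            if np.min(v) < -1.0 or np.max(v) > 1.0:
                raise ValidationError("low-order FCN entries must lie in [-1, 1]")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        labels = self.roi_labels or [f"roi{i}" for i in range(self.n_rois)]
        pd.DataFrame(self.values, index=labels, columns=labels).to_csv(path)


@dataclass
class FeatureVector:
    """Strict upper triangle of a symmetric matrix, row-major order."""

    values: np.ndarray
    index_map: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != len(self.index_map):
            raise ValidationError("feature vector and index map lengths differ")

    def __len__(self) -> int:
        return len(self.values)


def pearson_fcn(ts: RoiTimeSeries) -> FcnMatrix:
    """Build the low-order FCN of one subject.

    A zero-variance (constant) ROI signal is a data defect, not a zero
    correlation, and raises naming the offending ROI.
    """
    x = ts.values
    if x.shape[0] < 3:
        raise ValidationError("need at least 3 time points for a correlation")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.flatnonzero(sd == 0)[0])
        name = ts.roi_labels[idx] if ts.roi_labels else f"column {idx}"
        raise ValidationError(
            f"subject {ts.subject_id!r}: ROI {name} has constant signal "
            "(zero variance); cannot correlate"
        )
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)  # kill fp drift before hypergraph distances
    return FcnMatrix(values=corr, kind="low_order", roi_labels=ts.roi_labels)


def _upper_index_map(m: int) -> list[tuple[int, int]]:
    iu, ju = np.triu_indices(m, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


def vectorize_upper(matrix: FcnMatrix | np.ndarray, tol: float = 1e-8) -> FeatureVector:
    """Vectorize a symmetric matrix into its strict upper triangle.

    Row-major order over pairs (i, j), i < j; length M(M-1)/2.
    """
    values = matrix.values if isinstance(matrix, FcnMatrix) else np.asarray(matrix, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError("can only vectorize a square matrix")
    if np.max(np.abs(values - values.T)) > tol:
        raise ValidationError(f"matrix asymmetric beyond tolerance {tol}")
    m = values.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    return FeatureVector(values=values[iu, ju], index_map=_upper_index_map(m))


def devectorize(fv: FeatureVector, diagonal: float = 1.0, kind: str = "low_order") -> FcnMatrix:
    """Inverse of :func:`vectorize_upper` given the implied diagonal."""
    n = len(fv)
    # n = m(m-1)/2  =>  m = (1 + sqrt(1 + 8n)) / 2
    m = int(round((1 + np.sqrt(1 + 8 * n)) / 2))
    if m * (m - 1) // 2 != n:
        raise ValidationError(f"length {n} is not a triangular number")
    out = np.full((m, m), 0.0)
    iu, ju = np.triu_indices(m, k=1)
    out[iu, ju] = fv.values
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return FcnMatrix(values=out, kind=kind)
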