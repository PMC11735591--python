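"""Feature engineering for multimodal fusion.

Turns raw per-subject inputs — grey-matter feature maps and white-matter
connectomes (streamline counts and mean tract FA on a common parcellation)
— into the aligned subjects x features matrices that the joint decomposition
consumes, plus whole-brain tissue summaries used by the association
statistics.

Edge features use the strict upper triangle of the R x R connectome in
row-major order, so an R-region parcellation yields R*(R-1)/2 edge features
(7260 for the 121-region DKT-style parcellation used throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "ModalityMatrix",
    "combine_fa_streamlines",
    "vectorize_connectome",
    "unvectorize_edges",
    "edge_labels",
    "gm_roi_volumes",
    "tissue_summaries",
    "read_connectome_csv",
    "write_connectome_csv",
    "read_modality_csv",
    "write_modality_csv",
]


class AlignmentError(ValueError):
    """Inputs that should describe the same subjects/regions do not line up."""


@dataclass
class Connectome:
    """Symmetric R x R region-by-region connection matrix.

    ``kind`` records what the weights mean: raw streamline counts
    (``"streamlines"``), mean tract FA (``"fa"``), or the product used as
    ICA input (``"combined"``).
    """

    weights: np.ndarray
    roi_labels: Sequence[str]
    kind: Literal["streamlines", "fa", "combined"] = "combined"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"connectome must be square, got shape {w.shape}")
        if len(self.roi_labels) != w.shape[0]:
            raise AlignmentError(
                f"{len(self.roi_labels)} ROI labels for a {w.shape[0]}-region matrix"
            )
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("connectome matrix must be symmetric")
        if not np.allclose(np.diag(w), 0.0, atol=1e-12):
            raise ValueError("connectome diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        self.weights = w
        self.roi_labels = list(self.roi_labels)

    @property
    def n_rois(self) -> int:
        return self.weights.shape[0]


@dataclass
class ModalityMatrix:
    """Aligned subjects x features matrix for one modality.

    ``feature_index`` describes each column: a voxel/ROI label for GM, an
    ``"roiA--roiB"`` pair label for WM edges.
    """

    data: np.ndarray
    modality: Literal["GM", "WM"]
    feature_index: Sequence[str]
    subject_ids: Sequence[str]

    def __post_init__(self) -> None:
        x = np.asarray(self.data, dtype=float)
        if x.ndim != 2:
            raise ValueError("modality data must be 2-D (subjects x features)")
        if x.shape[0] != len(self.subject_ids):
            raise AlignmentError("subject_ids length does not match data rows")
        if x.shape[1] != len(self.feature_index):
            raise AlignmentError("feature_index length does not match data columns")
        if not np.all(np.isfinite(x)):
            raise ValueError("modality matrix contains NaN/Inf")
        self.data = x
        self.feature_index = list(self.feature_index)
        self.subject_ids = list(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.subject_ids, columns=self.feature_index)


def combine_fa_streamlines(
    fa: Connectome,
    sc: Connectome,
    mode: Literal["product", "proportional"] = "product",
) -> Connectome:
    """Combine an FA connectome and a streamline-count connectome into one
    streamline-weighted FA connectome.

    ``mode="product"`` (default) uses the elementwise product
    ``w_ij = fa_ij * sc_ij``; ``mode="proportional"`` divides by the total
    streamline count, ``w_ij = fa_ij * sc_ij / sum(sc)``, so weights are FA
    contributions per unit of the subject's total connectivity. Edges with
    no streamlines always get weight zero.
    """
    if fa.weights.shape != sc.weights.shape:
        raise AlignmentError(
            f"shape mismatch: FA {fa.weights.shape} vs streamlines {sc.weights.shape}"
        )
    if list(fa.roi_labels) != list(sc.roi_labels):
        raise AlignmentError("ROI labels of FA and streamline connectomes differ")
    w = fa.weights * sc.weights
    if mode == "proportional":
        total = np.triu(sc.weights, k=1).sum()
        if total > 0:
            w = w / total
    elif mode != "product":
        raise ValueError(f"unknown combination mode {mode!r}")
    return Connectome(w, fa.roi_labels, kind="combined")


def vectorize_connectome(c: Connectome | np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major, length R(R-1)/2."""
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(w, w.T, atol=1e-10):
        raise ValueError("matrix must be symmetric to vectorize")
    iu = np.triu_indices(w.shape[0], k=1)
    return w[iu].copy()


def unvectorize_edges(
    v: np.ndarray, n_rois: int, roi_labels: Sequence[str] | None = None
) -> Connectome:
    """Inverse of :func:`vectorize_connectome`: rebuild the symmetric matrix."""
    v = np.asarray(v, dtype=float)
    expected = n_rois * (n_rois - 1) // 2
    if v.shape != (expected,):
        raise ValueError(f"edge vector must have length {expected} for R={n_rois}, got {v.shape}")
    w = np.zeros((n_rois, n_rois))
    iu = np.triu_indices(n_rois, k=1)
    w[iu] = v
    w = w + w.T
    if roi_labels is None:
        roi_labels = [f"roi{i:03d}" for i in range(n_rois)]
    # kind "combined" because edge vectors may hold arbitrary real values
    # (e.g. z-scored source maps); bypass the nonnegativity check.
    c = Connectome.__new__(Connectome)
    c.weights = w
    c.roi_labels = list(roi_labels)
    c.kind = "combined"
    return c


def edge_labels(roi_labels: Sequence[str]) -> list[str]:
    """Labels ``"roiA--roiB"`` for every strict-upper-triangle edge, row-major."""
    r = len(roi_labels)
    iu, ju = np.triu_indices(r, k=1)
    return [f"{roi_labels[i]}--{roi_labels[j]}" for i, j in zip(iu, ju)]


def edge_index_pairs(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) ROI index arrays for each edge feature, i < j, row-major."""
    return np.triu_indices(n_rois, k=1)


def gm_roi_volumes(
    gm_row: np.ndarray,
    feature_rois: Sequence[str],
    tiv: float,
    atlas_rois: Sequence[str] | None = None,
) -> pd.Series:
    """TIV-normalised per-ROI GM volume for one subject.

    ``volume_r = sum(features assigned to ROI r) / tiv``. ``feature_rois``
    gives the ROI label of each GM feature (voxel or ROI-level).
    ``atlas_rois`` fixes the output order and flags labels absent from the
    feature index (warned, volume 0).
    """
    if tiv <= 0:
        raise ValueError(f"TIV must be positive, got {tiv}")
    gm_row = np.asarray(gm_row, dtype=float)
    if gm_row.shape[0] != len(feature_rois):
        raise AlignmentError("feature_rois length does not match GM row")
    sums = pd.Series(gm_row).groupby(list(feature_rois)).sum()
    if atlas_rois is not None:
        missing = [r for r in atlas_rois if r not in sums.index]
        if missing:
            warnings.warn(f"{len(missing)} atlas ROIs have no GM features; volume set to 0")
        sums = sums.reindex(list(atlas_rois), fill_value=0.0)
    return sums / tiv


def tissue_summaries(
    gm: ModalityMatrix,
    feature_rois: Sequence[str],
    deep_rois: Sequence[str],
    tiv: Sequence[float],
    fa_edges: np.ndarray,
    sc_edges: np.ndarray,
) -> pd.DataFrame:
    """Whole-brain tissue summaries per subject.

    Returns a DataFrame indexed by subject id with columns ``cgm_volume``
    and ``dgm_volume`` (TIV-normalised cortical / deep GM volume),
    ``mean_fa`` (mean FA over edges with at least one streamline) and
    ``n_streamlines`` (total streamline count).

    ``fa_edges`` and ``sc_edges`` are subjects x edges arrays in the same
    edge order as the WM modality matrix.
    """
    deep = set(deep_rois)
    is_deep = np.array([r in deep for r in feature_rois])
    tiv = np.asarray(tiv, dtype=float)
    if np.any(tiv <= 0):
        raise ValueError("all TIV values must be positive")
    cgm = gm.data[:, ~is_deep].sum(axis=1) / tiv
    dgm = gm.data[:, is_deep].sum(axis=1) / tiv
    fa_edges = np.asarray(fa_edges, dtype=float)
    sc_edges = np.asarray(sc_edges, dtype=float)
    nonzero = sc_edges > 0
    with np.errstate(invalid="ignore"):
        mean_fa = np.where(
            nonzero.sum(axis=1) > 0,
            (fa_edges * nonzero).sum(axis=1) / np.maximum(nonzero.sum(axis=1), 1),
            0.0,
        )
    return pd.DataFrame(
        {
            "cgm_volume": cgm,
            "dgm_volume": dgm,
            "mean_fa": mean_fa,
            "n_streamlines": sc_edges.sum(axis=1),
        },
        index=pd.Index(gm.subject_ids, name="subject_id"),
    )


# ---------------------------------------------------------------------------
# plain-text readers/writers


def read_connectome_csv(
    path: str | Path,
    roi_labels: Sequence[str] | None = None,
    kind: Literal["streamlines", "fa", "combined"] = "combined",
) -> Connectome:
    """Read an R x R connectome from CSV.

    Headerless plain numeric matrices are the default; a headered variant
    (first row/column are ROI labels) is auto-detected.
    """
    path = Path(path)
    first = path.open().readline()
    tokens = first.strip().split(",")

    def _is_number(t: str) -> bool:
        try:
            float(t)
            return True
        except ValueError:
            return False

    if all(_is_number(t) for t in tokens if t != ""):
        w = np.loadtxt(path, delimiter=",", ndmin=2)
        labels = roi_labels
    else:
        df = pd.read_csv(path, index_col=0)
        w = df.to_numpy(dtype=float)
        labels = roi_labels if roi_labels is not None else list(df.columns)
    if labels is None:
        labels = [f"roi{i:03d}" for i in range(w.shape[0])]
    return Connectome(w, labels, kind=kind)


def write_connectome_csv(c: Connectome, path: str | Path, header: bool = False) -> None:
    path = Path(path)
    if header:
        pd.DataFrame(c.weights, index=c.roi_labels, columns=c.roi_labels).to_csv(path)
    else:
        np.savetxt(path, c.weights, delimiter=",", fmt="%.10g")


def read_modality_csv(path: str | Path, modality: Literal["GM", "WM"]) -> ModalityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ModalityMatrix(
        df.to_numpy(dtype=float),
        modality,
        [str(c) for c in df.columns],
        [str(i) for i in df.index],
    )


def write_modality_csv(m: ModalityMatrix, path: str | Path) -> None:
    m.to_frame().rename_axis("subject_id").to_csv(path)
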