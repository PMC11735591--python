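"""Joint independent component analysis of concatenated modality matrices.

The fusion model is ``X = A S``: the subjects x features data matrix (GM
features concatenated with WM edge features, after per-feature centering
and per-modality variance balancing) is decomposed into a shared subjects x
components loading matrix ``A`` and a components x features source matrix
``S`` whose rows are maximally non-Gaussian spatial/edge patterns. Each
source row splits back into a GM part and a WM part at the recorded
concatenation boundary, so every component is one multimodal pattern with a
single subject weighting.

Estimation treats features as the i.i.d. samples of spatial ICA: the data
are PCA-whitened to the requested model order and unmixed with the
fixed-point FastICA iteration under symmetric decorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .features import AlignmentError, ModalityMatrix

__all__ = [
    "Preprocessing",
    "Decomposition",
    "normalize_and_concat",
    "fastica_fit",
    "jointica_fit",
    "single_tissue_ica",
]


@dataclass
class Preprocessing:
    """Invertible record of the normalization applied before ICA."""

    feature_center: np.ndarray                 # per-feature means (over subjects)
    modality_scales: dict[str, float]          # divisor per modality block
    slices: dict[str, slice]                   # feature slice per modality

    def transform(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        parts = []
        for name, sl in self.slices.items():
            x = blocks[name] - self.feature_center[sl]
            parts.append(x / self.modality_scales[name])
        return np.concatenate(parts, axis=1)

    def inverse_transform(self, joint: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for name, sl in self.slices.items():
            out[name] = joint[:, sl] * self.modality_scales[name] + self.feature_center[sl]
        return out


@dataclass
class Decomposition:
    """Shared loadings and modality-spanning sources of one ICA fit."""

    loadings: np.ndarray                  # n_subjects x C  (mixing matrix A)
    sources: np.ndarray                   # C x F_total     (source matrix S)
    slices: dict[str, slice]              # modality feature slices into sources
    preprocessing: Preprocessing | None
    n_components: int
    seed: int
    converged: bool
    n_iter: int
    subject_ids: list[str] = field(default_factory=list)
    feature_index: list[str] = field(default_factory=list)
    sample_mean: np.ndarray | None = None  # per-subject offset removed by ICA centering
    unmixing: np.ndarray | None = None     # C x n_subjects map from data to sources

    @property
    def sources_gm(self) -> np.ndarray:
        return self.sources[:, self.slices["GM"]]

    @property
    def sources_wm(self) -> np.ndarray:
        return self.sources[:, self.slices["WM"]]

    def loadings_z(self) -> np.ndarray:
        """Loadings standardized per component over subjects (sample SD)."""
        a = self.loadings
        return (a - a.mean(0)) / a.std(0, ddof=1)

    def reconstruction(self) -> np.ndarray:
        """A @ S plus the removed per-subject offset: the rank-C PCA part of
        the preprocessed data."""
        rec = self.loadings @ self.sources
        if self.sample_mean is not None:
            rec = rec + self.sample_mean[:, None]
        return rec


def normalize_and_concat(
    gm: ModalityMatrix, wm: ModalityMatrix
) -> tuple[np.ndarray, Preprocessing]:
    """Center features and balance modality variances, then concatenate.

    Each feature is centered across subjects; each modality block is divided
    by the square root of its total feature variance so both blocks
    contribute unit total variance to the joint matrix — without this the
    7260-edge WM block would dominate a 2000-feature GM block purely by
    feature count.
    """
    if list(gm.subject_ids) != list(wm.subject_ids):
        raise AlignmentError("GM and WM matrices list different subjects (or order)")
    if gm.n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    center = np.concatenate([gm.data.mean(0), wm.data.mean(0)])
    slices = {"GM": slice(0, gm.n_features),
              "WM": slice(gm.n_features, gm.n_features + wm.n_features)}
    scales = {}
    parts = []
    for name, mod in (("GM", gm), ("WM", wm)):
        xc = mod.data - mod.data.mean(0)
        total_var = xc.var(0, ddof=0).sum()
        if total_var <= 0:
            raise ValueError(f"{name} block has zero variance")
        s = float(np.sqrt(total_var))
        scales[name] = s
        parts.append(xc / s)
    joint = np.concatenate(parts, axis=1)
    prep = Preprocessing(feature_center=center, modality_scales=scales, slices=slices)
    return joint, prep


def _fix_signs_and_order(
    A: np.ndarray, S: np.ndarray, W: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic orientation: each source's largest-|value| element is
    positive; components ordered by descending variance explained. The
    optional unmixing matrix ``W`` (components x subjects) gets the same
    sign flips and row order."""
    A = A.copy()
    S = S.copy()
    W = None if W is None else W.copy()
    for c in range(S.shape[0]):
        j = int(np.argmax(np.abs(S[c])))
        if S[c, j] < 0:
            S[c] *= -1.0
            A[:, c] *= -1.0
            if W is not None:
                W[c] *= -1.0
    var = (A ** 2).sum(0) * (S ** 2).sum(1)
    order = np.argsort(-var, kind="stable")
    if W is None:
        return A[:, order], S[order]
    return A[:, order], S[order], W[order]


def fastica_fit(
    X: np.ndarray,
    n_components: int,
    seed: int = 0,
    fun: Literal["logcosh", "cube"] = "logcosh",
    max_iter: int = 1000,
    tol: float = 1e-6,
    slices: dict[str, slice] | None = None,
    preprocessing: Preprocessing | None = None,
    subject_ids: Sequence[str] | None = None,
    feature_index: Sequence[str] | None = None,
) -> Decomposition:
    """One FastICA run on a subjects x features matrix.

    Features are the samples: the transposed matrix is PCA-whitened to
    ``n_components`` dimensions and unmixed by the fixed-point iteration
    with symmetric decorrelation. Deterministic given ``seed`` (random
    orthonormal initialisation). Non-convergence is flagged on the result,
    not raised.
    """
    X = np.asarray(X, dtype=float)
    n, f = X.shape
    if n_components > min(n, f):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_subjects, n_features)"
            f"={min(n, f)}"
        )
    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        whiten="unit-variance",
        fun=fun,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        src = ica.fit_transform(X.T)               # F x C, unit-variance sources
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    S = src.T                                      # C x F
    A = ica.mixing_                                # n x C
    A, S, W = _fix_signs_and_order(A, S, ica.components_)
    if slices is None:
        slices = {"GM": slice(0, f), "WM": slice(f, f)}
    return Decomposition(
        loadings=A,
        sources=S,
        slices=slices,
        preprocessing=preprocessing,
        n_components=n_components,
        seed=seed,
        converged=converged,
        n_iter=int(ica.n_iter_),
        subject_ids=list(subject_ids) if subject_ids is not None else [],
        feature_index=list(feature_index) if feature_index is not None else [],
        sample_mean=np.asarray(ica.mean_, dtype=float),
        unmixing=W,
    )


def jointica_fit(
    gm: ModalityMatrix,
    wm: ModalityMatrix,
    n_components: int = 20,
    seed: int = 0,
    **fastica_kwargs,
) -> Decomposition:
    """Joint ICA: normalize, concatenate, unmix, and keep the modality split.

    Returns a single shared loading matrix over subjects and a source matrix
    whose GM and WM parts are addressed by the recorded slices.
    """
    joint, prep = normalize_and_concat(gm, wm)
    # feature centering removes one degree of freedom from the subject space
    if n_components > min(gm.n_subjects - 1, joint.shape[1]):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_subjects-1, n_features)"
        )
    return fastica_fit(
        joint,
        n_components,
        seed=seed,
        slices=prep.slices,
        preprocessing=prep,
        subject_ids=gm.subject_ids,
        feature_index=list(gm.feature_index) + list(wm.feature_index),
        **fastica_kwargs,
    )


def single_tissue_ica(
    modality: ModalityMatrix,
    n_components: int = 20,
    seed: int = 0,
    **fastica_kwargs,
) -> Decomposition:
    """Plain per-modality ICA, used as the single-tissue comparison model."""
    xc = modality.data - modality.data.mean(0)
    total_var = xc.var(0, ddof=0).sum()
    if total_var <= 0:
        raise ValueError("modality block has zero variance")
    scale = float(np.sqrt(total_var))
    if n_components > min(modality.n_subjects - 1, modality.n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_subjects-1, n_features)"
        )
    prep = Preprocessing(
        feature_center=modality.data.mean(0),
        modality_scales={modality.modality: scale},
        slices={modality.modality: slice(0, modality.n_features)},
    )
    f = modality.n_features
    if modality.modality == "GM":
        slices = {"GM": slice(0, f), "WM": slice(f, f)}
    else:
        slices = {"GM": slice(0, 0), "WM": slice(0, f)}
    return fastica_fit(
        xc / scale,
        n_components,
        seed=seed,
        slices=slices,
        preprocessing=prep,
        subject_ids=modality.subject_ids,
        feature_index=modality.feature_index,
        **fastica_kwargs,
    )
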