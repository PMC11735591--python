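"""Thresholding and anatomical attribution of joint components.

Source maps are z-scored within each modality part; GM features survive at
|z| > 5 (strict) and are mapped to atlas ROIs, a region counting as a
contributor when at least 5% of its features are suprathreshold (inclusive
boundary). WM edge maps are thresholded at the two-sided 99% confidence
bound of the standard normal (|z| >= 2.5758...) and reported as ROI-pair
edges. Directionality of each reported region/edge is the sign of the
Spearman correlation between its per-subject tissue value and the
component's subject loadings (up-arrow for positive, down for negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import Decomposition
from .features import edge_index_pairs

__all__ = [
    "ComponentAttribution",
    "zscore_source",
    "threshold_gm",
    "roi_overlap",
    "threshold_wm",
    "directionality",
    "attribute_components",
    "gm_attribution_frame",
    "wm_attribution_frame",
]

UP, DOWN = "↑", "↓"


@dataclass
class ComponentAttribution:
    """Thresholded anatomy of one component."""

    component: int
    gm_rois: pd.DataFrame     # roi, overlap, direction, direction_r, direction_p
    wm_edges: pd.DataFrame    # roi_i, roi_j, z, direction, direction_r, direction_p
    gm_tau: float
    overlap_min: float
    wm_ci: float


def zscore_source(source_row: np.ndarray) -> np.ndarray:
    """Standardize a source map across its features (sample SD)."""
    x = np.asarray(source_row, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 features to z-score")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant source map cannot be z-scored")
    return (x - x.mean()) / sd


def threshold_gm(zmap: np.ndarray, tau: float = 5.0) -> np.ndarray:
    """Boolean mask of features with |z| strictly above tau."""
    return np.abs(np.asarray(zmap, dtype=float)) > tau


def roi_overlap(
    mask: np.ndarray,
    feature_rois: Sequence[str],
    min_overlap: float = 0.05,
    atlas_rois: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-ROI overlap of a suprathreshold mask with the parcellation.

    overlap(r) = suprathreshold features in r / total features in r. ROIs
    with overlap >= ``min_overlap`` (boundary inclusive) are flagged as
    contributing. ROIs with zero features are excluded with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != len(feature_rois):
        raise ValueError("mask length does not match feature_rois")
    rois = pd.Series(list(feature_rois))
    total = rois.value_counts()
    hits = rois[mask].value_counts()
    if atlas_rois is not None:
        empty = [r for r in atlas_rois if r not in total.index]
        if empty:
            warnings.warn(f"{len(empty)} ROIs have zero features; excluded from overlap")
        order = [r for r in atlas_rois if r in total.index]
    else:
        order = list(total.index)
    overlap = (hits.reindex(order, fill_value=0) / total.reindex(order)).astype(float)
    df = pd.DataFrame({"roi": order, "overlap": overlap.to_numpy()})
    df["contributing"] = df["overlap"] >= min_overlap
    return df


def wm_ci_threshold(ci_level: float = 0.99) -> float:
    """Two-sided normal quantile for the given confidence level."""
    if not 0 <= ci_level < 1:
        raise ValueError("ci_level must be in [0, 1)")
    return float(stats.norm.ppf(1 - (1 - ci_level) / 2))


def threshold_wm(
    z_edges: np.ndarray,
    roi_labels: Sequence[str],
    ci_level: float = 0.99,
) -> pd.DataFrame:
    """Edges whose |z| reaches the two-sided ``ci_level`` normal bound.

    Returns one row per surviving edge with its ROI-pair labels, upper
    triangle edge index, and z value.
    """
    z = np.asarray(z_edges, dtype=float)
    r = len(roi_labels)
    if z.shape[0] != r * (r - 1) // 2:
        raise ValueError("edge vector length does not match ROI count")
    thr = wm_ci_threshold(ci_level)
    keep = np.abs(z) >= thr
    iu, ju = edge_index_pairs(r)
    idx = np.flatnonzero(keep)
    return pd.DataFrame(
        {
            "edge_index": idx,
            "roi_i": [roi_labels[i] for i in iu[idx]],
            "roi_j": [roi_labels[j] for j in ju[idx]],
            "z": z[idx],
        }
    )


def directionality(
    loading_column: np.ndarray, regional_measure: np.ndarray
) -> tuple[float, float, str]:
    """Spearman correlation of a regional tissue measure with component
    loadings; the arrow is the sign of rho."""
    x = np.asarray(loading_column, dtype=float)
    y = np.asarray(regional_measure, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 subjects for directionality")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant measure: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), (UP if rho > 0 else DOWN)


def attribute_components(
    decomp: Decomposition,
    feature_rois: Sequence[str],
    roi_labels: Sequence[str],
    gm_roi_volumes_by_subject: pd.DataFrame | None = None,
    wm_edge_values: np.ndarray | None = None,
    gm_tau: float = 5.0,
    overlap_min: float = 0.05,
    wm_ci: float = 0.99,
) -> list[ComponentAttribution]:
    """Full attribution of every component in a decomposition.

    ``gm_roi_volumes_by_subject`` (subjects x ROIs, TIV-normalised) and
    ``wm_edge_values`` (subjects x edges) supply the per-subject tissue
    values used for directionality; when omitted the direction columns are
    left NaN.
    """
    out: list[ComponentAttribution] = []
    s_gm, s_wm = decomp.sources_gm, decomp.sources_wm
    loadings = decomp.loadings
    for c in range(decomp.n_components):
        # --- GM ---
        if s_gm.shape[1] >= 2 and s_gm[c].std() > 0:
            mask = threshold_gm(zscore_source(s_gm[c]), gm_tau)
            rois = roi_overlap(mask, feature_rois, overlap_min, atlas_rois=roi_labels)
            rois = rois[rois["contributing"]].drop(columns="contributing").reset_index(drop=True)
        else:
            rois = pd.DataFrame(columns=["roi", "overlap"])
        rois["direction"] = pd.Series([pd.NA] * len(rois), dtype="object")
        rois[["direction_r", "direction_p"]] = np.nan
        if gm_roi_volumes_by_subject is not None and len(rois):
            for i, roi in enumerate(rois["roi"]):
                r, p, arrow = directionality(
                    loadings[:, c], gm_roi_volumes_by_subject[roi].to_numpy()
                )
                rois.loc[i, ["direction", "direction_r", "direction_p"]] = [arrow, r, p]
        # --- WM ---
        if s_wm.shape[1] >= 2 and s_wm[c].std() > 0:
            edges = threshold_wm(zscore_source(s_wm[c]), roi_labels, wm_ci)
        else:
            edges = pd.DataFrame(columns=["edge_index", "roi_i", "roi_j", "z"])
        edges["direction"] = pd.Series([pd.NA] * len(edges), dtype="object")
        edges[["direction_r", "direction_p"]] = np.nan
        if wm_edge_values is not None and len(edges):
            for i, eidx in enumerate(edges["edge_index"]):
                r, p, arrow = directionality(loadings[:, c], wm_edge_values[:, int(eidx)])
                edges.loc[i, ["direction", "direction_r", "direction_p"]] = [arrow, r, p]
        out.append(
            ComponentAttribution(
                component=c, gm_rois=rois, wm_edges=edges,
                gm_tau=gm_tau, overlap_min=overlap_min, wm_ci=wm_ci,
            )
        )
    return out


def gm_attribution_frame(attributions: list[ComponentAttribution]) -> pd.DataFrame:
    frames = []
    for a in attributions:
        df = a.gm_rois.copy()
        df.insert(0, "component", a.component)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def wm_attribution_frame(attributions: list[ComponentAttribution]) -> pd.DataFrame:
    frames = []
    for a in attributions:
        df = a.wm_edges.copy()
        df.insert(0, "component", a.component)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
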