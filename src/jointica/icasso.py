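"""ICASSO-style stability analysis of ICA components.

FastICA converges to different fixed points from different random
initialisations; a component is only trustworthy if it reappears across
runs. The procedure here reruns the decomposition M times, measures
similarity between all M*C source estimates as the absolute Pearson
correlation of their source rows, clusters the estimates (average-linkage
agglomerative clustering on distance 1 - |corr|, cut at C clusters), and
summarises each cluster by

* a quality index Iq = mean intra-cluster similarity (off-diagonal) minus
  mean similarity to all estimates outside the cluster — near 1 for a
  component that every run reproduces; and
* a centrotype — the member with the largest summed similarity to its
  cluster, used as the representative estimate.

The final decomposition is assembled from the C centrotypes, with loadings
recomputed by least squares of the preprocessed data on the centrotype
sources.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .decomposition import Decomposition, _fix_signs_and_order, fastica_fit, normalize_and_concat
from .features import ModalityMatrix

__all__ = ["IcassoSummary", "run_icasso", "select_centrotypes"]


@dataclass
class IcassoSummary:
    """All-run estimates, their similarity structure, and cluster quality."""

    n_runs: int
    n_components: int
    estimates: np.ndarray            # (n_used_runs * C) x F source rows
    estimate_run: np.ndarray         # run index of each estimate row
    similarity: np.ndarray           # |corr| between estimate rows, in [0, 1]
    clusters: np.ndarray             # cluster id (0..C-1) per estimate
    iq: np.ndarray                   # quality index per cluster
    centrotype_indices: np.ndarray   # estimate row index per cluster
    run_seeds: list[int]
    failed_runs: list[int]
    slices: dict[str, slice]
    preprocessed: np.ndarray         # joint matrix the runs were fit on
    preprocessing: object
    subject_ids: list[str] = field(default_factory=list)
    feature_index: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        sizes = np.bincount(self.clusters, minlength=self.n_components)
        payload = {
            "n_runs": self.n_runs,
            "n_components": self.n_components,
            "run_seeds": self.run_seeds,
            "failed_runs": self.failed_runs,
            "iq": self.iq.tolist(),
            "cluster_sizes": sizes.tolist(),
            "centrotype_indices": self.centrotype_indices.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def similarity_to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.similarity, delimiter=",", fmt="%.6f")


def _abs_corr(rows: np.ndarray) -> np.ndarray:
    """|Pearson correlation| between rows, clipped to [0, 1]."""
    c = np.corrcoef(rows)
    c = np.abs(np.nan_to_num(c, nan=0.0))
    np.fill_diagonal(c, 1.0)
    return np.clip(c, 0.0, 1.0)


def _quality_index(similarity: np.ndarray, clusters: np.ndarray, c: int) -> float:
    """Mean intra-cluster (off-diagonal) minus mean extra-cluster similarity."""
    inside = clusters == c
    idx = np.flatnonzero(inside)
    sub = similarity[np.ix_(idx, idx)]
    if idx.size > 1:
        intra = (sub.sum() - np.trace(sub)) / (idx.size * (idx.size - 1))
    else:
        intra = 1.0
    outside = np.flatnonzero(~inside)
    extra = similarity[np.ix_(idx, outside)].mean() if outside.size else 0.0
    return float(intra - extra)


def run_icasso(
    gm: ModalityMatrix,
    wm: ModalityMatrix,
    n_components: int,
    n_runs: int = 20,
    base_seed: int = 0,
    resampling: str = "both",
    **fastica_kwargs,
) -> IcassoSummary:
    """Rerun joint ICA ``n_runs`` times (seeds ``base_seed .. base_seed+M-1``)
    and cluster the pooled source estimates.

    ``resampling`` controls what varies between runs: ``"randinit"`` varies
    only the random initialisation, ``"bootstrap"`` refits on bootstrap
    resamples of the features (the ICA samples) with a fixed initialisation,
    and ``"both"`` (default, the canonical ICASSO setting) varies both. With
    resampled runs the estimated unmixing is re-applied to the full data so
    source estimates stay comparable across runs. Random initialisation
    alone probes only algorithmic convergence — FastICA converges to the
    same fixed points from almost any start when feature-samples are
    plentiful — whereas bootstrapping also probes statistical reliability,
    which is what separates weak components from strong ones.

    Runs that fail to converge are recorded in ``failed_runs`` and excluded
    from the clustering (with a warning), matching the principle that an
    unstable fixed point should not vote on component stability.
    """
    if n_runs < 2:
        raise ValueError("ICASSO needs at least 2 runs")
    if resampling not in ("randinit", "bootstrap", "both"):
        raise ValueError(f"unknown resampling mode {resampling!r}")
    joint, prep = normalize_and_concat(gm, wm)
    n_features = joint.shape[1]
    seeds = [base_seed + i for i in range(n_runs)]
    all_rows, row_run, failed = [], [], []
    for i, seed in enumerate(seeds):
        init_seed = seed if resampling in ("randinit", "both") else base_seed
        if resampling in ("bootstrap", "both"):
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, n_features, n_features)
            fit_data = joint[:, idx]
        else:
            fit_data = joint
        dec = fastica_fit(fit_data, n_components, seed=init_seed,
                          slices=prep.slices, preprocessing=prep, **fastica_kwargs)
        if not dec.converged:
            failed.append(i)
            warnings.warn(f"ICASSO run {i} (seed {seed}) did not converge; excluded")
            continue
        if resampling in ("bootstrap", "both"):
            # unmixing estimated on the resample, applied to the full data
            sources = dec.unmixing @ (joint - dec.sample_mean[:, None])
        else:
            sources = dec.sources
        all_rows.append(sources)
        row_run.extend([i] * n_components)
    if not all_rows:
        raise RuntimeError("no ICASSO run converged")
    estimates = np.vstack(all_rows)
    similarity = _abs_corr(estimates)
    dist = squareform(1.0 - similarity, checks=False)
    z = linkage(dist, method="average")
    clusters = fcluster(z, t=n_components, criterion="maxclust") - 1
    if len(np.unique(clusters)) != n_components:
        warnings.warn(
            f"clustering produced {len(np.unique(clusters))} clusters for "
            f"{n_components} components"
        )
    iq = np.array([_quality_index(similarity, clusters, c)
                   for c in range(n_components)])
    # centrotype: member maximising summed intra-cluster similarity; argmax
    # takes the first maximum, so ties break to the lowest run index.
    centrotypes = np.full(n_components, -1, dtype=int)
    for c in range(n_components):
        idx = np.flatnonzero(clusters == c)
        if idx.size == 0:
            continue
        score = similarity[np.ix_(idx, idx)].sum(axis=1)
        centrotypes[c] = idx[int(np.argmax(score))]
    return IcassoSummary(
        n_runs=n_runs,
        n_components=n_components,
        estimates=estimates,
        estimate_run=np.asarray(row_run),
        similarity=similarity,
        clusters=clusters,
        iq=iq,
        centrotype_indices=centrotypes,
        run_seeds=seeds,
        failed_runs=failed,
        slices=prep.slices,
        preprocessed=joint,
        preprocessing=prep,
        subject_ids=list(gm.subject_ids),
        feature_index=list(gm.feature_index) + list(wm.feature_index),
    )


def select_centrotypes(summary: IcassoSummary) -> Decomposition:
    """Assemble the representative decomposition from cluster centrotypes.

    Sources are the centrotype estimates; loadings are the least-squares
    regression of the (sample-centered) preprocessed data on those sources;
    the deterministic sign/ordering convention is re-applied.
    """
    valid = summary.centrotype_indices >= 0
    if not np.all(valid):
        raise RuntimeError("empty ICASSO cluster: cannot select centrotypes")
    S = summary.estimates[summary.centrotype_indices]
    X = summary.preprocessed
    sample_mean = X.mean(axis=1)            # per-subject offset over features
    Xc = X - sample_mean[:, None]
    # A = argmin ||Xc - A S||_F  ->  solve S S^T A^T = S Xc^T
    A = np.linalg.solve(S @ S.T, S @ Xc.T).T
    A, S = _fix_signs_and_order(A, S)
    return Decomposition(
        loadings=A,
        sources=S,
        slices=summary.slices,
        preprocessing=summary.preprocessing,
        n_components=summary.n_components,
        seed=summary.run_seeds[0],
        converged=len(summary.failed_runs) == 0,
        n_iter=0,
        subject_ids=list(summary.subject_ids),
        feature_index=list(summary.feature_index),
        sample_mean=sample_mean,
    )
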