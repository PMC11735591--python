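"""Synthetic multimodal cohorts with planted joint sources.

The generator emulates the study design the package analyses: a cohort of
~89 people with multiple sclerosis in three clinical phenotypes (RRMS,
SPMS, PPMS), a 121-region DKT-style grey-matter parcellation with a
20-region deep-GM subset, voxel-level GM feature maps, and 121 x 121
FA-weighted structural connectomes. K latent joint sources each carry a
sparse GM spatial pattern and a sparse WM edge pattern; a shared
subjects x K loading matrix mixes them into both modalities, and cognitive
domain scores are linear functions of the loadings plus an age effect.

Because every planted quantity is retained in :class:`GroundTruth`, the
generator doubles as the package's validation harness: decomposition,
stability, attribution and association stages can all be scored against
known answers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .features import (
    Connectome,
    ModalityMatrix,
    edge_index_pairs,
    edge_labels,
    unvectorize_edges,
    write_connectome_csv,
    write_modality_csv,
)

__all__ = ["SimConfig", "GroundTruth", "JointDataset", "generate_dataset",
           "ground_truth_connectomes", "write_dataset", "DOMAINS", "DOMAIN_TESTS"]


class InvalidConfigError(ValueError):
    """Simulation configuration violates an invariant."""


#: Cognitive domains and the raw tests feeding each (a compact MS-style
#: battery: symbol-digit / PASAT for processing speed, list learning for
#: verbal memory, visuospatial learning for visual memory, fluency and
#: inhibition for executive function, span tasks for working memory).
DOMAINS: tuple[str, ...] = ("IPS", "vermem", "vismem", "EF", "workmem")
DOMAIN_TESTS: dict[str, tuple[str, ...]] = {
    "IPS": ("sdmt", "pasat"),
    "vermem": ("list_learning", "list_delayed"),
    "vismem": ("spatial_learning", "spatial_delayed"),
    "EF": ("fluency", "stroop"),
    "workmem": ("digit_span", "spatial_span"),
}

#: (mean raw score, raw-score SD scale) per test, loosely matching published
#: normative ranges so subjects.csv looks like a plausible battery export.
_TEST_SCALES: dict[str, tuple[float, float]] = {
    "sdmt": (50.0, 10.0),
    "pasat": (45.0, 10.0),
    "list_learning": (55.0, 9.0),
    "list_delayed": (10.0, 2.5),
    "spatial_learning": (20.0, 5.0),
    "spatial_delayed": (8.0, 2.0),
    "fluency": (40.0, 9.0),
    "stroop": (50.0, 8.0),
    "digit_span": (16.0, 4.0),
    "spatial_span": (14.0, 3.5),
}

_GROUPS = ("RRMS", "SPMS", "PPMS")
#: Cohort age distributions per phenotype (mean, SD in years).
_AGE_BY_GROUP = {"RRMS": (41.9, 10.1), "SPMS": (54.0, 7.24), "PPMS": (50.9, 8.99)}
_P_MALE = 29 / 89


def _default_beta(k: int) -> np.ndarray:
    """Default cognition-on-loading effects (domains x sources).

    Each domain leans on one or two sources with moderate slopes so the
    association battery has real signal to find without any domain being a
    deterministic copy of a loading column.
    """
    beta = np.zeros((len(DOMAINS), k))
    primary = [0.55, 0.50, 0.50, 0.45, 0.50]
    secondary = [0.20, 0.15, 0.20, 0.25, 0.15]
    for d in range(len(DOMAINS)):
        beta[d, d % k] = primary[d]
        if k > 1:
            beta[d, (d + 1) % k] = secondary[d]
    return beta


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the emulated cohort: 90 subjects split across RRMS /
    SPMS / PPMS at the 53:22:14 cohort ratio, 121 ROIs (20 deep GM), 2000
    voxel-level GM features, 5 joint sources, and signal-to-noise ratio 5
    per modality (ratio of source-signal SD to additive-noise SD).
    """

    n_subjects: int = 90
    group_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"RRMS": 53 / 89, "SPMS": 22 / 89, "PPMS": 14 / 89}
    )
    n_rois: int = 121
    n_deep_rois: int = 20
    gm_features: int = 2000
    k_sources: int = 5
    snr_gm: float = 5.0
    snr_wm: float = 5.0
    #: domains x k_sources slopes of cognition on loadings; None -> default pattern
    beta: np.ndarray | None = None
    #: per-domain slope of cognition on age (z-units per year)
    age_effect: float | Sequence[float] = -0.015
    #: fraction of GM features active per source, and whether supports overlap.
    #: 0.02 keeps every active feature's |z| above the GM attribution
    #: threshold of 5 in the noiseless limit: active magnitudes are bounded
    #: below by 1 while the source row SD is ~sqrt(sparsity * E[v^2]), so
    #: min |z| ~ 1/sqrt(0.02 * 1.6) ~ 5.6 (at 5% it would be ~4.5 < 5 and
    #: the planted support would be undetectable by construction).
    source_sparsity: float = 0.02
    disjoint_supports: bool = True
    #: per-source modality confinement: "joint", "gm" or "wm"
    source_modality: Sequence[str] | None = None
    #: ROIs whose mutual edges form each WM source pattern; None derives the
    #: clique size from source_sparsity (m(m-1)/2 ~ sparsity * n_edges),
    #: capped so k disjoint cliques fit in the parcellation
    rois_per_wm_source: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        props = dict(self.group_proportions)
        if abs(sum(props.values()) - 1.0) > 1e-12:
            raise InvalidConfigError("group_proportions must sum to 1")
        for name, val in [
            ("n_subjects", self.n_subjects), ("n_rois", self.n_rois),
            ("gm_features", self.gm_features), ("k_sources", self.k_sources),
        ]:
            if val <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {val}")
        if not 0 < self.n_deep_rois < self.n_rois:
            raise InvalidConfigError("n_deep_rois must be in (0, n_rois)")
        if self.snr_gm <= 0 or self.snr_wm <= 0:
            raise InvalidConfigError("SNR values must be > 0")
        n_edges = self.n_rois * (self.n_rois - 1) // 2
        if self.k_sources > min(self.n_subjects, self.gm_features, n_edges):
            raise InvalidConfigError(
                f"k_sources={self.k_sources} exceeds min(n_subjects, features)"
            )
        if not 0 < self.source_sparsity <= 1:
            raise InvalidConfigError("source_sparsity must be in (0, 1]")
        if self.source_modality is not None:
            if len(self.source_modality) != self.k_sources:
                raise InvalidConfigError("source_modality must have k_sources entries")
            bad = set(self.source_modality) - {"joint", "gm", "wm"}
            if bad:
                raise InvalidConfigError(f"unknown source_modality values {bad}")
        if self.beta is not None:
            b = np.asarray(self.beta, dtype=float)
            if b.shape != (len(DOMAINS), self.k_sources):
                raise InvalidConfigError(
                    f"beta must be {len(DOMAINS)} x {self.k_sources}, got {b.shape}"
                )
            self.beta = b

    @property
    def n_edges(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    def resolved_beta(self) -> np.ndarray:
        return _default_beta(self.k_sources) if self.beta is None else np.asarray(self.beta)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery scoring."""

    true_sources_gm: np.ndarray      # k x gm_features, unit-norm rows
    true_sources_wm: np.ndarray      # k x n_edges, unit-norm rows
    true_loadings: np.ndarray        # n x k
    cognition_betas: np.ndarray      # domains x k
    age_effect: np.ndarray           # per-domain slope
    noise_sds: dict[str, float]
    gm_support: list[np.ndarray]     # per-source active GM feature indices
    wm_support: list[np.ndarray]     # per-source active edge indices
    domain_scores: np.ndarray        # n x domains, raw generated scores
    fa_edges: np.ndarray             # n x n_edges, per-subject FA values in (0,1)
    wm_features: np.ndarray          # n x n_edges, combined (FA*count) values
    roi_labels: list[str]
    deep_rois: list[str]
    gm_feature_rois: list[str]       # ROI label per GM feature

    @property
    def k(self) -> int:
        return self.true_loadings.shape[1]


@dataclass
class JointDataset:
    """Aligned subject table + per-modality feature matrices."""

    subjects: pd.DataFrame          # id, group, age_years, sex, tiv_ml, raw tests
    gm: ModalityMatrix
    wm: ModalityMatrix
    roi_labels: list[str]
    deep_rois: list[str]
    gm_feature_rois: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["id"])


def _group_counts(n: int, props: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n subjects to groups."""
    names = list(props)
    exact = np.array([props[g] * n for g in names])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(names, counts))


def _sparse_unit_sources(
    rng: np.random.Generator, k: int, n_features: int, sparsity: float, disjoint: bool
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sparse unit-norm source rows with (optionally disjoint) supports."""
    per = max(2, int(round(sparsity * n_features)))
    if disjoint and per * k > n_features:
        raise InvalidConfigError("disjoint supports need sparsity * k <= 1")
    sources = np.zeros((k, n_features))
    supports: list[np.ndarray] = []
    if disjoint:
        perm = rng.permutation(n_features)
        chunks = [np.sort(perm[i * per:(i + 1) * per]) for i in range(k)]
    else:
        chunks = [np.sort(rng.choice(n_features, size=per, replace=False)) for _ in range(k)]
    for i, idx in enumerate(chunks):
        # magnitudes bounded below by 1 so every active feature stands clear
        # of the z-threshold; random signs keep the source mean near zero.
        vals = rng.choice([-1.0, 1.0], size=per) * (1.0 + 0.3 * np.abs(rng.normal(size=per)))
        sources[i, idx] = vals
        sources[i] /= np.linalg.norm(sources[i])
        supports.append(idx)
    return sources, supports


def _wm_clique_sources(
    rng: np.random.Generator, k: int, n_rois: int, rois_per_source: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """WM edge sources: each source activates the edges among a small ROI set.

    Mimics a covarying subnetwork: a handful of regions whose mutual
    connections strengthen or weaken together across subjects.
    """
    iu, ju = edge_index_pairs(n_rois)
    n_edges = iu.size
    sources = np.zeros((k, n_edges))
    supports: list[np.ndarray] = []
    roi_perm = rng.permutation(n_rois)
    for s in range(k):
        rois = roi_perm[s * rois_per_source:(s + 1) * rois_per_source]
        if rois.size < 2:  # fall back to random ROI picks if parcellation exhausted
            rois = rng.choice(n_rois, size=rois_per_source, replace=False)
        in_set = np.isin(iu, rois) & np.isin(ju, rois)
        idx = np.flatnonzero(in_set)
        vals = rng.choice([-1.0, 1.0], size=idx.size) * (
            1.0 + 0.3 * np.abs(rng.normal(size=idx.size))
        )
        sources[s, idx] = vals
        sources[s] /= np.linalg.norm(sources[s])
        supports.append(idx)
    return sources, supports


def generate_dataset(config: SimConfig) -> tuple[JointDataset, GroundTruth]:
    """Generate one synthetic cohort with planted joint sources.

    The generative model per subject i is::

        gm_i = gm_baseline + A[i] @ S_gm * amp_gm + noise_gm
        wm_i = wm_baseline + A[i] @ S_wm * amp_wm + noise_wm
        domain_d,i = beta[d] @ A[i] + age_effect[d] * age_i + noise_cog

    with noise SDs set from the configured per-modality SNR (signal SD /
    noise SD) and the cognitive noise chosen so each raw domain score has
    variance ~1 before cohort z-scoring. The same seed always yields a
    bit-identical dataset.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_subjects, cfg.k_sources
    n_edges = cfg.n_edges

    # --- cohort table -----------------------------------------------------
    counts = _group_counts(n, cfg.group_proportions)
    groups = np.concatenate([[g] * c for g, c in counts.items()])
    age = np.concatenate(
        [
            np.clip(rng.normal(*_AGE_BY_GROUP.get(g, (46.3, 10.7)), size=c), 18, 65)
            for g, c in counts.items()
        ]
    )
    sex = np.where(rng.random(n) < _P_MALE, "M", "F")
    tiv = rng.normal(1450.0, 120.0, size=n).clip(1100, 1900)  # ml
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]

    # --- parcellation -----------------------------------------------------
    n_cort = cfg.n_rois - cfg.n_deep_rois
    roi_labels = [f"ctx-{i + 1:03d}" for i in range(n_cort)] + [
        f"dgm-{i + 1:03d}" for i in range(cfg.n_deep_rois)
    ]
    deep_rois = roi_labels[n_cort:]
    # assign GM features to ROIs in contiguous blocks (voxels of a region
    # are spatially contiguous); block sizes near-equal.
    bounds = np.linspace(0, cfg.gm_features, cfg.n_rois + 1).astype(int)
    gm_feature_rois = [
        roi_labels[r] for r in range(cfg.n_rois) for _ in range(bounds[r + 1] - bounds[r])
    ]

    # --- planted sources and loadings ------------------------------------
    s_gm, gm_support = _sparse_unit_sources(
        rng, k, cfg.gm_features, cfg.source_sparsity, cfg.disjoint_supports
    )
    m = cfg.rois_per_wm_source
    if m is None:
        target_edges = cfg.source_sparsity * n_edges
        m = int(round((1 + np.sqrt(1 + 8 * target_edges)) / 2))
        m = max(3, min(m, cfg.n_rois // k))
    s_wm, wm_support = _wm_clique_sources(rng, k, cfg.n_rois, m)
    modality = list(cfg.source_modality) if cfg.source_modality is not None else ["joint"] * k
    for s, m in enumerate(modality):
        if m == "gm":
            s_wm[s] = 0.0
            wm_support[s] = np.array([], dtype=int)
        elif m == "wm":
            s_gm[s] = 0.0
            gm_support[s] = np.array([], dtype=int)

    loadings = rng.normal(0.0, 1.0, size=(n, k))
    loadings = (loadings - loadings.mean(0)) / loadings.std(0, ddof=0)
    # phenotype structure: the first two sources are expressed more strongly
    # in progressive disease, echoing group differences in component loadings.
    loadings[:, 0] += np.array([{"RRMS": -0.3, "SPMS": 0.6, "PPMS": 0.2}[g] for g in groups])
    if k > 1:
        loadings[:, 1] += np.array([{"RRMS": -0.1, "SPMS": 0.1, "PPMS": 0.4}[g] for g in groups])

    # --- GM modality ------------------------------------------------------
    # SNR is the ratio of signal SD to noise SD measured over the features a
    # source actually touches; measuring over all features would dilute the
    # signal SD by the sparsity and understate the effective noise.
    amp_gm = 1.0
    signal_gm = loadings @ s_gm * amp_gm
    active_gm = np.abs(s_gm).sum(0) > 0
    sd_sig_gm = signal_gm[:, active_gm].std() if active_gm.any() else 0.0
    noise_sd_gm = sd_sig_gm / cfg.snr_gm if sd_sig_gm > 0 else 1e-3
    gm_baseline = rng.uniform(0.4, 0.8, size=cfg.gm_features)
    gm_data = gm_baseline + signal_gm + rng.normal(0.0, noise_sd_gm, size=(n, cfg.gm_features))

    # --- WM modality ------------------------------------------------------
    amp_wm = 1.0
    signal_wm = loadings @ s_wm * amp_wm
    active_wm = np.abs(s_wm).sum(0) > 0
    sd_sig_wm = signal_wm[:, active_wm].std() if active_wm.any() else 0.0
    noise_sd_wm = sd_sig_wm / cfg.snr_wm if sd_sig_wm > 0 else 1e-3
    # positive baseline keeps combined FA*count weights nonnegative; constant
    # across subjects so it vanishes under feature centering.
    wm_baseline = rng.uniform(6.0, 14.0, size=n_edges)
    wm_data = wm_baseline + signal_wm + rng.normal(0.0, noise_sd_wm, size=(n, n_edges))
    np.clip(wm_data, 0.0, None, out=wm_data)

    # per-subject FA values (plausible tract FA range) used to factor the
    # combined weight into FA x streamline-count matrices.
    fa_base = rng.uniform(0.25, 0.65, size=n_edges)
    fa_edges = np.clip(fa_base + rng.normal(0.0, 0.03, size=(n, n_edges)), 0.05, 0.95)

    # --- cognition --------------------------------------------------------
    beta = cfg.resolved_beta()
    age_eff = np.asarray(cfg.age_effect, dtype=float)
    if age_eff.ndim == 0:
        age_eff = np.full(len(DOMAINS), float(age_eff))
    if age_eff.shape != (len(DOMAINS),):
        raise InvalidConfigError("age_effect must be scalar or per-domain")
    cog_signal = loadings @ beta.T + np.outer(age, age_eff)  # n x domains
    noise_var = np.maximum(1.0 - cog_signal.var(axis=0), 0.05)
    domain_scores = cog_signal + rng.normal(0.0, np.sqrt(noise_var), size=(n, len(DOMAINS)))

    # raw test scores: each test is an affine transform of its domain score
    # plus test-specific noise, as in a real battery export.
    tests: dict[str, np.ndarray] = {}
    for d, dom in enumerate(DOMAINS):
        for t in DOMAIN_TESTS[dom]:
            mu, sd = _TEST_SCALES[t]
            tests[t] = mu + sd * (domain_scores[:, d] + rng.normal(0.0, 0.3, size=n))

    subjects = pd.DataFrame(
        {"id": subject_ids, "group": groups, "age_years": np.round(age, 1),
         "sex": sex, "tiv_ml": np.round(tiv, 1), **{t: np.round(v, 2) for t, v in tests.items()}}
    )

    gm = ModalityMatrix(gm_data, "GM", [f"gmfeat{j:04d}" for j in range(cfg.gm_features)],
                        subject_ids)
    wm = ModalityMatrix(wm_data, "WM", edge_labels(roi_labels), subject_ids)

    dataset = JointDataset(subjects, gm, wm, roi_labels, deep_rois, gm_feature_rois)
    truth = GroundTruth(
        true_sources_gm=s_gm, true_sources_wm=s_wm, true_loadings=loadings,
        cognition_betas=beta, age_effect=age_eff,
        noise_sds={"GM": noise_sd_gm, "WM": noise_sd_wm},
        gm_support=gm_support, wm_support=wm_support, domain_scores=domain_scores,
        fa_edges=fa_edges, wm_features=wm_data, roi_labels=roi_labels,
        deep_rois=deep_rois, gm_feature_rois=gm_feature_rois,
    )
    return dataset, truth


def ground_truth_connectomes(gt: GroundTruth, subject: int) -> tuple[Connectome, Connectome]:
    """Per-subject (FA, streamline-count) connectome pair.

    Factors the stored combined WM feature row ``w`` into an FA matrix and a
    streamline matrix such that ``fa_ij * sc_ij == w_ij`` exactly, so the
    feature-builder path (combine then vectorize) reproduces the WM row.
    """
    n = gt.wm_features.shape[0]
    if not 0 <= subject < n:
        raise IndexError(f"subject index {subject} out of range [0, {n})")
    w = gt.wm_features[subject]
    fa = gt.fa_edges[subject].copy()
    fa[w == 0] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        sc = np.where(fa > 0, w / np.where(fa > 0, fa, 1.0), 0.0)
    r = len(gt.roi_labels)
    fa_c = unvectorize_edges(fa, r, gt.roi_labels)
    fa_c.kind = "fa"
    sc_c = unvectorize_edges(sc, r, gt.roi_labels)
    sc_c.kind = "streamlines"
    return fa_c, sc_c


def write_dataset(
    dataset: JointDataset,
    gt: GroundTruth,
    outdir: str | Path,
    connectomes: bool = True,
    nifti: bool = False,
) -> None:
    """Write the cohort to plain-text files (optionally NIfTI for GM).

    Emits subjects.csv, gm_features.csv, wm_features.csv, per-subject FA and
    streamline connectome CSVs, and ground_truth.json + source CSVs. With
    ``nifti=True`` additionally writes the GM features as a 4D NIfTI stack
    plus a 3D integer-label atlas volume (features laid out on a compact
    grid).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.subjects.to_csv(out / "subjects.csv", index=False)
    write_modality_csv(dataset.gm, out / "gm_features.csv")
    write_modality_csv(dataset.wm, out / "wm_features.csv")
    pd.DataFrame({"feature": dataset.gm.feature_index, "roi": dataset.gm_feature_rois}).to_csv(
        out / "gm_feature_rois.csv", index=False
    )
    if connectomes:
        cdir = out / "connectomes"
        cdir.mkdir(exist_ok=True)
        for i, sid in enumerate(dataset.subject_ids):
            fa, sc = ground_truth_connectomes(gt, i)
            write_connectome_csv(fa, cdir / f"{sid}_fa.csv")
            write_connectome_csv(sc, cdir / f"{sid}_streamlines.csv")
    np.savetxt(out / "true_sources_gm.csv", gt.true_sources_gm, delimiter=",", fmt="%.10g")
    np.savetxt(out / "true_sources_wm.csv", gt.true_sources_wm, delimiter=",", fmt="%.10g")
    np.savetxt(out / "true_loadings.csv", gt.true_loadings, delimiter=",", fmt="%.10g")
    meta = {
        "cognition_betas": gt.cognition_betas.tolist(),
        "age_effect": gt.age_effect.tolist(),
        "noise_sds": gt.noise_sds,
        "gm_support": [s.tolist() for s in gt.gm_support],
        "wm_support": [s.tolist() for s in gt.wm_support],
        "roi_labels": gt.roi_labels,
        "deep_rois": gt.deep_rois,
        "domains": list(DOMAINS),
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=1))
    if nifti:
        _write_nifti(dataset, out)


def _write_nifti(dataset: JointDataset, out: Path) -> None:
    """GM features as a 4D NIfTI stack + integer-label atlas volume."""
    import nibabel as nib

    f = dataset.gm.n_features
    side = int(np.ceil(f ** (1 / 3)))
    vol = side ** 3
    n = dataset.n_subjects
    stack = np.zeros((vol, n), dtype=np.float32)
    stack[:f] = dataset.gm.data.T
    stack4d = stack.reshape(side, side, side, n)
    roi_ids = {r: i + 1 for i, r in enumerate(dataset.roi_labels)}
    labels = np.zeros(vol, dtype=np.int16)
    labels[:f] = [roi_ids[r] for r in dataset.gm_feature_rois]
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(stack4d, affine), out / "gm_features.nii")
    nib.save(nib.Nifti1Image(labels.reshape(side, side, side), affine), out / "gm_atlas.nii")
    pd.DataFrame({"label": list(roi_ids.values()), "roi": list(roi_ids.keys())}).to_csv(
        out / "gm_atlas_labels.csv", index=False
    )
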