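"""End-to-end pipeline: simulate -> features -> decompositions -> ICASSO ->
attribution -> associations -> model comparison, plus ground-truth recovery
scoring.

All randomness flows from a single root seed through fixed offsets per
stage (simulation uses the root seed, single-run ICA seed = root + 1000,
ICASSO base seed = root + 2000), so a rerun with the same configuration is
bit-identical for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import __version__
from .decomposition import Decomposition, jointica_fit, single_tissue_ica
from .features import (
    gm_roi_volumes,
    read_connectome_csv,
    read_modality_csv,
    tissue_summaries,
    vectorize_connectome,
)
from .icasso import run_icasso, select_centrotypes
from .report import attribute_components, gm_attribution_frame, wm_attribution_frame
from .simulate import (
    DOMAIN_TESTS,
    DOMAINS,
    GroundTruth,
    JointDataset,
    SimConfig,
    generate_dataset,
    write_dataset,
)
from .stats import (
    ancova_tukey,
    cognitive_domain_scores,
    compare_models_lrt,
    encode_sex,
    fdr_bh,
    partial_pearson,
    spearman_assoc,
    stepwise_regression,
)

log = logging.getLogger("jointica")

#: seed offsets per stage, all derived from the root seed
SEED_ICA = 1000
SEED_ICASSO = 2000

__all__ = ["PipelineConfig", "RecoveryReport", "run_pipeline", "match_components",
           "amari_index", "roi_volume_table", "load_dataset"]


def load_dataset(input_dir: str | Path) -> tuple[JointDataset, np.ndarray, np.ndarray]:
    """Read a cohort from the plain-text layout written by ``write_dataset``.

    Requires subjects.csv, gm_features.csv, wm_features.csv,
    gm_feature_rois.csv, and a connectomes/ directory of per-subject FA and
    streamline matrices. Returns the dataset plus subjects x edges FA and
    streamline-count arrays for the tissue summaries.
    """
    d = Path(input_dir)
    required = ["subjects.csv", "gm_features.csv", "wm_features.csv",
                "gm_feature_rois.csv"]
    for fname in required:
        if not (d / fname).exists():
            raise FileNotFoundError(f"missing input file: {d / fname}")
    subjects = pd.read_csv(d / "subjects.csv")
    gm = read_modality_csv(d / "gm_features.csv", "GM")
    wm = read_modality_csv(d / "wm_features.csv", "WM")
    feature_rois = pd.read_csv(d / "gm_feature_rois.csv")["roi"].astype(str).tolist()
    # edge labels "roiA--roiB" in row-major upper-triangle order: the first
    # R-1 labels enumerate roi0 paired with roi1..roi(R-1).
    n_edges = wm.n_features
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    first = [lbl.split("--") for lbl in wm.feature_index[: r - 1]]
    roi_labels = [first[0][0]] + [pair[1] for pair in first]
    meta_path = d / "ground_truth.json"
    if meta_path.exists():
        deep = json.loads(meta_path.read_text()).get("deep_rois", [])
    else:
        deep = [lbl for lbl in roi_labels if lbl.startswith("dgm")]
    dataset = JointDataset(subjects, gm, wm, roi_labels, deep, feature_rois)
    cdir = d / "connectomes"
    if not cdir.exists():
        raise FileNotFoundError(f"missing input directory: {cdir}")
    fa_rows, sc_rows = [], []
    for sid in dataset.subject_ids:
        for suffix, rows, kind in (("fa", fa_rows, "fa"),
                                   ("streamlines", sc_rows, "streamlines")):
            path = cdir / f"{sid}_{suffix}.csv"
            if not path.exists():
                raise FileNotFoundError(f"missing input file: {path}")
            rows.append(vectorize_connectome(read_connectome_csv(path, roi_labels, kind)))
    return dataset, np.vstack(fa_rows), np.vstack(sc_rows)


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run."""

    out_dir: str = "jointica_run"
    n_components: int = 5
    icasso_runs: int = 10
    gm_tau: float = 5.0
    overlap_min: float = 0.05
    wm_ci: float = 0.99
    stepwise_criterion: str = "aic"
    fdr_family: str = "per_summary"
    seed: int = 0
    #: simulation settings (used when no input directory is given)
    sim: dict = field(default_factory=dict)
    #: optional directory of pre-built inputs (subjects.csv, gm/wm features)
    input_dir: str | None = None
    write_inputs: bool = True
    run_icasso_stage: bool = True
    single_tissue: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RecoveryReport:
    """How well an estimated decomposition recovers the planted sources."""

    assignment: list[tuple[int, int]]       # (true source, matched component)
    loading_corr: np.ndarray                # |corr| per matched pair
    gm_source_corr: np.ndarray
    wm_source_corr: np.ndarray
    unmatched_true: list[int]
    unmatched_est: list[int]

    @property
    def mean_loading_corr(self) -> float:
        return float(self.loading_corr.mean())

    @property
    def mean_gm_source_corr(self) -> float:
        vals = self.gm_source_corr[~np.isnan(self.gm_source_corr)]
        return float(vals.mean()) if vals.size else float("nan")

    @property
    def mean_wm_source_corr(self) -> float:
        vals = self.wm_source_corr[~np.isnan(self.wm_source_corr)]
        return float(vals.mean()) if vals.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_source": [a[0] for a in self.assignment],
                "component": [a[1] for a in self.assignment],
                "loading_abs_corr": self.loading_corr,
                "gm_source_abs_corr": self.gm_source_corr,
                "wm_source_abs_corr": self.wm_source_corr,
            }
        )


def _abs_corr_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|corr| between columns of a (n x p) and columns of b (n x q)."""
    a = (a - a.mean(0)) / a.std(0, ddof=0)
    b = (b - b.mean(0)) / b.std(0, ddof=0)
    return np.abs(a.T @ b) / a.shape[0]


def _safe_abs_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(abs(np.corrcoef(x, y)[0, 1]))


def match_components(truth: GroundTruth, est: Decomposition) -> RecoveryReport:
    """Hungarian assignment of estimated components to planted sources,
    maximising total |corr| between loading columns."""
    A_true = truth.true_loadings
    A_est = est.loadings
    if A_true.shape[0] != A_est.shape[0]:
        raise ValueError("truth and estimate have different subject counts")
    k, c = A_true.shape[1], A_est.shape[1]
    corr = _abs_corr_matrix(A_true, A_est)          # k x c
    r_true, r_est = linear_sum_assignment(-corr)
    pairs = list(zip(r_true.tolist(), r_est.tolist()))
    loading_corr = np.array([corr[i, j] for i, j in pairs])
    gm_corr = np.array(
        [_safe_abs_corr(truth.true_sources_gm[i], est.sources_gm[j]) for i, j in pairs]
    )
    wm_corr = np.array(
        [_safe_abs_corr(truth.true_sources_wm[i], est.sources_wm[j]) for i, j in pairs]
    )
    matched_true = {i for i, _ in pairs}
    matched_est = {j for _, j in pairs}
    return RecoveryReport(
        assignment=pairs,
        loading_corr=loading_corr,
        gm_source_corr=gm_corr,
        wm_source_corr=wm_corr,
        unmatched_true=[i for i in range(k) if i not in matched_true],
        unmatched_est=[j for j in range(c) if j not in matched_est],
    )


def amari_index(w_est: np.ndarray, mixing_true: np.ndarray) -> float:
    """Amari separation index between an estimated unmixing matrix and the
    true mixing matrix (0 = perfect separation up to permutation/scale)."""
    p = np.abs(np.asarray(w_est) @ np.asarray(mixing_true))
    k = p.shape[0]
    rows = (p.sum(1) / p.max(1) - 1).sum() / (k - 1)
    cols = (p.sum(0) / p.max(0) - 1).sum() / (k - 1)
    return float((rows + cols) / (2 * k))


def roi_volume_table(dataset: JointDataset) -> pd.DataFrame:
    """Subjects x ROIs table of TIV-normalised GM volumes."""
    rows = []
    for i, sid in enumerate(dataset.subject_ids):
        vols = gm_roi_volumes(
            dataset.gm.data[i], dataset.gm_feature_rois,
            float(dataset.subjects["tiv_ml"].iloc[i]), atlas_rois=dataset.roi_labels,
        )
        rows.append(vols.rename(sid))
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all artifacts to ``config.out_dir``.

    Returns the output directory. See the module docstring for the seed
    discipline; ``manifest.json`` records the package version, config hash
    and stage seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)

    # --- stage 1: data ----------------------------------------------------
    if config.input_dir is not None:
        dataset, fa_edges, sc_edges = load_dataset(config.input_dir)
        truth = None
        log.info("loaded cohort from %s: n=%d", config.input_dir, dataset.n_subjects)
    else:
        sim_cfg = SimConfig(seed=config.seed, **config.sim)
        log.info("simulating cohort: n=%d, k=%d, seed=%d",
                 sim_cfg.n_subjects, sim_cfg.k_sources, config.seed)
        dataset, truth = generate_dataset(sim_cfg)
        if config.write_inputs:
            write_dataset(dataset, truth, out / "inputs", connectomes=False)
        fa_edges = truth.fa_edges
        sc_edges = np.where(fa_edges > 0, truth.wm_features / fa_edges, 0.0)

    # --- stage 2: features ------------------------------------------------
    summaries = tissue_summaries(
        dataset.gm, dataset.gm_feature_rois, dataset.deep_rois,
        dataset.subjects["tiv_ml"].to_numpy(), fa_edges, sc_edges,
    )
    summaries.to_csv(out / "tissue_summaries.csv")

    # --- stage 3: decompositions -----------------------------------------
    ica_seed = config.seed + SEED_ICA
    joint = jointica_fit(dataset.gm, dataset.wm, config.n_components, seed=ica_seed)
    log.info("joint ICA: converged=%s after %d iterations", joint.converged, joint.n_iter)
    singles: dict[str, Decomposition] = {}
    if config.single_tissue:
        singles["GM"] = single_tissue_ica(dataset.gm, config.n_components, seed=ica_seed)
        singles["WM"] = single_tissue_ica(dataset.wm, config.n_components, seed=ica_seed)

    # --- stage 4: ICASSO --------------------------------------------------
    if config.run_icasso_stage:
        summary = run_icasso(dataset.gm, dataset.wm, config.n_components,
                             n_runs=config.icasso_runs,
                             base_seed=config.seed + SEED_ICASSO)
        summary.to_json(out / "icasso_summary.json")
        summary.similarity_to_csv(out / "similarity_matrix.csv")
        final = select_centrotypes(summary)
        log.info("ICASSO: Iq per cluster = %s", np.round(summary.iq, 3).tolist())
    else:
        final = joint

    _write_decomposition(final, out)

    # --- stage 5: attribution --------------------------------------------
    roi_vols = roi_volume_table(dataset)
    attributions = attribute_components(
        final, dataset.gm_feature_rois, dataset.roi_labels,
        gm_roi_volumes_by_subject=roi_vols,
        wm_edge_values=dataset.wm.data,
        gm_tau=config.gm_tau, overlap_min=config.overlap_min, wm_ci=config.wm_ci,
    )
    gm_attribution_frame(attributions).to_csv(out / "components_gm.csv", index=False)
    wm_attribution_frame(attributions).to_csv(out / "components_wm.csv", index=False)

    # --- stage 6: associations -------------------------------------------
    comp_names = [f"comp{c + 1:02d}" for c in range(final.n_components)]
    loadings_df = pd.DataFrame(final.loadings_z(), index=pd.Index(dataset.subject_ids,
                               name="subject_id"), columns=comp_names)
    assoc = spearman_assoc(loadings_df, summaries, fdr_family=config.fdr_family)

    domains = cognitive_domain_scores(
        dataset.subjects.set_index("id"), DOMAIN_TESTS
    )
    age = dataset.subjects["age_years"].to_numpy(dtype=float)
    sex = encode_sex(dataset.subjects["sex"])
    cov = np.column_stack([age, sex])
    partial_rows = []
    for dom in DOMAINS:
        for comp in comp_names:
            r, p = partial_pearson(domains[dom].to_numpy(), loadings_df[comp].to_numpy(), cov)
            partial_rows.append({"component": comp, "target": dom,
                                 "method": "partial_pearson", "r": r, "p": p,
                                 "covariates": "age,sex", "n": len(age)})
    partial_df = pd.DataFrame(partial_rows)
    partial_df["p_fdr"] = partial_df.groupby("target")["p"].transform(
        lambda s: fdr_bh(s.to_numpy())
    )
    pd.concat([assoc, partial_df], ignore_index=True).to_csv(
        out / "associations.csv", index=False
    )

    group = dataset.subjects["group"].to_numpy()
    contrast_rows = []
    for comp in comp_names:
        res = ancova_tukey(loadings_df[comp].to_numpy(), group,
                           pd.DataFrame({"age": age, "sex": sex}))
        tuk = res["tukey"].assign(outcome=comp, F=res["F"], p_group=res["p"])
        contrast_rows.append(tuk)
    pd.concat(contrast_rows, ignore_index=True).to_csv(out / "group_contrasts.csv",
                                                       index=False)

    # --- stage 7: model comparison ---------------------------------------
    model_rows = []
    if config.single_tissue:
        forced = pd.DataFrame({"age": age, "sex": sex}, index=loadings_df.index)
        model_sets = {"joint": loadings_df}
        for name, dec in singles.items():
            model_sets[name] = pd.DataFrame(
                dec.loadings_z(), index=loadings_df.index,
                columns=[f"{name.lower()}{c + 1:02d}" for c in range(dec.n_components)],
            )
        for dom in DOMAINS:
            yd = domains[dom].to_numpy()
            fits = {name: stepwise_regression(yd, cands, forced,
                                              criterion=config.stepwise_criterion)
                    for name, cands in model_sets.items()}
            for pair in (("joint", "GM"), ("joint", "WM"), ("GM", "WM")):
                lrt = compare_models_lrt(fits[pair[0]], fits[pair[1]])
                model_rows.append({
                    "domain": dom, "model_a": pair[0], "model_b": pair[1],
                    "adj_r2_a": fits[pair[0]].adj_r2, "adj_r2_b": fits[pair[1]].adj_r2,
                    "predictors_a": "+".join(fits[pair[0]].selected) or "(covariates)",
                    "predictors_b": "+".join(fits[pair[1]].selected) or "(covariates)",
                    "lrt_statistic": lrt["statistic"], "lrt_df": lrt["df"],
                    "lrt_p": lrt["p"], "non_nested": lrt["non_nested"],
                })
        pd.DataFrame(model_rows).to_csv(out / "model_comparison.csv", index=False)
        (out / "model_comparison.json").write_text(
            json.dumps(model_rows, indent=1, default=float)
        )

    # --- stage 8: recovery + manifest ------------------------------------
    recovery = None
    if truth is not None:
        recovery = match_components(truth, final)
        recovery.to_frame().to_csv(out / "recovery.csv", index=False)
    manifest = {
        "jointica_version": __version__,
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seeds": {"root": config.seed, "ica": ica_seed,
                  "icasso_base": config.seed + SEED_ICASSO},
        "n_subjects": dataset.n_subjects,
        "recovery_mean_loading_corr": (recovery.mean_loading_corr
                                       if recovery is not None else None),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("pipeline complete: %s", out)
    return out


def _write_decomposition(dec: Decomposition, out: Path) -> None:
    comp_names = [f"comp{c + 1:02d}" for c in range(dec.n_components)]
    idx = pd.Index(dec.subject_ids or range(dec.loadings.shape[0]), name="subject_id")
    pd.DataFrame(dec.loadings, index=idx, columns=comp_names).to_csv(out / "loadings.csv")
    pd.DataFrame(dec.loadings_z(), index=idx, columns=comp_names).to_csv(
        out / "loadings_z.csv"
    )
    np.savetxt(out / "sources_gm.csv", dec.sources_gm, delimiter=",", fmt="%.10g")
    np.savetxt(out / "sources_wm.csv", dec.sources_wm, delimiter=",", fmt="%.10g")
    info = {
        "n_components": dec.n_components,
        "seed": dec.seed,
        "converged": dec.converged,
        "n_iter": dec.n_iter,
        "modality_scales": (dec.preprocessing.modality_scales
                            if dec.preprocessing is not None else None),
        "gm_features": dec.sources_gm.shape[1],
        "wm_features": dec.sources_wm.shape[1],
    }
    (out / "decomposition.json").write_text(json.dumps(info, indent=1, default=float))


def _setup_logging(out: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(sh)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)
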