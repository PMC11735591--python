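"""Brain-behaviour statistics for component loadings.

Implements the full battery relating subject loadings to tissue summaries,
clinical phenotype, and cognition:

* cohort z-scoring of raw cognitive tests and averaging into domain scores
  (information processing speed, verbal/visual/working memory, executive
  function);
* Spearman correlations of loadings with whole-brain tissue summaries;
* Pearson partial correlations of loadings with domain scores controlling
  for age and sex;
* ANCOVA (group factor adjusted for age and sex) with covariate-adjusted
  Tukey HSD post-hoc contrasts;
* data-driven bidirectional stepwise linear regression (AIC criterion,
  forced covariates) of each domain on candidate loadings; and
* likelihood-ratio comparison of competing regression models, with
  Benjamini-Hochberg FDR adjustment within each analysis family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cognitive_domain_scores",
    "spearman_assoc",
    "partial_pearson",
    "ancova_tukey",
    "StepwiseResult",
    "stepwise_regression",
    "compare_models_lrt",
    "fdr_bh",
    "encode_sex",
]


def encode_sex(sex: Sequence[str]) -> np.ndarray:
    """0/1 encoding (F=0, M=1) used wherever sex enters a design matrix."""
    return np.asarray([1.0 if s in ("M", "m", "male", 1, True) else 0.0 for s in sex])


def cognitive_domain_scores(
    raw_tests: pd.DataFrame, domain_map: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Cohort z-scores per test, averaged into one score per domain.

    Each raw test column is standardized against the cohort mean and sample
    SD; a domain score is the mean of its constituent test z-scores (over
    the tests available for that subject). Returns the domain columns.
    """
    z = pd.DataFrame(index=raw_tests.index)
    for tests in domain_map.values():
        for t in tests:
            if t in z.columns:
                continue
            col = raw_tests[t].astype(float)
            if col.count() < 2:
                raise ValueError(f"test {t!r} needs at least 2 observed subjects")
            sd = col.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"test {t!r} is constant: cannot z-score")
            z[t] = (col - col.mean()) / sd
    out = pd.DataFrame(index=raw_tests.index)
    for dom, tests in domain_map.items():
        out[dom] = z[list(tests)].mean(axis=1)
    return out


def spearman_assoc(
    loadings: pd.DataFrame, summaries: pd.DataFrame, fdr_family: str = "per_summary"
) -> pd.DataFrame:
    """Spearman rho of every loading column against every tissue summary.

    FDR is applied within each summary column (across components) by
    default; ``fdr_family="all"`` corrects over the whole table instead.
    """
    if not loadings.index.equals(summaries.index):
        raise ValueError("loadings and summaries index different subjects")
    rows = []
    for comp in loadings.columns:
        x = loadings[comp].to_numpy(dtype=float)
        for name in summaries.columns:
            y = summaries[name].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                raise ValueError(f"constant column in Spearman association ({name})")
            rho, p = stats.spearmanr(x, y)
            rows.append({"component": comp, "target": name, "method": "spearman",
                         "r": float(rho), "p": float(p), "n": len(x)})
    df = pd.DataFrame(rows)
    if fdr_family == "per_summary":
        df["p_fdr"] = df.groupby("target")["p"].transform(lambda s: fdr_bh(s.to_numpy()))
    else:
        df["p_fdr"] = fdr_bh(df["p"].to_numpy())
    return df


def partial_pearson(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on the
    covariates (with intercept) by least squares.

    p is two-sided from t with n - 2 - k degrees of freedom (k covariates).
    With no covariates this is the plain Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.shape[0]
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.ones((n, 1))
        k = 0
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        z = np.column_stack([np.ones(n), cov])
        k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k_covariates + 2 (n={n}, k={k})")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt(df / (1 - r_clip ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def ancova_tukey(
    outcome: np.ndarray,
    group: Sequence[str],
    covariates: pd.DataFrame | np.ndarray | None = None,
    alpha: float = 0.05,
) -> dict:
    """ANCOVA of ``outcome ~ group + covariates`` plus Tukey HSD post-hoc.

    The group F-test comes from the partial (type-II) sum of squares of the
    group factor. Post-hoc contrasts compare covariate-adjusted group means
    using the studentized-range distribution with the model residual df
    (Tukey-Kramer for unequal group sizes).
    """
    y = np.asarray(outcome, dtype=float)
    group = np.asarray(group)
    levels = sorted(pd.unique(group))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = pd.Series(group).value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = y.shape[0]
    dummies = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    if covariates is None:
        cov = np.empty((n, 0))
        cov_names: list[str] = []
    else:
        cov_df = pd.DataFrame(covariates)
        cov = cov_df.to_numpy(dtype=float)
        cov_names = [str(c) for c in cov_df.columns]
    X_full = sm.add_constant(np.column_stack([dummies, cov]), has_constant="add")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("singular ANCOVA design")
    full = sm.OLS(y, X_full).fit()
    X_red = sm.add_constant(cov, has_constant="add")
    reduced = sm.OLS(y, X_red).fit()
    df_num = len(levels) - 1
    df_den = int(full.df_resid)
    # the nested SSR difference is nonnegative by construction; clamp the
    # catastrophic-cancellation case of an exactly-fitting reduced model
    extra_ssr = max(reduced.ssr - full.ssr, 0.0)
    f_stat = (extra_ssr / df_num) / (full.ssr / df_den) if full.ssr > 0 else 0.0
    p = float(stats.f.sf(f_stat, df_num, df_den))

    # covariate-adjusted means: group effect evaluated at mean covariates
    cov_mean = cov.mean(axis=0) if cov.shape[1] else np.empty(0)
    params = full.params
    cov_params = full.cov_params()
    k_groups = len(levels)
    rows = []
    for i in range(k_groups):
        for j in range(i + 1, k_groups):
            # contrast on the dummy coefficients: level i vs level j
            cvec = np.zeros(X_full.shape[1])
            if i > 0:
                cvec[i] = 1.0
            if j > 0:
                cvec[j] = -1.0
            diff = float(cvec @ params)
            se = float(np.sqrt(cvec @ cov_params @ cvec))
            q = abs(diff) / (se / np.sqrt(2))
            p_tukey = float(stats.studentized_range.sf(q, k_groups, df_den))
            rows.append({"group_a": levels[i], "group_b": levels[j],
                         "adjusted_diff": diff, "se": se, "q": q,
                         "p_tukey": p_tukey, "reject": p_tukey < alpha})
    adjusted_means = {}
    for i, g in enumerate(levels):
        m = params[0] + (params[i] if i > 0 else 0.0)
        if cov.shape[1]:
            m += float(params[k_groups:] @ cov_mean)
        adjusted_means[g] = float(m)
    return {
        "F": float(f_stat), "p": p, "df": (df_num, df_den),
        "adjusted_means": adjusted_means,
        "tukey": pd.DataFrame(rows),
        "model": full,
    }


@dataclass
class StepwiseResult:
    """Outcome of a stepwise regression: selection, fit, and likelihood."""

    selected: list[str]
    forced: list[str]
    params: pd.Series
    r2: float
    adj_r2: float
    llf: float
    aic: float
    n_params: int
    n: int
    model: object = field(repr=False, default=None)

    @property
    def rss(self) -> float:
        return float(self.model.ssr)


def _fit_ols(y: np.ndarray, X: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def stepwise_regression(
    y: np.ndarray,
    candidates: pd.DataFrame,
    forced: pd.DataFrame | None = None,
    criterion: str = "aic",
) -> StepwiseResult:
    """Bidirectional stepwise selection by AIC with forced covariates.

    Starts from the forced-covariate model; at each step considers adding
    any unselected candidate or dropping any selected one (forced columns
    are never dropped) and takes the single move with the lowest AIC,
    breaking ties toward the earlier-indexed candidate; stops when no move
    improves. Candidates that make the design singular are skipped with a
    warning. Deterministic.
    """
    if criterion != "aic":
        raise ValueError("only the AIC criterion is implemented")
    y = np.asarray(y, dtype=float)
    forced_df = pd.DataFrame(forced) if forced is not None else pd.DataFrame(index=candidates.index)
    forced_names = [str(c) for c in forced_df.columns]
    if y.shape[0] <= len(forced_names) + 2:
        raise ValueError("need n > n_forced + 2")
    cand_names = [str(c) for c in candidates.columns]
    selected: list[str] = []

    def design(sel: list[str]) -> pd.DataFrame:
        parts = [forced_df] if forced_names else []
        if sel:
            parts.append(candidates[sel])
        return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=candidates.index)

    def try_fit(sel: list[str]):
        X = design(sel)
        Xm = sm.add_constant(X, has_constant="add").to_numpy(dtype=float)
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            return None
        return _fit_ols(y, X)

    current = try_fit(selected)
    if current is None:
        raise ValueError("forced-covariate design is singular")
    current_aic = current.aic
    improved = True
    while improved:
        improved = False
        best_move, best_aic, best_fit = None, current_aic, None
        for name in cand_names:                      # additions, in index order
            if name in selected:
                continue
            fit = try_fit(selected + [name])
            if fit is None:
                warnings.warn(f"candidate {name!r} collinear with design; skipped")
                continue
            if fit.aic < best_aic - 1e-10:
                best_move, best_aic, best_fit = ("add", name), fit.aic, fit
        for name in selected:                        # removals
            rest = [s for s in selected if s != name]
            fit = try_fit(rest)
            if fit is not None and fit.aic < best_aic - 1e-10:
                best_move, best_aic, best_fit = ("drop", name), fit.aic, fit
        if best_move is not None:
            op, name = best_move
            if op == "add":
                selected.append(name)
            else:
                selected.remove(name)
            current, current_aic = best_fit, best_aic
            improved = True
    selected = [c for c in cand_names if c in selected]  # stable order
    return StepwiseResult(
        selected=selected,
        forced=forced_names,
        params=current.params,
        r2=float(current.rsquared),
        adj_r2=float(current.rsquared_adj),
        llf=float(current.llf),
        aic=float(current.aic),
        n_params=int(current.df_model) + 1,
        n=int(current.nobs),
        model=current,
    )


def compare_models_lrt(model_a, model_b) -> dict:
    """Likelihood-ratio comparison of two Gaussian OLS models of the same
    outcome.

    statistic = 2 * |ll_A - ll_B| (equivalently n * ln(RSS_worse /
    RSS_better) for OLS); df = |n_params_A - n_params_B| with a floor of 1;
    p from the chi-square upper tail. Models with different selected
    regressors are flagged ``non_nested`` — the chi-square reference is
    then an approximation, reported as the field-standard convention rather
    than silently corrected.
    """
    def _unpack(m):
        if isinstance(m, StepwiseResult):
            return m.llf, m.n_params, m.n, set(m.forced) | set(m.selected)
        return float(m.llf), int(m.df_model) + 1, int(m.nobs), None

    ll_a, k_a, n_a, terms_a = _unpack(model_a)
    ll_b, k_b, n_b, terms_b = _unpack(model_b)
    if n_a != n_b:
        raise ValueError(f"models fit on different n ({n_a} vs {n_b})")
    statistic = float(2.0 * abs(ll_a - ll_b))
    df = max(abs(k_a - k_b), 1)
    p = float(stats.chi2.sf(statistic, df))
    non_nested = None
    if terms_a is not None and terms_b is not None:
        non_nested = not (terms_a <= terms_b or terms_b <= terms_a)
    return {
        "statistic": statistic, "df": df, "p": p,
        "better": "a" if ll_a > ll_b else ("b" if ll_b > ll_a else "tie"),
        "non_nested": non_nested,
    }


def fdr_bh(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
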