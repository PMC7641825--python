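"""Model-development pipeline: screening, selection, pruning, CV.

The pipeline mirrors how the published algorithms were developed:

1. *Screening*: candidate covariates for direct mapping are a fixed,
   conceptually chosen subscale set; candidates for each EQ-5D item's
   ordinal equation are the subscales whose absolute Spearman rank
   correlation with the item reaches the source-specific threshold
   (0.4 for EORTC QLQ-C30, 0.3 for FACT-G).  Age and sex always enter
   the candidate set.
2. *Backward selection*: repeatedly drop the covariate with the largest
   Wald P value while it exceeds 0.15 and refit.  Two-part models select
   per part, indirect models per item equation.
3. *Face-validity pruning*: covariates whose coefficient sign opposes
   the anticipated direction (functioning/well-being/global health up,
   symptoms down) *and* whose P value exceeds 0.05 are removed together
   and the model refit once.
4. *Ninefold cross-validation*: the whole pipeline is rerun on each
   training split and RMSE / MAE / Pearson correlation are averaged
   over the held-out folds (overfitting-corrected performance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MappingDataset
from .engines import (
    DIRECT_METHODS,
    TWOPART_METHODS,
    FittedDirectModel,
    IndirectModel,
    OrdinalItemModel,
    fit_direct,
    fit_ordinal_item,
    predict_expected_index,
    predict_indirect_index,
    simulate_index,
)
from .valueset import DIMENSIONS, ValueSet

P_STAY_DEFAULT = 0.15   #: backward-selection retention threshold
P_DROP_DEFAULT = 0.05   #: face-validity pruning threshold
SCREEN_THRESHOLD = {"eortc": 0.4, "factg": 0.3}

#: conceptually chosen direct-mapping candidates (before age/sex)
DIRECT_CANDIDATES = {
    "eortc": ["pf", "rf", "ef", "cf", "sf", "ghs", "fa", "pa"],
    "factg": ["pwb", "swb", "ewb", "fwb"],
}

_POSITIVE_SCALES = {"pf", "rf", "ef", "cf", "sf", "ghs", "pwb", "swb", "ewb", "fwb"}
_NEGATIVE_SCALES = {"fa", "nv", "pa", "dy", "sl", "ap", "co", "di", "fi"}

__all__ = [
    "PerformanceReport", "SelectionTrace",
    "expected_signs", "screen_candidates", "backward_select",
    "backward_select_ordinal", "face_validity_prune", "performance",
    "kfold_cv", "fold_indices", "develop_direct", "develop_indirect",
    "evaluate_methods", "calibration_summaries",
]


@dataclass
class PerformanceReport:
    """RMSE, MAE and Pearson correlation of predictions vs observations."""

    rmse: float
    mae: float
    rho: float
    n: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"rmse": self.rmse, "mae": self.mae, "rho": self.rho, "n": self.n}


@dataclass
class SelectionTrace:
    """Ordered record of backward-selection drops for one equation."""

    equation: str
    steps: list = field(default_factory=list)  # (step, dropped covariate, P value)
    final: list = field(default_factory=list)


def expected_signs(source: str) -> dict:
    """Anticipated coefficient sign per covariate on the index scale.

    +1 for better-health scales, -1 for symptom scales, 0 (no
    constraint) for age and sex.
    """
    signs = {"age": 0, "female": 0}
    for s in DIRECT_CANDIDATES[source]:
        signs[s] = 1 if s in _POSITIVE_SCALES else -1
    if source == "eortc":
        for s in _NEGATIVE_SCALES:
            signs[s] = -1
        for s in _POSITIVE_SCALES - set(signs):
            signs[s] = 1
    return signs


def performance(observed, predicted) -> PerformanceReport:
    """RMSE, MAE and Pearson correlation between two index vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 observations")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    flags = []
    if np.std(obs) == 0 or np.std(pred) == 0:
        rho = float("nan")
        flags.append("rho undefined: zero variance")
    else:
        rho = float(np.corrcoef(obs, pred)[0, 1])
    return PerformanceReport(rmse, mae, rho, int(obs.size), flags)


def screen_candidates(data: MappingDataset, source: str | None = None) -> dict:
    """Candidate covariate sets for direct and per-item indirect mapping.

    Spearman rank correlations (average ranks for ties) are computed
    between every subscale and every EQ-5D item; a subscale becomes an
    item's candidate when |rho| meets the source threshold.  Age and sex
    are always appended.  Returns ``{"direct": [...], "items": {item:
    [...]}, "correlations": DataFrame}``.
    """
    source = source or data.source
    thr = SCREEN_THRESHOLD[source]
    subs = list(data.subscale_columns)
    direct = DIRECT_CANDIDATES[source] + ["age", "female"]
    out = {"direct": direct, "items": {}, "correlations": None}
    if not data.has_states:
        raise ValueError("indirect screening needs EQ-5D item columns")
    corr = pd.DataFrame(index=subs, columns=list(DIMENSIONS), dtype=float)
    for s in subs:
        x = data.df[s]
        if x.nunique(dropna=True) <= 1:
            warnings.warn(f"subscale {s!r} is constant; excluded from screening")
            continue
        for item in DIMENSIONS:
            rho = stats.spearmanr(x, data.df[item], nan_policy="omit").statistic
            corr.loc[s, item] = rho
    out["correlations"] = corr
    for item in DIMENSIONS:
        # 1e-12 guard so a rank correlation exactly at the threshold is
        # admitted despite floating-point representation
        keep = [s for s in subs
                if pd.notna(corr.loc[s, item]) and abs(corr.loc[s, item]) >= thr - 1e-12]
        out["items"][item] = keep + ["age", "female"]
    return out


def _drop_worst(pvalues: pd.Series, current: list, p_stay: float):
    """Largest-P covariate above threshold; ties drop the later declared."""
    ps = pvalues.reindex(current)
    if ps.isna().any():
        raise RuntimeError(f"missing P value for {ps.index[ps.isna()].tolist()}")
    worst = ps.max()
    if worst <= p_stay:
        return None, None
    # last occurrence of the maximum = later in declared order
    idx = max(i for i, c in enumerate(current) if ps[c] == worst)
    return current[idx], float(worst)


def _backward(fit_fn, candidates: list, p_stay: float, equation: str):
    """Generic backward selection over one equation.

    ``fit_fn(covariates)`` must return an object with ``.pvalues``
    (intercepts excluded or ignored via reindex).
    """
    current = list(candidates)
    trace = SelectionTrace(equation=equation)
    fitted = fit_fn(current)
    step = 0
    while current:
        drop, pval = _drop_worst(fitted.pvalues, current, p_stay)
        if drop is None:
            break
        step += 1
        trace.steps.append((step, drop, pval))
        current.remove(drop)
        fitted = fit_fn(current)
    trace.final = list(current)
    return fitted, trace


def backward_select(method: str, data: MappingDataset, candidates,
                    p_stay: float = P_STAY_DEFAULT, **fit_kw):
    """Backward selection for a direct method.

    Two-part methods run selection independently within each part
    (logistic and continuous) as separate equations.  Returns
    ``(FittedDirectModel, [SelectionTrace, ...])``.
    """
    if method not in DIRECT_METHODS:
        raise ValueError(f"unknown direct method {method!r}")
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate set must be non-empty")

    if method not in TWOPART_METHODS:
        def fit_fn(covs):
            return fit_direct(method, data, covs, **fit_kw).part
        part, trace = _backward(fit_fn, candidates, p_stay, method)
        model = fit_direct(method, data, trace.final, **fit_kw)
        return model, [trace]

    # per-part selection: each part refit alone during its own search
    def fit_logi(covs):
        return fit_direct(method, data, candidates, logistic_covariates=covs,
                          **fit_kw).logistic

    _, trace_logi = _backward(fit_logi, candidates, p_stay, f"{method}:logistic")

    def fit_cont(covs):
        return fit_direct(method, data, covs,
                          logistic_covariates=trace_logi.final, **fit_kw).part

    _, trace_cont = _backward(fit_cont, candidates, p_stay, f"{method}:continuous")
    model = fit_direct(method, data, trace_cont.final,
                       logistic_covariates=trace_logi.final, **fit_kw)
    return model, [trace_logi, trace_cont]


def backward_select_ordinal(data: MappingDataset, item: str, candidates,
                            p_stay: float = P_STAY_DEFAULT):
    """Backward selection for one EQ-5D item's proportional-odds equation."""
    def fit_fn(covs):
        return fit_ordinal_item(data, item, covs)
    return _backward(fit_fn, list(candidates), p_stay, f"ordinal:{item}")


def _wrong_sign(params: pd.Series, pvalues: pd.Series, covs, signs: dict,
                p_drop: float, flip: bool = False) -> list:
    removed = []
    for c in covs:
        s = signs.get(c, 0)
        if s == 0:
            continue
        coef = -params[c] if flip else params[c]
        if np.sign(coef) == -s and pvalues[c] > p_drop:
            removed.append(c)
    return removed


def face_validity_prune(method: str, data: MappingDataset,
                        model, signs: dict,
                        p_drop: float = P_DROP_DEFAULT, item: str | None = None,
                        **fit_kw):
    """Remove wrong-signed, non-significant covariates and refit once.

    A covariate is removed only when its sign opposes the anticipated
    direction *and* its Wald P exceeds ``p_drop``; significant
    wrong-signed covariates are retained.  Returns ``(model, removed)``.
    """
    if isinstance(model, OrdinalItemModel):
        removed = _wrong_sign(model.params, model.pvalues, model.covariates,
                              signs, p_drop)
        if removed:
            keep = [c for c in model.covariates if c not in removed]
            model = fit_ordinal_item(data, item or model.item, keep)
        return model, removed

    if not isinstance(model, FittedDirectModel):
        raise TypeError("model must be a FittedDirectModel or OrdinalItemModel")
    rm_cont = _wrong_sign(model.part.params, model.part.pvalues,
                          model.part.covariates, signs, p_drop)
    rm_logi = []
    if model.logistic is not None:
        rm_logi = _wrong_sign(model.logistic.params, model.logistic.pvalues,
                              model.logistic.covariates, signs, p_drop)
    removed = rm_cont + [f"logistic:{c}" for c in rm_logi]
    if removed:
        keep_cont = [c for c in model.part.covariates if c not in rm_cont]
        kw = dict(fit_kw)
        if model.logistic is not None:
            kw["logistic_covariates"] = [
                c for c in model.logistic.covariates if c not in rm_logi
            ]
        model = fit_direct(method, data, keep_cont, **kw)
    return model, removed


def develop_direct(method: str, data: MappingDataset, candidates=None,
                   p_stay: float = P_STAY_DEFAULT, p_drop: float = P_DROP_DEFAULT,
                   prune: bool = True, **fit_kw):
    """Full selection pipeline for one direct method; returns (model, traces)."""
    if candidates is None:
        candidates = DIRECT_CANDIDATES[data.source] + ["age", "female"]
    model, traces = backward_select(method, data, candidates, p_stay, **fit_kw)
    removed = []
    if prune:
        model, removed = face_validity_prune(method, data, model,
                                             expected_signs(data.source),
                                             p_drop, **fit_kw)
    return model, {"selection": traces, "pruned": removed}


def develop_indirect(data: MappingDataset, vs: ValueSet, candidates=None,
                     p_stay: float = P_STAY_DEFAULT, p_drop: float = P_DROP_DEFAULT,
                     prune: bool = True):
    """Full selection pipeline for the indirect model (per-item equations)."""
    if candidates is None:
        candidates = screen_candidates(data)["items"]
    signs = expected_signs(data.source)
    items, info = {}, {}
    for item in DIMENSIONS:
        fitted, trace = backward_select_ordinal(data, item, candidates[item], p_stay)
        removed = []
        if prune:
            fitted, removed = face_validity_prune(
                None, data, fitted, signs, p_drop, item=item
            )
        items[item] = fitted
        info[item] = {"selection": trace, "pruned": removed}
    return IndirectModel(items=items, valueset=vs), info


def fold_indices(n: int, k: int, seed) -> list:
    """Random partition of range(n) into k near-equal folds."""
    rng = np.random.default_rng(seed)
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _predict(model, df: pd.DataFrame) -> np.ndarray:
    if isinstance(model, IndirectModel):
        return predict_indirect_index(model, df)
    return predict_expected_index(model, df)


def kfold_cv(method: str, data: MappingDataset, k: int = 9, seed=0,
             vs: ValueSet | None = None, candidates=None,
             p_stay: float = P_STAY_DEFAULT, p_drop: float = P_DROP_DEFAULT,
             prune_in_cv: bool = True, **fit_kw) -> PerformanceReport:
    """Overfitting-corrected performance by k-fold cross-validation.

    The full pipeline (screening for indirect, backward selection,
    pruning, final fit) is rerun on every training set and fold-level
    metrics on the held-out rows are averaged unweighted.  ``method``
    may be any direct method or ``'ordinal'`` (requires ``vs``).
    """
    if data.n < 2 * k:
        raise ValueError(f"need at least {2 * k} rows for {k}-fold CV")
    folds = fold_indices(data.n, k, seed)
    metrics, flags = [], []
    for i, test_idx in enumerate(folds):
        train_mask = np.ones(data.n, dtype=bool)
        train_mask[test_idx] = False
        train = MappingDataset(data.df.loc[train_mask].copy(), data.source)
        test_df = data.df.loc[~train_mask]
        try:
            if method == "ordinal":
                if vs is None:
                    raise ValueError("ordinal CV requires a value set")
                model, _ = develop_indirect(train, vs, p_stay=p_stay,
                                            p_drop=p_drop, prune=prune_in_cv)
            else:
                model, _ = develop_direct(method, train, candidates=candidates,
                                          p_stay=p_stay, p_drop=p_drop,
                                          prune=prune_in_cv, **fit_kw)
        except ValueError as exc:
            flags.append(f"fold {i}: {exc}")
            continue
        pred = _predict(model, test_df)
        rep = performance(test_df["y"].to_numpy(), pred)
        metrics.append([rep.rmse, rep.mae, rep.rho])
        flags.extend(f"fold {i}: {f}" for f in rep.flags)
    if not metrics:
        raise RuntimeError(f"all folds failed: {flags}")
    mean = np.nanmean(np.asarray(metrics), axis=0)
    return PerformanceReport(float(mean[0]), float(mean[1]), float(mean[2]),
                             n=data.n, flags=flags)


def evaluate_methods(data: MappingDataset, vs: ValueSet, methods=None,
                     k: int = 9, seed=0, **pipe_kw) -> pd.DataFrame:
    """Whole-sample and CV performance grid over mapping methods.

    Returns a tidy frame (method, sample, rmse, mae, rho) shaped like a
    method-comparison table.
    """
    methods = list(methods) if methods is not None else list(DIRECT_METHODS) + ["ordinal"]
    rows = []
    for m in methods:
        if m == "ordinal":
            model, _ = develop_indirect(data, vs, **{k_: v for k_, v in pipe_kw.items()
                                                     if k_ in ("p_stay", "p_drop", "prune")})
        else:
            model, _ = develop_direct(m, data, **pipe_kw)
        whole = performance(data.df["y"].to_numpy(), _predict(model, data.df))
        cv = kfold_cv(m, data, k=k, seed=seed, vs=vs, **pipe_kw)
        rows.append((m, "whole", whole.rmse, whole.mae, whole.rho))
        rows.append((m, "cv", cv.rmse, cv.mae, cv.rho))
    return pd.DataFrame(rows, columns=["method", "sample", "rmse", "mae", "rho"])


def calibration_summaries(data: MappingDataset, model, grouping: str,
                          seed=0, n_reps: int = 100) -> dict:
    """Observed vs simulated means by subgroup, plus global ECDFs.

    For each level of ``grouping`` (a column of the dataset): observed
    mean index with a normal-approximation 95% CI and the mean of
    ``n_reps`` simulated draws per row.  Empty subgroups are omitted
    with a note.  ECDF pairs are the sorted observed indexes and pooled
    simulated draws.
    """
    if grouping not in data.df.columns:
        raise ValueError(f"grouping column {grouping!r} not in dataset")
    rng = np.random.default_rng(seed)
    df = data.df
    draws = np.stack([
        simulate_index(model, df, rng)[0] if isinstance(model, IndirectModel)
        else simulate_index(model, df, rng)
        for _ in range(n_reps)
    ])  # (n_reps, n)
    rows, notes = [], []
    for g, idx in df.groupby(grouping, observed=True).groups.items():
        pos = df.index.get_indexer(idx)
        obs = df.loc[idx, "y"].dropna().to_numpy()
        if obs.size == 0:
            notes.append(f"subgroup {g!r} empty; omitted")
            continue
        m, sd = obs.mean(), obs.std(ddof=1) if obs.size > 1 else 0.0
        half = 1.96 * sd / np.sqrt(obs.size)
        rows.append((g, obs.size, m, m - half, m + half, float(draws[:, pos].mean())))
    subgroups = pd.DataFrame(
        rows, columns=[grouping, "n", "obs_mean", "ci_lo", "ci_hi", "sim_mean"]
    )
    ecdf = {
        "observed": np.sort(df["y"].dropna().to_numpy()),
        "simulated": np.sort(draws.ravel()),
    }
    return {"subgroups": subgroups, "ecdf": ecdf, "notes": notes}
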