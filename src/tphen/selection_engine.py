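"""Feature-selection methods and the nested Monte Carlo cross-validation harness.

With ~31 cases and 114 features, picking the best cut point on all data
overfits badly. The harness estimates out-of-sample stratification
performance with three nested levels: (1) an outer Monte Carlo loop that
repeatedly partitions the cohort at random into N folds, (2) an N-fold
cross-validation loop where each fold in turn is held out and a model is
fitted on the remaining N-1 folds, and (3) the inner model-selection step,
which only ever sees the training folds it is handed. Test-fold predictions
are aggregated per run; the distribution of per-run accuracies over the M
runs is the comparison currency between methods.

Uni-variate feature-selection strategies (all ending in a cut-point model):

* ``whole_data``   — best (feature, threshold) on the full training set;
* ``bootstrap``    — repeated 95% subsampling without replacement; the
  feature most often in a subsample's top-k wins, threshold refit on the
  full training set;
* ``loocv``        — leave-one-out; the feature with the best aggregated
  held-out accuracy wins, threshold refit;
* ``repeated_cv``  — inner_M-times repeated inner_N-fold cross validation
  with per-run top-k ranking by aggregated test-fold accuracy; the feature
  most frequently in the top-k wins, threshold refit. The log-rank variant
  swaps the cut-point objective to minimising the log-rank p-value.

Thresholds are always refit on the training folds only, never on the held-out
fold, to avoid leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .stratifiers import (
    CutpointModel,
    NoAdmissibleCutError,
    _scan_matrix,
    fit_cutpoint,
    scan_all_features,
)

SELECTION_METHODS = ("whole_data", "bootstrap", "loocv", "repeated_cv")


@dataclass(frozen=True)
class SelectionConfig:
    method: str = "repeated_cv"
    k_top: int = 5
    inner_M: int = 10
    inner_N: int = 8
    objective: str = "accuracy"
    bootstrap_fraction: float = 0.95
    bootstrap_reps: int = 100
    min_per_class: int = 3

    def __post_init__(self) -> None:
        if self.method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection method {self.method!r}")
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")
        if not 0 < self.bootstrap_fraction < 1:
            raise ValueError("bootstrap_fraction must be in (0, 1)")


@dataclass(frozen=True)
class MccvConfig:
    """Outer harness shape: M Monte Carlo runs of N-fold cross validation."""

    M: int = 50
    N: int = 10
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.N < 2:
            raise ValueError("N must be >= 2")


@dataclass
class MccvResult:
    """Aggregated test-fold predictions and accuracies of one harness run."""

    predictions: np.ndarray  # (M, n_cases) of 1.0/0.0/NaN
    accuracies: np.ndarray  # (M,)
    case_ids: tuple[str, ...]
    truth: np.ndarray  # (n_cases,) bool
    config: MccvConfig
    model_descriptions: list = field(default_factory=list)
    incomplete_runs: tuple[int, ...] = ()
    flags: list = field(default_factory=list)

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for m in range(self.predictions.shape[0]):
            for i, cid in enumerate(self.case_ids):
                rows.append((m, cid, self.predictions[m, i], float(self.truth[i])))
        return pd.DataFrame(rows, columns=["run", "case_id", "prediction", "truth"])


def _rank_features(frame: pd.DataFrame, k: int) -> list[str]:
    """Top-k feature names by accuracy; ties resolved by canonical order."""
    order = frame.assign(_i=np.arange(len(frame))).sort_values(
        ["accuracy", "_i"], ascending=[False, True], kind="mergesort"
    )
    order = order[np.isfinite(order.accuracy)]
    return list(order.index[:k])


def _fit_best_cut(X: pd.DataFrame, y: np.ndarray, cfg: SelectionConfig,
                  survival: pd.DataFrame | None) -> CutpointModel:
    """Best single-feature cut on the given data (the whole_data rule)."""
    if cfg.objective == "logrank_p":
        best = None
        for name in X.columns:
            try:
                m = fit_cutpoint(
                    X[name].to_numpy(dtype=float), y, feature=name,
                    objective="logrank_p", min_per_class=cfg.min_per_class,
                    times=survival.os_months.to_numpy(), events=survival.event.to_numpy(),
                )
            except NoAdmissibleCutError:
                continue
            if best is None or m.train_logrank_p < best.train_logrank_p:
                best = m
        if best is None:
            raise NoAdmissibleCutError("no admissible cut for any feature")
        return best
    table = scan_all_features(X, y, cfg.min_per_class)
    ranked = _rank_features(table, 1)
    if not ranked:
        raise NoAdmissibleCutError("no admissible cut for any feature")
    name = ranked[0]
    row = table.loc[name]
    return CutpointModel(name, row.direction, float(row.threshold),
                         min_per_class=cfg.min_per_class, train_accuracy=float(row.accuracy),
                         margin=float(row.gap))


def _refit_feature(name: str, X: pd.DataFrame, y: np.ndarray, cfg: SelectionConfig,
                   survival: pd.DataFrame | None) -> CutpointModel:
    kwargs = {}
    if cfg.objective == "logrank_p":
        kwargs = {"times": survival.os_months.to_numpy(), "events": survival.event.to_numpy()}
    return fit_cutpoint(X[name].to_numpy(dtype=float), y, feature=name,
                        objective=cfg.objective, min_per_class=cfg.min_per_class, **kwargs)


def _winner_by_frequency(counter: dict[str, int], mean_acc: dict[str, float],
                         canonical: list[str]) -> str:
    """Most frequent feature; ties by higher mean accuracy, then canonical order."""
    pos = {name: i for i, name in enumerate(canonical)}
    return min(
        counter,
        key=lambda f: (-counter[f], -mean_acc.get(f, -np.inf), pos[f]),
    )


def _random_folds(rng: np.random.Generator, n: int, n_folds: int,
                  y: np.ndarray | None = None) -> list[np.ndarray]:
    """Random partition into folds whose sizes differ by at most one."""
    if y is None:
        perm = rng.permutation(n)
        return [fold for fold in np.array_split(perm, n_folds)]
    # class-stratified variant (off by default in the harness)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (True, False):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for j, i in enumerate(idx):
            folds[j % n_folds].append(int(i))
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def _scan_np(V: np.ndarray, y: np.ndarray, min_per_class: int):
    """Numpy cut scan over a value matrix (NaN-aware per column)."""
    n, F = V.shape
    if n < 2:
        return np.full(F, np.nan), np.full(F, np.nan), np.zeros(F, dtype=bool)
    acc, thr, gt, _ = _scan_matrix(V, y, min_per_class)
    return acc, thr, gt


def _topk_np(acc: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k best accuracies; ties by canonical (lower) index."""
    order = np.lexsort((np.arange(len(acc)), -acc))
    order = order[np.isfinite(acc[order])]
    return order[:k]


def select_feature(
    X: pd.DataFrame,
    labels: np.ndarray,
    cfg: SelectionConfig,
    survival: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> CutpointModel:
    """Run one feature-selection method on a training set.

    Returns a fitted :class:`~tphen.stratifiers.CutpointModel`; for every
    method except ``whole_data`` the winning feature's threshold is refit on
    the full training set handed in (and nothing beyond it).
    """
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least two cases per class in the training set")
    if cfg.k_top > X.shape[1]:
        raise ValueError("k_top exceeds the number of features")
    if cfg.objective == "logrank_p" and survival is None:
        raise ValueError("logrank_p objective requires a survival table")
    rng = rng or np.random.default_rng(0)
    canonical = list(X.columns)
    n, F = X.shape
    V = X.to_numpy(dtype=float)
    yf = y.astype(float)

    if cfg.method == "whole_data":
        return _fit_best_cut(X, y, cfg, survival)

    counts = np.zeros(F, dtype=int)
    acc_sum = np.zeros(F)

    def _winner() -> str:
        if not counts.any():
            raise NoAdmissibleCutError("no admissible feature in any repetition")
        mean_acc = np.where(counts > 0, acc_sum / np.maximum(counts, 1), -np.inf)
        order = np.lexsort((np.arange(F), -mean_acc, -counts))
        return canonical[int(order[0])]

    if cfg.method == "bootstrap":
        size = min(n, max(2 * cfg.min_per_class, int(np.floor(cfg.bootstrap_fraction * n))))
        for _ in range(cfg.bootstrap_reps):
            idx = rng.choice(n, size=size, replace=False)
            ys = y[idx]
            if ys.all() or not ys.any():
                continue
            acc, _, _ = _scan_np(V[idx], ys, cfg.min_per_class)
            top = _topk_np(acc, cfg.k_top)
            counts[top] += 1
            acc_sum[top] += acc[top]
        return _refit_feature(_winner(), X, y, cfg, survival)

    if cfg.method == "loocv":
        preds = np.full((n, F), np.nan)
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            acc, thr, gt = _scan_np(V[mask], y[mask], cfg.min_per_class)
            vals = V[i]
            ok = np.isfinite(acc) & np.isfinite(vals)
            p = np.where(gt, vals > thr, vals <= thr).astype(float)
            p[~ok] = np.nan
            preds[i] = p
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            loo_acc = np.nanmean(preds == yf[:, None], axis=0)
        loo_acc[np.isnan(loo_acc)] = -np.inf
        best_i = int(np.argmax(loo_acc))  # argmax takes the first = canonical order
        return _refit_feature(canonical[best_i], X, y, cfg, survival)

    # repeated_cv
    for _ in range(cfg.inner_M):
        folds = _random_folds(rng, n, min(cfg.inner_N, n))
        preds = np.full((n, F), np.nan)
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            ys = y[mask]
            if ys.all() or not ys.any():
                continue
            if cfg.objective == "logrank_p":
                thr = np.full(F, np.nan)
                gt = np.zeros(F, dtype=bool)
                okf = np.zeros(F, dtype=bool)
                surv_tr = survival[mask] if survival is not None else None
                for fi, name in enumerate(canonical):
                    try:
                        m = _refit_feature(name, X[mask], ys, cfg, surv_tr)
                    except NoAdmissibleCutError:
                        continue
                    thr[fi], gt[fi], okf[fi] = m.threshold, m.direction == "greater", True
            else:
                acc, thr, gt = _scan_np(V[mask], ys, cfg.min_per_class)
                okf = np.isfinite(acc)
            vals = V[fold]
            p = np.where(gt[None, :], vals > thr[None, :], vals <= thr[None, :]).astype(float)
            p[:, ~okf] = np.nan
            p[~np.isfinite(vals)] = np.nan
            preds[fold] = p
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            run_acc = np.nanmean(preds == yf[:, None], axis=0)
        run_acc[np.isnan(run_acc)] = -np.inf
        finite_acc = np.where(np.isfinite(run_acc), run_acc, np.nan)
        top = _topk_np(finite_acc, cfg.k_top)
        counts[top] += 1
        acc_sum[top] += run_acc[top]
    return _refit_feature(_winner(), X, y, cfg, survival)


def selection_model_factory(cfg: SelectionConfig) -> Callable:
    """Model factory wrapping :func:`select_feature` for :func:`run_mccv`."""

    def factory(X, y, rng, survival=None):
        return select_feature(X, y, cfg, survival=survival, rng=rng)

    return factory


def tree_model_factory(tree_cfg=None, features: list[str] | None = None) -> Callable:
    """Factory fitting a CART tree (optionally on a fixed feature subset)."""
    from .stratifiers import TreeConfig, fit_tree

    tree_cfg = tree_cfg or TreeConfig()

    def factory(X, y, rng, survival=None):
        cols = features if features is not None else list(X.columns)
        return fit_tree(X[cols], y, tree_cfg)

    return factory


def bivariate_model_factory(features: list[str], ops=("AND", "OR", "XOR"),
                            min_per_class: int = 3) -> Callable:
    """Factory fitting the best bi-variate logical cut-point model over all
    pairs of the given candidate features."""
    from itertools import combinations

    from .stratifiers import fit_bivariate

    def factory(X, y, rng, survival=None):
        best = None
        for fa, fb in combinations(features, 2):
            try:
                m = fit_bivariate(
                    X[fa].to_numpy(dtype=float), X[fb].to_numpy(dtype=float), y,
                    feature_a=fa, feature_b=fb, ops_allowed=ops, min_per_class=min_per_class,
                )
            except NoAdmissibleCutError:
                continue
            if best is None or m.train_accuracy > best.train_accuracy + 1e-12:
                best = m
        if best is None:
            raise NoAdmissibleCutError("no admissible bi-variate model")
        return best

    return factory


def linear_model_factory(kind: str, features: list[str]) -> Callable:
    """Factory for the scikit-learn-backed linear baselines."""
    from .stratifiers import LinearStratifier

    def factory(X, y, rng, survival=None):
        seed = int(rng.integers(0, 2**31 - 1))
        return LinearStratifier(kind=kind, features=tuple(features)).fit(X, y, random_state=seed)

    return factory


def run_mccv(
    X: pd.DataFrame,
    labels: np.ndarray,
    model_factory: Callable,
    cfg: MccvConfig,
    survival: pd.DataFrame | None = None,
) -> MccvResult:
    """The outer Monte Carlo cross-validation loop.

    ``model_factory(X_train, y_train, rng, survival=...)`` must return a
    fitted model exposing ``predict``; it only ever receives the N-1 training
    folds. Per run, every case is predicted exactly once as a test sample;
    fold sizes differ by at most one. One master seed spawns independent
    per-run substreams, so results are reproducible end to end.
    """
    y = np.asarray(labels, dtype=bool)
    n = len(X)
    if cfg.N > n:
        raise ValueError("more folds than cases")
    master = np.random.SeedSequence(cfg.seed)
    run_seeds = master.spawn(cfg.M)

    preds = np.full((cfg.M, n), np.nan)
    accs = np.full(cfg.M, np.nan)
    descriptions: list[list] = []
    incomplete: list[int] = []
    flags: list[str] = []
    for m in range(cfg.M):
        rng = np.random.default_rng(run_seeds[m])
        folds = _random_folds(rng, n, cfg.N, y if cfg.stratified else None)
        run_models = []
        failed = False
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            y_test = y[fold]
            if len(np.unique(y_test)) < 2:
                flags.append(f"run {m}: single-class test fold")
            surv_tr = survival[mask] if survival is not None else None
            try:
                model = model_factory(X[mask], y[mask], rng, survival=surv_tr)
            except Exception as exc:
                flags.append(f"run {m}: model_factory failed on a fold ({exc})")
                failed = True
                run_models.append(None)
                continue
            run_models.append(getattr(model, "to_dict", lambda: repr(model))())
            preds[m, fold] = np.asarray(model.predict(X.iloc[fold]), dtype=float)
        descriptions.append(run_models)
        if failed:
            incomplete.append(m)
        ok = np.isfinite(preds[m])
        if ok.any():
            accs[m] = float((preds[m, ok] == y[ok].astype(float)).mean())
    return MccvResult(
        predictions=preds,
        accuracies=accs,
        case_ids=tuple(X.index.astype(str)),
        truth=y,
        config=cfg,
        model_descriptions=descriptions,
        incomplete_runs=tuple(incomplete),
        flags=flags,
    )


def compare_methods(results: dict[str, MccvResult]) -> dict[str, pd.DataFrame]:
    """Pairwise t / Mann–Whitney tests and one-way ANOVA on per-run accuracies.

    All result sets must share the same number of Monte Carlo runs. Returns
    ``{"pairwise": ..., "anova": ..., "summary": ...}`` ready for box plots.
    """
    if len(results) < 2:
        raise ValueError("need at least two methods to compare")
    sizes = {name: len(r.accuracies) for name, r in results.items()}
    if len(set(sizes.values())) != 1:
        raise ValueError(f"mismatched numbers of Monte Carlo runs: {sizes}")
    names = list(results)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            xa, xb = results[a].accuracies, results[b].accuracies
            t_p = stats.ttest_ind(xa, xb).pvalue
            try:
                u_p = stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            except ValueError:  # identical constant samples
                u_p = 1.0
            if np.isnan(t_p):  # zero variance in both samples
                t_p = 1.0
            if np.isnan(u_p):
                u_p = 1.0
            rows.append((a, b, float(t_p), float(u_p)))
    pairwise = pd.DataFrame(rows, columns=["method_a", "method_b", "t_p", "mannwhitney_p"])
    if all(np.allclose(results[n].accuracies, results[names[0]].accuracies) for n in names):
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*[results[n].accuracies for n in names]).pvalue)
    summary = pd.DataFrame(
        {
            "mean": [float(np.nanmean(results[n].accuracies)) for n in names],
            "std": [float(np.nanstd(results[n].accuracies)) for n in names],
            "median": [float(np.nanmedian(results[n].accuracies)) for n in names],
        },
        index=names,
    )
    return {"pairwise": pairwise, "anova": pd.DataFrame({"anova_p": [anova_p]}), "summary": summary}


def finalize_model(
    X: pd.DataFrame,
    labels: np.ndarray,
    model_factory: Callable,
    survival: pd.DataFrame | None = None,
    seed: int = 0,
):
    """Refit the chosen model on the complete data set.

    Returns ``(model, report)``; the reported training accuracy is labelled
    optimistic — it involves no cross validation and may be inflated by
    overfitting.
    """
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    model = model_factory(X, y, rng, survival=survival)
    preds = np.asarray(model.predict(X), dtype=float)
    ok = np.isfinite(preds)
    report = {
        "train_accuracy_optimistic": float((preds[ok] == y[ok].astype(float)).mean()),
        "n_cases": int(len(X)),
        "note": "training-set performance; no cross validation involved, may be optimistic",
    }
    return model, report
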