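"""Patient stratification models.

All models map a feature row to a binary prediction, with *responder*
(complete or partial response) as the positive class:

* :class:`CutpointModel` — one feature thresholded at an exhaustively
  optimised cut point (all midpoints between consecutive sorted unique
  values, both directions), under a minimum-samples-per-predicted-class
  constraint; the objective is either stratification accuracy or the
  log-rank test p-value of the induced survival split.
* :class:`BiVariateModel` — two cut points combined with a logical AND, OR
  or XOR; thresholds are optimised jointly given the combination function.
* :class:`TreeModel` — greedy CART with gini or cross-entropy impurity,
  bounded depth and minimum node/leaf sizes; leaves expose class
  proportions p_mk as prediction confidence.
* linear baselines (soft-margin SVM, perceptron, logistic regression)
  delegated to scikit-learn behind the same contract, with feature
  standardisation.

Determinism: ties on the objective prefer the cut with the widest value gap,
then the smaller threshold, then the ``greater`` direction; tree splits tie-
break on the canonical feature order, then the smaller threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# impurity measures
# ---------------------------------------------------------------------------

def _check_proportions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("class proportions must be non-negative and sum to 1")
    return p


def gini_impurity(p: Sequence[float]) -> float:
    """Gini impurity ``1 - sum_k p_k^2`` of a node's class proportions."""
    p = _check_proportions(p)
    return float(1.0 - (p**2).sum())


def cross_entropy_impurity(p: Sequence[float]) -> float:
    """Cross entropy ``-sum_k p_k log p_k`` (natural log, 0·log0 := 0)."""
    p = _check_proportions(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


IMPURITY = {"gini": gini_impurity, "cross_entropy": cross_entropy_impurity}


# ---------------------------------------------------------------------------
# uni-variate cut points
# ---------------------------------------------------------------------------

class NoAdmissibleCutError(ValueError):
    """No threshold satisfies the minimum-samples-per-class constraint."""


@dataclass
class CutpointModel:
    feature: str
    direction: str  # 'greater' | 'less_equal'
    threshold: float
    objective: str = "accuracy"
    min_per_class: int = 3
    train_accuracy: float = float("nan")
    train_logrank_p: float = float("nan")
    margin: float = float("nan")

    def decide(self, values: np.ndarray) -> np.ndarray:
        """Float predictions (1 responder, 0 non-responder, NaN missing)."""
        v = np.asarray(values, dtype=float)
        pred = v > self.threshold if self.direction == "greater" else v <= self.threshold
        out = pred.astype(float)
        out[~np.isfinite(v)] = np.nan
        return out

    def predict(self, rows: pd.DataFrame | pd.Series | dict) -> np.ndarray:
        values = _feature_column(rows, self.feature)
        return self.decide(values)

    def to_dict(self) -> dict:
        return {
            "type": "cutpoint",
            "feature": self.feature,
            "direction": self.direction,
            "threshold": self.threshold,
            "objective": self.objective,
            "min_per_class": self.min_per_class,
            "train_accuracy": self.train_accuracy,
        }


def _feature_column(rows, feature: str) -> np.ndarray:
    if isinstance(rows, dict):
        rows = pd.Series(rows)
    if isinstance(rows, pd.Series):
        if feature not in rows.index:
            raise KeyError(f"unknown feature {feature!r}")
        return np.asarray([rows[feature]], dtype=float)
    if feature not in rows.columns:
        raise KeyError(f"unknown feature {feature!r}")
    return rows[feature].to_numpy(dtype=float)


def _scan_matrix(V: np.ndarray, y: np.ndarray, min_per_class: int):
    """Vectorised exhaustive cut scan over an (n, F) value matrix.

    NaN values are excluded per feature (the column is fitted on its finite
    subset). For every split position between consecutive sorted samples the
    accuracy of both directions is evaluated; positions between tied values
    are invalid (a midpoint there would not separate them). Tie-breaking per
    feature: max accuracy, then max value gap, then min threshold, then the
    ``greater`` direction. Returns (acc, thr, direction_is_greater, gap)
    arrays of length F with NaN accuracy where no admissible cut exists.
    """
    n, F = V.shape
    finite = np.isfinite(V)
    V_inf = np.where(finite, V, np.inf)  # NaN/inf samples sort to the end
    order = np.argsort(V_inf, axis=0, kind="mergesort")
    Vs = np.take_along_axis(V_inf, order, axis=0)
    Ys = y[order]
    W = np.take_along_axis(finite, order, axis=0)
    cum_resp = np.cumsum(Ys & W, axis=0).astype(float)
    n_f = W.sum(axis=0).astype(float)  # finite samples per column
    total_resp = cum_resp[-1]
    i = np.arange(1, n, dtype=float)[:, None]  # split after the first i samples
    resp_le = cum_resp[:-1]
    correct_gt = (total_resp[None, :] - resp_le) + (i - resp_le)  # (n-1, F)
    with np.errstate(invalid="ignore"):  # inf - inf in all-missing tails
        gaps = Vs[1:] - Vs[:-1]
        mids = (Vs[1:] + Vs[:-1]) / 2.0
        valid = (
            (gaps > 0)
            & np.isfinite(mids)
            & (i >= min_per_class)
            & (n_f[None, :] - i >= min_per_class)
        )

    safe_nf = np.maximum(n_f, 1.0)
    acc2 = np.concatenate([correct_gt, n_f[None, :] - correct_gt], axis=0) / safe_nf
    gaps2 = np.concatenate([gaps, gaps], axis=0)
    mids2 = np.concatenate([mids, mids], axis=0)
    valid2 = np.concatenate([valid, valid], axis=0)
    greater2 = np.zeros_like(acc2, dtype=bool)
    greater2[: n - 1] = True

    neg = np.where(valid2, acc2, -np.inf)
    best_acc = neg.max(axis=0)
    tie = neg == best_acc[None, :]
    best_gap = np.where(tie, gaps2, -np.inf).max(axis=0)
    tie &= gaps2 == best_gap[None, :]
    best_mid = np.where(tie, mids2, np.inf).min(axis=0)
    tie &= mids2 == best_mid[None, :]
    best_greater = (tie & greater2).any(axis=0)

    ok = np.isfinite(best_acc) & (best_acc > -np.inf)
    acc_out = np.where(ok, best_acc, np.nan)
    return acc_out, best_mid, best_greater, best_gap


def scan_cutpoints(values: np.ndarray, labels: np.ndarray, min_per_class: int):
    """Best (accuracy, threshold, direction, gap) for one feature, or None.

    Exhaustive scan over all midpoints of consecutive sorted unique values.
    Returns None when no admissible cut exists. NaN feature values are
    excluded before the scan.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    ok = np.isfinite(v)
    v, y = v[ok], y[ok]
    if len(v) == 0 or len(np.unique(v)) < 2:
        return None
    acc, thr, greater, gap = _scan_matrix(v[:, None], y, min_per_class)
    if not np.isfinite(acc[0]):
        return None
    return float(acc[0]), float(thr[0]), "greater" if greater[0] else "less_equal", float(gap[0])


def fit_cutpoint(
    values: np.ndarray,
    labels: np.ndarray,
    *,
    feature: str = "feature",
    objective: str = "accuracy",
    min_per_class: int = 3,
    times: np.ndarray | None = None,
    events: np.ndarray | None = None,
) -> CutpointModel:
    """Exhaustive cut-point optimisation for a single feature.

    ``objective='accuracy'`` maximises response-prediction accuracy;
    ``objective='logrank_p'`` minimises the log-rank p-value of the survival
    split induced by the threshold (requires ``times``/``events``), assigning
    the *responder* label to the arm with the better survival.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if objective == "accuracy":
        res = scan_cutpoints(v, y, min_per_class)
        if res is None:
            raise NoAdmissibleCutError(f"no admissible cut for feature {feature!r}")
        acc, thr, direction, gap = res
        return CutpointModel(feature, direction, thr, objective, min_per_class,
                             train_accuracy=acc, margin=gap)
    if objective != "logrank_p":
        raise ValueError(f"unknown objective {objective!r}")
    if times is None or events is None:
        raise ValueError("logrank_p objective requires survival times and events")
    from .survival_eval import km_estimate, logrank_test

    ok = np.isfinite(v)
    v_, y_, t_, e_ = v[ok], y[ok], np.asarray(times, float)[ok], np.asarray(events, bool)[ok]
    u = np.unique(v_)
    n = len(v_)
    best = None
    for thr, gap in zip((u[:-1] + u[1:]) / 2.0, np.diff(u)):
        hi = v_ > thr
        n_hi = int(hi.sum())
        if n_hi < min_per_class or n - n_hi < min_per_class:
            continue
        _, p = logrank_test(t_[hi], e_[hi], t_[~hi], e_[~hi])
        cand = (p, -gap, thr)
        if best is None or cand < best[0]:
            # responder arm = the better-surviving side (larger mean observed time
            # as a median-robust proxy)
            direction = "greater" if t_[hi].mean() >= t_[~hi].mean() else "less_equal"
            pred = hi if direction == "greater" else ~hi
            best = (cand, CutpointModel(
                feature, direction, float(thr), objective, min_per_class,
                train_accuracy=float((pred == y_).mean()), train_logrank_p=float(p),
                margin=float(gap)))
    if best is None:
        raise NoAdmissibleCutError(f"no admissible cut for feature {feature!r}")
    return best[1]


def scan_all_features(X: pd.DataFrame, labels: np.ndarray, min_per_class: int) -> pd.DataFrame:
    """Best accuracy cut per feature; one row per column of ``X``.

    Columns: accuracy, threshold, direction, gap; features with no admissible
    cut get NaN accuracy. Used heavily by the selection engine.
    """
    y = np.asarray(labels, dtype=bool)
    V = X.to_numpy(dtype=float)
    n, F = V.shape
    if n >= 2:
        acc, thr, greater, gap = _scan_matrix(V, y, min_per_class)
    else:
        acc = np.full(F, np.nan)
        thr = np.full(F, np.nan)
        gap = np.full(F, np.nan)
        greater = np.zeros(F, dtype=bool)
    direction = np.where(greater, "greater", "less_equal")
    direction = np.where(np.isfinite(acc), direction, "")
    return pd.DataFrame(
        {"accuracy": acc, "threshold": thr, "direction": direction, "gap": gap},
        index=pd.Index(X.columns, name="feature"),
    )


# ---------------------------------------------------------------------------
# bi-variate logical combinations
# ---------------------------------------------------------------------------

LOGICAL_OPS = ("AND", "OR", "XOR")
_OP_FUNCS = {
    "AND": np.logical_and,
    "OR": np.logical_or,
    "XOR": np.logical_xor,
}


@dataclass
class BiVariateModel:
    model_a: CutpointModel
    model_b: CutpointModel
    op: str
    train_accuracy: float = float("nan")

    def predict(self, rows: pd.DataFrame | pd.Series | dict) -> np.ndarray:
        pa = self.model_a.predict(rows)
        pb = self.model_b.predict(rows)
        out = _OP_FUNCS[self.op](pa == 1.0, pb == 1.0).astype(float)
        out[~np.isfinite(pa) | ~np.isfinite(pb)] = np.nan
        return out

    def to_dict(self) -> dict:
        return {
            "type": "bivariate",
            "op": self.op,
            "a": self.model_a.to_dict(),
            "b": self.model_b.to_dict(),
            "train_accuracy": self.train_accuracy,
        }


def fit_bivariate(
    values_a: np.ndarray,
    values_b: np.ndarray,
    labels: np.ndarray,
    *,
    feature_a: str = "a",
    feature_b: str = "b",
    ops_allowed: Sequence[str] = LOGICAL_OPS,
    min_per_class: int = 3,
) -> BiVariateModel:
    """Joint grid search over both thresholds, directions, and the operator.

    Maximises accuracy of the combined prediction; the minimum-class-size
    constraint applies to the combined predicted classes. Ties prefer
    operators in the order AND, OR, XOR, then the lexicographically first
    threshold pair.
    """
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    ok = np.isfinite(va) & np.isfinite(vb)
    va, vb, y = va[ok], vb[ok], y[ok]
    n = len(y)
    ua, ub = np.unique(va), np.unique(vb)
    if len(ua) < 2 or len(ub) < 2:
        raise NoAdmissibleCutError("both features must take at least two values")
    mids_a = (ua[:-1] + ua[1:]) / 2.0
    mids_b = (ub[:-1] + ub[1:]) / 2.0

    # candidate boolean predictions per (threshold, direction)
    def _cands(v, mids):
        gt = v[None, :] > mids[:, None]  # (T, n)
        return np.concatenate([gt, ~gt]), ["greater"] * len(mids) + ["less_equal"] * len(mids), np.concatenate([mids, mids])

    pa, dirs_a, thr_a = _cands(va, mids_a)
    pb, dirs_b, thr_b = _cands(vb, mids_b)

    best = None
    for op in ops_allowed:
        if op not in _OP_FUNCS:
            raise ValueError(f"unknown logical op {op!r}")
        comb = _OP_FUNCS[op](pa[:, None, :], pb[None, :, :])  # (Ta, Tb, n)
        n_pos = comb.sum(axis=2)
        valid = (n_pos >= min_per_class) & (n - n_pos >= min_per_class)
        if not valid.any():
            continue
        acc = (comb == y[None, None, :]).mean(axis=2)
        acc = np.where(valid, acc, -1.0)
        i, j = np.unravel_index(int(np.argmax(acc)), acc.shape)
        cand_acc = float(acc[i, j])
        if best is None or cand_acc > best[0] + 1e-12:
            best = (cand_acc, op, i, j)
    if best is None:
        raise NoAdmissibleCutError("no admissible bi-variate cut")
    acc, op, i, j = best
    ma = CutpointModel(feature_a, dirs_a[i], float(thr_a[i]), min_per_class=min_per_class)
    mb = CutpointModel(feature_b, dirs_b[j], float(thr_b[j]), min_per_class=min_per_class)
    return BiVariateModel(ma, mb, op, train_accuracy=acc)


# ---------------------------------------------------------------------------
# CART decision trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeConfig:
    """CART hyper-parameters: depth, node-size floors, impurity measure."""

    depth: int = 2
    s_min: int = 5
    l_min: int = 5
    impurity: str = "gini"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.impurity not in IMPURITY:
            raise ValueError(f"impurity must be one of {sorted(IMPURITY)}")


@dataclass
class TreeNode:
    n: int
    p_mk: tuple[float, float]  # (non-responder, responder) proportions
    output: bool  # majority class (responder?)
    feature: str | None = None
    threshold: float = float("nan")
    gain: float = float("nan")
    left: "TreeNode | None" = None  # value <= threshold
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def confidence(self) -> float:
        return max(self.p_mk)

    def to_dict(self) -> dict:
        d = {"n": self.n, "p_mk": list(self.p_mk), "output": bool(self.output)}
        if not self.is_leaf:
            d.update(feature=self.feature, threshold=self.threshold, gain=self.gain,
                     left=self.left.to_dict(), right=self.right.to_dict())
        return d


@dataclass
class TreeModel:
    root: TreeNode
    config: TreeConfig
    feature_order: tuple[str, ...] = ()
    train_accuracy: float = float("nan")

    def predict(self, rows: pd.DataFrame, with_confidence: bool = False):
        if isinstance(rows, (pd.Series, dict)):
            rows = pd.DataFrame([rows])
        preds = np.full(len(rows), np.nan)
        confs = np.full(len(rows), np.nan)
        for i, (_, row) in enumerate(rows.iterrows()):
            node = self.root
            missing = False
            while not node.is_leaf:
                val = row.get(node.feature, np.nan)
                if not np.isfinite(val):
                    missing = True
                    break
                node = node.left if val <= node.threshold else node.right
            if not missing:
                preds[i] = float(node.output)
                confs[i] = node.confidence
        return (preds, confs) if with_confidence else preds

    def to_dict(self) -> dict:
        return {
            "type": "tree",
            "config": {"depth": self.config.depth, "s_min": self.config.s_min,
                       "l_min": self.config.l_min, "impurity": self.config.impurity},
            "root": self.root.to_dict(),
            "train_accuracy": self.train_accuracy,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _node_stats(y: np.ndarray) -> tuple[tuple[float, float], bool]:
    n = len(y)
    p_resp = float(y.sum() / n)
    p_mk = (1.0 - p_resp, p_resp)
    # majority; exact tie goes to non-responder (the cohort's prior class)
    return p_mk, p_resp > 0.5


def _binary_impurity(p: np.ndarray, impurity: str) -> np.ndarray:
    """Vectorised two-class impurity of responder proportion(s) p."""
    p = np.clip(p, 0.0, 1.0)
    if impurity == "gini":
        return 2.0 * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0) + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
    return -term


def _best_split(X: pd.DataFrame, y: np.ndarray, cfg: TreeConfig):
    """Exhaustive (feature, threshold) search maximising impurity decrease.

    Vectorised over all split positions of all fully finite features
    (features with missing values are not split on). Ties on the gain go to
    the earlier canonical feature, then the smaller threshold.
    """
    n = len(y)
    V = X.to_numpy(dtype=float)
    finite = np.isfinite(V).all(axis=0)
    if not finite.any() or n < 2:
        return None
    Vf = V[:, finite]
    order = np.argsort(Vf, axis=0, kind="mergesort")
    Vs = np.take_along_axis(Vf, order, axis=0)
    Ys = y[order]
    cum_resp = np.cumsum(Ys, axis=0).astype(float)
    total_resp = float(y.sum())
    i = np.arange(1, n, dtype=float)[:, None]
    p_left = cum_resp[:-1] / i
    p_right = (total_resp - cum_resp[:-1]) / (n - i)
    parent = _binary_impurity(np.array([total_resp / n]), cfg.impurity)[0]
    weighted = (i * _binary_impurity(p_left, cfg.impurity)
                + (n - i) * _binary_impurity(p_right, cfg.impurity)) / n
    gain = parent - weighted
    gaps = Vs[1:] - Vs[:-1]
    valid = (gaps > 0) & (i >= cfg.l_min) & (n - i >= cfg.l_min)
    gain = np.where(valid, gain, -np.inf)
    best_gain = gain.max()
    if not np.isfinite(best_gain) or best_gain <= 1e-12:
        return None
    mids = (Vs[1:] + Vs[:-1]) / 2.0
    rows, cols = np.nonzero(gain == best_gain)
    col_ids = np.flatnonzero(finite)[cols]
    pick = np.lexsort((mids[rows, cols], col_ids))[0]
    fi = int(col_ids[pick])
    thr = float(mids[rows[pick], cols[pick]])
    return X.columns[fi], thr, float(best_gain)


def _grow(X: pd.DataFrame, y: np.ndarray, cfg: TreeConfig, depth: int) -> TreeNode:
    p_mk, output = _node_stats(y)
    node = TreeNode(n=len(y), p_mk=p_mk, output=output)
    if depth >= cfg.depth or len(y) < cfg.s_min or len(np.unique(y)) < 2:
        return node
    split = _best_split(X, y, cfg)
    if split is None:
        return node
    feat, thr, gain = split
    le = X[feat].to_numpy(dtype=float) <= thr
    node.feature, node.threshold, node.gain = feat, thr, gain
    node.left = _grow(X[le], y[le], cfg, depth + 1)
    node.right = _grow(X[~le], y[~le], cfg, depth + 1)
    return node


def fit_tree(X: pd.DataFrame, labels: np.ndarray, cfg: TreeConfig | None = None) -> TreeModel:
    """Greedy CART on a feature table (rows = cases, columns = features)."""
    cfg = cfg or TreeConfig()
    y = np.asarray(labels, dtype=bool)
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    root = _grow(X, y, cfg, depth=0)
    model = TreeModel(root=root, config=cfg, feature_order=tuple(X.columns))
    preds = model.predict(X)
    model.train_accuracy = float(np.nanmean(preds == y.astype(float)))
    return model


# ---------------------------------------------------------------------------
# linear baselines (delegated to scikit-learn)
# ---------------------------------------------------------------------------

@dataclass
class LinearStratifier:
    """Standardised linear model behind the common predict contract.

    ``kind`` in {'svm_hinge', 'svm_squared_hinge', 'perceptron', 'logistic'}.
    These are comparison baselines, not bespoke computation.
    """

    kind: str
    features: tuple[str, ...]
    pipeline: object = None

    def fit(self, X: pd.DataFrame, labels: np.ndarray, random_state: int = 0) -> "LinearStratifier":
        from sklearn.linear_model import SGDClassifier
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        losses = {
            "svm_hinge": "hinge",
            "svm_squared_hinge": "squared_hinge",
            "perceptron": "perceptron",
            "logistic": "log_loss",
        }
        if self.kind not in losses:
            raise ValueError(f"unknown linear model kind {self.kind!r}")
        self.pipeline = make_pipeline(
            StandardScaler(),
            SGDClassifier(loss=losses[self.kind], random_state=random_state, max_iter=2000, tol=1e-4),
        )
        self.pipeline.fit(X[list(self.features)].to_numpy(dtype=float), np.asarray(labels, dtype=int))
        return self

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        V = rows[list(self.features)].to_numpy(dtype=float)
        out = np.full(len(rows), np.nan)
        ok = np.isfinite(V).all(axis=1)
        if ok.any():
            out[ok] = self.pipeline.predict(V[ok]).astype(float)
        return out


def predict(model, rows):
    """Uniform prediction entry point for any fitted stratifier."""
    return model.predict(rows)


def _node_from_dict(d: dict) -> TreeNode:
    node = TreeNode(n=d["n"], p_mk=tuple(d["p_mk"]), output=bool(d["output"]))
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = d["threshold"]
        node.gain = d["gain"]
        node.left = _node_from_dict(d["left"])
        node.right = _node_from_dict(d["right"])
    return node


def model_from_dict(d: dict):
    """Rebuild a serialized stratifier (cutpoint, bivariate, or tree)."""
    kind = d.get("type")
    if kind == "cutpoint":
        return CutpointModel(
            feature=d["feature"], direction=d["direction"], threshold=d["threshold"],
            objective=d.get("objective", "accuracy"),
            min_per_class=d.get("min_per_class", 3),
            train_accuracy=d.get("train_accuracy", float("nan")),
        )
    if kind == "bivariate":
        return BiVariateModel(
            model_a=model_from_dict(d["a"]), model_b=model_from_dict(d["b"]), op=d["op"],
            train_accuracy=d.get("train_accuracy", float("nan")),
        )
    if kind == "tree":
        cfg = TreeConfig(**d["config"])
        return TreeModel(root=_node_from_dict(d["root"]), config=cfg,
                         train_accuracy=d.get("train_accuracy", float("nan")))
    raise ValueError(f"unknown model type {kind!r}")
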