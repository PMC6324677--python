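"""Classification and statistics harness.

Biopsies are labelled clinically significant (Gleason sum >= 7) or
insignificant (Gleason 6) and discriminated with shallow decision trees.
Class imbalance is removed with SMOTE (synthetic minority over-sampling:
convex interpolation between a minority sample and one of its k nearest
minority neighbours) calibrated to exact balance.  Validation is
leave-one-out within a cohort — with SMOTE applied inside each training
fold only, so the held-out biopsy never influences the balanced set — or
train-on-one / test-on-the-other across cohorts.  AUCs of competing feature
tuples are compared with the paired DeLong test and the resulting p-values
corrected by Benjamini–Hochberg false discovery rate.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "BiopsyRecord",
    "EvalResult",
    "label_biopsies",
    "smote_balance",
    "evaluate_loo",
    "evaluate_cross_cohort",
    "tuple_search",
    "delong_test",
    "fdr_correct",
    "DCE_FEATURE_NAMES",
]

DCE_FEATURE_NAMES = ("sp", "tau", "wi", "wo", "auci", "aucf", "mio")
SIGNIFICANT_GLEASON_SUM = 7
DEFAULT_TREE_DEPTH = 3
DEFAULT_SMOTE_K = 5


@dataclass(frozen=True)
class BiopsyRecord:
    biopsy_id: str
    patient_id: str
    gleason_primary: int
    gleason_secondary: int

    def __post_init__(self) -> None:
        for g in (self.gleason_primary, self.gleason_secondary):
            if not 3 <= g <= 5:
                raise ValueError(f"Gleason component {g} outside 3..5")

    @property
    def gleason_sum(self) -> int:
        return self.gleason_primary + self.gleason_secondary

    @property
    def label(self) -> int:
        """1 = clinically significant (GS >= 7), 0 = insignificant (GS 6)."""
        return int(self.gleason_sum >= SIGNIFICANT_GLEASON_SUM)


@dataclass
class EvalResult:
    feature_names: tuple[str, ...]
    scheme: str  # "LOO" | "cross_cohort"
    sensitivity: float
    specificity: float
    auc: float
    scores: np.ndarray
    y_true: np.ndarray
    seed: int
    n: int
    flags: list[str] = field(default_factory=list)


def label_biopsies(table: pd.DataFrame) -> tuple[list[BiopsyRecord], int]:
    """Build labelled records from a biopsy table; drop unscored rows.

    Rows whose Gleason components are missing or non-positive (benign
    tissue, hyperplasia) are discarded; the count of discarded rows is
    returned and logged.  Components outside 3..5 raise.
    """
    records: list[BiopsyRecord] = []
    dropped = 0
    for _, row in table.iterrows():
        gp, gs = row.get("gleason_primary"), row.get("gleason_secondary")
        if gp is None or gs is None or pd.isna(gp) or pd.isna(gs) or gp <= 0 or gs <= 0:
            dropped += 1
            continue
        records.append(BiopsyRecord(
            biopsy_id=str(row.get("biopsy_id", len(records))),
            patient_id=str(row.get("patient_id", "")),
            gleason_primary=int(gp), gleason_secondary=int(gs),
        ))
    if dropped:
        logger.info("discarded %d biopsies without an assigned Gleason score", dropped)
    return records, dropped


# ---------------------------------------------------------------------------
# SMOTE


def smote_balance(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = DEFAULT_SMOTE_K,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Over-sample the minority class to exact balance.

    Each synthetic sample is x + w (x' - x) with w ~ U[0, 1], where x is a
    uniformly chosen minority sample and x' one of its k nearest minority
    neighbours (Euclidean).  Majority samples are returned unaltered, in
    their original order, with synthetic rows appended.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE balancing expects exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    if k < 1:
        raise ValueError("k must be >= 1")
    Xm = X[y == minority]
    k_eff = min(k, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xm)
    neigh = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
    rng = np.random.default_rng(seed)
    n_syn = int(n_maj - n_min)
    base = rng.integers(0, n_min, size=n_syn)
    pick = rng.integers(0, k_eff, size=n_syn)
    w = rng.random(n_syn)
    x_base = Xm[base]
    x_neigh = Xm[neigh[base, pick]]
    synth = x_base + w[:, None] * (x_neigh - x_base)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_syn, minority, dtype=y.dtype)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# classification


def _fit_tree(X: np.ndarray, y: np.ndarray, seed: int,
              max_depth: int) -> DecisionTreeClassifier:
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X, y)
    return tree


def _score_positive(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    proba = tree.predict_proba(X)
    if 1 in tree.classes_:
        return proba[:, list(tree.classes_).index(1)]
    return np.zeros(X.shape[0])


def _sens_spec(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    pos, neg = y_true == 1, y_true == 0
    sens = float((y_pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((y_pred[neg] == 0).mean()) if neg.any() else float("nan")
    return sens, spec


def evaluate_loo(
    features: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...] = (),
    seed: int = 0,
    smote_k: int = DEFAULT_SMOTE_K,
    max_depth: int = DEFAULT_TREE_DEPTH,
    smote_scope: str = "fold",
) -> EvalResult:
    """Leave-one-out evaluation with fold-wise SMOTE balancing.

    For each held-out biopsy the remaining samples are balanced with SMOTE
    and a decision tree fitted; pooled held-out class-probability scores
    give the AUC, pooled hard predictions give sensitivity/specificity.

    ``smote_scope="global"`` instead balances the whole cohort once before
    cross-validation and leaves the synthetic samples in every training
    fold.  Synthetic samples derived from the held-out biopsy then leak
    into training; the mode exists only to quantify that optimism against
    the default.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if smote_scope not in ("fold", "global"):
        raise ValueError("smote_scope must be 'fold' or 'global'")
    flags_global: list[str] = []
    if smote_scope == "global":
        X, y = smote_balance(X, y, k=smote_k, seed=seed)
        flags_global.append("global_smote_leaky")
    n = X.shape[0]
    if np.unique(y).size < 2 or min(np.bincount(y)) < 2:
        raise ValueError("LOO needs at least 2 samples in each class")
    scores = np.full(n, np.nan)
    preds = np.full(n, -1)
    flags: list[str] = list(flags_global)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        X_tr, y_tr = X[keep], y[keep]
        if np.unique(y_tr).size < 2 or min(np.bincount(y_tr)) < 2:
            flags.append(f"fold_{i}_degenerate")
            continue
        if smote_scope == "fold":
            X_bal, y_bal = smote_balance(X_tr, y_tr, k=smote_k, seed=seed + i)
        else:
            X_bal, y_bal = X_tr, y_tr
        tree = _fit_tree(X_bal, y_bal, seed=seed, max_depth=max_depth)
        scores[i] = _score_positive(tree, X[i:i + 1])[0]
        preds[i] = tree.predict(X[i:i + 1])[0]
    ok = np.isfinite(scores)
    if np.unique(y[ok]).size < 2:
        flags.append("pooled_single_class")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y[ok], scores[ok]))
    sens, spec = _sens_spec(y[ok], preds[ok])
    return EvalResult(feature_names=tuple(feature_names), scheme="LOO",
                      sensitivity=sens, specificity=spec, auc=auc,
                      scores=scores, y_true=y, seed=seed, n=n, flags=flags)


def evaluate_cross_cohort(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    test_labels: np.ndarray,
    feature_names: tuple[str, ...] = (),
    seed: int = 0,
    smote_k: int = DEFAULT_SMOTE_K,
    max_depth: int = DEFAULT_TREE_DEPTH,
) -> EvalResult:
    """Train on one whole (SMOTE-balanced) cohort, test on the other
    unbalanced cohort."""
    X_tr = np.asarray(train_features, dtype=float)
    y_tr = np.asarray(train_labels).astype(int)
    X_te = np.asarray(test_features, dtype=float)
    y_te = np.asarray(test_labels).astype(int)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ValueError("train and test cohorts disagree on feature columns")
    X_bal, y_bal = smote_balance(X_tr, y_tr, k=smote_k, seed=seed)
    tree = _fit_tree(X_bal, y_bal, seed=seed, max_depth=max_depth)
    scores = _score_positive(tree, X_te)
    preds = tree.predict(X_te)
    auc = float(roc_auc_score(y_te, scores))
    sens, spec = _sens_spec(y_te, preds)
    return EvalResult(feature_names=tuple(feature_names), scheme="cross_cohort",
                      sensitivity=sens, specificity=spec, auc=auc,
                      scores=scores, y_true=y_te, seed=seed, n=y_te.size)


# ---------------------------------------------------------------------------
# exhaustive tuple search


def tuple_search(
    features: pd.DataFrame,
    labels: np.ndarray,
    dce_names: tuple[str, ...] = DCE_FEATURE_NAMES,
    adc_pairs: list[tuple[str, str]] | None = None,
    scheme: str = "loo",
    test_features: pd.DataFrame | None = None,
    test_labels: np.ndarray | None = None,
    seed: int = 0,
    **eval_kwargs,
) -> tuple[pd.DataFrame, dict[tuple[str, ...], EvalResult]]:
    """Exhaustive evaluation of DCE singles, pairs and (optionally)
    DCE-pair x ADC-pair quadruples.

    With the seven curve descriptors this yields 7 singles + 21 unordered
    pairs = 28 evaluations; adding n ADC pairs appends 21*n quadruples.
    Returns a table ranked by AUC (no tuples dropped) and the raw results.
    """
    missing = [n for n in dce_names if n not in features.columns]
    if missing:
        raise KeyError(f"features table lacks columns {missing}")
    tuples: list[tuple[str, ...]] = [(n,) for n in dce_names]
    dce_pairs = list(itertools.combinations(dce_names, 2))
    tuples += [tuple(p) for p in dce_pairs]
    if adc_pairs:
        for dp in dce_pairs:
            for ap in adc_pairs:
                tuples.append(dp + tuple(ap))

    results: dict[tuple[str, ...], EvalResult] = {}
    rows = []
    for tup in tuples:
        X = features.loc[:, list(tup)].to_numpy(dtype=float)
        if scheme == "loo":
            res = evaluate_loo(X, labels, feature_names=tup, seed=seed,
                               **eval_kwargs)
        elif scheme == "cross_cohort":
            if test_features is None or test_labels is None:
                raise ValueError("cross_cohort scheme needs a test cohort")
            X_te = test_features.loc[:, list(tup)].to_numpy(dtype=float)
            res = evaluate_cross_cohort(X, labels, X_te, test_labels,
                                        feature_names=tup, seed=seed,
                                        **eval_kwargs)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        results[tup] = res
        rows.append({
            "features": "+".join(tup), "n_features": len(tup),
            "scheme": res.scheme, "sensitivity": res.sensitivity,
            "specificity": res.specificity, "auc": res.auc, "n": res.n,
            "seed": seed,
        })
    table = pd.DataFrame(rows).sort_values(
        "auc", ascending=False, kind="mergesort").reset_index(drop=True)
    return table, results


# ---------------------------------------------------------------------------
# DeLong test and FDR


def _midrank_placements(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """P(x_i beats a random y), with ties counting 1/2 (per x_i)."""
    return np.array([
        ((xi > y).sum() + 0.5 * (xi == y).sum()) / y.size for xi in x
    ])


def delong_test(scores_a: np.ndarray, scores_b: np.ndarray,
                labels: np.ndarray) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same labelled samples.

    AUCs are the Mann-Whitney statistics; the variance of their difference
    comes from the empirical covariance of the structural components (the
    per-positive and per-negative placement values).  Returns
    (auc_a, auc_b, two-sided p).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != y.shape or sb.shape != y.shape:
        raise ValueError("scores and labels must share one shape")
    pos, neg = y == 1, y == 0
    m, n = int(pos.sum()), int(neg.sum())
    if m == 0 or n == 0:
        raise ValueError("DeLong test needs both classes present")

    v10 = np.vstack([_midrank_placements(s[pos], s[neg]) for s in (sa, sb)])
    v01 = np.vstack([1.0 - _midrank_placements(s[neg], s[pos]) for s in (sa, sb)])
    aucs = v10.mean(axis=1)
    s10 = np.cov(v10, bias=False) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01, bias=False) if n > 1 else np.zeros((2, 2))
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    diff = aucs[0] - aucs[1]
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return float(aucs[0]), float(aucs[1]), p


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05
                ) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up control of the false discovery rate.

    Sorts the m p-values, finds the largest k with p_(k) <= k*alpha/m and
    returns (adjusted_threshold = p_(k), flags of p <= threshold); the
    threshold is 0 (nothing significant) when no k qualifies.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 0.0, np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.sort(p)
    ks = np.nonzero(order <= (np.arange(1, m + 1) * alpha / m))[0]
    if ks.size == 0:
        return 0.0, np.zeros(m, dtype=bool)
    threshold = float(order[ks[-1]])
    return threshold, p <= threshold
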