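"""Spatially aware model validation and discrimination metrics.

With a few tens of spatially clustered presences, random cross-validation
leaks spatial structure between train and test splits and flatters the
model.  The primary scheme here is leave-one-cluster-out (LOCO): presence
records are grouped into clusters with DBSCAN (default eps 250 m) and each
cluster is held out whole.  Random k-fold CV is kept for the selection
grid and sensitivity sweeps and is labeled "random-CV" so the two are
never conflated.

Metrics: rank-based AUC (Mann-Whitney, ties at 0.5), standardized partial
AUC restricted to specificity >= 0.90 (McClish rescaling so chance maps
to 0.5 and perfection to 1.0), and RelRMSE (RMSE of scores against the
0/1 labels, normalized by the within-fold score range).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .maxent import ModelConfig, fit_maxent, predict_model
from .occurrence import consolidate_sites

__all__ = [
    "FoldPlan",
    "ValidationReport",
    "loco_folds",
    "presence_kfold",
    "auc_mw",
    "pauc_standardized",
    "rel_rmse",
    "evaluate_loco",
    "kfold_cv",
]


@dataclasses.dataclass
class FoldPlan:
    """Cluster-level fold assignment for LOCO validation."""

    cluster_of_presence: np.ndarray  # cluster (= fold) id per presence
    eps_m: float

    @property
    def n_folds(self) -> int:
        return int(self.cluster_of_presence.max()) + 1


@dataclasses.dataclass
class ValidationReport:
    """Per-fold metrics plus mean +/- SD summaries."""

    scheme: str  # "LOCO" or "random-CV"
    per_fold: pd.DataFrame
    eps_m: float | None = None

    def summary(self) -> dict[str, float]:
        out = {"scheme": self.scheme, "n_folds": len(self.per_fold)}
        for col in ("auc", "pauc", "relrmse"):
            vals = self.per_fold[col].dropna()
            out[f"{col}_mean"] = float(vals.mean())
            out[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return out


def loco_folds(presence_xy: np.ndarray, eps_m: float = 250.0) -> FoldPlan:
    """One fold per presence cluster (DBSCAN components at eps_m)."""
    labels = consolidate_sites(np.asarray(presence_xy, dtype=float), eps_m=eps_m)
    if labels.max() < 1:
        raise ValueError(
            "all presences fall in a single cluster; use a smaller eps_m"
        )
    return FoldPlan(cluster_of_presence=labels, eps_m=eps_m)


def presence_kfold(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded random fold assignment with sizes differing by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than presences")
    rng = np.random.default_rng(seed)
    fold = np.arange(n) % k
    rng.shuffle(fold)
    return fold


def auc_mw(pos_scores, neg_scores) -> float:
    """AUC via the Mann-Whitney statistic (ties count 0.5)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be nonempty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _roc_points(pos: np.ndarray, neg: np.ndarray):
    """Empirical ROC as (fpr, tpr) over unique-score thresholds."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    order = np.argsort(-scores, kind="mergesort")
    scores, labels = scores[order], labels[order]
    distinct = np.nonzero(np.diff(scores))[0]
    cut = np.r_[distinct, len(scores) - 1]
    tps = np.cumsum(labels)[cut]
    fps = np.cumsum(1 - labels)[cut]
    tpr = np.r_[0.0, tps / len(pos)]
    fpr = np.r_[0.0, fps / len(neg)]
    return fpr, tpr


def pauc_standardized(pos_scores, neg_scores, spec_range=(0.90, 1.0)) -> float:
    """Standardized partial AUC over a high-specificity band.

    The ROC area is integrated over FPR in [1 - spec_hi, 1 - spec_lo]
    (default [0, 0.10]) with vertical interpolation at the boundary, then
    McClish-standardized: pAUC* = (1 + (A - A_min)/(A_max - A_min)) / 2,
    where A_max is the band width and A_min the chance area within it, so
    a chance classifier scores 0.5 and a perfect one 1.0.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be nonempty")
    spec_lo, spec_hi = min(spec_range), max(spec_range)
    f0, f1 = 1.0 - spec_hi, 1.0 - spec_lo
    fpr, tpr = _roc_points(pos, neg)
    fpr = np.r_[fpr, 1.0]
    tpr = np.r_[tpr, 1.0]
    # trapezoidal area over the ROC polyline, each segment clipped to the
    # FPR band with vertical interpolation at the boundary
    area = 0.0
    for i in range(len(fpr) - 1):
        x0, x1 = fpr[i], fpr[i + 1]
        y0, y1 = tpr[i], tpr[i + 1]
        lo, hi = max(x0, f0), min(x1, f1)
        if hi <= lo or x1 == x0:
            continue
        ylo = y0 + (y1 - y0) * (lo - x0) / (x1 - x0)
        yhi = y0 + (y1 - y0) * (hi - x0) / (x1 - x0)
        area += 0.5 * (ylo + yhi) * (hi - lo)
    a_max = f1 - f0
    a_min = (f1**2 - f0**2) / 2.0  # chance diagonal within the band
    if a_max - a_min <= 0:
        raise ValueError("degenerate specificity band")
    return 0.5 * (1.0 + (area - a_min) / (a_max - a_min))


def rel_rmse(scores, labels) -> float:
    """RMSE against 0/1 labels normalized by the score range.

    Returns NaN (flagged, excluded from fold means) when every score is
    identical, since the normalization is then undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(scores) == 0:
        raise ValueError("scores must be nonempty")
    rng = scores.max() - scores.min()
    if rng <= 0:
        return float("nan")
    rmse = float(np.sqrt(np.mean((scores - labels) ** 2)))
    return rmse / rng


def _fold_metrics(pos: np.ndarray, neg: np.ndarray) -> dict[str, float]:
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return {
        "auc": auc_mw(pos, neg),
        "pauc": pauc_standardized(pos, neg),
        "relrmse": rel_rmse(scores, labels),
        "n_test_presence": len(pos),
        "n_eval_background": len(neg),
    }


def evaluate_loco(
    config: ModelConfig,
    folds: FoldPlan,
    presence_rows: np.ndarray,
    background_rows: np.ndarray,
    presence_cells: np.ndarray | None = None,
    background_cells: np.ndarray | None = None,
    var_names=None,
) -> ValidationReport:
    """Leave-one-cluster-out evaluation of a model configuration.

    Per fold, the model is refit on the training clusters plus the fixed
    training background, and scored on the held-out presences against the
    evaluation background — the background sample minus any cell occupied
    by a test presence (cell identity given by ``*_cells`` index arrays;
    when omitted, no pixel exclusion is needed).  Metrics are on the
    cloglog scale; fold failures are flagged and skipped with a warning.
    """
    P = np.asarray(presence_rows, dtype=float)
    B = np.asarray(background_rows, dtype=float)
    rows = []
    for f in range(folds.n_folds):
        test_mask = folds.cluster_of_presence == f
        train = P[~test_mask]
        test = P[test_mask]
        eval_bg = np.ones(len(B), dtype=bool)
        if presence_cells is not None and background_cells is not None:
            test_cells = set(map(tuple, np.asarray(presence_cells)[test_mask]))
            eval_bg = np.array(
                [tuple(c) not in test_cells for c in np.asarray(background_cells)]
            )
        try:
            model = fit_maxent(train, B, config, var_names)
            pos = predict_model(model, test, type="cloglog")
            neg = predict_model(model, B[eval_bg], type="cloglog")
            from .decision import _youden_threshold  # per-fold Youden cutoffs

            rows.append({"fold": f, **_fold_metrics(pos, neg),
                         "youden_theta": _youden_threshold(pos, neg)})
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - defensive
            import warnings

            warnings.warn(f"LOCO fold {f} failed and was skipped: {exc}")
    if not rows:
        raise RuntimeError("every LOCO fold failed")
    return ValidationReport(scheme="LOCO", per_fold=pd.DataFrame(rows), eps_m=folds.eps_m)


def kfold_cv(
    presence_rows: np.ndarray,
    background_rows: np.ndarray,
    config: ModelConfig,
    k: int = 5,
    seed: int = 42,
    var_names=None,
) -> ValidationReport:
    """Random presence k-fold CV (background shared across folds).

    Used only for the selection grid and the background sweeps; the
    report is labeled "random-CV" because its optimism is not comparable
    to LOCO.
    """
    P = np.asarray(presence_rows, dtype=float)
    B = np.asarray(background_rows, dtype=float)
    fold_of = presence_kfold(len(P), k, seed)
    rows = []
    for f in range(k):
        model = fit_maxent(P[fold_of != f], B, config, var_names)
        pos = predict_model(model, P[fold_of == f], type="cloglog")
        neg = predict_model(model, B, type="cloglog")
        rows.append({"fold": f, **_fold_metrics(pos, neg)})
    return ValidationReport(scheme="random-CV", per_fold=pd.DataFrame(rows))
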