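"""Presence-background maximum-entropy (MaxEnt) habitat model.

The model estimates a Gibbs distribution over landscape cells,
``raw(x) = exp(sum_j lambda_j f_j(x)) / Z``, where the features f_j are
expansions (linear, quadratic, hinge) of min-max-scaled predictors and Z
normalizes raw scores to sum to 1 over the training background.  The
coefficients minimize the convex L1-penalized objective

    -(1/m) sum_presences link(x_i) + log Z + sum_j beta_j |lambda_j|,

with per-feature penalties beta_j following the published MaxEnt default
schedule scaled by a regularization multiplier (RM) — larger RM, sparser
and smoother models.  Optimization is FISTA (accelerated proximal
gradient with soft-thresholding and backtracking line search), which
suits the objective's smooth-plus-L1 structure with no extra
dependencies.

Predictions come in three monotonically related scales: ``link`` (the
linear predictor), ``raw`` (normalized over training background), and
``cloglog`` = 1 - exp(-e^H * raw), with H the entropy of the fitted raw
distribution — the standard suitability index in (0, 1).

The module also houses the supporting design steps: collinearity pruning
(Spearman then VIF, with ecologically protected variables), the
accessible background mask and sampler, AICc over presences, and the
feature-class x RM selection grid scored by the robustness criterion
(mean CV AUC - 0.5 x SD).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from scipy.stats import spearmanr

__all__ = [
    "ModelConfig",
    "FeatureExpander",
    "MaxentModel",
    "BackgroundSample",
    "expand_features",
    "default_penalties",
    "fit_maxent",
    "predict_model",
    "spearman_prune",
    "vif_prune",
    "accessible_mask",
    "sample_background",
    "partial_response",
    "aicc",
    "select_model_grid",
]

# Published MaxEnt default regularization tables: beta as a function of
# presence sample size, linearly interpolated (clamped at the ends).
_BETA_TABLES = {
    # linear+quadratic(+product) feature classes
    "lq": {"n": [0, 10, 17, 30, 100], "beta": [1.3, 0.8, 0.5, 0.25, 0.05]},
    # linear-only models
    "l": {"n": [0, 10, 30, 100], "beta": [1.0, 1.0, 0.2, 0.05]},
    # hinge features: flat schedule
    "h": {"n": [0, 100], "beta": [0.5, 0.5]},
}

_CLASS_ORDER = {"l": 0, "lq": 1, "lqh": 2}  # simpler first, for tie-breaks


@dataclasses.dataclass
class ModelConfig:
    """Feature and regularization settings of one MaxEnt fit."""

    feature_classes: str = "lq"  # subset of {l, q, h} as a compact string
    rm: float = 1.4
    hinge_knots: int = 50
    background_target_ratio: float = 25.0
    mask_dist_m: float = 300.0
    seed: int = 42

    def __post_init__(self) -> None:
        classes = set(self.feature_classes)
        if not classes or not classes <= {"l", "q", "h"}:
            raise ValueError("feature_classes must be a nonempty subset of 'lqh'")
        if "q" in classes and "l" not in classes:
            raise ValueError("quadratic features require linear features")
        if not 0.5 <= self.rm <= 5:
            raise ValueError("rm must lie in [0.5, 5]")


class FeatureExpander:
    """Min-max scaling plus l/q/h feature expansion, frozen at training.

    Scaling bounds come from the training rows (presences and background
    together); prediction rows are scaled with the same bounds and gently
    clamped to [-0.1, 1.1] so mild extrapolation cannot explode features.
    Hinge features use ``hinge_knots`` equally spaced interior knots with
    forward max(0, (x-t)/(1-t)) and reverse max(0, (t-x)/t) bases.
    """

    def __init__(self, training_X: np.ndarray, var_names, classes: str, hinge_knots: int = 50):
        X = np.asarray(training_X, dtype=float)
        self.classes = "".join(c for c in "lqh" if c in set(classes))
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        keep = hi - lo > 0
        dropped = [n for n, k in zip(var_names, keep) if not k]
        if dropped:
            warnings.warn(f"zero-variance variables excluded: {dropped}")
        self.var_names = [n for n, k in zip(var_names, keep) if k]
        self._keep = keep
        self.lo = lo[keep]
        self.hi = hi[keep]
        self.knots = np.linspace(0, 1, hinge_knots + 2)[1:-1] if "h" in self.classes else np.empty(0)
        self.feature_names: list[str] = []
        self.feature_classes: list[str] = []
        for name in self.var_names:
            if "l" in self.classes:
                self.feature_names.append(name)
                self.feature_classes.append("l")
            if "q" in self.classes:
                self.feature_names.append(f"{name}^2")
                self.feature_classes.append("q")
        for name in self.var_names:
            for t in self.knots:
                self.feature_names.append(f"hinge({name},{t:.3f})")
                self.feature_classes.append("h")
                self.feature_names.append(f"rhinge({name},{t:.3f})")
                self.feature_classes.append("h")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] == len(self._keep):
            X = X[:, self._keep]
        elif X.shape[1] != len(self.var_names):
            raise ValueError("row width does not match the training variables")
        S = np.clip((X - self.lo) / (self.hi - self.lo), -0.1, 1.1)
        cols = []
        for j in range(S.shape[1]):
            if "l" in self.classes:
                cols.append(S[:, j])
            if "q" in self.classes:
                cols.append(S[:, j] ** 2)
        for j in range(S.shape[1]):
            for t in self.knots:
                cols.append(np.maximum(0.0, (S[:, j] - t) / (1 - t)))
                cols.append(np.maximum(0.0, (t - S[:, j]) / t))
        return np.column_stack(cols) if cols else np.empty((len(S), 0))


def expand_features(X, classes: str, scaling: FeatureExpander) -> np.ndarray:
    """Expand rows with a frozen training-time expander."""
    if set(classes) != set(scaling.classes):
        raise ValueError("classes disagree with the expander")
    return scaling.transform(X)


def default_penalties(
    classes_per_feature,
    n_presence: int,
    sd_per_feature,
    rm: float = 1.0,
    sd_floor: float = 0.0,
) -> np.ndarray:
    """Per-feature L1 penalties from the published default schedule.

    beta_j = RM x beta_class(n_presence) x sd_j / sqrt(n_presence), with
    beta_class interpolated from the published sample-size tables (the
    linear/quadratic table when quadratic features are present, the
    linear-only table otherwise, a flat 0.5 for hinge features).

    ``sd_floor`` is a minimum deviation on the [0, 1] feature scale:
    features that are almost constant over the training rows (typical for
    hinge bases active on a handful of cells) otherwise get a vanishing
    penalty, which leaves the coefficient unbounded whenever the feature
    separates presences from background — the same failure the published
    implementations guard against with a minimum-deviation rule.
    """
    if n_presence < 2:
        raise ValueError("need at least 2 presences for the penalty schedule")
    classes_per_feature = list(classes_per_feature)
    sd = np.maximum(np.asarray(sd_per_feature, dtype=float), sd_floor)
    has_q = "q" in classes_per_feature
    beta = np.empty(len(classes_per_feature))
    for j, cls in enumerate(classes_per_feature):
        if cls == "h":
            table = _BETA_TABLES["h"]
        elif has_q:
            table = _BETA_TABLES["lq"]
        else:
            table = _BETA_TABLES["l"]
        beta[j] = np.interp(n_presence, table["n"], table["beta"])
    return rm * beta * sd / np.sqrt(n_presence)


@dataclasses.dataclass
class MaxentModel:
    """A fitted model: coefficients plus everything needed to predict."""

    lambdas: np.ndarray
    expander: FeatureExpander
    log_z: float
    entropy: float
    config: ModelConfig
    n_presence: int
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        """Number of nonzero coefficients (AICc complexity)."""
        return int(np.sum(np.abs(self.lambdas) > 1e-8))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "lambdas": self.lambdas.tolist(),
            "feature_names": self.expander.feature_names,
            "var_names": self.expander.var_names,
            "scaling_lo": self.expander.lo.tolist(),
            "scaling_hi": self.expander.hi.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "config": dataclasses.asdict(self.config),
            "n_presence": self.n_presence,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _objective_parts(lam, F_pres, F_bg):
    link_p = F_pres @ lam
    link_b = F_bg @ lam
    lz = logsumexp(link_b)
    return -link_p.mean() + lz, link_b, lz


def fit_maxent(
    presence_rows: np.ndarray,
    background_rows: np.ndarray,
    config: ModelConfig,
    var_names=None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    penalties: np.ndarray | None = None,
) -> MaxentModel:
    """Fit the L1-penalized MaxEnt model with FISTA.

    ``presence_rows`` and ``background_rows`` are raw predictor matrices
    (same columns).  Feature scaling and penalties are derived from the
    pooled training rows; an explicit ``penalties`` vector (e.g. zeros
    for an unpenalized fit) overrides the default schedule.  Raises if
    the optimizer fails to converge.
    """
    P = np.asarray(presence_rows, dtype=float)
    B = np.asarray(background_rows, dtype=float)
    if len(P) < 2:
        raise ValueError("need at least 2 presences")
    if var_names is None:
        var_names = [f"x{j}" for j in range(P.shape[1])]
    expander = FeatureExpander(np.vstack([P, B]), var_names, config.feature_classes,
                               config.hinge_knots)
    F_pres = expander.transform(P)
    F_bg = expander.transform(B)
    if penalties is not None:
        beta = np.asarray(penalties, dtype=float)
        if beta.shape != (expander.n_features,):
            raise ValueError("penalties length must match the expanded features")
    else:
        sd = np.vstack([F_pres, F_bg]).std(axis=0, ddof=1)
        beta = default_penalties(expander.feature_classes, len(P), sd, rm=config.rm,
                                 sd_floor=0.05)

    lam = np.zeros(expander.n_features)
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    obj_prev, _, _ = _objective_parts(lam, F_pres, F_bg)
    obj_prev += beta @ np.abs(lam)
    mean_fp = F_pres.mean(axis=0)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        smooth_y, link_b, lz = _objective_parts(y, F_pres, F_bg)
        w = np.exp(link_b - lz)  # raw distribution over background
        grad = -mean_fp + w @ F_bg
        # backtracking line search on the smooth part
        while True:
            cand = y - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta, 0.0)
            smooth_c, _, _ = _objective_parts(cand, F_pres, F_bg)
            diff = cand - y
            if smooth_c <= smooth_y + grad @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        t_next = (1 + np.sqrt(1 + 4 * t_mom**2)) / 2
        y = cand + ((t_mom - 1) / t_next) * (cand - lam)
        lam, t_mom = cand, t_next
        obj = smooth_c + beta @ np.abs(lam)
        if obj > obj_prev:  # restart momentum on non-monotone step
            y, t_mom = lam.copy(), 1.0
        if abs(obj_prev - obj) < tol:
            converged = True
            obj_prev = obj
            break
        obj_prev = obj
    if not converged:
        raise RuntimeError(
            f"MaxEnt fit did not converge in {max_iter} iterations "
            f"(last objective {obj_prev:.6g}); consider increasing RM"
        )
    _, link_b, lz = _objective_parts(lam, F_pres, F_bg)
    raw = np.exp(link_b - lz)
    entropy = float(-np.sum(raw * np.log(np.maximum(raw, 1e-300))))
    return MaxentModel(
        lambdas=lam,
        expander=expander,
        log_z=float(lz),
        entropy=entropy,
        config=config,
        n_presence=len(P),
        converged=converged,
        n_iter=n_iter,
    )


def predict_model(model: MaxentModel, rows: np.ndarray, type: str = "cloglog") -> np.ndarray:
    """Score rows on the link, raw or cloglog scale.

    raw normalizes by the training-background partition function, so raw
    scores sum to 1 over the training background; cloglog applies the
    entropy transform 1 - exp(-e^H * raw).
    """
    F = model.expander.transform(np.asarray(rows, dtype=float))
    link = F @ model.lambdas
    if type == "link":
        return link
    raw = np.exp(link - model.log_z)
    if type == "raw":
        return raw
    if type == "cloglog":
        return 1.0 - np.exp(-np.exp(model.entropy) * raw)
    raise ValueError(f"unknown prediction type: {type}")


# ---------------------------------------------------------------------------
# collinearity pruning


def spearman_prune(rows: np.ndarray, var_names, threshold: float = 0.7, protected=()):
    """Greedy Spearman-|rho| pruning of collinear variable pairs.

    While any retained pair exceeds the threshold, drop the unprotected
    member (or, when both are unprotected, the one with the larger mean
    |rho| against all other retained variables).  Pairs of two protected
    variables are kept with a warning.
    """
    rows = np.asarray(rows, dtype=float)
    names = list(var_names)
    if len(names) < 2:
        return names
    protected = set(protected)
    keep = list(range(len(names)))
    while len(keep) >= 2:
        sub = rows[:, keep]
        if len(keep) == 2:
            r = spearmanr(sub[:, 0], sub[:, 1]).statistic
            rho = np.array([[0.0, r], [r, 0.0]])
        else:
            rho = np.atleast_2d(spearmanr(sub).statistic)
            np.fill_diagonal(rho, 0.0)
        offending = []
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                if abs(rho[a, b]) > threshold:
                    offending.append((abs(rho[a, b]), a, b))
        offending.sort(reverse=True)
        dropped = False
        for _, a, b in offending:
            na, nb = names[keep[a]], names[keep[b]]
            prot_a, prot_b = na in protected, nb in protected
            if prot_a and prot_b:
                warnings.warn(f"protected pair exceeds threshold: {na}, {nb}")
                continue
            if prot_a:
                victim = b
            elif prot_b:
                victim = a
            else:
                mean_a = np.abs(rho[a]).mean()
                mean_b = np.abs(rho[b]).mean()
                victim = a if mean_a >= mean_b else b
            keep.pop(victim)
            dropped = True
            break
        if not dropped:
            break
    return [names[i] for i in keep]


def _vif(rows: np.ndarray) -> np.ndarray:
    """VIF per column: 1/(1-R^2) regressing it on the others + intercept."""
    n, p = rows.shape
    out = np.empty(p)
    X1 = np.column_stack([rows, np.ones(n)])
    for j in range(p):
        yj = rows[:, j]
        others = np.delete(X1, j, axis=1)
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_prune(rows: np.ndarray, var_names, max_vif: float = 5.0, protected=()):
    """Iterative VIF pruning: drop the worst unprotected variable until
    every variance-inflation factor is at or below ``max_vif``."""
    rows = np.asarray(rows, dtype=float)
    names = list(var_names)
    protected = set(protected)
    keep = list(range(len(names)))
    while len(keep) >= 2:
        vif = _vif(rows[:, keep])
        worst_order = np.argsort(-vif)
        if vif[worst_order[0]] <= max_vif:
            break
        victim = None
        for idx in worst_order:
            if vif[idx] <= max_vif:
                break
            if names[keep[idx]] not in protected:
                victim = idx
                break
        if victim is None:
            prot_rows = rows[:, keep]
            if np.any(np.isinf(vif)):
                raise ValueError("perfect collinearity among protected variables")
            warnings.warn("only protected variables exceed the VIF limit; keeping them")
            break
        keep.pop(victim)
    return [names[i] for i in keep]


# ---------------------------------------------------------------------------
# background design


@dataclasses.dataclass
class BackgroundSample:
    """Sampled background cells with their predictor rows.

    ``cell_rows``/``cell_cols`` index the sampling grid (the native-
    resolution accessible mask); ``xy`` holds the cell centers so rows
    can be re-extracted from a stack at any scale.
    """

    rows: np.ndarray  # predictor matrix
    cell_rows: np.ndarray
    cell_cols: np.ndarray
    xy: np.ndarray
    realized_ratio: float


def realized_ratio(n_background: int, n_presence: int) -> float:
    """Background:presence ratio as reported (one decimal)."""
    return round(n_background / n_presence, 1)


def accessible_mask(dist_coast_data: np.ndarray, max_dist_m: float,
                    valid: np.ndarray | None = None) -> np.ndarray:
    """Cells within the accessible coastal band, valid on every predictor."""
    mask = np.isfinite(dist_coast_data) & (dist_coast_data <= max_dist_m)
    if valid is not None:
        mask &= valid
    if not mask.any():
        raise ValueError("accessible mask is empty")
    return mask


def sample_background(
    mask: np.ndarray,
    stack,
    var_names,
    n_presence: int,
    target_ratio: float = 25.0,
    seed: int = 42,
    mask_grid=None,
) -> BackgroundSample:
    """Draw background cells uniformly without replacement from the mask.

    The mask lives on the native-resolution grid.  When ``mask_grid`` (a
    Raster sharing the mask's geometry) is given and the stack is at a
    coarser fitting scale, predictor rows are read from the stack at the
    sampled cells' centers — native-cell background with aggregated-fit
    predictors.
    """
    rows, cols = np.nonzero(mask)
    n_avail = len(rows)
    if n_avail < n_presence:
        warnings.warn("accessible mask smaller than the presence sample")
    n_bg = min(n_avail, int(round(target_ratio * n_presence)))
    rng = np.random.default_rng(seed)
    pick = rng.choice(n_avail, size=n_bg, replace=False)
    rr, cc = rows[pick], cols[pick]
    if mask_grid is not None:
        nrow = mask.shape[0]
        x = mask_grid.origin[0] + (cc + 0.5) * mask_grid.cell_m
        y = mask_grid.origin[1] + (nrow - rr - 0.5) * mask_grid.cell_m
        X = stack.extract_at_xy(x, y, var_names)
    else:
        x = stack.origin[0] + (cc + 0.5) * stack.cell_m
        y = stack.origin[1] + (mask.shape[0] - rr - 0.5) * stack.cell_m
        X = stack.extract_rows(rr, cc, var_names)
    return BackgroundSample(X, rr, cc, np.column_stack([x, y]),
                            realized_ratio(n_bg, n_presence))


def partial_response(
    model: MaxentModel, reference_rows: np.ndarray, var: str, n_points: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-link partial response curve for one predictor.

    The focal variable sweeps its observed range while every other
    variable sits at its median over ``reference_rows``; the curve is the
    change in the linear predictor relative to the all-median point.  The
    sign of the end-to-end change summarizes the direction of the
    response.
    """
    names = model.expander.var_names
    if var not in names:
        raise KeyError(f"{var} is not a model variable")
    ref = np.asarray(reference_rows, dtype=float)
    if ref.shape[1] == len(model.expander._keep):
        ref = ref[:, model.expander._keep]
    j = names.index(var)
    med = np.median(ref, axis=0)
    grid = np.linspace(ref[:, j].min(), ref[:, j].max(), n_points)
    X = np.tile(med, (n_points, 1))
    X[:, j] = grid
    link = predict_model(model, X, type="link")
    base = predict_model(model, med[None, :], type="link")[0]
    return grid, link - base


def aicc(model: MaxentModel, presence_rows: np.ndarray) -> float:
    """Small-sample AIC over presence likelihoods (NaN when n <= k + 1)."""
    n = len(presence_rows)
    k = model.k
    if n <= k + 1:
        return float("nan")
    raw = predict_model(model, presence_rows, type="raw")
    ll = float(np.sum(np.log(np.maximum(raw, 1e-300))))
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)


def select_model_grid(
    presence_rows: np.ndarray,
    background_rows: np.ndarray,
    var_names=None,
    classes_grid=("l", "lq", "lqh"),
    rm_grid=(1.0, 1.2, 1.4, 1.6, 1.8, 2.0),
    folds: int = 5,
    seed: int = 42,
    hinge_knots: int = 50,
):
    """Feature-class x RM grid search scored by the robustness criterion.

    Each combination is evaluated with seeded random k-fold CV on the
    presences (background shared): robustness = mean fold AUC - 0.5 x SD.
    Delta-AICc comes from full-data fits.  Ties break toward the simpler
    feature class, then the larger RM.  Returns (table, chosen_config).
    """
    from .validation import auc_mw, presence_kfold

    P = np.asarray(presence_rows, dtype=float)
    B = np.asarray(background_rows, dtype=float)
    fold_of = presence_kfold(len(P), folds, seed)
    records = []
    for classes in classes_grid:
        for rm in rm_grid:
            config = ModelConfig(feature_classes=classes, rm=rm, hinge_knots=hinge_knots)
            fold_aucs = []
            failed = False
            try:
                for f in range(folds):
                    train = P[fold_of != f]
                    test = P[fold_of == f]
                    if len(test) == 0 or len(train) < 2:
                        continue
                    m = fit_maxent(train, B, config, var_names)
                    pos = predict_model(m, test, type="link")
                    neg = predict_model(m, B, type="link")
                    fold_aucs.append(auc_mw(pos, neg))
                full = fit_maxent(P, B, config, var_names)
            except RuntimeError as exc:
                warnings.warn(f"grid cell ({classes}, RM={rm}) failed: {exc}")
                failed = True
            if failed:
                records.append(
                    {"classes": classes, "rm": rm, "cv_auc_mean": np.nan,
                     "cv_auc_sd": np.nan, "robustness": np.nan, "aicc": np.nan,
                     "k": -1}
                )
                continue
            fold_aucs = np.asarray(fold_aucs)
            mean, sd = fold_aucs.mean(), fold_aucs.std(ddof=1)
            records.append(
                {
                    "classes": classes,
                    "rm": rm,
                    "cv_auc_mean": mean,
                    "cv_auc_sd": sd,
                    "robustness": mean - 0.5 * sd,
                    "aicc": aicc(full, P),
                    "k": full.k,
                }
            )
    import pandas as pd

    table = pd.DataFrame(records)
    finite = table["aicc"].dropna()
    table["delta_aicc"] = table["aicc"] - (finite.min() if len(finite) else np.nan)
    table["_simplicity"] = table["classes"].map(_CLASS_ORDER)
    best = table.sort_values(
        ["robustness", "_simplicity", "rm"], ascending=[False, True, False]
    ).iloc[0]
    table = table.drop(columns="_simplicity")
    chosen = ModelConfig(feature_classes=best["classes"], rm=float(best["rm"]),
                         hinge_knots=hinge_knots)
    return table, chosen
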