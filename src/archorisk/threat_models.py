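"""Threat-status imputation: PGLM + random-forest + neural-net ensemble.

Threat categories are coded ordinally (LC=1, NT=2, VU=3, EN=4, CR=5, EX=6)
and modeled as a continuous response on [1, 6].  Three models are fit to the
species with known status and used to predict the masked (DD/UA) species:

* a phylogenetic/spatial GLS ("PGLM") on standardized predictors with a
  combined residual correlation w*C_phylo + (1-w)*C_spatial, w profiled;
* a random-forest regression on all untransformed predictors;
* a single-hidden-layer perceptron on min-max scaled predictors.

Predictions are clamped to [1, 6]; the ensemble estimate is the mean of the
three clamped predictions, rounded half-up (toward the more threatened
category) for the categorical call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import RepeatedKFold
from sklearn.neural_network import MLPRegressor

from .bodysize import vcv_matrix
from .trees import to_arrays

__all__ = [
    "STATUS_CODES",
    "status_to_code",
    "code_to_status",
    "encode_predictors",
    "pcoa_axes",
    "build_design",
    "fit_pglm",
    "fit_rf",
    "fit_ann",
    "crossvalidate",
    "pool_predictions",
    "concordance",
    "impute_ensemble",
]

STATUS_CODES = {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5, "EX": 6}
_CODE_TO_STATUS = {v: k for k, v in STATUS_CODES.items()}

#: raw continuous predictors and whether they are log-transformed
CONTINUOUS = {
    "body_length_cm": True, "body_mass_g": True, "range_area": True,
    "hei": False, "clim1": False, "clim2": False, "clim3": False,
    "clim4": False, "clim5": False, "aet": True, "npp": True,
}
CATEGORICAL = ("microhabitat", "endemicity", "ecoregion")


def status_to_code(status) -> float:
    """Ordinal code 1..6 for LC..EX; DD/UA/missing map to NaN."""
    if status in STATUS_CODES:
        return float(STATUS_CODES[status])
    if status in ("DD", "UA") or status is None or (isinstance(status, float) and np.isnan(status)):
        return np.nan
    raise ValueError(f"unknown status label {status!r}")


def code_to_status(value: float) -> str:
    """Nearest category for a continuous estimate; x.5 rounds toward threat."""
    v = min(max(float(value), 1.0), 6.0)
    return _CODE_TO_STATUS[int(min(math.floor(v + 0.5), 6))]


# ---------------------------------------------------------------------------
# predictor encoding


@dataclass
class PredictorEncoder:
    scheme: str
    centers: dict = field(default_factory=dict)   # col -> (a, b): x' = (x-a)/b
    levels: dict = field(default_factory=dict)    # categorical col -> levels
    columns: list = field(default_factory=list)

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col, do_log in CONTINUOUS.items():
            x = raw[col].to_numpy(dtype=float)
            if do_log:
                if np.any(x <= 0):
                    raise ValueError(f"non-positive values in log column {col!r}")
                x = np.log(x)
            a, b = self.centers[col]
            out[col] = (x - a) / b
        for col in CATEGORICAL:
            seen = set(raw[col].unique())
            unseen = seen - set(self.levels[col])
            if unseen:
                raise ValueError(f"unseen {col} level(s) at predict time: {sorted(unseen)}")
            for lev in self.levels[col]:
                out[f"{col}={lev}"] = (raw[col] == lev).astype(float).to_numpy()
        X = pd.DataFrame(out, index=raw.index)
        return X[self.columns]


def encode_predictors(raw: pd.DataFrame, scheme: str = "pglm"):
    """Encode the raw species table into a numeric predictor matrix.

    ``scheme="pglm"``: continuous columns log-transformed (where positive by
    construction), centered and scaled to unit sd.  ``scheme="minmax"``:
    the same transforms mapped to [0, 1].  Categorical predictors become
    one-hot blocks (each block sums to 1 per species).  The fitted encoder is
    returned for reuse on prediction rows.
    """
    if scheme not in ("pglm", "minmax"):
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    enc = PredictorEncoder(scheme=scheme)
    for col, do_log in CONTINUOUS.items():
        x = raw[col].to_numpy(dtype=float)
        if do_log:
            if np.any(x <= 0):
                raise ValueError(f"non-positive values in log column {col!r}")
            x = np.log(x)
        if scheme == "pglm":
            enc.centers[col] = (float(x.mean()), float(x.std() or 1.0))
        else:
            lo, hi = float(x.min()), float(x.max())
            enc.centers[col] = (lo, (hi - lo) or 1.0)
    for col in CATEGORICAL:
        enc.levels[col] = sorted(raw[col].unique())
    enc.columns = list(CONTINUOUS) + [f"{c}={l}" for c in CATEGORICAL
                                      for l in enc.levels[c]]
    return enc.transform(raw), enc


def pcoa_axes(distance_matrix: np.ndarray, k: int = 2) -> np.ndarray:
    """First ``k`` principal coordinates of a distance matrix.

    Classical MDS: eigendecomposition of the double-centered squared-distance
    matrix; axes ordered by eigenvalue, negative eigenvalues truncated to
    zero-variance axes.  Signs are fixed so each axis's largest-magnitude
    coordinate is positive.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    coords = np.zeros((n, k))
    for j, idx in enumerate(order):
        lam = max(evals[idx], 0.0)
        axis = evecs[:, idx] * math.sqrt(lam)
        if abs(axis.min()) > abs(axis.max()):
            axis = -axis
        coords[:, j] = axis
    return coords


def build_design(species_table: pd.DataFrame, tree, scheme: str = "pglm"):
    """Full predictor matrix: encoded traits plus 2+2 PCoA covariate axes.

    Phylogenetic axes come from the patristic distance matrix, spatial axes
    from pairwise centroid distances.  Under ``minmax`` the PCoA axes are
    min-max scaled like every other continuous column.
    """
    X, enc = encode_predictors(species_table, scheme=scheme)
    arr = to_arrays(tree) if not hasattr(tree, "clade_matrix") else tree
    order = [arr.labels.index(sp) for sp in species_table.index]
    C = vcv_matrix(arr)[np.ix_(order, order)]
    depth = np.diag(C)
    Dphy = depth[:, None] + depth[None, :] - 2.0 * C
    np.fill_diagonal(Dphy, 0.0)
    cent = species_table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    Dspa = squareform(pdist(cent))
    for name, D in (("phy", Dphy), ("spa", Dspa)):
        ax = pcoa_axes(D, k=2)
        for j in range(2):
            col = ax[:, j]
            if scheme == "pglm":
                col = (col - col.mean()) / (col.std() or 1.0)
            else:
                lo, hi = col.min(), col.max()
                col = (col - lo) / ((hi - lo) or 1.0)
            X[f"{name}_pcoa{j + 1}"] = col
    return X, enc


# ---------------------------------------------------------------------------
# models


def _clamp(x):
    return np.clip(np.asarray(x, dtype=float), 1.0, 6.0)


@dataclass
class PGLMResult:
    coef: pd.Series
    weight_phylo: float
    selected: list
    importance: pd.Series
    sigma2: float
    cond: float
    _whitener: np.ndarray = None

    def predict(self, X: pd.DataFrame) -> pd.Series:
        Z = X[self.selected].to_numpy(dtype=float)
        Z = np.column_stack([np.ones(len(Z)), Z])
        beta = self.coef.to_numpy()
        return pd.Series(_clamp(Z @ beta), index=X.index)


def _gls_fit(Xd: np.ndarray, y: np.ndarray, L: np.ndarray):
    """GLS via pre-computed Cholesky factor L of the correlation matrix."""
    from scipy.linalg import solve_triangular
    Xw = solve_triangular(L, Xd, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, res, rank, sv = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n, p = Xw.shape
    sigma2 = float(resid @ resid) / max(n - rank, 1)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    XtX = Xw.T @ Xw
    cov = sigma2 * np.linalg.pinv(XtX)
    # gaussian loglik (for profiling w): -n/2 log(2pi sigma2_ml) - log|L| - rss/2sigma2_ml
    rss = float(resid @ resid)
    sigma2_ml = max(rss / n, 1e-300)
    ll = (-0.5 * n * math.log(2 * math.pi * sigma2_ml)
          - np.log(np.diag(L)).sum() - 0.5 * n)
    return beta, cov, sigma2, cond, ll


def _drop_reference_levels(X: pd.DataFrame) -> list:
    """Columns retained for the linear model: first level of each one-hot
    block is dropped as the reference to keep the design full-rank."""
    keep, seen_block = [], set()
    for col in X.columns:
        if "=" in col:
            block = col.split("=", 1)[0]
            if block not in seen_block:
                seen_block.add(block)
                continue  # reference level
        keep.append(col)
    return keep


def fit_pglm(X: pd.DataFrame, y: pd.Series, phylo_corr: np.ndarray,
             spatial_corr: np.ndarray, n_select: int = 15,
             w_grid=None) -> PGLMResult:
    """GLS with combined phylogenetic + spatial residual correlation.

    The residual correlation is w*C_phylo + (1-w)*C_spatial with w chosen by
    profile likelihood on a grid.  A preliminary full fit ranks predictors by
    |t| (by |coefficient| in the zero-residual case) and the ``n_select``
    best are retained for the final fit and prediction.  Predictions are
    clamped to [1, 6].
    """
    known = y.notna()
    idx = np.flatnonzero(known.to_numpy())
    yk = y.to_numpy(dtype=float)[idx]
    cols = _drop_reference_levels(X)
    # levels unobserved in the training rows give constant columns; drop them
    cols = [c for c in cols
            if np.ptp(X.iloc[idx][c].to_numpy(dtype=float)) > 0]
    Xk = X.iloc[idx][cols].to_numpy(dtype=float)
    Cp = phylo_corr[np.ix_(idx, idx)]
    Cs = spatial_corr[np.ix_(idx, idx)]
    if w_grid is None:
        w_grid = np.linspace(0.0, 1.0, 11)
    Xd = np.column_stack([np.ones(len(yk)), Xk])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        sv = np.linalg.svd(Xd, compute_uv=False)
        raise ValueError(
            f"singular design matrix (condition number "
            f"{sv[0] / max(sv[-1], 1e-300):.3g})")
    best = None
    for w in w_grid:
        R = w * Cp + (1 - w) * Cs
        R = R + 1e-8 * np.eye(len(R))
        L = np.linalg.cholesky(R)
        beta, cov, sigma2, cond, ll = _gls_fit(Xd, yk, L)
        if best is None or ll > best[0]:
            best = (ll, w, beta, cov, sigma2, cond, L)
    ll, w, beta, cov, sigma2, cond, L = best
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.abs(beta) / se
    tvals = np.where(np.isfinite(tvals), tvals, np.abs(beta) * np.inf)
    if sigma2 < 1e-12:
        rank_stat = np.abs(beta[1:])
    else:
        rank_stat = np.where(np.isfinite(tvals[1:]), tvals[1:], 0.0)
    order = np.argsort(rank_stat)[::-1]
    selected = [cols[i] for i in order[: min(n_select, len(cols))]]
    Xs = np.column_stack([np.ones(len(yk)),
                          X.iloc[idx][selected].to_numpy(dtype=float)])
    beta_s, cov_s, sigma2_s, cond_s, _ = _gls_fit(Xs, yk, L)
    coef = pd.Series(beta_s, index=["(intercept)"] + selected)
    importance = pd.Series(0.0, index=list(X.columns), name="importance")
    importance[selected] = np.abs(beta_s[1:])
    return PGLMResult(coef=coef, weight_phylo=float(w), selected=selected,
                      importance=importance, sigma2=sigma2_s, cond=cond_s)


@dataclass
class SKModelResult:
    model: object
    importance: pd.Series
    columns: list
    tuning: dict

    def predict(self, X: pd.DataFrame) -> pd.Series:
        return pd.Series(_clamp(self.model.predict(X[self.columns].to_numpy())),
                         index=X.index)


def fit_rf(X: pd.DataFrame, y: pd.Series, n_trees: int = 500,
           mtry_grid=(0.33, "sqrt", 1.0), seed=None) -> SKModelResult:
    """Random-forest regression on the ordinal code over all predictors.

    ``mtry`` (sklearn ``max_features``) is tuned by out-of-bag R2 over 500
    trees; permutation importance on the training data is attached.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    known = y.notna()
    Xk = X[known].to_numpy(dtype=float)
    yk = y[known].to_numpy(dtype=float)
    best = None
    for mtry in mtry_grid:
        rf = RandomForestRegressor(n_estimators=n_trees, max_features=mtry,
                                   oob_score=True, random_state=seed,
                                   n_jobs=1, bootstrap=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(Xk, yk)
        score = rf.oob_score_
        if best is None or score > best[0]:
            best = (score, mtry, rf)
    score, mtry, rf = best
    perm = permutation_importance(rf, Xk, yk, n_repeats=5, random_state=seed)
    importance = pd.Series(perm.importances_mean, index=X.columns,
                           name="importance")
    return SKModelResult(model=rf, importance=importance, columns=list(X.columns),
                         tuning={"max_features": mtry, "oob_r2": float(score)})


def fit_ann(X: pd.DataFrame, y: pd.Series, hidden_sizes_grid=(8, 16),
            weight_decay_grid=(1e-3, 1e-1), k_folds: int = 10,
            repeats: int = 5, max_iter: int = 2000, seed=None) -> SKModelResult:
    """Single-hidden-layer perceptron on min-max scaled predictors.

    Hidden size and weight decay (L2) are tuned by repeated k-fold
    cross-validated RMSE; importances are the summed absolute input-layer
    weights per feature.  Inputs outside [0, 1] are rejected — encode with
    the ``minmax`` scheme first.
    """
    if any(h < 1 for h in hidden_sizes_grid):
        raise ValueError("hidden layer must have at least 1 neuron")
    vals = X.to_numpy(dtype=float)
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
        raise ValueError("ANN inputs must be min-max scaled to [0, 1]")
    known = y.notna()
    Xk = X[known].to_numpy(dtype=float)
    yk = y[known].to_numpy(dtype=float)
    cv = RepeatedKFold(n_splits=k_folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(Xk))
    best = None
    for h in hidden_sizes_grid:
        for wd in weight_decay_grid:
            sse, cnt = 0.0, 0
            for tr, te in splits:
                net = _make_mlp(h, wd, seed, max_iter)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net.fit(Xk[tr], yk[tr])
                pred = net.predict(Xk[te])
                sse += float(((pred - yk[te]) ** 2).sum())
                cnt += len(te)
            rmse = math.sqrt(sse / cnt)
            if best is None or rmse < best[0]:
                best = (rmse, h, wd)
    rmse, h, wd = best
    net = _make_mlp(h, wd, seed, max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(Xk, yk)
    W1 = np.abs(net.coefs_[0]).sum(axis=1)
    importance = pd.Series(W1, index=X.columns, name="importance")
    return SKModelResult(model=net, importance=importance, columns=list(X.columns),
                         tuning={"hidden": h, "weight_decay": wd, "cv_rmse": rmse})


def _make_mlp(hidden: int, weight_decay: float, seed, max_iter: int):
    return MLPRegressor(hidden_layer_sizes=(hidden,), alpha=weight_decay,
                        solver="lbfgs", max_iter=max_iter, random_state=seed)


# ---------------------------------------------------------------------------
# cross-validation, pooling, concordance


def crossvalidate(fit_fn, X: pd.DataFrame, y: pd.Series, scheme: str = "loocv",
                  k: int = 10, repeats: int = 1, seed=None) -> dict:
    """Confusion matrix and accuracy for a fit function under CV.

    ``fit_fn(X_train, y_train)`` must return an object with
    ``predict(X_test) -> Series``.  Continuous predictions are rounded to the
    nearest category (half-up toward higher threat) before tabulation.  Folds
    whose training part misses a class are reported in ``warnings``, never
    silently dropped.
    """
    known = y.notna()
    Xk, yk = X[known], y[known]
    idx = np.arange(len(yk))
    classes = sorted(set(int(v) for v in yk))
    if scheme == "loocv":
        folds = [(np.delete(idx, i), np.array([i])) for i in idx]
    elif scheme == "repeated_kfold":
        cv = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
        folds = list(cv.split(idx))
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")
    confusion = np.zeros((6, 6), dtype=int)
    dist_counts: dict = {}
    warn = []
    for f, (tr, te) in enumerate(folds):
        missing = set(classes) - set(int(v) for v in yk.iloc[tr])
        if missing:
            warn.append(f"fold {f}: class(es) {sorted(missing)} absent from training")
        model = fit_fn(Xk.iloc[tr], yk.iloc[tr])
        pred = model.predict(Xk.iloc[te])
        for true_v, p in zip(yk.iloc[te], np.asarray(pred, dtype=float)):
            pc = int(min(math.floor(min(max(p, 1.0), 6.0) + 0.5), 6))
            tc = int(true_v)
            confusion[tc - 1, pc - 1] += 1
            d = abs(pc - tc)
            dist_counts[d] = dist_counts.get(d, 0) + 1
    total = confusion.sum()
    acc = float(np.trace(confusion)) / total if total else float("nan")
    sens, spec = {}, {}
    for c in range(1, 7):
        tp = confusion[c - 1, c - 1]
        fn = confusion[c - 1].sum() - tp
        fp = confusion[:, c - 1].sum() - tp
        tn = total - tp - fn - fp
        sens[c] = tp / (tp + fn) if tp + fn else float("nan")
        spec[c] = tn / (tn + fp) if tn + fp else float("nan")
    return {"confusion": pd.DataFrame(confusion,
                                      index=[_CODE_TO_STATUS[c] for c in range(1, 7)],
                                      columns=[_CODE_TO_STATUS[c] for c in range(1, 7)]),
            "accuracy": acc, "sensitivity": sens, "specificity": spec,
            "error_distance_counts": dict(sorted(dist_counts.items())),
            "warnings": warn}


def pool_predictions(p_pglm, p_rf, p_ann):
    """Mean of the three clamped predictions on [1, 6] plus the category.

    Returns ``(pooled_mean, pooled_code)``; for Series inputs both are
    Series.  Ties at x.5 round up toward the more threatened class.
    """
    parts = [p_pglm, p_rf, p_ann]
    if any(p is None for p in parts):
        raise ValueError("all three model predictions are required")
    as_series = isinstance(p_pglm, pd.Series)
    arrs = [np.asarray(p, dtype=float) for p in parts]
    if any(np.any(~np.isfinite(a)) for a in arrs):
        raise ValueError("missing prediction")
    mean = np.mean([_clamp(a) for a in arrs], axis=0)
    code = np.minimum(np.floor(mean + 0.5), 6).astype(int)
    if as_series:
        return (pd.Series(mean, index=p_pglm.index),
                pd.Series(code, index=p_pglm.index))
    return mean, code


def concordance(categories: pd.DataFrame) -> dict:
    """Agreement statistics for per-model categorical predictions.

    ``categories`` has one column per model (3 expected) and one row per
    species.  Pairwise comparisons count the three unordered model pairs per
    species (3*S in total); "identical" means the same category and
    "adjacent" a one-category difference.
    """
    if categories.isna().any().any():
        raise ValueError("missing categories")
    M = categories.to_numpy(dtype=int)
    S, m = M.shape
    if m != 3:
        raise ValueError("expected exactly three model columns")
    pairs = [(0, 1), (0, 2), (1, 2)]
    ident = np.zeros(S, dtype=int)
    adjac = np.zeros(S, dtype=int)
    for a, b in pairs:
        d = np.abs(M[:, a] - M[:, b])
        ident += d == 0
        adjac += d == 1
    n_all = int((ident == 3).sum())
    n_two = int((ident == 1).sum())  # exactly one identical pair = 2 models agree
    total_pairs = 3 * S
    n_ident = int(ident.sum())
    n_adj = int(adjac.sum())
    return {
        "n_species": S,
        "n_all_identical": n_all,
        "n_two_agree": n_two,
        "total_pairwise": total_pairs,
        "pairwise_identical": n_ident,
        "pairwise_adjacent": n_adj,
        "pct_identical": 100.0 * n_ident / total_pairs,
        "pct_adjacent": 100.0 * n_adj / total_pairs,
        "pct_identical_or_adjacent": 100.0 * (n_ident + n_adj) / total_pairs,
    }


# ---------------------------------------------------------------------------
# ensemble driver


@dataclass
class ImputationResult:
    predictions: pd.DataFrame     # per-species continuous predictions + pooled
    pooled_codes: pd.Series
    importances: dict             # model -> Series
    models: dict
    concordance: dict
    cv: dict                      # model -> crossvalidate() output (if run)


def _exp_corr(D: np.ndarray, length_scale=None) -> np.ndarray:
    if length_scale is None:
        off = D[np.triu_indices_from(D, k=1)]
        length_scale = float(np.median(off)) if off.size else 1.0
    return np.exp(-D / max(length_scale, 1e-12))


def impute_ensemble(species_table: pd.DataFrame, tree, seed=None,
                    n_select: int = 15, run_cv: bool = False,
                    ann_kwargs=None) -> ImputationResult:
    """Fit the three-model ensemble and impute masked statuses.

    Species with a known category (EX included) form the training set; the
    DD/UA species are predicted by each model, clamped, pooled by the mean
    and rounded to a category.  Returns per-model predictions, variable
    importances, and the concordance summary over the imputed species.
    """
    rng_seed = None if seed is None else int(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31))
    y = species_table["status"].map(status_to_code)
    Xp, _ = build_design(species_table, tree, scheme="pglm")
    Xm, _ = build_design(species_table, tree, scheme="minmax")

    arr = to_arrays(tree) if not hasattr(tree, "clade_matrix") else tree
    order = [arr.labels.index(sp) for sp in species_table.index]
    C = vcv_matrix(arr)[np.ix_(order, order)]
    d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    phylo_corr = C / np.outer(d, d)
    cent = species_table[["centroid_x", "centroid_y"]].to_numpy(dtype=float)
    spatial_corr = _exp_corr(squareform(pdist(cent)))

    Xraw = _raw_design(species_table, tree)
    pglm = fit_pglm(Xp, y, phylo_corr, spatial_corr, n_select=n_select)
    rf = fit_rf(Xraw, y, seed=rng_seed)
    ann = fit_ann(Xm, y, seed=rng_seed, **(ann_kwargs or {}))

    missing = y.isna()
    preds = pd.DataFrame(index=species_table.index)
    preds["pglm"] = pglm.predict(Xp)
    preds["rf"] = rf.predict(Xraw)
    preds["ann"] = ann.predict(Xm)
    pooled_mean, pooled_code = pool_predictions(preds["pglm"], preds["rf"],
                                                preds["ann"])
    preds["pooled"] = pooled_mean
    cat = preds[missing].copy()
    per_model_codes = pd.DataFrame({
        m: np.minimum(np.floor(_clamp(cat[m]) + 0.5), 6).astype(int)
        for m in ("pglm", "rf", "ann")}, index=cat.index)
    conc = concordance(per_model_codes)
    cv = {}
    if run_cv:
        cv["pglm"] = crossvalidate(
            lambda Xtr, ytr: fit_pglm(Xtr, ytr,
                                      phylo_corr[np.ix_(_pos(y, Xtr.index), _pos(y, Xtr.index))],
                                      spatial_corr[np.ix_(_pos(y, Xtr.index), _pos(y, Xtr.index))],
                                      n_select=n_select),
            Xp, y, scheme="loocv")
    return ImputationResult(predictions=preds, pooled_codes=pooled_code[missing],
                            importances={"pglm": pglm.importance,
                                         "rf": rf.importance,
                                         "ann": ann.importance},
                            models={"pglm": pglm, "rf": rf, "ann": ann},
                            concordance=conc, cv=cv)


def _pos(y: pd.Series, idx) -> np.ndarray:
    lookup = {sp: i for i, sp in enumerate(y.index)}
    return np.array([lookup[sp] for sp in idx])


def _raw_design(species_table: pd.DataFrame, tree) -> pd.DataFrame:
    """Untransformed predictors (plus PCoA axes) for the random forest."""
    X = species_table[list(CONTINUOUS)].copy()
    for col in CATEGORICAL:
        for lev in sorted(species_table[col].unique()):
            X[f"{col}={lev}"] = (species_table[col] == lev).astype(float)
    Xp, _ = build_design(species_table, tree, scheme="pglm")
    for c in ("phy_pcoa1", "phy_pcoa2", "spa_pcoa1", "spa_pcoa2"):
        X[c] = Xp[c]
    return X
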