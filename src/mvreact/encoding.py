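"""Per-vertex feature-level encoding models.

Each model predicts one vertex's single-trial amplitude from the (up to)
100 layer features most positively correlated with it, with non-negative
lasso weights:

    v_it = h' f_lt + eps,   h >= 0

fitted by cyclic coordinate descent on 0.5*||v - F h||^2 + lambda*sum(h).
The penalty is chosen per vertex from 5 log-spaced values in [1e-4, 1] by
held-out sum of squared errors, under 3-fold cross-validation over the
encoded images; movie-viewing samples join the training rows of every
fold so that predictions for an image never see that image's encoding
trials.  The non-negativity constraint discourages complex signed
combinations of low-level features from mimicking high-level ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .features import assign_level

__all__ = [
    "NnlassoConvergenceError",
    "EncodingModel",
    "FoldPlan",
    "make_fold_plan",
    "default_lambda_grid",
    "select_features",
    "fit_nnlasso",
    "select_lambda",
    "fit_vertex_model",
    "fit_encoding_models",
    "predict_patterns",
]


class NnlassoConvergenceError(RuntimeError):
    pass


def default_lambda_grid(n: int = 5, lo: float = 1e-4, hi: float = 1.0) -> np.ndarray:
    """Geometrically spaced penalty grid, 1e-4 .. 1 by default."""
    return np.geomspace(lo, hi, n)


def select_features(F: np.ndarray, v: np.ndarray, k: int = 100) -> np.ndarray:
    """Indices of up to *k* features most positively correlated with *v*.

    Zero-variance columns (or a zero-variance target) are excluded; only
    strictly positive Pearson correlations qualify, so the selection may
    be smaller than *k* or empty.  Indices come back ordered by
    decreasing correlation.
    """
    F = np.asarray(F, dtype=float)
    v = np.asarray(v, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("need at least 3 samples to correlate")
    vc = v - v.mean()
    v_sd = np.sqrt(vc @ vc)
    if v_sd == 0:
        return np.array([], dtype=int)
    Fc = F - F.mean(axis=0)
    col_sd = np.sqrt(np.einsum("ij,ij->j", Fc, Fc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Fc.T @ vc) / (col_sd * v_sd)
    r[col_sd == 0] = np.nan
    pos = np.flatnonzero(r > 0)
    if len(pos) == 0:
        return np.array([], dtype=int)
    order = pos[np.argsort(-r[pos], kind="stable")]
    return order[:k]


def fit_nnlasso(F: np.ndarray, v: np.ndarray, lam: float, tol: float = 1e-6,
                max_iter: int = 10_000, h0: np.ndarray | None = None) -> np.ndarray:
    """Non-negative lasso by cyclic coordinate descent.

    Minimizes ``0.5*||v - F h||^2 + lam*sum(h)`` subject to ``h >= 0``.
    Each coordinate update is the one-dimensional minimizer
    ``h_j = max(0, (F_j . r_j - lam) / ||F_j||^2)`` with an incrementally
    maintained residual.  Converges when the largest single-sweep weight
    change drops below *tol*; raises with diagnostics otherwise.
    """
    F = np.asarray(F, dtype=float)
    v = np.asarray(v, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, p = F.shape
    col_sq = np.einsum("ij,ij->j", F, F)
    h = np.zeros(p) if h0 is None else np.array(h0, dtype=float)
    r = v - F @ h
    prev_obj = 0.5 * float(r @ r) + lam * float(h.sum())
    prev_delta = np.inf
    for sweep in range(max_iter):
        h_start = h.copy()
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] == 0.0:
                continue
            hj = h[j]
            rho = F[:, j] @ r + col_sq[j] * hj
            new = max(0.0, (rho - lam) / col_sq[j])
            if new != hj:
                r += F[:, j] * (hj - new)
                h[j] = new
                max_delta = max(max_delta, abs(new - hj))
        if max_delta < tol * max(1.0, float(np.abs(h).max(initial=0.0))):
            return h
        obj = 0.5 * float(r @ r) + lam * float(h.sum())
        if prev_obj - obj < 1e-11 * (1.0 + abs(obj)):
            # flat face of a singular design: current point is optimal
            return h
        if max_delta > 0.9 * prev_delta:
            # barely-contracting sweeps on a rank-deficient design mean the
            # weights are drifting along a null direction of F (objective
            # falls linearly via the penalty); jump straight to the boundary
            d = h - h_start
            Fd = F @ d
            if float(Fd @ Fd) <= 1e-16 * float(d @ d) * max(col_sq.max(), 1.0):
                neg = d < 0
                if neg.any() and lam * d.sum() < 0:
                    t = float(np.min(h[neg] / -d[neg]))
                    h = np.maximum(0.0, h + t * d)
                    r = v - F @ h
                return h
        prev_delta = max_delta
        prev_obj = obj
    raise NnlassoConvergenceError(
        f"non-negative lasso did not converge in {max_iter} sweeps "
        f"(n={n}, p={p}, lambda={lam:g}, last max |dh|={max_delta:.3e})"
    )


def nnlasso_objective(F: np.ndarray, v: np.ndarray, h: np.ndarray,
                      lam: float) -> float:
    r = v - F @ h
    return 0.5 * float(r @ r) + lam * float(np.sum(h))


def select_lambda(F_train: np.ndarray, v_train: np.ndarray,
                  F_val: np.ndarray, v_val: np.ndarray,
                  grid: np.ndarray | None = None,
                  **fit_kw) -> tuple[float, np.ndarray]:
    """Pick the penalty with the smallest held-out SSE (ties -> smaller lambda).

    Returns ``(lambda, sse_per_grid_point)`` with the grid sorted ascending.
    """
    grid = default_lambda_grid() if grid is None else np.sort(np.asarray(grid, float))
    if grid.size == 0:
        raise ValueError("lambda grid must be non-empty")
    sse = np.empty(len(grid))
    h = None
    for i, lam in enumerate(grid[::-1]):  # warm-start from strongest penalty
        h = fit_nnlasso(F_train, v_train, lam, h0=h, **fit_kw)
        resid = v_val - F_val @ h
        sse[len(grid) - 1 - i] = resid @ resid
    best = int(np.argmin(sse))  # argmin takes the first (smallest) lambda on ties
    return float(grid[best]), sse


@dataclass
class EncodingModel:
    """Fitted per-vertex model for one layer and cross-validation fold."""

    vertex_id: int
    layer_id: int
    fold_id: int
    selected_features: np.ndarray
    weights: np.ndarray
    lambda_: float
    cv_sse: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_mean: np.ndarray = field(default_factory=lambda: np.array([]))
    feature_scale: np.ndarray = field(default_factory=lambda: np.array([]))
    target_mean: float = 0.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.selected_features = np.asarray(self.selected_features, dtype=int)
        if np.any(self.weights < 0):
            raise ValueError("encoding weights must be non-negative")
        if len(self.weights) != len(self.selected_features):
            raise ValueError("weights misaligned with selected features")

    @property
    def level(self) -> str:
        return assign_level(self.layer_id)

    def predict(self, F: np.ndarray) -> np.ndarray:
        """Predict vertex amplitude for rows of raw layer features."""
        F = np.atleast_2d(np.asarray(F, dtype=float))
        if self.selected_features.size == 0:
            return np.full(F.shape[0], self.target_mean)
        Fs = F[:, self.selected_features]
        if self.feature_mean.size:
            Fs = (Fs - self.feature_mean) / self.feature_scale
        return self.target_mean + Fs @ self.weights


@dataclass
class FoldPlan:
    """Assignment of images to cross-validation folds.

    Every image is held out in exactly one fold; movie samples belong to
    the training rows of all folds.
    """

    image_ids: list
    fold_of: dict
    n_folds: int = 3

    def held_out(self, fold: int) -> list:
        return [i for i in self.image_ids if self.fold_of[i] == fold]

    def training_images(self, fold: int) -> list:
        return [i for i in self.image_ids if self.fold_of[i] != fold]

    def fold_for_image(self, image_id) -> int:
        try:
            return self.fold_of[image_id]
        except KeyError:
            raise KeyError(f"image {image_id!r} missing from fold plan")


def make_fold_plan(image_ids, n_folds: int = 3,
                   rng: np.random.Generator | None = None) -> FoldPlan:
    """Randomly partition images into near-equal folds (deterministic given rng)."""
    ids = list(image_ids)
    order = np.arange(len(ids))
    if rng is not None:
        rng.shuffle(order)
    folds = {ids[j]: int(i % n_folds) for i, j in enumerate(order)}
    return FoldPlan(image_ids=ids, fold_of=folds, n_folds=n_folds)


def _standardize_train(F: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = F.mean(axis=0)
    s = F.std(axis=0)
    s[s == 0] = 1.0
    return (F - m) / s, m, s


def fit_vertex_model(F: np.ndarray, v: np.ndarray, val_rows: np.ndarray,
                     vertex_id: int = 0, layer_id: int = 1, fold_id: int = 0,
                     k: int = 100, grid: np.ndarray | None = None,
                     standardize: bool = True, tol: float = 1e-6) -> EncodingModel:
    """Full per-vertex fit: select features, tune lambda on *val_rows*, refit.

    *F*, *v* contain both training and validation rows; ``val_rows`` is a
    boolean mask of the held-out rows used only for lambda selection.
    """
    val_rows = np.asarray(val_rows, dtype=bool)
    tr = ~val_rows
    sel = select_features(F[tr], v[tr], k=k)
    grid = default_lambda_grid() if grid is None else np.asarray(grid, float)
    if sel.size == 0:
        return EncodingModel(vertex_id, layer_id, fold_id, sel, np.array([]),
                             float(grid[-1]), target_mean=float(v[tr].mean()))
    Fs = F[:, sel]
    # features are always centered on the training rows (the centered target
    # is otherwise unreachable under the non-negativity constraint);
    # `standardize` additionally scales them to unit variance
    m = Fs[tr].mean(axis=0)
    if standardize:
        s = Fs[tr].std(axis=0)
        s[s == 0] = 1.0
    else:
        s = np.ones(sel.size)
    Ftr = (Fs[tr] - m) / s
    Fval = (Fs[val_rows] - m) / s
    v_mean = float(v[tr].mean())
    vtr = v[tr] - v_mean
    vval = v[val_rows] - v_mean
    if len(vval):
        lam, sse = select_lambda(Ftr, vtr, Fval, vval, grid=grid, tol=tol)
    else:
        lam, sse = float(grid[0]), np.full(len(grid), np.nan)
    h = fit_nnlasso(Ftr, vtr, lam, tol=tol)
    return EncodingModel(vertex_id, layer_id, fold_id, sel, h, lam, cv_sse=sse,
                         feature_mean=m, feature_scale=s, target_mean=v_mean)


def fit_encoding_models(layer_features: dict[int, np.ndarray],
                        feature_image_ids: list,
                        enc_betas: np.ndarray, enc_trial_images: list,
                        fold_plan: FoldPlan,
                        movie_features: dict[int, np.ndarray] | None = None,
                        movie_activity: np.ndarray | None = None,
                        k: int = 100, grid: np.ndarray | None = None,
                        standardize: bool = True,
                        ) -> dict[int, dict[int, list[EncodingModel]]]:
    """Fit models for every layer x fold x vertex of one ROI.

    ``layer_features[layer]`` is an images x features matrix aligned to
    ``feature_image_ids``; encoding trials map to feature rows through
    ``enc_trial_images``.  Movie samples (features + activity) are
    appended to the training rows of every fold.  Feature selection and
    lambda tuning happen inside each fold, on training rows only.

    Returns ``models[layer][fold] = [EncodingModel per vertex]``.
    """
    row_of_image = {img: i for i, img in enumerate(feature_image_ids)}
    trial_rows = np.array([row_of_image[i] for i in enc_trial_images])
    enc_betas = np.asarray(enc_betas, dtype=float)
    n_vertices = enc_betas.shape[1]
    have_movie = movie_features is not None and movie_activity is not None
    out: dict[int, dict[int, list[EncodingModel]]] = {}
    for layer, feats in layer_features.items():
        F_trials = np.asarray(feats, float)[trial_rows]
        out[layer] = {}
        for fold in range(fold_plan.n_folds):
            held = set(fold_plan.held_out(fold))
            val_mask = np.array([img in held for img in enc_trial_images])
            if have_movie:
                F_all = np.vstack([F_trials, movie_features[layer]])
                val_all = np.concatenate(
                    [val_mask, np.zeros(len(movie_features[layer]), bool)])
            else:
                F_all, val_all = F_trials, val_mask
            fold_models = []
            for vx in range(n_vertices):
                v_all = enc_betas[:, vx]
                if have_movie:
                    v_all = np.concatenate([v_all, movie_activity[:, vx]])
                fold_models.append(fit_vertex_model(
                    F_all, v_all, val_all, vertex_id=vx, layer_id=layer,
                    fold_id=fold, k=k, grid=grid, standardize=standardize))
            out[layer][fold] = fold_models
    return out


def predict_patterns(models: dict[int, dict[int, list[EncodingModel]]],
                     layer_features: dict[int, np.ndarray],
                     feature_image_ids: list,
                     fold_plan: FoldPlan) -> dict[int, np.ndarray]:
    """Cross-validated predicted patterns: images x vertices per layer.

    The prediction for image *i* comes from the fold in which *i* was held
    out, so its own encoding trials never touched the weights that
    generate its predicted pattern.
    """
    row_of_image = {img: i for i, img in enumerate(feature_image_ids)}
    out = {}
    for layer, per_fold in models.items():
        feats = np.asarray(layer_features[layer], float)
        n_vertices = len(next(iter(per_fold.values())))
        pred = np.empty((len(fold_plan.image_ids), n_vertices))
        for i, img in enumerate(fold_plan.image_ids):
            fold = fold_plan.fold_for_image(img)
            f_row = feats[row_of_image[img]][None, :]
            for vx, model in enumerate(per_fold[fold]):
                pred[i, vx] = model.predict(f_row)[0]
        out[layer] = pred
    return out
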