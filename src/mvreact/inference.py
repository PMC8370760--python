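"""Mixed-model inference relating recognition accuracy to reactivation.

Four model families are supported, all mirroring the study design:

* ``featureHC`` — trial accuracy ~ 8 residualized hippocampal
  reactivation measures (aHC/pHC x 4 levels) + their interactions with
  subject mean lure accuracy + probe type, with crossed random
  intercepts for subject and image pair (binomial family);
* ``imageHC`` — the image-specific variant (2 reactivation measures);
* ``calcarineInteraction`` — adds calcarine low-level reactivation, its
  two-way interactions with the 8 hippocampal measures and with lure
  accuracy, and the 8 three-way terms;
* ``betweenSubject`` — a subject-level OLS of mean lure accuracy on the
  8 subject-mean reactivation values over correct trials.

Fitting uses a Laplace approximation: penalized IRLS over the joint
(fixed, random) coefficients inside, and the approximate profile
likelihood of the two variance components outside.  When the variance
components collapse to zero the fit falls back to a plain fixed-effects
logistic regression (statsmodels), with a warning.  Uncertainty comes
from bootstrap draws — parametric (simulate responses from the fitted
model, refit) within subject, or resampling subjects between subject —
summarized as 90% percentile CIs and tail-count p-values with a 1/B
floor.  FDR correction is Benjamini-Hochberg within a declared family,
with prioritized terms passed through unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .features import LEVEL_ORDER

__all__ = [
    "ModelSpec",
    "GlmmFit",
    "feature_hc_spec",
    "image_hc_spec",
    "calcarine_spec",
    "attach_lure_accuracy",
    "fit_glmm",
    "bootstrap_inference",
    "pvalue_from_draws",
    "ci_from_draws",
    "paired_difference",
    "simple_slopes",
    "level_average",
    "fdr_correct",
    "between_subject_model",
]

HC_MEASURES = tuple(f"{roi}_{lvl}" for roi in ("ahc", "phc") for lvl in LEVEL_ORDER)

_VAR_FLOOR = 1e-4  # variance components below this count as collapsed


# ---------------------------------------------------------------- model specs

@dataclass
class ModelSpec:
    """Fixed-effect term plan for a binomial mixed model.

    ``measures`` are trial-level reactivation columns; each enters as a
    main effect and in interaction with the (standardized) subject-level
    moderator.  ``calcarine`` optionally adds a cortical measure with
    two-way and three-way interaction terms.  Random intercepts: subject
    and image pair.
    """

    name: str
    measures: tuple[str, ...]
    moderator: str = "lure_acc"
    probe: str = "is_lure"
    calcarine: str | None = None
    response: str = "accuracy"
    family: str = "binomial"

    def term_names(self) -> list[str]:
        terms = ["intercept", *self.measures]
        if self.calcarine:
            terms.append(self.calcarine)
            terms += [f"{m}:{self.calcarine}" for m in self.measures]
            terms += [f"{m}:{self.moderator}" for m in self.measures]
            terms.append(f"{self.calcarine}:{self.moderator}")
            terms += [f"{m}:{self.calcarine}:{self.moderator}" for m in self.measures]
        else:
            terms += [f"{m}:{self.moderator}" for m in self.measures]
        terms.append(self.probe)
        return terms

    def design(self, data: pd.DataFrame) -> pd.DataFrame:
        """Build the fixed-effects design matrix (intercept first)."""
        cols = {"intercept": np.ones(len(data))}
        for m in self.measures:
            cols[m] = data[m].to_numpy(float)
        mod = data[self.moderator].to_numpy(float)
        if self.calcarine:
            cal = data[self.calcarine].to_numpy(float)
            cols[self.calcarine] = cal
            for m in self.measures:
                cols[f"{m}:{self.calcarine}"] = cols[m] * cal
            for m in self.measures:
                cols[f"{m}:{self.moderator}"] = cols[m] * mod
            cols[f"{self.calcarine}:{self.moderator}"] = cal * mod
            for m in self.measures:
                cols[f"{m}:{self.calcarine}:{self.moderator}"] = cols[m] * cal * mod
        else:
            for m in self.measures:
                cols[f"{m}:{self.moderator}"] = cols[m] * mod
        cols[self.probe] = data[self.probe].to_numpy(float)
        return pd.DataFrame(cols, index=data.index)


def feature_hc_spec() -> ModelSpec:
    return ModelSpec(name="featureHC", measures=HC_MEASURES)


def image_hc_spec() -> ModelSpec:
    return ModelSpec(name="imageHC",
                     measures=("ahc_image_specific", "phc_image_specific"))


def calcarine_spec() -> ModelSpec:
    return ModelSpec(name="calcarineInteraction", measures=HC_MEASURES,
                     calcarine="calcarine_low")


def attach_lure_accuracy(trials: pd.DataFrame, standardize: bool = True,
                         ) -> tuple[pd.DataFrame, float, float]:
    """Add each subject's mean lure accuracy as a trial-level moderator column.

    Returns ``(trials, mean, sd)`` where mean/sd are the across-subject
    anchors of the raw proportion (used to report +/-1 SD simple slopes
    on the accuracy scale).  The column is standardized by default.
    """
    lure = trials[trials["is_lure"] == 1]
    per_subj = lure.groupby("subject")["accuracy"].mean()
    mu, sd = float(per_subj.mean()), float(per_subj.std(ddof=0))
    vals = trials["subject"].map(per_subj).astype(float)
    if standardize:
        vals = (vals - mu) / (sd if sd > 0 else 1.0)
    out = trials.copy()
    out["lure_acc"] = vals
    return out, mu, sd


# ------------------------------------------------------------- Laplace GLMM

def _random_design(labels: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels))
    idx = {g: i for i, g in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    Z[np.arange(len(labels)), [idx[g] for g in labels]] = 1.0
    return Z, levels


def _pirls(X: np.ndarray, Z: np.ndarray, y: np.ndarray, dvec: np.ndarray,
           gamma0: np.ndarray | None = None, max_iter: int = 100,
           tol: float = 1e-9, ridge: float = 0.0):
    """Penalized IRLS for the joint (beta, u) mode at fixed variances.

    Maximizes the Bernoulli log-likelihood minus ``0.5 * u' D^-1 u``
    (plus an optional small ridge on beta for separation fallback).
    Returns ``(gamma, H, penalized_ll)``.
    """
    n, p = X.shape
    q = Z.shape[1]
    M = np.hstack([X, Z])
    pen = np.concatenate([np.full(p, ridge), 1.0 / dvec])
    gamma = np.zeros(p + q) if gamma0 is None else gamma0.copy()

    def pll(g):
        eta = M @ g
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * (pen * g * g).sum())

    cur = pll(gamma)
    H = None
    for _ in range(max_iter):
        eta = M @ gamma
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = M.T @ (y - mu) - pen * gamma
        H = (M.T * w) @ M
        H[np.diag_indices_from(H)] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8
            step = np.linalg.solve(H, grad)
        t = 1.0
        for _ in range(30):
            new = pll(gamma + t * step)
            if new >= cur - 1e-12:
                break
            t *= 0.5
        gamma = gamma + t * step
        moved = np.max(np.abs(t * step))
        cur = pll(gamma)
        if moved < tol:
            break
    return gamma, H, cur


def _laplace_loglik(theta_log: np.ndarray, X, Z, y, q_subj, warm: dict) -> float:
    s2 = np.exp(theta_log)
    q = Z.shape[1]
    dvec = np.concatenate([np.full(q_subj, s2[0]), np.full(q - q_subj, s2[1])])
    gamma, H, pen_ll = _pirls(X, Z, y, dvec, gamma0=warm.get("gamma"))
    warm["gamma"] = gamma
    p = X.shape[1]
    Huu = H[p:, p:]
    sign, logdet = np.linalg.slogdet(Huu)
    if sign <= 0:
        return -np.inf
    return pen_ll - 0.5 * np.sum(np.log(dvec)) - 0.5 * logdet


@dataclass
class GlmmFit:
    """A fitted model plus (optionally) its bootstrap draws."""

    spec: ModelSpec
    coefficients: pd.Series
    var_subject: float = 0.0
    var_pair: float = 0.0
    method: str = "laplace"
    B: int = 0
    draws: pd.DataFrame | None = None
    n_failed: int = 0
    # private plumbing for simulation / refits
    _X: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)
    _Z: np.ndarray | None = field(default=None, repr=False)
    _q_subj: int = 0
    _u: np.ndarray | None = field(default=None, repr=False)
    _subject_of_row: np.ndarray | None = field(default=None, repr=False)

    @property
    def terms(self) -> list[str]:
        return list(self.coefficients.index)

    def ci(self, level: float = 0.90) -> pd.DataFrame:
        if self.draws is None:
            raise ValueError("run bootstrap_inference first")
        return ci_from_draws(self.draws, level)

    def pvalues(self, tail: str = "two") -> pd.Series:
        if self.draws is None:
            raise ValueError("run bootstrap_inference first")
        return self.draws.apply(lambda c: pvalue_from_draws(c.to_numpy(), tail=tail))


def fit_glmm(spec: ModelSpec, data: pd.DataFrame,
             subject_col: str = "subject", pair_col: str = "pair",
             force_fixed: bool = False) -> GlmmFit:
    """Fit the binomial mixed model with crossed subject/pair intercepts.

    Laplace-approximate ML over the two variance components; if both
    collapse to (near) zero the model reduces to a fixed-effects logistic
    regression and is refitted as such with a warning.  Coefficient
    vectors showing signs of separation trigger a lightly ridged refit.
    ``force_fixed`` pins both variance components at zero, making the fit
    a plain logistic regression (useful as a contract check).
    """
    from scipy.optimize import minimize

    Xdf = spec.design(data)
    X = Xdf.to_numpy(float)
    y = data[spec.response].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")
    Z_s, subj_levels = _random_design(data[subject_col])
    Z_p, _ = _random_design(data[pair_col])
    Z = np.hstack([Z_s, Z_p])
    q_subj = Z_s.shape[1]
    subj_rows_fixed = np.argmax(Z_s, axis=1)
    if force_fixed:
        beta = _fixed_logit(X, y)
        return GlmmFit(spec, pd.Series(beta, index=Xdf.columns),
                       var_subject=0.0, var_pair=0.0, method="logit_fallback",
                       _X=X, _y=y, _Z=Z, _q_subj=q_subj,
                       _u=np.zeros(Z.shape[1]),
                       _subject_of_row=subj_rows_fixed)
    warm: dict = {}
    res = minimize(lambda th: -_laplace_loglik(th, X, Z, y, q_subj, warm),
                   x0=np.log([0.1, 0.1]), method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 200})
    s2 = np.exp(res.x)
    subj_rows = np.argmax(Z_s, axis=1)
    if max(s2) < _VAR_FLOOR:
        warnings.warn("variance components collapsed to 0; "
                      "falling back to fixed-effects logistic regression",
                      RuntimeWarning, stacklevel=2)
        beta = _fixed_logit(X, y)
        return GlmmFit(spec, pd.Series(beta, index=Xdf.columns),
                       var_subject=0.0, var_pair=0.0, method="logit_fallback",
                       _X=X, _y=y, _Z=Z, _q_subj=q_subj,
                       _u=np.zeros(Z.shape[1]), _subject_of_row=subj_rows)
    dvec = np.concatenate([np.full(q_subj, max(s2[0], 1e-8)),
                           np.full(Z.shape[1] - q_subj, max(s2[1], 1e-8))])
    gamma, _, _ = _pirls(X, Z, y, dvec, gamma0=warm.get("gamma"))
    p = X.shape[1]
    beta, u = gamma[:p], gamma[p:]
    if np.max(np.abs(beta)) > 15:
        warnings.warn("possible separation (|beta| > 15); refitting with a "
                      "small ridge penalty", RuntimeWarning, stacklevel=2)
        gamma, _, _ = _pirls(X, Z, y, dvec, ridge=1e-2)
        beta, u = gamma[:p], gamma[p:]
    return GlmmFit(spec, pd.Series(beta, index=Xdf.columns),
                   var_subject=float(s2[0]), var_pair=float(s2[1]),
                   method="laplace", _X=X, _y=y, _Z=Z, _q_subj=q_subj, _u=u,
                   _subject_of_row=subj_rows)


def _fixed_logit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = np.asarray(fit.params)
            if np.max(np.abs(beta)) <= 15 and np.all(np.isfinite(beta)):
                return beta
        except Exception:
            pass
        # separation or failure: lightly ridged IRLS
        gamma, _, _ = _pirls(X, np.zeros((len(y), 0)), y, np.ones(0), ridge=1e-2)
        return gamma[: X.shape[1]]


# ---------------------------------------------------------------- bootstrap

def _refit_beta(fit: GlmmFit, y_star: np.ndarray) -> np.ndarray:
    """Refit the coefficient vector for a bootstrap response.

    Variance components stay fixed at their point estimates (conditional
    parametric bootstrap); collapsed fits refit as plain logistic.
    """
    X, Z = fit._X, fit._Z
    if fit.method == "logit_fallback":
        return _fixed_logit(X, y_star)
    q = Z.shape[1]
    dvec = np.concatenate([
        np.full(fit._q_subj, max(fit.var_subject, 1e-8)),
        np.full(q - fit._q_subj, max(fit.var_pair, 1e-8)),
    ])
    gamma0 = np.concatenate([fit.coefficients.to_numpy(), fit._u])
    gamma, _, _ = _pirls(X, Z, y_star, dvec, gamma0=gamma0)
    return gamma[: X.shape[1]]


def bootstrap_inference(fit: GlmmFit, B: int = 1000, scheme: str = "parametric",
                        rng: np.random.Generator | None = None,
                        max_fail_frac: float = 0.10) -> GlmmFit:
    """Attach B bootstrap coefficient draws to a fitted model.

    ``parametric``: simulate binary responses from the fitted model
    (fixed effects + fresh random-intercept draws at the estimated
    variances), refit, and collect the coefficients — the within-subject
    scheme.  ``subjects``: resample whole subjects with replacement and
    refit — the between-subject scheme.  Raises if more than
    ``max_fail_frac`` of the refits fail.
    """
    rng = np.random.default_rng() if rng is None else rng
    X, Z, y = fit._X, fit._Z, fit._y
    beta = fit.coefficients.to_numpy()
    draws = np.empty((B, len(beta)))
    n_failed = 0
    if scheme == "parametric":
        sd_vec = np.concatenate([
            np.full(fit._q_subj, np.sqrt(fit.var_subject)),
            np.full(Z.shape[1] - fit._q_subj, np.sqrt(fit.var_pair)),
        ])
        eta_fixed = X @ beta
        for b in range(B):
            u_star = rng.normal(0.0, sd_vec)
            p_star = expit(eta_fixed + Z @ u_star)
            y_star = (rng.random(len(y)) < p_star).astype(float)
            try:
                draws[b] = _refit_beta(fit, y_star)
            except Exception:
                draws[b] = np.nan
                n_failed += 1
    elif scheme == "subjects":
        subj = fit._subject_of_row
        subjects = np.unique(subj)
        rows_of = {s: np.flatnonzero(subj == s) for s in subjects}
        for b in range(B):
            pick = rng.choice(subjects, size=len(subjects), replace=True)
            rows = np.concatenate([rows_of[s] for s in pick])
            try:
                if fit.method == "logit_fallback":
                    draws[b] = _fixed_logit(X[rows], y[rows])
                else:
                    # rebuild subject indicators so resampled copies stay distinct
                    Zs = np.zeros((len(rows), len(pick)))
                    off = 0
                    for k, s in enumerate(pick):
                        m = len(rows_of[s])
                        Zs[off:off + m, k] = 1.0
                        off += m
                    Zp = Z[rows, fit._q_subj:]
                    dvec = np.concatenate([
                        np.full(len(pick), max(fit.var_subject, 1e-8)),
                        np.full(Zp.shape[1], max(fit.var_pair, 1e-8)),
                    ])
                    gamma, _, _ = _pirls(X[rows], np.hstack([Zs, Zp]), y[rows], dvec)
                    draws[b] = gamma[: X.shape[1]]
            except Exception:
                draws[b] = np.nan
                n_failed += 1
    else:
        raise ValueError(f"unknown bootstrap scheme {scheme!r}")
    if n_failed > max_fail_frac * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap refits failed")
    fit.draws = pd.DataFrame(draws, columns=fit.terms).dropna()
    fit.B = B
    fit.n_failed = n_failed
    return fit


def pvalue_from_draws(draws: np.ndarray, null: float = 0.0,
                      tail: str = "two") -> float:
    """Tail-count bootstrap p-value with a 1/B floor.

    ``greater`` tests beta > null (p = fraction of draws <= null);
    ``less`` the reverse; ``two`` doubles the smaller tail.
    """
    draws = np.asarray(draws, dtype=float)
    B = len(draws)
    lo = np.mean(draws <= null)
    hi = np.mean(draws >= null)
    if tail == "greater":
        p = lo
    elif tail == "less":
        p = hi
    elif tail == "two":
        p = 2.0 * min(lo, hi)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(min(1.0, max(p, 1.0 / B)))


def ci_from_draws(draws: pd.DataFrame, level: float = 0.90) -> pd.DataFrame:
    alpha = (1.0 - level) / 2.0
    lo = draws.quantile(alpha)
    hi = draws.quantile(1.0 - alpha)
    return pd.DataFrame({"lower": lo, "upper": hi})


def paired_difference(fit: GlmmFit, term_a: str, term_b: str,
                      tail: str = "greater") -> tuple[np.ndarray, float]:
    """Per-draw difference beta_a - beta_b and its tail-count p-value."""
    if fit.draws is None:
        raise ValueError("run bootstrap_inference first")
    for t in (term_a, term_b):
        if t not in fit.draws.columns:
            raise KeyError(f"term {t!r} not in fit")
    diff = (fit.draws[term_a] - fit.draws[term_b]).to_numpy()
    if term_a == term_b:
        return diff, 1.0
    return diff, pvalue_from_draws(diff, tail=tail)


def simple_slopes(fit: GlmmFit, terms: list[str] | None = None,
                  moderator: str = "lure_acc",
                  at: tuple[float, ...] = (-1.0, 1.0),
                  level: float = 0.90) -> pd.DataFrame:
    """Conditional slopes beta_main + beta_interaction * m at moderator values.

    With the moderator standardized, ``at=(-1, 1)`` evaluates the slopes
    one SD below and above the mean.  Draw-wise slopes give bootstrap CIs
    and two-tailed p-values.
    """
    coefs = fit.coefficients
    if terms is None:
        terms = [t for t in fit.terms
                 if f"{t}:{moderator}" in coefs.index and ":" not in t]
    rows = []
    for t in terms:
        it = f"{t}:{moderator}"
        if it not in coefs.index:
            raise KeyError(f"no interaction term {it!r} in model")
        for m in at:
            est = coefs[t] + coefs[it] * m
            row = {"term": t, "moderator_value": m, "slope": est}
            if fit.draws is not None:
                d = (fit.draws[t] + fit.draws[it] * m).to_numpy()
                alpha = (1 - level) / 2
                row["lower"] = float(np.quantile(d, alpha))
                row["upper"] = float(np.quantile(d, 1 - alpha))
                row["p_two"] = pvalue_from_draws(d, tail="two")
                row["p_greater"] = pvalue_from_draws(d, tail="greater")
            rows.append(row)
    return pd.DataFrame(rows)


def level_average(fit: GlmmFit, roi: str, moderator: str | None = "lure_acc",
                  level: float = 0.90) -> dict:
    """Average a ROI's four feature-level coefficients (draw-wise).

    With ``moderator`` set, averages the ROI's four interaction terms;
    with ``moderator=None``, the four main effects.
    """
    if moderator:
        terms = [f"{roi}_{lvl}:{moderator}" for lvl in LEVEL_ORDER]
    else:
        terms = [f"{roi}_{lvl}" for lvl in LEVEL_ORDER]
    missing = [t for t in terms if t not in fit.coefficients.index]
    if missing:
        raise KeyError(f"missing level terms {missing}")
    out = {"terms": terms,
           "estimate": float(fit.coefficients[terms].mean())}
    if fit.draws is not None:
        d = fit.draws[terms].mean(axis=1).to_numpy()
        alpha = (1 - level) / 2
        out["draws"] = d
        out["lower"] = float(np.quantile(d, alpha))
        out["upper"] = float(np.quantile(d, 1 - alpha))
        out["p_greater"] = pvalue_from_draws(d, tail="greater")
        out["p_two"] = pvalue_from_draws(d, tail="two")
    return out


def fdr_correct(pvals: pd.Series, family: list[str],
                exclude: tuple[str, ...] = ()) -> pd.Series:
    """Benjamini-Hochberg within *family*; excluded/other terms pass through.

    Terms in ``exclude`` (e.g. the prioritized low-level features) keep
    their raw p-values.
    """
    if any((p < 0) or (p > 1) for p in pvals):
        raise ValueError("p-values must lie in [0, 1]")
    fam = [t for t in family if t not in exclude]
    if not fam:
        raise ValueError("FDR family is empty")
    out = pvals.copy().astype(float)
    _, adj, _, _ = multipletests(pvals[fam].to_numpy(), method="fdr_bh")
    out[fam] = adj
    return out


# --------------------------------------------------- between-subject model

@dataclass
class BetweenSubjectFit:
    coefficients: pd.Series
    draws: pd.DataFrame
    subject_means: pd.DataFrame
    B: int

    def ci(self, level: float = 0.90) -> pd.DataFrame:
        return ci_from_draws(self.draws, level)

    def pvalues(self, tail: str = "two") -> pd.Series:
        return self.draws.apply(lambda c: pvalue_from_draws(c.to_numpy(), tail=tail))


def between_subject_model(trials: pd.DataFrame,
                          measures: tuple[str, ...] = HC_MEASURES,
                          B: int = 1000,
                          rng: np.random.Generator | None = None,
                          ) -> BetweenSubjectFit:
    """OLS of subject mean lure accuracy on subject-mean reactivation.

    Reactivation means use correct trials only (successful recall);
    subjects with no correct trials are dropped with a warning.  CIs and
    p-values come from resampling subjects with replacement.
    """
    rng = np.random.default_rng() if rng is None else rng
    rows = []
    for s, g in trials.groupby("subject"):
        correct = g[g["accuracy"] == 1]
        if len(correct) == 0:
            warnings.warn(f"subject {s!r} has no correct trials; excluded",
                          RuntimeWarning, stacklevel=2)
            continue
        lure = g[g["is_lure"] == 1]
        row = {"subject": s, "lure_acc": lure["accuracy"].mean()}
        for m in measures:
            row[m] = correct[m].mean()
        rows.append(row)
    sub = pd.DataFrame(rows)
    if len(sub) <= len(measures) + 1:
        raise ValueError("too few subjects for the between-subject model")
    names = ["intercept", *measures]

    def _ols(tab: pd.DataFrame) -> np.ndarray:
        X = np.column_stack([np.ones(len(tab)), tab[list(measures)].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, tab["lure_acc"].to_numpy(float), rcond=None)
        return beta

    beta = _ols(sub)
    draws = np.empty((B, len(names)))
    for b in range(B):
        pick = rng.integers(0, len(sub), size=len(sub))
        draws[b] = _ols(sub.iloc[pick])
    return BetweenSubjectFit(pd.Series(beta, index=names),
                             pd.DataFrame(draws, columns=names), sub, B)
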