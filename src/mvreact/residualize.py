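"""Removing variance shared between feature levels and between aHC and pHC.

Trial-by-trial reactivation scores are correlated across feature levels
and across the hippocampal long axis.  To isolate each measure's unique
contribution, every within-subject analysis replaces the raw score with
the residuals of an OLS regression on the shared components:

* hippocampal level-specific target: 3 same-ROI non-target levels plus
  all 4 opposite-ROI levels (7 covariates);
* hippocampal image-specific target: the opposite ROI's image-specific
  score (1 covariate);
* cortical level-specific target: the 3 same-ROI non-target levels.

Residualizing regressions are fitted within subject by default, since the
analyses they feed are within-subject and pooling would leak
between-subject variance into the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import LEVEL_ORDER

__all__ = ["ResidualPlan", "build_plan", "residualize", "residualize_table"]

HIPPOCAMPAL_ROIS = ("ahc", "phc")

IMAGE_SPECIFIC = "image_specific"


@dataclass
class ResidualPlan:
    """One residualizing regression: a target measure and its covariates."""

    target: tuple[str, str]              # (roi, scale)
    covariates: list[tuple[str, str]] = field(default_factory=list)
    per_subject: bool = True

    def __post_init__(self) -> None:
        if self.target in self.covariates:
            raise ValueError("target cannot be one of its own covariates")


def build_plan(target: tuple[str, str],
               hippocampal_rois: tuple[str, str] = HIPPOCAMPAL_ROIS,
               per_subject: bool = True) -> ResidualPlan:
    """Covariate recipe for a (roi, scale) target."""
    roi, scale = target
    if roi in hippocampal_rois:
        other = hippocampal_rois[1 - hippocampal_rois.index(roi)]
        if scale == IMAGE_SPECIFIC:
            cov = [(other, IMAGE_SPECIFIC)]
        elif scale in LEVEL_ORDER:
            cov = [(roi, lvl) for lvl in LEVEL_ORDER if lvl != scale]
            cov += [(other, lvl) for lvl in LEVEL_ORDER]
        else:
            raise ValueError(f"unknown scale {scale!r}")
    elif scale in LEVEL_ORDER:
        cov = [(roi, lvl) for lvl in LEVEL_ORDER if lvl != scale]
    else:
        raise ValueError(
            f"no residualization recipe for cortical target with scale {scale!r}")
    return ResidualPlan(target=target, covariates=cov, per_subject=per_subject)


def residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS residuals of *y* on *X* plus an intercept.

    Collinear covariate columns are dropped (with a warning) so the fit
    never fails; the residuals are mean-zero and orthogonal to every
    retained column.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("y and X row counts differ")
    design = np.column_stack([np.ones(len(y)), X])
    if len(y) <= design.shape[1]:
        raise ValueError("need more trials than covariates to residualize")
    # rank-revealing QR to drop collinear columns
    keep = _independent_columns(design)
    if len(keep) < design.shape[1]:
        dropped = sorted(set(range(design.shape[1])) - set(keep))
        warnings.warn(f"dropping collinear covariate column(s) {dropped}",
                      RuntimeWarning, stacklevel=2)
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _qr_pivot(A: np.ndarray):
    from scipy.linalg import qr
    return qr(A, mode="economic", pivoting=True)


def _independent_columns(A: np.ndarray, tol: float = 1e-10) -> list[int]:
    _, r, piv = _qr_pivot(A)
    diag = np.abs(np.diag(r))
    thresh = tol * max(diag[0], 1.0)
    rank = int(np.sum(diag > thresh))
    return sorted(piv[:rank])


def residualize_table(table: pd.DataFrame, targets: list[tuple[str, str]],
                      per_subject: bool = True) -> pd.DataFrame:
    """Residualize reactivation measures in a long ReactivationTable.

    *table* has columns subject, trial, roi, scale, adjusted_rank.  Each
    target's plan comes from :func:`build_plan`; regressions run within
    subject unless ``per_subject`` is False (pooled, for sensitivity
    checks).  Returns the same long schema restricted to the targets,
    with ``residualized=True``.
    """
    plans = [build_plan(t, per_subject=per_subject) for t in targets]
    wide = table.pivot_table(index=["subject", "trial"], columns=["roi", "scale"],
                             values="adjusted_rank")
    pieces = []
    for plan in plans:
        need = [plan.target] + plan.covariates
        missing = [c for c in need if c not in wide.columns]
        if missing:
            raise ValueError(f"reactivation table lacks measures {missing}")
        sub = wide[need].dropna()
        y = sub[plan.target].to_numpy()
        X = sub[plan.covariates].to_numpy()
        if per_subject:
            resid = np.empty(len(sub))
            subjects = sub.index.get_level_values("subject")
            for s in subjects.unique():
                rows = subjects == s
                resid[rows] = residualize(y[rows], X[rows])
        else:
            resid = residualize(y, X)
        out = pd.DataFrame({
            "subject": sub.index.get_level_values("subject"),
            "trial": sub.index.get_level_values("trial"),
            "roi": plan.target[0],
            "scale": plan.target[1],
            "adjusted_rank": resid,
            "residualized": True,
        })
        pieces.append(out)
    return pd.concat(pieces, ignore_index=True)
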