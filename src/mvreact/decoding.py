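"""Rank-based reactivation decoding.

A retrieval trial's observed recall pattern is Pearson-correlated, across
vertices within an ROI, with the predicted pattern of every candidate
image.  The descending rank of the cued image's prediction among the N
candidates, subtracted from the mean rank (N+1)/2, is the adjusted rank:
0 is chance, +(N-1)/2 the best possible score and -(N-1)/2 the worst
(+/-44.5 for the 90-image design).  Per-layer adjusted ranks are averaged
within the four feature levels; image-specific scores use each image's
averaged encoding patterns as templates instead of model predictions.
Hippocampal sections are averaged bilaterally and grouped into anterior
(sections 1-2) and posterior (sections 4-5) ROIs, dropping the middle
section to limit signal bleed between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import LEVELS, LEVEL_ORDER

__all__ = [
    "RoiAggregation",
    "correlation_profile",
    "rank_reactivation",
    "adjusted_ranks",
    "feature_specific_scores",
    "image_specific_scores",
    "aggregate_rois",
]


def _center_norm(X: np.ndarray) -> np.ndarray:
    """Row-center and unit-normalize; zero-variance rows become zero rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    flat = norms[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance pattern(s); their correlations "
            "are treated as 0", RuntimeWarning, stacklevel=3)
        norms[flat] = 1.0
    return Xc / norms


def correlation_profile(observed: np.ndarray, predictions: np.ndarray) -> np.ndarray:
    """Pearson correlation of each observed row with each prediction row.

    ``observed`` is trials x vertices (a single vector is promoted to one
    trial); ``predictions`` is N x vertices.  Returns trials x N.
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    if observed.shape[1] != predictions.shape[1]:
        raise ValueError("observed and predictions disagree on vertex count")
    if observed.shape[1] < 3:
        raise ValueError("need at least 3 vertices to correlate")
    return _center_norm(observed) @ _center_norm(predictions).T


def adjusted_ranks(corrs: np.ndarray) -> np.ndarray:
    """Convert correlation rows into centered descending ranks.

    The best-correlated candidate gets +(N-1)/2, the worst -(N-1)/2; ties
    share the mean of their rank positions, which keeps the chance
    expectation at exactly 0.
    """
    corrs = np.atleast_2d(np.asarray(corrs, dtype=float))
    n = corrs.shape[1]
    ranks = rankdata(-corrs, method="average", axis=1)
    return (n + 1) / 2.0 - ranks


def rank_reactivation(observed: np.ndarray, predictions: np.ndarray,
                      target_index: int) -> float:
    """Adjusted rank of the target image's prediction for one trial."""
    predictions = np.atleast_2d(predictions)
    if predictions.shape[0] < 2:
        raise ValueError("need at least 2 candidate predictions to rank")
    corrs = correlation_profile(observed, predictions)
    return float(adjusted_ranks(corrs)[0, target_index])


def feature_specific_scores(observed: np.ndarray,
                            predictions_by_layer: dict[int, np.ndarray],
                            target_indices: np.ndarray,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial adjusted ranks for each layer, then averaged into levels.

    ``observed`` is trials x vertices; ``predictions_by_layer[layer]`` is
    the N x vertices cross-validated predicted-pattern matrix; the trial's
    cued image is ``target_indices[trial]`` (row index into predictions).

    Returns ``(layer_scores, level_scores)``: trials x 16 and trials x 4
    DataFrames.  Missing layer predictions raise.
    """
    expected = {lay for lays in LEVELS.values() for lay in lays}
    missing = expected - set(predictions_by_layer)
    if missing:
        raise ValueError(f"missing predictions for layers {sorted(missing)}")
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    target_indices = np.asarray(target_indices, dtype=int)
    n_trials = observed.shape[0]
    rows = np.arange(n_trials)
    layer_scores = pd.DataFrame(index=rows, columns=sorted(expected), dtype=float)
    for layer in sorted(expected):
        corrs = correlation_profile(observed, predictions_by_layer[layer])
        layer_scores[layer] = adjusted_ranks(corrs)[rows, target_indices]
    level_scores = pd.DataFrame(
        {lvl: layer_scores[list(LEVELS[lvl])].mean(axis=1) for lvl in LEVEL_ORDER})
    return layer_scores, level_scores


def encoding_templates(enc_betas: np.ndarray, enc_trial_images: list,
                       image_ids: list) -> np.ndarray:
    """Average each image's encoding-trial betas into an images x vertices template."""
    enc_betas = np.asarray(enc_betas, dtype=float)
    img_arr = np.asarray(enc_trial_images)
    templates = np.empty((len(image_ids), enc_betas.shape[1]))
    for i, img in enumerate(image_ids):
        rows = np.flatnonzero(img_arr == img)
        if rows.size == 0:
            raise ValueError(f"image {img!r} has no encoding trials")
        templates[i] = enc_betas[rows].mean(axis=0)
    return templates


def image_specific_scores(observed: np.ndarray, enc_betas: np.ndarray,
                          enc_trial_images: list, image_ids: list,
                          target_indices: np.ndarray) -> np.ndarray:
    """Per-trial adjusted rank against averaged own-image encoding patterns."""
    templates = encoding_templates(enc_betas, enc_trial_images, image_ids)
    corrs = correlation_profile(observed, templates)
    ranks = adjusted_ranks(corrs)
    rows = np.arange(ranks.shape[0])
    return ranks[rows, np.asarray(target_indices, dtype=int)]


@dataclass
class RoiAggregation:
    """Bilateral averaging + hippocampal long-axis grouping.

    Hippocampal section ROIs are named ``{prefix}_{hemi}_{section}`` with
    section 1 most anterior and 5 most posterior.  aHC averages bilateral
    sections 1-2 and pHC sections 4-5; the middle section is excluded.
    Cortical ROIs are averaged over the bilateral pairs in
    ``cortical_pairs``.
    """

    hippocampus_prefix: str = "hc"
    hemispheres: tuple[str, str] = ("l", "r")
    n_sections: int = 5
    anterior_sections: tuple[int, ...] = (1, 2)
    posterior_sections: tuple[int, ...] = (4, 5)
    cortical_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def section_roi(self, hemi: str, section: int) -> str:
        return f"{self.hippocampus_prefix}_{hemi}_{section}"

    def hippocampal_rois(self) -> list[str]:
        return [self.section_roi(h, s) for h in self.hemispheres
                for s in range(1, self.n_sections + 1)]


def aggregate_rois(records: pd.DataFrame, aggregation: RoiAggregation,
                   value_col: str = "adjusted_rank") -> pd.DataFrame:
    """Collapse per-hemisphere ROIs to bilateral aHC/pHC + cortical means.

    *records* is a long table with at least ``roi`` and *value_col*
    columns; all other columns form the grouping key (subject, trial,
    scale, ...).  Both hemispheres must be present for every averaged ROI.
    """
    keys = [c for c in records.columns if c not in ("roi", value_col)]
    wide = records.pivot_table(index=keys, columns="roi", values=value_col,
                               aggfunc="mean")
    out = {}
    agg = aggregation
    # bilateral hippocampal sections, then long-axis grouping
    sections = {}
    for s in range(1, agg.n_sections + 1):
        pair = [agg.section_roi(h, s) for h in agg.hemispheres]
        missing = [r for r in pair if r not in wide.columns]
        if missing:
            raise ValueError(f"missing hemisphere ROI(s) {missing} for section {s}")
        sections[s] = wide[pair].mean(axis=1)
    out["ahc"] = sum(sections[s] for s in agg.anterior_sections) / len(agg.anterior_sections)
    out["phc"] = sum(sections[s] for s in agg.posterior_sections) / len(agg.posterior_sections)
    for name, (left, right) in agg.cortical_pairs.items():
        missing = [r for r in (left, right) if r not in wide.columns]
        if missing:
            raise ValueError(f"missing hemisphere ROI(s) {missing} for {name}")
        out[name] = wide[[left, right]].mean(axis=1)
    long = pd.DataFrame(out).rename_axis(columns="roi").stack().rename(value_col)
    return long.reset_index()
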