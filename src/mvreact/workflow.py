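"""High-level flows: experiment -> reactivation tables -> model battery.

These functions wire the stage primitives together for the common case of
a simulated experiment: decode every subject x ROI, average hemispheres
and group the hippocampal long axis, residualize the standard targets,
assemble the wide trial-by-measure table, and fit the within- and
between-subject models with bootstrap inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoding import (aggregate_rois, feature_specific_scores,
                       image_specific_scores)
from .features import LEVEL_ORDER
from .inference import (GlmmFit, attach_lure_accuracy, bootstrap_inference,
                        between_subject_model, calcarine_spec,
                        feature_hc_spec, fit_glmm, image_hc_spec)
from .residualize import IMAGE_SPECIFIC, residualize_table
from .synthetic import Experiment

__all__ = [
    "RESIDUAL_TARGETS",
    "truth_layer_predictions",
    "decode_experiment",
    "residualize_standard",
    "build_model_data",
    "run_within_subject_models",
]

#: Measures carried into the within-subject models, in (roi, scale) form.
RESIDUAL_TARGETS: list[tuple[str, str]] = (
    [("ahc", lvl) for lvl in LEVEL_ORDER]
    + [("phc", lvl) for lvl in LEVEL_ORDER]
    + [("ahc", IMAGE_SPECIFIC), ("phc", IMAGE_SPECIFIC), ("calcarine", "low")]
)


def truth_layer_predictions(exp: Experiment, subject: int, roi: str,
                            prepared: dict[int, np.ndarray] | None = None,
                            ) -> dict[int, np.ndarray]:
    """Noise-free per-layer predicted patterns from the generative weights.

    Equivalent to perfectly fitted encoding models: prediction of image i
    at layer k is ``W_k f_{k,i}``.  Used by simulation studies that
    exercise the decode->infer path without refitting tens of thousands
    of per-vertex lassos.
    """
    if prepared is None:
        prepared = exp.features.prepared_by_layer()
    W = exp.truth.vertex_weights[(subject, roi)]
    return {layer: prepared[layer] @ W[layer].T for layer in W}


def decode_experiment(exp: Experiment,
                      model_predictions: dict | None = None,
                      include_image_specific: bool = True) -> pd.DataFrame:
    """Decode every subject x hemisphere-ROI into a long reactivation table.

    ``model_predictions[(subject, roi)]`` maps layers to cross-validated
    predicted-pattern matrices from fitted encoding models; pairs absent
    from it (or the whole argument) fall back to predictions derived from
    the ground-truth weights (:func:`truth_layer_predictions`).
    Image-specific scores always use the subject's averaged encoding
    betas as templates.
    """
    prepared = exp.features.prepared_by_layer()
    image_ids = exp.features.image_ids
    row_of = {img: i for i, img in enumerate(image_ids)}
    records = []
    for s in range(exp.config.n_subjects):
        targets = np.array([row_of[i] for i in exp.neural.retrieval_images[s]])
        for roi in exp.config.rois:
            observed = exp.neural.retrieval[(s, roi)]
            preds = None
            if model_predictions is not None:
                preds = model_predictions.get((s, roi))
            if preds is None:
                preds = truth_layer_predictions(exp, s, roi, prepared)
            _, level_scores = feature_specific_scores(observed, preds, targets)
            for lvl in LEVEL_ORDER:
                for t, val in enumerate(level_scores[lvl].to_numpy()):
                    records.append((s, t, roi, lvl, val))
            if include_image_specific:
                img_scores = image_specific_scores(
                    observed, exp.neural.encoding[(s, roi)],
                    exp.neural.encoding_images[s], image_ids, targets)
                for t, val in enumerate(img_scores):
                    records.append((s, t, roi, IMAGE_SPECIFIC, val))
    out = pd.DataFrame(records,
                       columns=["subject", "trial", "roi", "scale",
                                "adjusted_rank"])
    out["residualized"] = False
    return out


def residualize_standard(table_hemi: pd.DataFrame, exp: Experiment,
                         targets=None) -> pd.DataFrame:
    """Aggregate hemispheres/long axis, then residualize the standard targets."""
    agg = aggregate_rois(table_hemi.drop(columns="residualized"),
                         exp.config.aggregation)
    agg["residualized"] = False
    targets = RESIDUAL_TARGETS if targets is None else targets
    available = set(zip(agg["roi"], agg["scale"]))
    usable = [t for t in targets if t in available]
    return residualize_table(agg, usable), agg


def build_model_data(trials: pd.DataFrame, react: pd.DataFrame,
                     standardize: bool = True,
                     ) -> tuple[pd.DataFrame, float, float]:
    """Wide trial table: one row per trial, one column per (roi, scale) measure.

    Joins behavior (accuracy, probe type, image pair) with the
    reactivation measures, names columns ``{roi}_{scale}``, z-scores each
    measure within subject (so coefficients are per-SD of reactivation,
    comparable across ROIs and candidate-set sizes), and attaches the
    standardized lure-accuracy moderator.  Returns
    ``(data, lure_mean, lure_sd)`` with the raw-proportion anchors.
    """
    wide = react.pivot_table(index=["subject", "trial"],
                             columns=["roi", "scale"], values="adjusted_rank")
    wide.columns = [f"{roi}_{scale}" for roi, scale in wide.columns]
    beh = trials.set_index(["subject", "trial"])[
        ["accuracy", "is_lure", "pair_id", "image_id"]]
    data = beh.join(wide, how="inner").reset_index()
    data = data.rename(columns={"pair_id": "pair"})
    if standardize:
        meas = list(wide.columns)
        grp = data.groupby("subject")[meas]
        sd = grp.transform("std").replace(0.0, 1.0)
        data[meas] = (data[meas] - grp.transform("mean")) / sd
    data, mu, sd = attach_lure_accuracy(data)
    return data, mu, sd


def run_within_subject_models(data: pd.DataFrame, B: int = 1000,
                              rng: np.random.Generator | None = None,
                              include_calcarine: bool = True,
                              ) -> dict[str, GlmmFit]:
    """Fit + bootstrap the within-subject model battery."""
    rng = np.random.default_rng() if rng is None else rng
    out: dict[str, GlmmFit] = {}
    specs = [feature_hc_spec(), image_hc_spec()]
    if include_calcarine and "calcarine_low" in data.columns:
        specs.append(calcarine_spec())
    for spec in specs:
        need = [c for c in spec.measures if c not in data.columns]
        if need:
            raise ValueError(f"model {spec.name} missing measures {need}")
        fit = fit_glmm(spec, data)
        out[spec.name] = bootstrap_inference(fit, B=B, scheme="parametric",
                                             rng=rng)
    return out


def run_between_subject_model(data: pd.DataFrame, B: int = 1000,
                              rng: np.random.Generator | None = None):
    return between_subject_model(data, B=B, rng=rng)
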