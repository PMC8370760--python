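"""Synthetic experiment generator with known ground truth.

Emulates the statistical structure of the recognition-memory study end to
end: a 1-back encoding schedule (each image exactly four times per run,
one immediate repetition, other repetitions at least 4 apart), 16 layers
of non-negative image features with lure-pair correlation that rises
toward the semantic levels, sparse non-negative vertex sensitivities,
encoding/movie/retrieval multivoxel patterns per ROI, an
anterior-to-posterior fidelity gradient over five hippocampal sections,
and recognition behavior generated from a logistic model on trial-level
reactivation fidelity moderated by subject lure skill.

Every draw flows from ``SimConfig.seed`` through named
``numpy.random.SeedSequence`` children, so the same configuration always
yields bit-identical outputs.

Design notes: layer features are rectified correlated Gaussians with a
shared latent per lure pair (non-negativity plus pair similarity without
a real network); the retrieval distractor component mixes other images'
features, so incorrect trials can carry negative adjusted ranks; the
90 encoded images form 45 lure pairs, i.e. a lure probe for one image is
its (also encoded) pair partner, which keeps the candidate set at 90 and
gives the crossed "image pair" random effect 45 levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .decoding import RoiAggregation
from .features import FeatureTensor, LEVELS, LEVEL_ORDER, N_LAYERS, assign_level, prepare_tensor

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FeatureSet",
    "NeuralData",
    "ScheduleError",
    "make_schedule",
    "make_features",
    "draw_ground_truth",
    "make_neural",
    "make_behavior",
    "simulate_experiment",
    "default_aggregation",
]


class ScheduleError(RuntimeError):
    """The constraint sampler exhausted its restart budget."""


def default_aggregation() -> RoiAggregation:
    return RoiAggregation(cortical_pairs={
        "calcarine": ("calcarine_l", "calcarine_r"),
        "precentral": ("precentral_l", "precentral_r"),
    })


@dataclass
class SimConfig:
    """Generative parameters; defaults follow the study design.

    25 subjects, 90 images in 45 lure pairs, 3 encoding runs of 30
    images x 4 repetitions (120 trials/run, 360 total), 16 feature
    layers, 5 hippocampal sections per hemisphere plus calcarine and a
    precentral (distractor) ROI.  ``fidelity_gradient`` is the base
    retrieval fidelity of detail features per section, anterior (low) to
    posterior (high); the semantic level follows the reversed gradient.
    """

    n_subjects: int = 25
    n_images: int = 90                    # paired into n_images//2 lure pairs
    n_runs_encode: int = 3
    images_per_run: int = 30
    reps_per_image: int = 4
    n_layers: int = N_LAYERS
    channels_per_layer: int = 16          # conv grids are 3 x 3 x channels
    n_movie_samples: int = 3775
    n_vertices_per_roi: int = 60
    cortical_rois: tuple[str, ...] = ("calcarine", "precentral")
    fidelity_gradient: tuple[float, ...] = (0.15, 0.30, 0.45, 0.60, 0.75)
    lure_pair_correlation: dict[str, float] = field(default_factory=lambda: {
        "low": 0.55, "mid": 0.65, "high": 0.75, "semantic": 0.90})
    behavior_betas: dict[str, float] = field(default_factory=lambda: {
        "intercept": 1.7,
        "lure_skill": 0.5,
        "phc_low": 0.15,
        "phc_low:lure_skill": 0.30,
        "calcarine_low": 0.15,
        "calcarine_low:lure_skill": 0.20,
        "phc_low:calcarine_low:lure_skill": 0.20,
    })
    noise_sd: float = 0.5                 # activity noise, relative to signal SD
    activation_mean: float = 1.5          # pre-rectification mean of layer features
    fidelity_trial_sd: float = 0.15
    skill_fidelity_slope: float = 0.08    # lure skill -> pHC/calcarine detail fidelity
    subject_intercept_sd: float = 0.3
    pair_intercept_sd: float = 0.2
    nonresponse_rate: float = 0.01
    repetition_mode: str = "exactly"      # or "at_most": <=1 immediate repetition
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_images", "n_runs_encode", "images_per_run",
                     "reps_per_image", "n_layers", "channels_per_layer",
                     "n_vertices_per_roi", "n_movie_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_images % 2:
            raise ValueError("n_images must be even (images come in lure pairs)")
        if self.images_per_run * self.n_runs_encode != self.n_images:
            raise ValueError("images_per_run * n_runs_encode must equal n_images")
        for lvl, rho in self.lure_pair_correlation.items():
            if not -1.0 < rho < 1.0:
                raise ValueError(f"lure_pair_correlation[{lvl}] outside (-1, 1)")
        if any(not 0.0 <= g <= 1.0 for g in self.fidelity_gradient):
            raise ValueError("fidelity_gradient values must lie in [0, 1]")
        if self.repetition_mode not in ("exactly", "at_most"):
            raise ValueError("repetition_mode must be 'exactly' or 'at_most'")

    @property
    def n_pairs(self) -> int:
        return self.n_images // 2

    @property
    def aggregation(self) -> RoiAggregation:
        return RoiAggregation(cortical_pairs={
            r: (f"{r}_l", f"{r}_r") for r in self.cortical_rois})

    @property
    def rois(self) -> list[str]:
        agg = self.aggregation
        return agg.hippocampal_rois() + [h for pair in agg.cortical_pairs.values()
                                         for h in pair]

    def rng(self, *path: str | int) -> np.random.Generator:
        """Named child generator: same seed + path -> identical stream."""
        key = [int.from_bytes(str(p).encode(), "little") % (2**32) for p in path]
        return np.random.default_rng(np.random.SeedSequence([self.seed, *key]))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Latent quantities downstream stages try to recover."""

    vertex_weights: dict       # (subject, roi) -> {layer: V x p non-negative}
    trial_fidelity: dict       # (subject, roi) -> n_ret_trials x 4 levels, in [0,1]
    subject_lure_skill: np.ndarray
    behavior_betas: dict[str, float]

    def __post_init__(self) -> None:
        for w in self.vertex_weights.values():
            for arr in w.values():
                if np.any(arr < 0):
                    raise ValueError("vertex weights must be non-negative")
        for f in self.trial_fidelity.values():
            if np.any((f < 0) | (f > 1)):
                raise ValueError("fidelity must lie in [0, 1]")


# ------------------------------------------------------------------ schedule

def make_schedule(n_images: int, reps: int, rng: np.random.Generator,
                  mode: str = "exactly", max_restarts: int = 10_000,
                  min_gap: int = 4) -> pd.DataFrame:
    """Sample a 1-back encoding sequence honoring the repetition constraints.

    Each image appears exactly ``reps`` times; exactly one immediate
    repetition per image (``mode='at_most'`` relaxes this to at most
    one); all other same-image gaps are at least ``min_gap`` positions.
    Rejection sampling over a token construction (one adjacent double +
    singles per image); raises :class:`ScheduleError` after
    ``max_restarts`` failed shuffles.

    Returns a DataFrame with ``image_id`` (0-based within-run index) and
    the 1-back answer ``is_repeat``.
    """
    if n_images < 2 or reps < 2:
        raise ValueError("need at least 2 images and 2 repetitions")
    for attempt in range(max_restarts):
        tokens: list[tuple[int, int]] = []  # (image, run_length)
        for img in range(n_images):
            double = True if mode == "exactly" else bool(rng.integers(2))
            n_single = reps - (2 if double else 0)
            if n_single < 0:
                double, n_single = False, reps
            if double:
                tokens.append((img, 2))
            tokens.extend((img, 1) for _ in range(n_single))
        order = rng.permutation(len(tokens))
        seq: list[int] = []
        for k in order:
            img, length = tokens[k]
            seq.extend([img] * length)
        if _schedule_ok(seq, n_images, reps, mode, min_gap):
            arr = np.asarray(seq)
            is_rep = np.zeros(len(arr), dtype=bool)
            is_rep[1:] = arr[1:] == arr[:-1]
            return pd.DataFrame({"image_id": arr, "is_repeat": is_rep})
    raise ScheduleError(
        f"could not satisfy schedule constraints for n_images={n_images}, "
        f"reps={reps} in {max_restarts} restarts")


def _schedule_ok(seq: list[int], n_images: int, reps: int, mode: str,
                 min_gap: int) -> bool:
    positions: dict[int, list[int]] = {}
    for pos, img in enumerate(seq):
        positions.setdefault(img, []).append(pos)
    for img in range(n_images):
        pos = positions.get(img, [])
        if len(pos) != reps:
            return False
        gaps = np.diff(pos)
        n_adj = int(np.sum(gaps == 1))
        if mode == "exactly" and n_adj != 1:
            return False
        if mode == "at_most" and n_adj > 1:
            return False
        if np.any(gaps[gaps != 1] < min_gap):
            return False
    return True


# ------------------------------------------------------------------ features

@dataclass
class FeatureSet:
    """Raw feature tensors for the encoded images plus movie surrogates."""

    image_ids: list[str]
    tensors: dict[str, dict[int, FeatureTensor]]   # image -> layer -> tensor
    movie: dict[int, np.ndarray]                   # layer -> n_movie x p (raw)

    def prepared_by_layer(self, log_offset: float = 1.0) -> dict[int, np.ndarray]:
        """Log-transformed flattened image features: layer -> images x p."""
        out = {}
        for layer in sorted(next(iter(self.tensors.values()))):
            rows = [prepare_tensor(self.tensors[img][layer],
                                   log_offset=log_offset).flatten()
                    for img in self.image_ids]
            out[layer] = np.vstack(rows)
        return out

    def movie_by_layer(self, log_offset: float = 1.0) -> dict[int, np.ndarray]:
        return {layer: np.log1p(arr) if log_offset == 1.0
                else np.log(log_offset + arr)
                for layer, arr in self.movie.items()}


def image_label(i: int) -> str:
    return f"img{i:03d}"


def make_features(cfg: SimConfig, rng: np.random.Generator | None = None,
                  ) -> FeatureSet:
    """Draw non-negative layer features with lure-pair correlation structure.

    Per layer and pair, both members share a latent Gaussian mixed in with
    weight ``sqrt(rho)`` (rho from ``lure_pair_correlation`` of the
    layer's level), shifted by ``activation_mean`` and rectified at zero
    — so activations are non-negative with exact zeros, and within-pair
    correlation approximates rho (highest at the semantic levels).
    Convolutional layers come back as 3 x 3 x channels grids, fully
    connected layers as flat vectors of matching length.
    """
    rng = cfg.rng("features") if rng is None else rng
    c = cfg.channels_per_layer
    p = 9 * c
    ids = [image_label(i) for i in range(cfg.n_images)]
    tensors: dict[str, dict[int, FeatureTensor]] = {i: {} for i in ids}
    movie: dict[int, np.ndarray] = {}
    for layer in range(1, cfg.n_layers + 1):
        rho = cfg.lure_pair_correlation[assign_level(layer)]
        z_pair = rng.standard_normal((cfg.n_pairs, p))
        eps = rng.standard_normal((cfg.n_images, p))
        latent = (np.sqrt(rho) * np.repeat(z_pair, 2, axis=0)
                  + np.sqrt(1.0 - rho) * eps)
        acts = np.maximum(0.0, cfg.activation_mean + latent)
        for i, img in enumerate(ids):
            vals = acts[i].reshape(3, 3, c) if layer <= 13 else acts[i]
            tensors[img][layer] = FeatureTensor(
                image_id=img, layer_id=layer, values=vals,
                pooled=layer <= 13)
        movie[layer] = np.maximum(
            0.0, cfg.activation_mean
            + rng.standard_normal((cfg.n_movie_samples, p)))
    return FeatureSet(image_ids=ids, tensors=tensors, movie=movie)


# -------------------------------------------------------------- ground truth

_CALCARINE_BASE = {"low": 0.80, "mid": 0.50, "high": 0.30, "semantic": 0.20}
_DISTRACTOR_BASE = 0.05

_ROI_LEVEL_GAIN = {
    "calcarine": {"low": 1.5, "mid": 1.0, "high": 0.5, "semantic": 0.25},
    "precentral": {lvl: 0.3 for lvl in LEVEL_ORDER},
}


def _roi_base_fidelity(cfg: SimConfig, roi: str) -> np.ndarray:
    """Base fidelity per level for one ROI (4-vector, level order)."""
    if roi.startswith("hc_"):
        section = int(roi.split("_")[-1])
        g = cfg.fidelity_gradient[section - 1]
        g_rev = cfg.fidelity_gradient[len(cfg.fidelity_gradient) - section]
        return np.array([g, g, g, g_rev])
    name = roi.rsplit("_", 1)[0]
    if name == "calcarine":
        return np.array([_CALCARINE_BASE[lvl] for lvl in LEVEL_ORDER])
    return np.full(4, _DISTRACTOR_BASE)


def _skill_slope(cfg: SimConfig, roi: str) -> np.ndarray:
    """How strongly subject lure skill shifts each level's fidelity in a ROI."""
    s = cfg.skill_fidelity_slope
    if roi.startswith("hc_"):
        section = int(roi.split("_")[-1])
        if section >= 4:       # posterior sections: detail levels track skill
            return np.array([s, s, s, 0.0])
        return np.zeros(4)
    if roi.startswith("calcarine"):
        return np.array([s, 0.0, 0.0, 0.0])
    return np.zeros(4)


def draw_ground_truth(cfg: SimConfig, rng: np.random.Generator | None = None,
                      ) -> GroundTruth:
    """Sample sparse non-negative vertex weights, fidelities, and skills."""
    rng = cfg.rng("truth") if rng is None else rng
    skills = rng.standard_normal(cfg.n_subjects)
    p = 9 * cfg.channels_per_layer
    nnz = max(2, p // 10)
    weights: dict = {}
    fidelity: dict = {}
    n_trials = cfg.n_images  # each image cued once at retrieval
    for s in range(cfg.n_subjects):
        for roi in cfg.rois:
            gain_map = _ROI_LEVEL_GAIN.get(roi.rsplit("_", 1)[0], None)
            w_layers = {}
            for layer in range(1, cfg.n_layers + 1):
                gain = 1.0 if gain_map is None else gain_map[assign_level(layer)]
                V = cfg.n_vertices_per_roi
                # nnz random support columns per vertex, Exp(1) magnitudes
                cols = np.argpartition(rng.random((V, p)), nnz, axis=1)[:, :nnz]
                W = np.zeros((V, p))
                np.put_along_axis(W, cols, gain * rng.exponential(1.0, (V, nnz)),
                                  axis=1)
                w_layers[layer] = W
            weights[(s, roi)] = w_layers
            base = _roi_base_fidelity(cfg, roi)
            slope = _skill_slope(cfg, roi)
            phi = (base[None, :] + slope[None, :] * skills[s]
                   + rng.normal(0.0, cfg.fidelity_trial_sd, size=(n_trials, 4)))
            fidelity[(s, roi)] = np.clip(phi, 0.0, 1.0)
    return GroundTruth(vertex_weights=weights, trial_fidelity=fidelity,
                       subject_lure_skill=skills,
                       behavior_betas=dict(cfg.behavior_betas))


# ------------------------------------------------------------------- neural

@dataclass
class NeuralData:
    """Per-subject, per-ROI single-trial amplitude matrices."""

    encoding: dict          # (subject, roi) -> n_enc_trials x V
    retrieval: dict         # (subject, roi) -> n_ret_trials x V
    movie: dict             # (subject, roi) -> n_movie x V (optional; may be empty)
    encoding_images: dict   # subject -> list of image labels per encoding trial
    retrieval_images: dict  # subject -> list of cued image labels per trial
    schedules: dict         # (subject, run) -> schedule DataFrame


def _signal(weights: dict[int, np.ndarray],
            feats: dict[int, np.ndarray]) -> np.ndarray:
    """Noise-free activity for rows of prepared features: trials x V."""
    parts = [feats[layer] @ weights[layer].T for layer in weights]
    return np.sum(parts, axis=0)


def make_neural(cfg: SimConfig, features: FeatureSet, truth: GroundTruth,
                rng: np.random.Generator | None = None,
                include_movie: bool = False,
                fidelity_override: float | None = None) -> NeuralData:
    """Generate encoding, retrieval (and optionally movie) patterns per ROI.

    Encoding activity is ``weights @ features`` plus Gaussian noise scaled
    to ``noise_sd`` times the signal SD.  Retrieval activity mixes, per
    feature level, the cued image's noise-free template (weight: the
    trial's fidelity) with a random two-image mixture of other images'
    templates (weight: 1 - fidelity), plus the same noise.
    ``fidelity_override`` replaces every fidelity with a constant (used
    for chance/perfect-recall checks); with override 1 and noise 0 the
    retrieval pattern equals the encoding template exactly.
    """
    rng = cfg.rng("neural") if rng is None else rng
    prepared = features.prepared_by_layer()
    movie_prep = features.movie_by_layer() if include_movie else None
    level_layers = {lvl: list(LEVELS[lvl]) for lvl in LEVEL_ORDER}
    row_of = {img: i for i, img in enumerate(features.image_ids)}

    encoding, retrieval, movie = {}, {}, {}
    encoding_images, retrieval_images, schedules = {}, {}, {}
    n_img = cfg.n_images
    for s in range(cfg.n_subjects):
        # per-run schedules over that run's image block
        enc_rows = []
        enc_imgs: list[str] = []
        for run in range(cfg.n_runs_encode):
            block = np.arange(run * cfg.images_per_run,
                              (run + 1) * cfg.images_per_run)
            sched = make_schedule(cfg.images_per_run, cfg.reps_per_image,
                                  rng, mode=cfg.repetition_mode)
            schedules[(s, run)] = sched
            enc_imgs.extend(image_label(block[i]) for i in sched["image_id"])
        encoding_images[s] = enc_imgs
        enc_rows = np.array([row_of[i] for i in enc_imgs])
        # retrieval order: each image once, shuffled within run blocks
        ret_order = []
        for run in range(cfg.n_runs_encode):
            block = np.arange(run * cfg.images_per_run,
                              (run + 1) * cfg.images_per_run)
            ret_order.extend(rng.permutation(block))
        ret_order = np.array(ret_order)
        retrieval_images[s] = [image_label(i) for i in ret_order]

        for roi in cfg.rois:
            W = truth.vertex_weights[(s, roi)]
            templates = _signal(W, prepared)            # n_images x V
            # noise scales with the image-discriminating part of the signal
            # (templates share a large common vertex profile that carries no
            # identity information)
            sig_sd = float((templates - templates.mean(axis=0)).std()) or 1.0
            noise = cfg.noise_sd * sig_sd
            enc = templates[enc_rows] + rng.normal(0.0, noise,
                                                   (len(enc_rows),
                                                    cfg.n_vertices_per_roi))
            encoding[(s, roi)] = enc
            if include_movie:
                mov_sig = _signal(W, movie_prep)
                movie[(s, roi)] = mov_sig + rng.normal(
                    0.0, noise, mov_sig.shape)
            phi = truth.trial_fidelity[(s, roi)]
            if fidelity_override is not None:
                phi = np.full_like(phi, float(fidelity_override))
            ret = np.zeros((n_img, cfg.n_vertices_per_roi))
            level_templates = {
                lvl: _signal({lay: W[lay] for lay in level_layers[lvl]},
                             prepared)
                for lvl in LEVEL_ORDER}
            for li, lvl in enumerate(LEVEL_ORDER):
                T = level_templates[lvl]
                # two distinct distractor images per trial, never the target
                others = rng.integers(0, n_img - 1, size=(n_img, 2))
                others[:, 1] = (others[:, 0] + 1
                                + others[:, 1] % (n_img - 2)) % (n_img - 1)
                others = np.where(others >= ret_order[:, None], others + 1,
                                  others)
                distract = 0.5 * (T[others[:, 0]] + T[others[:, 1]])
                f = phi[:, li:li + 1]
                ret += f * T[ret_order] + (1.0 - f) * distract
            if fidelity_override is None or cfg.noise_sd > 0:
                ret += rng.normal(0.0, noise, ret.shape)
            retrieval[(s, roi)] = ret
    return NeuralData(encoding=encoding, retrieval=retrieval, movie=movie,
                      encoding_images=encoding_images,
                      retrieval_images=retrieval_images, schedules=schedules)


# ----------------------------------------------------------------- behavior

def _aggregate_fidelity(cfg: SimConfig, truth: GroundTruth,
                        subject: int) -> pd.DataFrame:
    """Fidelity of the aggregated ROIs (ahc/phc/cortical) per trial x level."""
    agg = cfg.aggregation
    cols = {}
    sections = {
        sec: np.mean([truth.trial_fidelity[(subject, agg.section_roi(h, sec))]
                      for h in agg.hemispheres], axis=0)
        for sec in range(1, agg.n_sections + 1)}
    ahc = np.mean([sections[s] for s in agg.anterior_sections], axis=0)
    phc = np.mean([sections[s] for s in agg.posterior_sections], axis=0)
    for li, lvl in enumerate(LEVEL_ORDER):
        cols[f"ahc_{lvl}"] = ahc[:, li]
        cols[f"phc_{lvl}"] = phc[:, li]
    for name, (l, r) in agg.cortical_pairs.items():
        bil = (truth.trial_fidelity[(subject, l)]
               + truth.trial_fidelity[(subject, r)]) / 2.0
        for li, lvl in enumerate(LEVEL_ORDER):
            cols[f"{name}_{lvl}"] = bil[:, li]
    return pd.DataFrame(cols)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def make_behavior(cfg: SimConfig, truth: GroundTruth,
                  neural: NeuralData | None = None,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate the old/lure recognition judgment for every retrieval trial.

    Probe type is balanced within subject (half old, half lure).  The
    probability of a correct response is
    ``logistic(b0 + sum_k b_k * x_k)`` where each ``behavior_betas`` term
    is a ':'-joined product of components: an aggregated fidelity measure
    (e.g. ``phc_low``, z-scored within subject), ``lure_skill`` (the
    subject's latent skill), or ``is_lure``; random intercepts for
    subject and image pair are added on the logit scale.  A small
    fraction of trials receive no response and are scored incorrect.

    Returns a BIDS-style trial table: onset_s, duration, subject, run,
    trial, image_id, pair_id, task, probe_type, is_lure, response,
    accuracy.
    """
    rng = cfg.rng("behavior") if rng is None else rng
    betas = truth.behavior_betas
    pair_u = rng.normal(0.0, cfg.pair_intercept_sd, cfg.n_pairs)
    subj_u = rng.normal(0.0, cfg.subject_intercept_sd, cfg.n_subjects)
    n_trials = cfg.n_images
    half = n_trials // 2
    records = []
    trial_spacing = 16.0  # nominal seconds between retrieval cue onsets
    for s in range(cfg.n_subjects):
        if neural is not None:
            imgs = neural.retrieval_images[s]
        else:
            imgs = [image_label(i) for i in rng.permutation(cfg.n_images)]
        fid = _aggregate_fidelity(cfg, truth, s)
        zfid = fid.apply(lambda c: _zscore(c.to_numpy()))
        is_lure = np.zeros(n_trials, dtype=int)
        is_lure[rng.choice(n_trials, size=half, replace=False)] = 1
        eta = np.full(n_trials, betas.get("intercept", 0.0))
        for term, b in betas.items():
            if term == "intercept" or b == 0.0:
                continue
            x = np.ones(n_trials)
            for comp in term.split(":"):
                if comp == "lure_skill":
                    x = x * truth.subject_lure_skill[s]
                elif comp == "is_lure":
                    x = x * is_lure
                elif comp in zfid.columns:
                    x = x * zfid[comp].to_numpy()
                else:
                    raise ValueError(f"unknown behavior term component {comp!r}")
            eta += b * x
        img_idx = np.array([int(i[3:]) for i in imgs])
        pair_idx = img_idx // 2
        eta += subj_u[s] + pair_u[pair_idx]
        p_correct = 1.0 / (1.0 + np.exp(-eta))
        correct = (rng.random(n_trials) < p_correct).astype(int)
        no_resp = rng.random(n_trials) < cfg.nonresponse_rate
        for t in range(n_trials):
            if no_resp[t]:
                response, acc = "n/a", 0
            else:
                if correct[t]:
                    response = "new" if is_lure[t] else "old"
                else:
                    response = "old" if is_lure[t] else "new"
                acc = int(correct[t])
            records.append({
                "onset_s": 10.0 + trial_spacing * (t % cfg.images_per_run),
                "duration": 6.0,
                "subject": s,
                "run": t // cfg.images_per_run,
                "trial": t,
                "image_id": imgs[t],
                "pair_id": int(pair_idx[t]),
                "task": "retrieval",
                "probe_type": "lure" if is_lure[t] else "old",
                "is_lure": int(is_lure[t]),
                "response": response,
                "accuracy": acc,
            })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------- experiment

def recovery_config(seed: int = 0, **overrides) -> SimConfig:
    """Strong-planted-effects conditions for parameter-recovery studies.

    25 subjects x 90 trials with a high trial-level fidelity variance
    (SD 0.3 on a low-baseline gradient, so the rank decoder has dynamic
    range), a reliable lure-skill moderator, and a strong generative
    pHC-low x lure-skill interaction.  Used by the end-to-end recovery
    simulations; the plain :class:`SimConfig` defaults remain the
    study-scale conditions.
    """
    kw = dict(
        n_subjects=25,
        channels_per_layer=6,
        n_vertices_per_roi=40,
        n_movie_samples=10,
        fidelity_trial_sd=0.3,
        fidelity_gradient=(0.1, 0.2, 0.3, 0.4, 0.5),
        behavior_betas={
            "intercept": 1.4,
            "lure_skill": 0.8,
            "phc_low": 0.3,
            "calcarine_low": 0.15,
            "phc_low:lure_skill": 1.2,
            "calcarine_low:lure_skill": 0.2,
        },
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """No reactivation-behavior coupling: every fidelity term is zero.

    Behavior retains a lure-skill main effect (real between-subject
    accuracy differences) but no dependence on neural fidelity, so any
    significant reactivation term downstream is a false positive.
    Sized smaller than the recovery conditions since null calibration
    needs many replicates.
    """
    kw = dict(
        n_subjects=15,
        channels_per_layer=4,
        n_vertices_per_roi=16,
        n_movie_samples=10,
        behavior_betas={"intercept": 1.7, "lure_skill": 0.5},
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass
class Experiment:
    config: SimConfig
    truth: GroundTruth
    features: FeatureSet
    neural: NeuralData
    trials: pd.DataFrame


def simulate_experiment(cfg: SimConfig, include_movie: bool = False) -> Experiment:
    """Generate a complete synthetic experiment from one seed."""
    features = make_features(cfg)
    truth = draw_ground_truth(cfg)
    neural = make_neural(cfg, features, truth, include_movie=include_movie)
    trials = make_behavior(cfg, truth, neural)
    return Experiment(config=cfg, truth=truth, features=features,
                      neural=neural, trials=trials)
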