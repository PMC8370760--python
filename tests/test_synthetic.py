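"""Generator contracts: determinism, feature structure, neural + behavior."""

import numpy as np
import pytest

from mvreact.decoding import image_specific_scores
from mvreact.features import LEVEL_ORDER
from mvreact.synthetic import (SimConfig, draw_ground_truth, make_behavior,
                               make_features, make_neural, null_config,
                               recovery_config, simulate_experiment)


def tiny_cfg(**kw):
    base = dict(n_subjects=2, n_images=12, images_per_run=4, n_runs_encode=3,
                channels_per_layer=3, n_vertices_per_roi=8,
                n_movie_samples=10, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestConfigValidation:
    def test_counts_must_be_positive(self):
        with pytest.raises(ValueError):
            tiny_cfg(n_subjects=0)

    def test_pair_correlation_bounds(self):
        with pytest.raises(ValueError):
            tiny_cfg(lure_pair_correlation={"low": 1.0, "mid": 0.5,
                                            "high": 0.5, "semantic": 0.5})

    def test_run_structure_consistency(self):
        with pytest.raises(ValueError):
            tiny_cfg(images_per_run=5)  # 5*3 != 12

    def test_gradient_bounds(self):
        with pytest.raises(ValueError):
            tiny_cfg(fidelity_gradient=(0.1, 0.2, 0.3, 0.4, 1.2))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = simulate_experiment(tiny_cfg())
        b = simulate_experiment(tiny_cfg())
        key = (0, "hc_l_1")
        assert np.array_equal(a.neural.encoding[key], b.neural.encoding[key])
        assert np.array_equal(a.neural.retrieval[key], b.neural.retrieval[key])
        assert a.trials.equals(b.trials)
        assert np.array_equal(a.truth.subject_lure_skill,
                              b.truth.subject_lure_skill)
        img = a.features.image_ids[0]
        assert np.array_equal(a.features.tensors[img][1].values,
                              b.features.tensors[img][1].values)

    def test_different_seed_differs(self):
        a = simulate_experiment(tiny_cfg(seed=5))
        b = simulate_experiment(tiny_cfg(seed=6))
        assert not a.trials.equals(b.trials)


class TestFeatures:
    def test_activations_nonnegative(self):
        fs = make_features(tiny_cfg())
        for layers in fs.tensors.values():
            for t in layers.values():
                assert t.values.min() >= 0.0
        for arr in fs.movie.values():
            assert arr.min() >= 0.0

    def test_pair_correlation_matches_target(self):
        rho = {lvl: 0.7 for lvl in LEVEL_ORDER}
        cfg = SimConfig(n_subjects=1, n_images=90, images_per_run=30,
                        channels_per_layer=12, n_vertices_per_roi=4,
                        n_movie_samples=5, lure_pair_correlation=rho, seed=2)
        fs = make_features(cfg)
        cors = []
        for p in range(cfg.n_pairs):
            a = fs.tensors[fs.image_ids[2 * p]][3].flatten()
            b = fs.tensors[fs.image_ids[2 * p + 1]][3].flatten()
            cors.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(cors) - 0.7) < 0.1

    def test_semantic_pair_similarity_highest_at_defaults(self):
        cfg = SimConfig(n_subjects=1, n_images=90, images_per_run=30,
                        channels_per_layer=12, n_vertices_per_roi=4,
                        n_movie_samples=5, seed=3)
        fs = make_features(cfg)

        def mean_pair_corr(layer):
            return np.mean([
                np.corrcoef(fs.tensors[fs.image_ids[2 * p]][layer].flatten(),
                            fs.tensors[fs.image_ids[2 * p + 1]][layer]
                            .flatten())[0, 1]
                for p in range(cfg.n_pairs)])

        assert mean_pair_corr(15) > mean_pair_corr(2)

    def test_equal_correlation_makes_pairs_indistinguishable(self):
        # null construction: pair rho equals the cross-image baseline (0)
        rho = {lvl: 1e-6 for lvl in LEVEL_ORDER}
        cfg = SimConfig(n_subjects=1, n_images=60, images_per_run=20,
                        channels_per_layer=12, n_vertices_per_roi=4,
                        n_movie_samples=5, lure_pair_correlation=rho, seed=4)
        fs = make_features(cfg)
        pair_c, nonpair_c = [], []
        rng = np.random.default_rng(0)
        for p in range(cfg.n_pairs):
            a = fs.tensors[fs.image_ids[2 * p]][2].flatten()
            b = fs.tensors[fs.image_ids[2 * p + 1]][2].flatten()
            pair_c.append(np.corrcoef(a, b)[0, 1])
            j = (2 * p + 3) % cfg.n_images
            c = fs.tensors[fs.image_ids[j]][2].flatten()
            nonpair_c.append(np.corrcoef(a, c)[0, 1])
        assert abs(np.mean(pair_c) - np.mean(nonpair_c)) < 0.1


class TestNeural:
    def test_degenerate_noise_reproduces_template_exactly(self):
        cfg = tiny_cfg(noise_sd=0.0)
        fs = make_features(cfg)
        truth = draw_ground_truth(cfg)
        neural = make_neural(cfg, fs, truth, fidelity_override=1.0)
        s, roi = 0, "hc_l_3"
        row_of = {img: i for i, img in enumerate(fs.image_ids)}
        enc_rows = [row_of[i] for i in neural.encoding_images[s]]
        ret_rows = [row_of[i] for i in neural.retrieval_images[s]]
        templates = {}
        enc = neural.encoding[(s, roi)]
        for r, img_row in enumerate(enc_rows):
            templates[img_row] = enc[r]  # noise-free encoding = template
        ret = neural.retrieval[(s, roi)]
        for t, img_row in enumerate(ret_rows):
            assert np.allclose(ret[t], templates[img_row], atol=1e-10)

    def test_zero_fidelity_decodes_at_chance(self):
        cfg = tiny_cfg(n_subjects=1, n_images=30, images_per_run=10,
                       n_vertices_per_roi=16, seed=8)
        fs = make_features(cfg)
        truth = draw_ground_truth(cfg)
        neural = make_neural(cfg, fs, truth, fidelity_override=0.0)
        scores = _image_scores(cfg, fs, neural, roi="calcarine_l")
        # mean over 30 trials; chance SE ~ sqrt((N^2-1)/12)/sqrt(30) ~ 1.6
        assert abs(np.mean(scores)) < 5.0

    def test_decoded_rank_monotone_in_fidelity(self):
        cfg = tiny_cfg(n_subjects=1, n_images=30, images_per_run=10,
                       n_vertices_per_roi=16, seed=9)
        fs = make_features(cfg)
        truth = draw_ground_truth(cfg)
        means = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = []
            for rep in range(7):  # 7 x 30 = 210 trials per fidelity value
                neural = make_neural(cfg, fs, truth, fidelity_override=f,
                                     rng=cfg.rng("mono", rep, int(f * 100)))
                vals.extend(_image_scores(cfg, fs, neural, roi="calcarine_l"))
            means.append(np.mean(vals))
        assert all(b >= a - 1.0 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 5.0


def _image_scores(cfg, fs, neural, roi, subject=0):
    row_of = {img: i for i, img in enumerate(fs.image_ids)}
    targets = [row_of[i] for i in neural.retrieval_images[subject]]
    return image_specific_scores(
        neural.retrieval[(subject, roi)], neural.encoding[(subject, roi)],
        neural.encoding_images[subject], fs.image_ids, targets)


class TestBehavior:
    def test_null_model_gives_chance_accuracy(self):
        cfg = SimConfig(n_subjects=8, n_images=90, images_per_run=30,
                        channels_per_layer=3, n_vertices_per_roi=4,
                        n_movie_samples=5,
                        behavior_betas={"intercept": 0.0},
                        nonresponse_rate=0.0, seed=13)
        truth = draw_ground_truth(cfg)
        trials = make_behavior(cfg, truth)
        assert trials["accuracy"].mean() == pytest.approx(0.5, abs=0.05)

    def test_probe_types_balanced_within_subject(self):
        exp = simulate_experiment(tiny_cfg())
        counts = exp.trials.groupby("subject")["is_lure"].mean()
        assert np.allclose(counts, 0.5)

    def test_nonresponses_scored_incorrect_and_kept(self):
        cfg = tiny_cfg(nonresponse_rate=0.5, seed=21)
        truth = draw_ground_truth(cfg)
        trials = make_behavior(cfg, truth)
        nr = trials[trials["response"] == "n/a"]
        assert len(nr) > 0
        assert (nr["accuracy"] == 0).all()
        assert len(trials) == cfg.n_subjects * cfg.n_images

    def test_unknown_behavior_term_rejected(self):
        cfg = tiny_cfg(behavior_betas={"intercept": 0.0, "banana": 1.0})
        truth = draw_ground_truth(cfg)
        with pytest.raises(ValueError, match="banana"):
            make_behavior(cfg, truth)


def test_factory_configs_are_valid():
    recovery_config(seed=1)
    null_config(seed=1)
    assert null_config().behavior_betas.get("phc_low", 0.0) == 0.0
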