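"""Config-driven staged pipeline with manifest bookkeeping and a CLI.

Seven stages — simulate, features, betas, encode, decode, residualize,
infer — communicate through files under the configured output directory
and a ``manifest.json`` recording parameters and content hashes, so
re-runs with unchanged inputs are skipped and corrupted upstream files
are caught before a stage runs.

The ``betas`` stage reconstructs single-trial amplitudes the way the
study estimated them: retrieval windows are synthesized on the 2-s grid
from the generated amplitudes and refitted with the two-regressor
(recall/probe) trial GLM; encoding runs are synthesized as overlapping
trial responses and refitted with least-squares-sum.  ``decode`` can
take its predicted patterns either from fitted encoding models
(``predictions: models``) or from the generative weights
(``predictions: truth``), which behave as perfectly fitted models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .decoding import RoiAggregation
from .hemodynamics import build_regressor, estimate_recall_betas, lss_betas, TrialWindow, trial_window_times
from .inference import fdr_correct, level_average, paired_difference, simple_slopes
from .synthetic import SimConfig, simulate_experiment
from .workflow import (build_model_data, decode_experiment,
                       residualize_standard, run_between_subject_model,
                       run_within_subject_models, truth_layer_predictions)

log = logging.getLogger("mvreact")

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES", "cli"]


@dataclass
class PipelineConfig:
    """Validated pipeline settings: paths, generator block, inference knobs."""

    out_dir: Path = Path("results/pipeline")
    sim: SimConfig = field(default_factory=SimConfig)
    bootstrap_b: int = 1000
    predictions: str = "truth"          # 'truth' or 'models'
    encode_rois: tuple[str, ...] | None = None
    fdr_exclude: tuple[str, ...] = ("low",)
    stages: tuple[str, ...] = ()        # empty = all

    _KNOWN = {"out_dir", "sim", "bootstrap_b", "predictions", "encode_rois",
              "fdr_exclude", "stages", "seed"}

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | Path | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, seed=seed, out_dir=out_dir)

    @classmethod
    def from_dict(cls, raw: dict, seed: int | None = None,
                  out_dir: str | Path | None = None) -> "PipelineConfig":
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim_kw = dict(raw.get("sim", {}))
        if seed is not None:
            sim_kw["seed"] = int(seed)
        elif "seed" in raw:
            sim_kw.setdefault("seed", int(raw["seed"]))
        if "lure_pair_correlation" in sim_kw:
            sim_kw["lure_pair_correlation"] = dict(sim_kw["lure_pair_correlation"])
        cfg = cls(
            out_dir=Path(out_dir or raw.get("out_dir", "results/pipeline")),
            sim=SimConfig(**sim_kw),
            bootstrap_b=int(raw.get("bootstrap_b", 1000)),
            predictions=str(raw.get("predictions", "truth")),
            encode_rois=tuple(raw["encode_rois"]) if raw.get("encode_rois") else None,
            fdr_exclude=tuple(raw.get("fdr_exclude", ("low",))),
            stages=tuple(raw.get("stages", ())),
        )
        if cfg.predictions not in ("truth", "models"):
            raise ValueError("predictions must be 'truth' or 'models'")
        return cfg

    def params_for(self, stage: str) -> dict:
        p = {"seed": self.sim.seed, "sim": _jsonable(dataclasses.asdict(self.sim))}
        if stage == "infer":
            p["bootstrap_b"] = self.bootstrap_b
        if stage == "decode":
            p["predictions"] = self.predictions
        if stage == "encode":
            p["encode_rois"] = list(self.encode_rois or [])
        return p


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_manifest(out: Path) -> dict:
    p = out / "manifest.json"
    return json.loads(p.read_text()) if p.exists() else {}


def _save_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))


# --------------------------------------------------------------- the stages
# Each stage function takes (cfg, exp_cache) and returns its output paths.
# exp_cache holds the in-memory Experiment so downstream stages in the same
# process don't re-simulate; on a fresh process they regenerate from seed.


def _experiment(cfg: PipelineConfig, cache: dict):
    if "exp" not in cache:
        cache["exp"] = simulate_experiment(cfg.sim, include_movie=True)
    return cache["exp"]


def _stage_simulate(cfg: PipelineConfig, cache: dict) -> list[Path]:
    exp = _experiment(cfg, cache)
    out = cfg.out_dir
    paths = [
        mio.write_trial_table(exp.trials, out / "trials.tsv"),
        mio.write_features_h5(out / "features_raw.h5", {
            img: layers for img, layers in exp.features.tensors.items()},
            movie=exp.features.movie),
        mio.write_betas_h5(out / "amp_encoding.h5", exp.neural.encoding,
                           exp.neural.encoding_images),
        mio.write_betas_h5(out / "amp_retrieval.h5", exp.neural.retrieval,
                           exp.neural.retrieval_images),
        mio.write_json({
            "subject_lure_skill": exp.truth.subject_lure_skill,
            "behavior_betas": exp.truth.behavior_betas,
            "config": _jsonable(dataclasses.asdict(cfg.sim)),
        }, out / "ground_truth.json"),
    ]
    if exp.neural.movie:
        paths.append(mio.write_betas_h5(out / "amp_movie.h5",
                                        exp.neural.movie))
    return paths


def _stage_features(cfg: PipelineConfig, cache: dict) -> list[Path]:
    exp = _experiment(cfg, cache)
    prepared = exp.features.prepared_by_layer()
    out = cfg.out_dir / "features_prepared.h5"
    import h5py
    with h5py.File(out, "w") as f:
        f.attrs["image_ids"] = exp.features.image_ids
        g = f.create_group("layers")
        for layer, mat in prepared.items():
            g.create_dataset(f"layer{layer}", data=mat, track_times=False)
        mg = f.create_group("movie")
        for layer, mat in exp.features.movie_by_layer().items():
            mg.create_dataset(f"layer{layer}", data=mat, track_times=False)
    return [out]


def _stage_betas(cfg: PipelineConfig, cache: dict) -> list[Path]:
    """Synthesize trial time-series from amplitudes and re-estimate betas."""
    exp = _experiment(cfg, cache)
    rng = cfg.sim.rng("betas_stage")
    times = trial_window_times()
    recall = build_regressor(1.0, 6.0, times, task="recall")
    probe = build_regressor(10.0, 3.0, times, task="probe")
    ret_betas = {}
    for (s, roi), amps in exp.neural.retrieval.items():
        est = np.empty_like(amps)
        for t in range(amps.shape[0]):
            amp = amps[t]
            probe_amp = rng.normal(0.0, 0.5 * (np.std(amp) or 1.0), len(amp))
            series = (np.outer(recall.values, amp)
                      + np.outer(probe.values, probe_amp)
                      + rng.normal(0.0, 0.02, (len(times), len(amp))))
            est[t], _ = estimate_recall_betas(TrialWindow(series), recall, probe)
        ret_betas[(s, roi)] = est
    # encoding runs: overlapping 1.8-s trials on a 2-s grid, LSS re-estimation
    n_per_run = cfg.sim.images_per_run * cfg.sim.reps_per_image
    onsets_run = 10.0 + 3.5 * np.arange(n_per_run)
    run_times = np.arange(0.0, onsets_run[-1] + 34.0, 2.0)
    regs = np.column_stack([
        build_regressor(t0, 1.8, run_times, task="encode").values
        for t0 in onsets_run])
    enc_betas = {}
    for (s, roi), amps in exp.neural.encoding.items():
        est = np.empty_like(amps)
        for run in range(cfg.sim.n_runs_encode):
            sl = slice(run * n_per_run, (run + 1) * n_per_run)
            series = regs @ amps[sl] + rng.normal(
                0.0, 0.02, (len(run_times), amps.shape[1]))
            est[sl] = lss_betas(series, onsets_run, run_times, duration_s=1.8)
        enc_betas[(s, roi)] = est
    out = cfg.out_dir
    paths = [
        mio.write_betas_h5(out / "betas_retrieval.h5", ret_betas,
                           exp.neural.retrieval_images),
        mio.write_betas_h5(out / "betas_encoding.h5", enc_betas,
                           exp.neural.encoding_images),
    ]
    cache["betas_retrieval"], cache["betas_encoding"] = ret_betas, enc_betas
    return paths


def _stage_encode(cfg: PipelineConfig, cache: dict) -> list[Path]:
    from .encoding import fit_encoding_models, make_fold_plan, predict_patterns
    exp = _experiment(cfg, cache)
    prepared = exp.features.prepared_by_layer()
    movie_prep = exp.features.movie_by_layer()
    fold_rng = cfg.sim.rng("folds")
    plan = make_fold_plan(exp.features.image_ids, n_folds=3, rng=fold_rng)
    rois = cfg.encode_rois or exp.config.rois
    enc_betas = cache.get("betas_encoding")
    predictions: dict = {}
    lambdas = {}
    for s in range(exp.config.n_subjects):
        for roi in rois:
            betas = (enc_betas[(s, roi)] if enc_betas is not None
                     else exp.neural.encoding[(s, roi)])
            models = fit_encoding_models(
                prepared, exp.features.image_ids, betas,
                exp.neural.encoding_images[s], plan,
                movie_features=movie_prep,
                movie_activity=exp.neural.movie.get((s, roi)),
                k=100)
            predictions[(s, roi)] = predict_patterns(
                models, prepared, exp.features.image_ids, plan)
            lambdas[f"s{s}:{roi}"] = {
                f"layer{lay}": [m.lambda_ for m in models[lay][0]]
                for lay in models}
    out = cfg.out_dir
    import h5py
    ppath = out / "predictions.h5"
    with h5py.File(ppath, "w") as f:
        for (s, roi), per_layer in predictions.items():
            g = f.require_group(f"subject{s}/roi/{roi}")
            for layer, mat in per_layer.items():
                g.create_dataset(f"layer{layer}", data=mat, track_times=False)
    mio.write_json({"fold_of": {str(k): v for k, v in plan.fold_of.items()},
                    "n_folds": plan.n_folds}, out / "fold_plan.json")
    mio.write_json(lambdas, out / "lambdas.json")
    cache["predictions"] = predictions
    return [ppath, out / "fold_plan.json", out / "lambdas.json"]


def _stage_decode(cfg: PipelineConfig, cache: dict) -> list[Path]:
    exp = _experiment(cfg, cache)
    preds = None
    if cfg.predictions == "models":
        preds = cache.get("predictions")
        if preds is None:
            import h5py
            preds = {}
            with h5py.File(cfg.out_dir / "predictions.h5", "r") as f:
                for sname, sg in f.items():
                    s = int(sname.removeprefix("subject"))
                    for roi, g in sg["roi"].items():
                        preds[(s, roi)] = {
                            int(n.removeprefix("layer")): d[()]
                            for n, d in g.items()}
    table = decode_experiment(exp, model_predictions=preds)
    path = mio.write_reactivation_table(table, cfg.out_dir / "reactivation.tsv")
    cache["reactivation"] = table
    return [path]


def _stage_residualize(cfg: PipelineConfig, cache: dict) -> list[Path]:
    exp = _experiment(cfg, cache)
    table = cache.get("reactivation")
    if table is None:
        table = mio.read_reactivation_table(cfg.out_dir / "reactivation.tsv")
    resid, agg = residualize_standard(table, exp)
    out = cfg.out_dir
    paths = [
        mio.write_reactivation_table(agg, out / "reactivation_agg.tsv"),
        mio.write_reactivation_table(resid, out / "reactivation_resid.tsv"),
    ]
    cache["react_agg"], cache["react_resid"] = agg, resid
    return paths


def _stage_infer(cfg: PipelineConfig, cache: dict) -> list[Path]:
    exp = _experiment(cfg, cache)
    agg = cache.get("react_agg")
    resid = cache.get("react_resid")
    if agg is None:
        agg = mio.read_reactivation_table(cfg.out_dir / "reactivation_agg.tsv")
    if resid is None:
        resid = mio.read_reactivation_table(cfg.out_dir / "reactivation_resid.tsv")
    rng = cfg.sim.rng("inference")
    data, mu, sd = build_model_data(exp.trials, resid)
    fits = run_within_subject_models(data, B=cfg.bootstrap_b, rng=rng)
    raw_data, _, _ = build_model_data(exp.trials, agg)
    from .inference import HC_MEASURES
    bfit = None
    if cfg.sim.n_subjects > len(HC_MEASURES) + 1:
        bfit = run_between_subject_model(raw_data, B=cfg.bootstrap_b, rng=rng)
    results = {"lure_accuracy_mean": mu, "lure_accuracy_sd": sd,
               "bootstrap_b": cfg.bootstrap_b, "models": {}}
    draws_frames = []
    for name, fit in fits.items():
        ci = fit.ci(0.90)
        interactions = [t for t in fit.terms if t.endswith(":lure_acc")
                        and t.count(":") == 1]
        praw = pd.Series({t: fit.pvalues("two")[t] for t in interactions})
        fam = [t for t in interactions if not any(
            t.startswith(f"{roi}_{lvl}") for roi in ("ahc", "phc")
            for lvl in cfg.fdr_exclude)]
        pfdr = fdr_correct(praw, family=list(praw.index),
                           exclude=tuple(t for t in praw.index if t not in fam))
        entry = {
            "coefficients": fit.coefficients.to_dict(),
            "var_subject": fit.var_subject, "var_pair": fit.var_pair,
            "method": fit.method,
            "ci90": {t: [ci.loc[t, "lower"], ci.loc[t, "upper"]]
                     for t in fit.terms},
            "p_two": fit.pvalues("two").to_dict(),
            "p_greater": fit.pvalues("greater").to_dict(),
            "p_fdr_interactions": pfdr.to_dict(),
        }
        if name == "featureHC":
            d, p = paired_difference(fit, "phc_low:lure_acc", "ahc_low:lure_acc")
            entry["phc_minus_ahc_low_interaction"] = {
                "estimate": float(np.mean(d)), "p_greater": p}
            entry["level_average"] = {
                roi: {k: v for k, v in level_average(fit, roi).items()
                      if k != "draws"}
                for roi in ("ahc", "phc")}
            entry["simple_slopes"] = simple_slopes(fit).to_dict("records")
        df = fit.draws.copy()
        df.insert(0, "model", name)
        draws_frames.append(df)
        results["models"][name] = entry
    if bfit is not None:
        results["between_subject"] = {
            "coefficients": bfit.coefficients.to_dict(),
            "p_two": bfit.pvalues("two").to_dict(),
            "ci90": {t: [bfit.ci().loc[t, "lower"], bfit.ci().loc[t, "upper"]]
                     for t in bfit.coefficients.index},
        }
    else:
        results["between_subject"] = {
            "skipped": "needs more subjects than reactivation measures"}
    out = cfg.out_dir
    fpath = mio.write_json(results, out / "fits.json")
    dpath = out / "bootstrap_draws.tsv"
    pd.concat(draws_frames).to_csv(dpath, sep="\t", index=False,
                                   float_format="%.10g")
    return [fpath, dpath]


STAGES: dict[str, dict] = {
    "simulate": {"fn": _stage_simulate, "needs": []},
    "features": {"fn": _stage_features, "needs": ["simulate"]},
    "betas": {"fn": _stage_betas, "needs": ["simulate", "features"]},
    "encode": {"fn": _stage_encode, "needs": ["betas"]},
    "decode": {"fn": _stage_decode, "needs": ["betas"]},
    "residualize": {"fn": _stage_residualize, "needs": ["decode"]},
    "infer": {"fn": _stage_infer, "needs": ["residualize"]},
}


def run_stage(name: str, cfg: PipelineConfig, cache: dict | None = None,
              force: bool = False) -> list[Path]:
    """Run one stage with manifest checks; skip if inputs are unchanged."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}")
    if name == "decode" and cfg.predictions == "models":
        STAGES["decode"]["needs"] = ["betas", "encode"]
    cache = {} if cache is None else cache
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(cfg.out_dir)
    input_hashes: dict[str, str] = {}
    for up in STAGES[name]["needs"]:
        entry = manifest.get(up)
        if entry is None:
            raise RuntimeError(
                f"stage {name!r} needs {up!r}; run `mvreact {up}` first")
        for f, recorded in entry["outputs"].items():
            p = Path(f)
            if not p.exists():
                raise RuntimeError(
                    f"missing upstream output {f} — re-run stage {up!r}")
            actual = _sha256(p)
            if actual != recorded:
                raise RuntimeError(
                    f"hash mismatch for {f} (stage {up!r}): upstream output "
                    "changed or corrupted — re-run it")
            input_hashes[f] = actual
    params = cfg.params_for(name)
    prev = manifest.get(name)
    if (not force and prev and prev["params"] == params
            and prev["inputs"] == input_hashes
            and all(Path(f).exists() and _sha256(Path(f)) == h2
                    for f, h2 in prev["outputs"].items())):
        log.info("stage %s unchanged; skipping", name)
        return [Path(f) for f in prev["outputs"]]
    log.info("running stage %s", name)
    outputs = STAGES[name]["fn"](cfg, cache)
    manifest[name] = {
        "params": params,
        "inputs": input_hashes,
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    _save_manifest(cfg.out_dir, manifest)
    return outputs


def run_all(cfg: PipelineConfig, force: bool = False) -> dict:
    cache: dict = {}
    order = [s for s in STAGES if not cfg.stages or s in cfg.stages]
    if cfg.predictions == "truth" and not cfg.stages:
        order = [s for s in order if s != "encode"]
    for name in order:
        run_stage(name, cfg, cache, force=force)
    return cache


# ----------------------------------------------------------------------- CLI

def _cfg_from_opts(config, seed, out):
    if config:
        return PipelineConfig.from_yaml(config, seed=seed, out_dir=out)
    return PipelineConfig.from_dict({}, seed=seed, out_dir=out)


@click.group()
@click.option("--config", type=click.Path(exists=True), default=None,
              help="YAML pipeline config")
@click.option("--seed", type=int, default=None, help="override RNG seed")
@click.option("--out", type=click.Path(), default=None,
              help="override output directory")
@click.option("--log-level", default="INFO")
@click.pass_context
def cli(ctx, config, seed, out, log_level):
    """Staged synthetic reactivation-decoding pipeline."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    ctx.obj = _cfg_from_opts(config, seed, out)


def _make_stage_command(stage_name):
    @cli.command(name=stage_name)
    @click.option("--force", is_flag=True, help="re-run even if unchanged")
    @click.pass_obj
    def _cmd(cfg, force):
        for up in STAGES[stage_name]["needs"]:
            pass  # dependency checking happens inside run_stage
        run_stage(stage_name, cfg, force=force)
    _cmd.__doc__ = f"Run the {stage_name} stage."
    return _cmd


for _name in STAGES:
    _make_stage_command(_name)


@cli.command()
@click.option("--force", is_flag=True)
@click.pass_obj
def run(cfg, force):
    """Run every configured stage in order."""
    run_all(cfg, force=force)


@cli.command()
@click.pass_obj
def report(cfg):
    """Print a short summary of the fitted models."""
    fits = mio.read_json(cfg.out_dir / "fits.json")
    click.echo(f"bootstrap B = {fits['bootstrap_b']}")
    for name, entry in fits["models"].items():
        click.echo(f"\n[{name}] ({entry['method']})")
        for term, beta in entry["coefficients"].items():
            if term.endswith(":lure_acc"):
                lo, hi = entry["ci90"][term]
                click.echo(f"  {term:40s} beta={beta:+.3f} "
                           f"90% CI [{lo:+.3f}, {hi:+.3f}] "
                           f"p(two)={entry['p_two'][term]:.3f}")
    if "between_subject" in fits:
        click.echo("\n[betweenSubject]")
        for term, beta in fits["between_subject"]["coefficients"].items():
            click.echo(f"  {term:20s} beta={beta:+.4f} "
                       f"p(two)={fits['between_subject']['p_two'][term]:.3f}")
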