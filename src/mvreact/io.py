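"""Round-trippable file formats: TSV event/score tables, HDF5 arrays, JSON fits.

Event tables follow the BIDS convention (onset/duration first, then task
columns).  Floats are written with enough digits that write-then-read is
an identity to 1e-12.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "write_trial_table", "read_trial_table",
    "write_reactivation_table", "read_reactivation_table",
    "write_features_h5", "read_features_h5",
    "write_betas_h5", "read_betas_h5",
    "write_json", "read_json",
]

TRIAL_COLUMNS = ["onset_s", "duration", "subject", "run", "trial", "image_id",
                 "pair_id", "task", "probe_type", "is_lure", "response",
                 "accuracy"]
PROBE_TYPES = {"old", "lure"}

REACT_COLUMNS = ["subject", "trial", "roi", "scale", "adjusted_rank",
                 "residualized"]

_FLOAT_FMT = "%.17g"


def write_trial_table(trials: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing column(s) {missing}")
    bad = set(trials["probe_type"].unique()) - PROBE_TYPES
    if bad:
        raise ValueError(f"invalid probe_type value(s) {sorted(bad)}")
    path = Path(path)
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False,
                                 float_format=_FLOAT_FMT)
    return path


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing column(s) {missing}")
    if len(df):
        bad = set(df["probe_type"].unique()) - PROBE_TYPES
        if bad:
            raise ValueError(f"invalid probe_type value(s) {sorted(bad)}")
    return df


def write_reactivation_table(table: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in REACT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reactivation table missing column(s) {missing}")
    path = Path(path)
    table[REACT_COLUMNS].to_csv(path, sep="\t", index=False,
                                float_format=_FLOAT_FMT)
    return path


def read_reactivation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REACT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"reactivation table missing column(s) {missing}")
    if len(df):
        df["residualized"] = df["residualized"].astype(bool)
    return df


def write_features_h5(path: str | Path, tensors: dict,
                      movie: dict | None = None, grid: int = 3) -> Path:
    """Store per-image layer features at ``/images/{id}/layer{k}``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["grid"] = grid
        images = f.create_group("images")
        for img, layers in tensors.items():
            g = images.create_group(str(img))
            for layer, tensor in layers.items():
                d = g.create_dataset(f"layer{layer}", data=tensor.values,
                                     track_times=False)
                d.attrs["log_transformed"] = bool(tensor.log_transformed)
                d.attrs["pooled"] = bool(tensor.pooled)
        if movie:
            mg = f.create_group("movie")
            for layer, arr in movie.items():
                mg.create_dataset(f"layer{layer}", data=arr, track_times=False)
    return path


def read_features_h5(path: str | Path):
    from .features import FeatureTensor
    tensors: dict = {}
    movie: dict = {}
    with h5py.File(path, "r") as f:
        for img, g in f["images"].items():
            tensors[img] = {}
            for name, d in g.items():
                layer = int(name.removeprefix("layer"))
                tensors[img][layer] = FeatureTensor(
                    image_id=img, layer_id=layer, values=d[()],
                    log_transformed=bool(d.attrs["log_transformed"]),
                    pooled=bool(d.attrs["pooled"]))
        if "movie" in f:
            for name, d in f["movie"].items():
                movie[int(name.removeprefix("layer"))] = d[()]
    return tensors, movie


def write_betas_h5(path: str | Path, betas: dict,
                   trial_images: dict | None = None) -> Path:
    """Store ``(subject, roi) -> trials x vertices`` matrices.

    Layout: ``/subject{s}/roi/{name}/betas`` with the trial image labels
    as an attribute.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        for (s, roi), mat in betas.items():
            g = f.require_group(f"subject{s}/roi/{roi}")
            d = g.create_dataset("betas", data=np.asarray(mat, float),
                                 track_times=False)
            if trial_images is not None:
                d.attrs["trial_images"] = [str(i) for i in trial_images[s]]
    return path


def read_betas_h5(path: str | Path):
    betas: dict = {}
    trial_images: dict = {}
    with h5py.File(path, "r") as f:
        for sname, sg in f.items():
            s = int(sname.removeprefix("subject"))
            for roi, g in sg["roi"].items():
                d = g["betas"]
                betas[(s, roi)] = d[()]
                if "trial_images" in d.attrs:
                    trial_images[s] = [str(x) for x in d.attrs["trial_images"]]
    return betas, trial_images


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
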