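"""Decode reactivation and aggregate ROIs.

Runs the `decode` stage: each retrieval trial's recall pattern is
correlated with the predicted pattern of all candidate images, the
target's descending rank is centered so 0 is chance, per-layer ranks are
averaged into four feature levels, and hemispheres/long-axis sections
are collapsed to aHC, pHC and bilateral cortical ROIs.  Fitted-model
predictions are used where the encode stage produced them; ROIs outside
that set fall back to generative-weight predictions.
"""

from pathlib import Path

from mvreact.decoding import aggregate_rois
from mvreact.pipeline import PipelineConfig, run_stage

HERE = Path(__file__).parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config_demo.yaml")
    cache: dict = {}
    for stage in ("simulate", "features", "betas", "encode", "decode"):
        run_stage(stage, cfg, cache)
    table = cache["reactivation"]
    exp = cache["exp"]

    agg = aggregate_rois(table.drop(columns="residualized"),
                         exp.config.aggregation)
    means = (agg.groupby(["roi", "scale"])["adjusted_rank"].mean()
             .unstack().round(2))
    out = Path("results") / "04_reactivation_by_roi.tsv"
    means.to_csv(out, sep="\t")
    print("mean adjusted rank by ROI and scale (0 = chance):")
    print(means.to_string())
    print(f"\nwritten to {out}")


if __name__ == "__main__":
    main()
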