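"""Fit the within- and between-subject model battery on the demo pipeline.

Runs the `infer` stage: binomial mixed models (crossed subject/pair
random intercepts) of trial accuracy on residualized reactivation and
its lure-accuracy interactions, with parametric-bootstrap CIs/p-values,
FDR over the non-prioritized feature levels, the pHC-aHC paired
difference and +/-1 SD simple slopes.  With only two demo subjects this
is a mechanics demonstration; script 07 runs the properly powered
simulation study.
"""

from pathlib import Path

from mvreact.io import read_json, write_json
from mvreact.pipeline import PipelineConfig, run_stage

HERE = Path(__file__).parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config_demo.yaml")
    cache: dict = {}
    for stage in ("simulate", "features", "betas", "encode", "decode",
                  "residualize", "infer"):
        run_stage(stage, cfg, cache)
    fits = read_json(cfg.out_dir / "fits.json")
    print(f"bootstrap B = {fits['bootstrap_b']}; "
          f"lure-accuracy anchors: mean {fits['lure_accuracy_mean']:.2f}, "
          f"SD {fits['lure_accuracy_sd']:.2f}")
    for name, entry in fits["models"].items():
        print(f"\n[{name}] fitted by {entry['method']}; "
              f"var(subject)={entry['var_subject']:.3f}, "
              f"var(pair)={entry['var_pair']:.3f}")
        for term, beta in entry["coefficients"].items():
            if term.endswith(":lure_acc") and term.count(":") == 1:
                lo, hi = entry["ci90"][term]
                print(f"  {term:28s} beta={beta:+.3f} "
                      f"[{lo:+.3f}, {hi:+.3f}] p={entry['p_two'][term]:.3f}")
    summary = {
        name: {
            "method": entry["method"],
            "interactions": {
                t: {"beta": entry["coefficients"][t],
                    "ci90": entry["ci90"][t],
                    "p_two": entry["p_two"][t]}
                for t in entry["coefficients"]
                if t.endswith(":lure_acc") and t.count(":") == 1},
        }
        for name, entry in fits["models"].items()}
    write_json(summary, Path("results") / "06_inference_summary.json")
    print("\nfull results in", cfg.out_dir / "fits.json")


if __name__ == "__main__":
    main()
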