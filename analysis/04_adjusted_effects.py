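#!/usr/bin/env python
"""The inferential core: per outcome, the baseline-adjusted mixed model,
per-timepoint adjusted between-group contrasts with 90% subject-level BCa
intervals, standardized mean differences and magnitude labels.

Kinematic outcomes pass through the measured chain first (trace synthesis →
landmark extraction → repetition selection), so their table values carry
realistic measurement error.  Compares recovered Post-0/Post-1 estimates
against the effects the generator injected.

Writes results/adjusted_effects.csv and results/run_report.json.
"""

import argparse

import pandas as pd

from judoperf.pipeline import RunConfig, cmd_analyze, cmd_simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out", default="results")
    ap.add_argument("--bootstrap-reps", type=int, default=200,
                    help="BCa replicates per interval (500 reproduces the reference analysis)")
    args = ap.parse_args()

    cfg = RunConfig(seed=args.seed, out_dir=args.out, bootstrap_reps=args.bootstrap_reps)
    data, truth, _ = cmd_simulate(cfg)
    results, report = cmd_analyze(cfg, data=data)
    print(f"{len(results)} adjusted effects -> {cfg.out_dir}/adjusted_effects.csv "
          f"({len(report.warnings)} warnings, {report.elapsed_s:.1f} s)")

    show = results.copy()
    show["injected"] = [
        truth["effects"][r.outcome][f"hypoxia:{r.timepoint}"] for r in results.itertuples()
    ]
    with pd.option_context("display.width", 120):
        print(show.round(3).to_string(index=False))
    print("\nNote: at n = 13/11 single-study estimates scatter around the injected "
          "values; systematic recovery is certified by the acceptance suite at n = 200/group.")


if __name__ == "__main__":
    main()
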