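#!/usr/bin/env python
"""Pre/post coupling statistics for the winning model.

Projects each subject's fitted coupling blocks back to frequency-frequency
maps, smooths them (8 Hz FWHM), and tests post−pre per connection with the
exhaustive sign-flip max-statistic permutation test (FWE over each map).
Lists the significant frequency pairs per connection.
"""

from pathlib import Path

import pandas as pd

from dcmir.pipeline import RunConfig, run_pipeline

HERE = Path(__file__).parent

if __name__ == "__main__":
    cfg = RunConfig.from_yaml(HERE / "demo_config.yaml")
    cfg.stages = ("simulate", "tfr", "fit", "bms", "stats")
    run_dir = run_pipeline(cfg)
    print("injected ground-truth changes (post - pre):")
    for src, tgt, f_out, f_in, delta in cfg.session_effect:
        print(f"  {src} -> {tgt}: {delta:+.1f} 1/s at "
              f"{f_in:.0f} Hz -> {f_out:.0f} Hz")
    sig = pd.read_csv(run_dir / "significant_couplings.csv")
    if len(sig) == 0:
        print("no coupling change survives FWE correction")
    else:
        print(f"{len(sig)} frequency pairs significant at FWE p<{cfg.alpha}:")
        by_conn = sig.groupby(["source", "target"])
        for (src, tgt), grp in by_conn:
            peak = grp.iloc[grp["t"].abs().argmax()]
            print(f"  {src} -> {tgt}: {len(grp)} pairs; strongest at "
                  f"{peak['f_in_hz']:.0f} Hz -> {peak['f_out_hz']:.0f} Hz "
                  f"(t={peak['t']:.1f}, p_fwe={peak['p_fwe']:.4f})")
    print("note: with a single driving input the coupling parameters are "
          "only partly identified, so intervention effects can surface on "
          "correlated connections/frequencies rather than exactly at the "
          "injected pair (see docs/methods.md)")
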