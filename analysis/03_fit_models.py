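#!/usr/bin/env python
"""Invert all 12 candidate models for every subject and session.

Gradient-matching Bayesian inversion of tau*dg/dt = A g + C u per model, with
the noise variance fixed under the fully connected design so log evidences
are comparable across models.  Writes evidence.csv and fits.h5; reports the
cohort-mean variance explained by the fully connected model.
"""

from pathlib import Path

import pandas as pd

from dcmir.pipeline import RunConfig, run_pipeline

HERE = Path(__file__).parent

if __name__ == "__main__":
    cfg = RunConfig.from_yaml(HERE / "demo_config.yaml")
    cfg.stages = ("simulate", "tfr", "fit")
    run_dir = run_pipeline(cfg)
    ev = pd.read_csv(run_dir / "evidence.csv")
    full = ev[ev["model"] == 12]
    print(f"fitted 12 models x {ev['subject'].nunique()} subjects x "
          f"{ev['session'].nunique()} sessions")
    print(f"fully connected model explains "
          f"{100 * full['variance_explained'].mean():.1f}% of the mode-series "
          f"variance on average")
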