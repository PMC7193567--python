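# Demo cohort: 8 virtual subjects, pre/post sessions, one task.
# The post-session ground truth carries two injected coupling changes:
#   - intrinsic iM1 gamma->beta (44 Hz -> 25 Hz) turned more negative,
#   - interhemispheric cM1 -> iM1 gamma-gamma (40 -> 40 Hz) reduced.
out_dir: results/demo_run
seed: 1
level: trials
n_subjects: 8
n_trials: 48
fs: 256.0
snr_db: 10.0
K: 4
alpha: 0.05
task: open
true_model: 12
session_effect:
  - [iM1, iM1, 25.0, 44.0, -0.6]
  - [cM1, iM1, 40.0, 40.0, -0.5]
car_ratios_pre:
  iM1S1: 0.30
  cM1S1: 0.30
  iSMA-PM: 0.20
  cSMA-PM: 0.20
car_ratios_post:
  iM1S1: 0.35
  cM1S1: 0.25
  iSMA-PM: 0.20
  cSMA-PM: 0.20
car_noise_sd: 0.1
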