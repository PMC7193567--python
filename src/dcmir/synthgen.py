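"""Synthetic cohorts with known ground truth for the induced-response analysis.

The generator emulates the statistical structure of a pre/post intervention
EEG study of motor preparation: 8 stroke survivors, two sessions, epoched
source-level trials around EMG onset, induced spectral power driven by a
gamma-shaped premotor input peaking 400 ms before movement, and node-level
current-density maps over the sensorimotor cortex.  Every downstream stage
(wavelet spectrograms, mode reduction, model inversion, model selection,
coupling statistics, CAR) can therefore be validated against known truth.

Ground-truth coupling lives in the frequency domain: per directed connection
a (target-frequency × source-frequency) matrix in 1/s, built from smooth
Gaussian bumps plus intrinsic same-frequency decay, rejection-sampled until
the full system matrix is stable (all eigenvalue real parts negative).
Induced power then obeys  tau * dg/dt = A g + C u  with g = 0 at the start
of the preparation window.

Randomness derives from a single master seed through ``numpy`` seed
sequences, spawned per subject and per trial, so any subset of the cohort is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from dcmir._exceptions import ParameterError, SimulationError
from dcmir.car import SENSORIMOTOR_ROIS, CurrentDensityMap
from dcmir.dcm import ModelSpec, integrate
from dcmir.tfr import DEFAULT_FREQ_GRID, Spectrogram, TrialSet

DEFAULT_EPOCH_WINDOW = (-2200.0, 500.0)
DEFAULT_SIM_WINDOW = (-1000.0, 0.0)


@dataclass
class SimConfig:
    """Cohort-level simulation settings.

    Defaults mirror the study design: 8 subjects, ~48 artifact-free trials
    per condition, 256 Hz sampling, epochs −2200..+500 ms around EMG onset,
    and a 4–48 Hz analysis grid.  ``session_effect`` lists pre→post coupling
    changes as (source_region, target_region, f_out_hz, f_in_hz, delta)
    tuples applied to the post-session ground truth.  ``snr_db`` is the power
    signal-to-noise ratio of the induced response.
    """

    n_subjects: int = 8
    n_trials: int = 48
    fs: float = 256.0
    epoch_window: tuple[float, float] = DEFAULT_EPOCH_WINDOW
    sim_window: tuple[float, float] = DEFAULT_SIM_WINDOW
    snr_db: float = 10.0
    seed: int = 0
    freq_grid: np.ndarray = field(default_factory=lambda: DEFAULT_FREQ_GRID.copy())
    session_effect: list[tuple[str, str, float, float, float]] = field(
        default_factory=list
    )
    dispersion_is_fwhm: bool = False

    def __post_init__(self) -> None:
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if self.n_subjects < 2:
            raise ParameterError("need at least 2 subjects")
        if self.fs < 2.0 * self.freq_grid.max():
            raise ParameterError(
                f"fs={self.fs} below Nyquist for {self.freq_grid.max()} Hz"
            )
        lo, hi = self.epoch_window
        if not (lo <= self.sim_window[0] and hi >= self.sim_window[1]):
            raise ParameterError("epoch window must contain the simulation window")

    def epoch_t_grid(self) -> np.ndarray:
        dt = 1000.0 / self.fs
        n_pre = int(round(-self.epoch_window[0] / dt))
        n_post = int(round(self.epoch_window[1] / dt))
        return dt * np.arange(-n_pre, n_post + 1)

    def sim_t_grid(self) -> np.ndarray:
        t = self.epoch_t_grid()
        lo, hi = self.sim_window
        return t[(t >= lo - 1e-9) & (t <= hi + 1e-9)]


@dataclass
class InputWaveform:
    """Nonnegative, unit-peak driving input on a time grid (ms)."""

    t_grid: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.u.shape != self.t_grid.shape:
            raise ParameterError("u and t_grid must align")


def make_input_waveform(
    t_grid: np.ndarray,
    peak_ms: float = -400.0,
    dispersion_ms: float = 400.0,
    support_start_ms: float = -1000.0,
    dispersion_is_fwhm: bool = False,
) -> InputWaveform:
    """Gamma-shaped input: mode at ``peak_ms``, dispersion ``dispersion_ms``.

    The support starts at the beginning of the preparation window
    (−1000 ms).  Dispersion is interpreted as the standard deviation of the
    gamma density by default (with ``dispersion_is_fwhm`` it is first
    converted via the Gaussian factor 2√(2 ln 2)).  With the defaults the
    shape works out to k = 4, θ = 200 ms.  The waveform is rescaled to unit
    peak on the sampled grid.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if dispersion_ms <= 0:
        raise ParameterError("dispersion must be positive")
    if not (t_grid[0] <= peak_ms <= t_grid[-1]):
        raise ParameterError(f"peak {peak_ms} ms outside time grid")
    if peak_ms <= support_start_ms:
        raise ParameterError("peak must lie after the support start")
    sd = dispersion_ms / (2.0 * np.sqrt(2.0 * np.log(2.0))) if dispersion_is_fwhm \
        else dispersion_ms
    mode = peak_ms - support_start_ms
    # solve (k−1)θ = mode, √k·θ = sd  =>  θ² + mode·θ − sd² = 0
    theta = (-mode + np.sqrt(mode**2 + 4.0 * sd**2)) / 2.0
    k = (sd / theta) ** 2
    x = t_grid - support_start_ms
    u = np.where(x > 0, stats.gamma.pdf(np.maximum(x, 0.0), a=k, scale=theta), 0.0)
    peak = u.max()
    if peak <= 0:
        raise ParameterError("input waveform is identically zero on this grid")
    return InputWaveform(t_grid=t_grid, u=u / peak)


@dataclass
class GroundTruth:
    """True frequency-domain coupling (A), input weights (C) and stability flag.

    ``A_freq`` is (J·F × J·F), block (i, j) coupling power at source
    frequencies of region j onto target frequencies of region i; ``C`` is
    (J·F,), nonzero only for the input region.  tau is fixed at 1 — coupling
    magnitudes absorb the scale.
    """

    model_id: int
    A_freq: np.ndarray
    C: np.ndarray
    freq_grid: np.ndarray
    regions: tuple[str, ...]
    tau: float = 1.0
    stable: bool = True

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def block(self, source: str, target: str) -> np.ndarray:
        F = self.freq_grid.size
        i = self.regions.index(target)
        j = self.regions.index(source)
        return self.A_freq[i * F : (i + 1) * F, j * F : (j + 1) * F]


def _gauss_bump(freq_grid: np.ndarray, f_out: float, f_in: float,
                amp: float, width_hz: float = 3.0) -> np.ndarray:
    fo = np.exp(-0.5 * ((freq_grid - f_out) / width_hz) ** 2)
    fi = np.exp(-0.5 * ((freq_grid - f_in) / width_hz) ** 2)
    return amp * np.outer(fo, fi)


def is_stable(A: np.ndarray, tau: float = 1.0) -> bool:
    return bool(np.max(np.linalg.eigvals(A / tau).real) < 0.0)


def sample_ground_truth(
    model_spec: ModelSpec,
    config: SimConfig,
    seed: int,
    max_tries: int = 50,
    decay_range: tuple[float, float] = (1.0, 2.5),
    bump_amp_range: tuple[float, float] = (0.25, 0.5),
    intrinsic_amp_range: tuple[float, float] = (0.3, 0.6),
    input_amp: float = 1.0,
) -> GroundTruth:
    """Draw a random stable ground truth respecting a model's connection mask.

    Intrinsic blocks get same-frequency decay (negative diagonal) and, when
    the model allows nonlinear intrinsic coupling, a smooth gamma→beta
    cross-frequency bump (high-frequency power driving low-frequency power,
    the regime the movement-preparation literature reports).  Each present
    extrinsic connection gets one bump whose source frequency lies in an
    energetic band (beta or gamma, where the premotor input injects power) so
    that every true connection carries signal.  Draws are rejected until the
    full system matrix has all eigenvalue real parts negative.  Deterministic
    given the seed.
    """
    fgrid = config.freq_grid
    F = fgrid.size
    J = model_spec.n_regions
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ext = model_spec.extrinsic_array()
    for _ in range(max_tries):
        A = np.zeros((J * F, J * F))
        for i in range(J):
            blk = slice(i * F, (i + 1) * F)
            decay = rng.uniform(*decay_range)
            A[blk, blk] -= decay * np.eye(F)
            if model_spec.intrinsic_nonlinear:
                f_in = rng.uniform(34.0, 46.0)   # gamma source
                f_out = rng.uniform(14.0, 30.0)  # beta target
                amp = rng.uniform(*intrinsic_amp_range) * rng.choice([-1.0, 1.0])
                bump = _gauss_bump(fgrid, f_out, f_in, amp)
                np.fill_diagonal(bump, 0.0)  # keep the decay diagonal intact
                A[blk, blk] += bump
        for i in range(J):
            for j in range(J):
                if i == j or not ext[i, j]:
                    continue
                band = rng.choice([0, 1])
                f_in = rng.uniform(18.0, 26.0) if band == 0 else rng.uniform(
                    34.0, 44.0
                )
                f_out = rng.uniform(8.0, 46.0)
                amp = rng.uniform(*bump_amp_range) * rng.choice([-1.0, 1.0])
                A[i * F : (i + 1) * F, j * F : (j + 1) * F] += _gauss_bump(
                    fgrid, f_out, f_in, amp
                )
        if is_stable(A):
            C = np.zeros(J * F)
            jin = model_spec.regions.index(model_spec.input_region)
            # smooth positive input profile with beta- and gamma-band weight
            profile = 0.6 * np.exp(-0.5 * ((fgrid - 22.0) / 6.0) ** 2) + 0.4 * np.exp(
                -0.5 * ((fgrid - 40.0) / 5.0) ** 2
            )
            C[jin * F : (jin + 1) * F] = input_amp * profile
            return GroundTruth(
                model_id=model_spec.model_id,
                A_freq=A,
                C=C,
                freq_grid=fgrid.copy(),
                regions=model_spec.regions,
                stable=True,
            )
    raise SimulationError(f"no stable ground truth in {max_tries} draws")


def apply_session_effect(
    gt: GroundTruth,
    effects: list[tuple[str, str, float, float, float]],
    width_hz: float = 3.0,
) -> GroundTruth:
    """Return a copy of the truth with coupling bumps added (post session)."""
    A = gt.A_freq.copy()
    F = gt.freq_grid.size
    for src, tgt, f_out, f_in, delta in effects:
        i = gt.regions.index(tgt)
        j = gt.regions.index(src)
        A[i * F : (i + 1) * F, j * F : (j + 1) * F] += _gauss_bump(
            gt.freq_grid, f_out, f_in, delta, width_hz
        )
    return replace(gt, A_freq=A, stable=is_stable(A))


def simulate_spectral_dynamics(
    gt: GroundTruth,
    input_waveform: InputWaveform,
    freq_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
) -> Spectrogram:
    """Noise-free induced-power trajectories g(t) per region and frequency.

    Integrates tau*dg/dt = A g + C u from g = 0 at the window start; g is the
    deviation of spectral power from baseline (it may be negative during
    desynchronization).
    """
    if not gt.stable:
        raise SimulationError("ground truth is unstable; refusing to integrate")
    if freq_grid is None:
        freq_grid = gt.freq_grid
    if not np.array_equal(freq_grid, gt.freq_grid):
        raise ParameterError("freq_grid does not match the ground truth grid")
    if t_grid is None:
        t_grid = input_waveform.t_grid
    if not np.array_equal(t_grid, input_waveform.t_grid):
        raise ParameterError("t_grid does not match the input waveform grid")
    g = integrate(gt.A_freq, gt.C, input_waveform.u, t_grid, tau=gt.tau)
    J, F = gt.n_regions, freq_grid.size
    return Spectrogram(
        power=g.reshape(J, F, t_grid.size),
        freq_grid=np.asarray(freq_grid, dtype=float),
        t_grid=np.asarray(t_grid, dtype=float),
        baseline_corrected=True,
        n_trials_used=0,
    )


def default_baseline_power(
    deviation: Spectrogram, margin: float = 0.5, floor_frac: float = 0.2
) -> np.ndarray:
    """A 1/f-shaped baseline guaranteed to keep total power positive.

    Per region and frequency the baseline is the larger of a pink-spectrum
    floor and (1 + margin) times the deepest desynchronization, so
    baseline + g stays ≥ margin-fraction of baseline everywhere.  The floor
    scales with each region's own dynamic range (with a small global
    minimum), keeping induced changes a comparable fraction of ongoing power
    across strongly and weakly driven regions.
    """
    dev = deviation.power
    global_scale = float(np.abs(dev).max())
    if global_scale == 0:
        global_scale = 1.0
    region_scale = np.abs(dev).max(axis=(1, 2))
    region_scale = np.maximum(region_scale, 0.05 * global_scale)
    f = deviation.freq_grid
    pink = floor_frac * region_scale[:, None] * (f.min() / f)[None, :]
    deepest = np.maximum(-dev.min(axis=2), 0.0)
    return np.maximum(pink, (1.0 + margin) * deepest)


def synthesize_trials(
    deviation: Spectrogram,
    baseline_power: np.ndarray,
    config: SimConfig,
    seed: int,
    labels: dict | None = None,
) -> TrialSet:
    """Oscillatory trials whose expected wavelet power tracks baseline + g.

    Each trial is, per region, a sum of narrowband cosines (one per frequency
    of the generating grid) with amplitude √(2·(baseline + g)) and
    independent uniform phases per trial, plus white noise at the configured
    power SNR.  Outside the simulation window the deviation is held at its
    boundary value (zero before, final value after).  A negative total power
    anywhere is a generation error and is reported with its location.
    """
    J, F, _ = deviation.power.shape
    if baseline_power.shape != (J, F):
        raise ParameterError("baseline_power must be (n_regions, n_freqs)")
    t_epoch = config.epoch_t_grid()
    # deviation extended over the whole epoch, held constant at the edges
    dev_full = np.empty((J, F, t_epoch.size))
    for r in range(J):
        for fi in range(F):
            dev_full[r, fi] = np.interp(
                t_epoch, deviation.t_grid, deviation.power[r, fi]
            )
    total_power = baseline_power[:, :, None] + dev_full
    if total_power.min() < 0:
        r, fi, ti = np.unravel_index(np.argmin(total_power), total_power.shape)
        raise SimulationError(
            f"negative total power at region {r}, "
            f"{deviation.freq_grid[fi]:g} Hz, t={t_epoch[ti]:g} ms"
        )
    amplitude = np.sqrt(2.0 * total_power)  # (J, F, T)
    sig_var = total_power.sum(axis=1).mean()  # mean instantaneous signal power
    noise_sd = np.sqrt(sig_var / 10.0 ** (config.snr_db / 10.0))

    phase_arg = 2.0 * np.pi * deviation.freq_grid[None, :, None] * (
        t_epoch[None, None, :] / 1000.0
    )  # (1, F, T)
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(config.n_trials)
    data = np.empty((J, t_epoch.size, config.n_trials))
    for k in range(config.n_trials):
        rng = np.random.default_rng(trial_seeds[k])
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(J, F, 1))
        osc = (amplitude * np.cos(phase_arg + phases)).sum(axis=1)  # (J, T)
        noise = noise_sd * rng.standard_normal((J, t_epoch.size))
        data[:, :, k] = osc + noise
    return TrialSet(
        data=data, fs=config.fs, t_grid=t_epoch, labels=dict(labels or {})
    )


def simulate_subject_session(
    gt: GroundTruth, config: SimConfig, seed: int, labels: dict | None = None
) -> TrialSet:
    """Full forward chain for one subject/session: truth → g → trials."""
    t_sim = config.sim_t_grid()
    wave = make_input_waveform(
        t_sim,
        support_start_ms=config.sim_window[0],
        dispersion_is_fwhm=config.dispersion_is_fwhm,
    )
    dev = simulate_spectral_dynamics(gt, wave)
    baseline = default_baseline_power(dev)
    return synthesize_trials(dev, baseline, config, seed, labels=labels)


def wavelet_matched_noise(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    freq_grid: np.ndarray,
    fs: float,
    n_cycles: int = 7,
) -> np.ndarray:
    """Unit-variance spectral noise with realistic temporal autocorrelation.

    Trial-averaged wavelet power is smooth in time because the wavelet
    integrates over ~n_cycles/f seconds; white noise per time sample would be
    unrealistically harsh.  Gaussian noise is therefore filtered along the
    time axis with the wavelet's envelope width σ_t = n_cycles/(2πf) per
    frequency, then rescaled back to unit marginal variance.
    """
    from scipy.ndimage import gaussian_filter1d

    z = rng.standard_normal(shape)
    out = np.empty_like(z)
    for fi, f in enumerate(np.asarray(freq_grid, dtype=float)):
        sigma = n_cycles / (2.0 * np.pi * f) * fs  # samples
        filt = gaussian_filter1d(z[..., fi, :], sigma=sigma, axis=-1,
                                 mode="reflect")
        x = np.arange(-int(4 * sigma), int(4 * sigma) + 1)
        k = np.exp(-0.5 * (x / sigma) ** 2)
        k /= k.sum()
        out[..., fi, :] = filt / np.sqrt((k**2).sum())
    return out


def _draw_subject_truth(
    model_spec: ModelSpec,
    config: SimConfig,
    seed_seq: np.random.SeedSequence,
    max_tries: int = 50,
) -> tuple[GroundTruth, GroundTruth]:
    """Subject truth plus its post-session variant, jointly stable."""
    for child in seed_seq.spawn(max_tries):
        gt = sample_ground_truth(
            model_spec, config, seed=child.generate_state(1)[0] % (2**31)
        )
        gt_post = (
            apply_session_effect(gt, config.session_effect)
            if config.session_effect
            else gt
        )
        if gt.stable and gt_post.stable:
            return gt, gt_post
    raise SimulationError(
        f"no jointly stable pre/post truth in {max_tries} draws"
    )


def simulate_cohort_spectra(
    model_spec: ModelSpec,
    config: SimConfig,
    seed: int | None = None,
    sessions: tuple[str, ...] = ("pre", "post"),
    task: str = "open",
) -> tuple[list[Spectrogram], dict[int, GroundTruth]]:
    """Spectral-level cohort: noisy induced-power spectrograms per subject/session.

    Skips the oscillatory-trial and wavelet stages: the noise-free deviation
    g(t) gets additive Gaussian spectral noise at ``config.snr_db`` (power
    signal-to-noise) with the temporal autocorrelation a 7-cycle wavelet
    estimate would have.  Subject-specific truths are drawn from the same model;
    ``config.session_effect`` perturbs the post-session truth.  Returns the
    spectrograms and the per-subject ground truths.
    """
    master = config.seed if seed is None else seed
    subj_seeds = np.random.SeedSequence(master).spawn(config.n_subjects)
    t_sim = config.sim_t_grid()
    wave = make_input_waveform(
        t_sim,
        support_start_ms=config.sim_window[0],
        dispersion_is_fwhm=config.dispersion_is_fwhm,
    )
    specs: list[Spectrogram] = []
    truths: dict[int, GroundTruth] = {}
    for s, sseq in enumerate(subj_seeds):
        child = sseq.spawn(1 + len(sessions))
        gt, gt_post = _draw_subject_truth(model_spec, config, child[0])
        truths[s] = gt
        for j, session in enumerate(sessions):
            gt_s = gt_post if session == "post" else gt
            dev = simulate_spectral_dynamics(gt_s, wave)
            rng = np.random.default_rng(child[1 + j])
            sig_rms = float(np.sqrt((dev.power**2).mean()))
            noise_sd = sig_rms / 10.0 ** (config.snr_db / 20.0)
            noise = wavelet_matched_noise(
                rng, dev.power.shape, dev.freq_grid, config.fs
            )
            noisy = dev.power + noise_sd * noise
            specs.append(
                Spectrogram(
                    power=noisy,
                    freq_grid=dev.freq_grid.copy(),
                    t_grid=dev.t_grid.copy(),
                    baseline_corrected=True,
                    n_trials_used=config.n_trials,
                    labels={"subject": s, "session": session, "task": task},
                )
            )
    return specs, truths


def simulate_cohort_trials(
    model_spec: ModelSpec,
    config: SimConfig,
    seed: int | None = None,
    sessions: tuple[str, ...] = ("pre", "post"),
    task: str = "open",
) -> tuple[list[TrialSet], dict[int, GroundTruth]]:
    """Trial-level cohort: oscillatory epochs per subject/session (full chain)."""
    master = config.seed if seed is None else seed
    subj_seeds = np.random.SeedSequence(master).spawn(config.n_subjects)
    trial_sets: list[TrialSet] = []
    truths: dict[int, GroundTruth] = {}
    for s, sseq in enumerate(subj_seeds):
        child = sseq.spawn(1 + len(sessions))
        gt, gt_post = _draw_subject_truth(model_spec, config, child[0])
        truths[s] = gt
        for j, session in enumerate(sessions):
            gt_s = gt_post if session == "post" else gt
            labels = {"subject": s, "session": session, "task": task}
            trial_sets.append(
                simulate_subject_session(
                    gt_s, config, seed=child[1 + j].generate_state(1)[0] % (2**31),
                    labels=labels,
                )
            )
    return trial_sets, truths


DEFAULT_NODES_PER_ROI = {roi: 100 for roi in SENSORIMOTOR_ROIS}


def simulate_current_density(
    roi_partition: dict[str, int] | None = None,
    target_ratios: dict[str, float] | None = None,
    noise_sd: float = 0.1,
    n_subjects: int = 8,
    seed: int = 0,
    session: str = "pre",
    task: str = "open",
    node_spacing_mm: float = 3.0,
) -> list[CurrentDensityMap]:
    """Node-strength maps whose expected per-ROI share equals ``target_ratios``.

    Each ROI holds ``roi_partition[roi]`` nodes of equal base strength
    (ratio / node count); per subject every node is multiplied by i.i.d.
    lognormal noise with unit mean and coefficient of variation ≈ noise_sd.
    Node coordinates are laid out on a ``node_spacing_mm`` grid as metadata.
    """
    if roi_partition is None:
        roi_partition = dict(DEFAULT_NODES_PER_ROI)
    if target_ratios is None:
        target_ratios = {roi: 1.0 / len(roi_partition) for roi in roi_partition}
    if set(target_ratios) != set(roi_partition):
        raise ParameterError("target_ratios and roi_partition must share ROIs")
    vals = np.array([target_ratios[r] for r in roi_partition])
    if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-9:
        raise ParameterError("target ratios must be nonnegative and sum to 1")
    rois = list(roi_partition)
    node_roi = np.concatenate(
        [np.full(roi_partition[r], r, dtype=object) for r in rois]
    )
    base = np.concatenate(
        [np.full(roi_partition[r], target_ratios[r] / roi_partition[r]) for r in rois]
    )
    xyz = []
    for ri, r in enumerate(rois):
        n = roi_partition[r]
        side = int(np.ceil(np.sqrt(n)))
        ix = np.arange(n)
        xyz.append(
            np.column_stack(
                [
                    node_spacing_mm * (ix % side) + 100.0 * ri,
                    node_spacing_mm * (ix // side),
                    np.full(n, 60.0),
                ]
            )
        )
    xyz = np.concatenate(xyz)
    subj_seeds = np.random.SeedSequence(seed).spawn(n_subjects)
    maps = []
    for s, sseq in enumerate(subj_seeds):
        rng = np.random.default_rng(sseq)
        if noise_sd > 0:
            sigma = np.sqrt(np.log1p(noise_sd**2))
            factor = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma,
                                   size=base.size)
        else:
            factor = np.ones_like(base)
        maps.append(
            CurrentDensityMap(
                node_strength=base * factor,
                node_roi=node_roi.copy(),
                labels={"subject": s, "session": session, "task": task},
                node_xyz=xyz.copy(),
            )
        )
    return maps
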