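"""Time-frequency preprocessing: Morlet spectrograms, baseline correction, SVD modes.

Epoched source-level trials are transformed with a 7-cycle Morlet wavelet,
averaged over trials, cropped to the motor-preparation window (−1000..0 ms),
baseline-corrected against the earliest sixth of that window, and reduced to a
small number of frequency modes by singular value decomposition.  The mode
series ``g`` (and its time derivative) are the states of the spectral
dynamical model fitted in :mod:`dcmir.dcm`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from mne.time_frequency import tfr_array_morlet

from dcmir._exceptions import ParameterError

DEFAULT_FREQ_GRID = np.arange(4.0, 49.0, 1.0)  # 4–48 Hz, 1 Hz steps
DEFAULT_BASELINE_WINDOW = (-1000.0, -833.0)
DEFAULT_CROP_WINDOW = (-1000.0, 0.0)


@dataclass
class TrialSet:
    """Epoched source time series, aligned to EMG onset (t = 0 ms).

    data has shape (n_sources, n_times, n_trials); t_grid is in ms with a
    uniform step of 1000/fs and must contain 0 ms.
    """

    data: np.ndarray
    fs: float
    t_grid: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("TrialSet.data must be (sources, times, trials)")
        if self.t_grid.shape[0] != self.data.shape[1]:
            raise ParameterError("t_grid length must match data time axis")
        step = np.diff(self.t_grid)
        if step.size and not np.allclose(step, 1000.0 / self.fs, rtol=1e-6):
            raise ParameterError("t_grid step must equal 1000/fs")
        if not (self.t_grid[0] <= 0.0 <= self.t_grid[-1]):
            raise ParameterError("EMG onset (0 ms) must lie inside t_grid")

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.t_grid)))


@dataclass
class Spectrogram:
    """Trial-averaged power, (n_sources, n_freqs, n_times)."""

    power: np.ndarray
    freq_grid: np.ndarray
    t_grid: np.ndarray
    baseline_corrected: bool = False
    n_trials_used: int = 0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        self.t_grid = np.asarray(self.t_grid, dtype=float)
        if self.power.shape[1] != self.freq_grid.size:
            raise ParameterError("power frequency axis does not match freq_grid")
        if self.power.shape[2] != self.t_grid.size:
            raise ParameterError("power time axis does not match t_grid")

    @property
    def n_sources(self) -> int:
        return self.power.shape[0]


@dataclass
class TrialSpectrograms:
    """Per-trial wavelet power, (n_trials, n_sources, n_freqs, n_times).

    ``edge_valid[f, t]`` is False where sample t lies within half a wavelet
    length of the epoch edge at frequency f (edge-contaminated estimates).
    """

    power: np.ndarray
    freq_grid: np.ndarray
    t_grid: np.ndarray
    fs: float
    edge_valid: np.ndarray
    labels: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.power.shape[0]


@dataclass
class ModeBasis:
    """Orthonormal frequency-mode loadings, (n_freqs, K)."""

    V: np.ndarray
    variance_preserved: float
    singular_values: np.ndarray
    freq_grid: np.ndarray

    @property
    def K(self) -> int:
        return self.V.shape[1]


@dataclass
class ModeSeries:
    """Mode-power trajectories g and their derivative dg, ((n_sources*K), n_times).

    Rows are source-major: row r*K + k is mode k of source r.  dg is in
    power units per second, estimated from the lightly smoothed trajectories
    ``g_smooth`` (smoothing is linear, so the dynamical relation between
    smoothed states, smoothed input, and their derivative is preserved);
    ``smooth_window`` is the moving-average width in samples.
    """

    g: np.ndarray
    dg: np.ndarray
    t_grid: np.ndarray
    n_sources: int
    K: int
    g_smooth: np.ndarray | None = None
    smooth_window: int = 1
    labels: dict = field(default_factory=dict)


def morlet_power(
    trials: TrialSet,
    freq_grid: np.ndarray = DEFAULT_FREQ_GRID,
    wavelet_number: int = 7,
) -> TrialSpectrograms:
    """Per-trial squared-magnitude Morlet wavelet transform.

    Uses a fixed number of cycles (default 7) at every frequency.  Power is
    calibrated so a sinusoid of amplitude a yields a²/2 (its mean power) at
    its own frequency, independent of frequency — undoing the 1/f scale of
    L2-normalized wavelets.  Frequencies must stay below the Nyquist rate;
    samples closer to an epoch edge than half the wavelet length are flagged
    in ``edge_valid``.
    """
    freq_grid = np.asarray(freq_grid, dtype=float)
    if wavelet_number < 3:
        raise ParameterError("wavelet_number must be >= 3")
    if freq_grid.max() * 2.0 > trials.fs:
        raise ParameterError(
            f"max frequency {freq_grid.max()} Hz above Nyquist ({trials.fs / 2} Hz)"
        )
    # mne expects (n_epochs, n_channels, n_times)
    data = np.moveaxis(trials.data, 2, 0)
    # zero-pad so the longest wavelet (lowest frequency) fits the epoch
    sigma_t = wavelet_number / (2.0 * np.pi * freq_grid.min())
    wavelet_len = int(np.ceil(10.0 * sigma_t * trials.fs)) + 2
    n_times = data.shape[2]
    pad = max(0, (wavelet_len - n_times) // 2 + 1)
    if pad:
        data = np.pad(data, ((0, 0), (0, 0), (pad, pad)))
    power = tfr_array_morlet(
        data,
        sfreq=trials.fs,
        freqs=freq_grid,
        n_cycles=wavelet_number,
        output="power",
        zero_mean=True,
    )
    if pad:
        power = power[..., pad:-pad]
    # amplitude calibration: unit sinusoid -> power 1/2 at every frequency
    calib = freq_grid * np.sqrt(np.pi) / (trials.fs * wavelet_number)
    power = power * calib[None, None, :, None]
    half_len_ms = 1000.0 * wavelet_number / (2.0 * freq_grid)
    t = trials.t_grid
    edge_valid = (t[None, :] - t[0] >= half_len_ms[:, None]) & (
        t[-1] - t[None, :] >= half_len_ms[:, None]
    )
    return TrialSpectrograms(
        power=power,
        freq_grid=freq_grid,
        t_grid=t.copy(),
        fs=trials.fs,
        edge_valid=edge_valid,
        labels=dict(trials.labels),
    )


def _window_mask(t_grid: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < t_grid[0] - 1e-9 or hi > t_grid[-1] + 1e-9:
        raise ParameterError(f"window {window} outside time grid "
                             f"[{t_grid[0]}, {t_grid[-1]}] ms")
    return (t_grid >= lo - 1e-9) & (t_grid <= hi + 1e-9)


def average_baseline_crop(
    stack: TrialSpectrograms,
    baseline_window: tuple[float, float] = DEFAULT_BASELINE_WINDOW,
    crop_window: tuple[float, float] = DEFAULT_CROP_WINDOW,
) -> Spectrogram:
    """Trial-average, subtract the per-frequency baseline mean, crop in time.

    The baseline is the mean power over ``baseline_window`` of the
    trial-averaged spectrogram, computed per source and frequency.
    """
    if stack.n_trials < 1:
        raise ParameterError("need at least one trial")
    mean_power = stack.power.mean(axis=0)  # (sources, freqs, times)
    base_mask = _window_mask(stack.t_grid, baseline_window)
    crop_mask = _window_mask(stack.t_grid, crop_window)
    baseline = mean_power[:, :, base_mask].mean(axis=2, keepdims=True)
    corrected = mean_power - baseline
    return Spectrogram(
        power=corrected[:, :, crop_mask],
        freq_grid=stack.freq_grid.copy(),
        t_grid=stack.t_grid[crop_mask],
        baseline_corrected=True,
        n_trials_used=stack.n_trials,
        labels=dict(stack.labels),
    )


def fit_modes(specs: list[Spectrogram], K: int = 4) -> ModeBasis:
    """Shared SVD frequency basis over a collection of spectrograms.

    Spectrograms are concatenated along (source × time × condition) so one
    basis serves every region and condition, which keeps coupling parameters
    comparable across regions.  The sign of each loading column is fixed by
    making its largest-magnitude element positive.
    """
    if not specs:
        raise ParameterError("empty spectrogram collection")
    freq_grid = specs[0].freq_grid
    for s in specs[1:]:
        if not np.array_equal(s.freq_grid, freq_grid):
            raise ParameterError("all spectrograms must share freq_grid")
    if K > freq_grid.size:
        raise ParameterError(f"K={K} exceeds number of frequencies {freq_grid.size}")
    X = np.concatenate(
        [s.power.transpose(1, 0, 2).reshape(freq_grid.size, -1) for s in specs],
        axis=1,
    )
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size else 0
    if K > rank:
        import warnings

        warnings.warn(f"K={K} exceeds data rank {rank}; reducing", stacklevel=2)
        K = max(rank, 1)
    V = U[:, :K].copy()
    # deterministic sign: largest-|loading| entry of each column positive
    for k in range(K):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    total = float((sv**2).sum())
    kept = float((sv[:K] ** 2).sum())
    return ModeBasis(
        V=V,
        variance_preserved=kept / total if total > 0 else 1.0,
        singular_values=sv.copy(),
        freq_grid=freq_grid.copy(),
    )


def project_modes(
    spec: Spectrogram, basis: ModeBasis, smoothing_ms: float = 12.0
) -> ModeSeries:
    """Project a spectrogram onto the mode basis and estimate the derivative.

    g = Vᵀ·power per source.  dg is obtained by central differences on a
    lightly smoothed copy of g (moving average of width ``smoothing_ms``),
    one-sided at the endpoints, in power units per second.
    """
    if not np.array_equal(spec.freq_grid, basis.freq_grid):
        raise ParameterError("spectrogram and basis frequency grids differ")
    n_src, _, n_t = spec.power.shape
    K = basis.K
    g = np.einsum("fk,sft->skt", basis.V, spec.power).reshape(n_src * K, n_t)
    dt_s = (spec.t_grid[1] - spec.t_grid[0]) / 1000.0
    win = max(1, int(round(smoothing_ms / (1000.0 * dt_s))))
    if win % 2 == 0:
        win += 1
    gs = moving_average(g, win)
    dg = np.gradient(gs, dt_s, axis=1)
    return ModeSeries(
        g=g, dg=dg, t_grid=spec.t_grid.copy(), n_sources=n_src, K=K,
        g_smooth=gs, smooth_window=win, labels=dict(spec.labels),
    )


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Edge-padded moving average along the last axis (identity for window 1)."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="edge")
    return np.apply_along_axis(lambda r: np.convolve(r, kernel, "valid"), -1, xp)


def back_project(series_g: np.ndarray, basis: ModeBasis, n_sources: int) -> np.ndarray:
    """Map mode trajectories back to the frequency domain, (sources, freqs, times)."""
    K = basis.K
    g = series_g.reshape(n_sources, K, -1)
    return np.einsum("fk,skt->sft", basis.V, g)


def wavelet_resolution_blur(
    spec: Spectrogram, wavelet_number: int = 7
) -> Spectrogram:
    """Blur a spectrogram to the resolution of the Morlet estimator.

    A fixed-cycle Morlet wavelet estimates power with spectral bandwidth
    σ_f = f / n_cycles and temporal width σ_t = n_cycles / (2πf).  Applying
    the equivalent Gaussian blur to a model spectrogram gives the quantity
    the wavelet transform can actually recover, which is the fair reference
    when checking reconstruction fidelity.
    """
    from scipy.ndimage import gaussian_filter1d

    f = spec.freq_grid
    dt_ms = float(np.diff(spec.t_grid).mean())
    out = np.empty_like(spec.power)
    for fi, freq in enumerate(f):
        sigma_f = freq / wavelet_number  # Hz
        row = np.exp(-0.5 * ((f - freq) / sigma_f) ** 2)
        row /= row.sum()
        blurred = np.einsum("g,sgt->st", row, spec.power)
        sigma_t = wavelet_number / (2.0 * np.pi * freq) * 1000.0 / dt_ms
        out[:, fi, :] = gaussian_filter1d(blurred, sigma=sigma_t, axis=-1,
                                          mode="nearest")
    return replace(spec, power=out)


def baseline_correct(spec: Spectrogram,
                     baseline_window: tuple[float, float]) -> Spectrogram:
    """Subtract the per-frequency mean over ``baseline_window`` (idempotent)."""
    mask = _window_mask(spec.t_grid, baseline_window)
    baseline = spec.power[:, :, mask].mean(axis=2, keepdims=True)
    return replace(spec, power=spec.power - baseline, baseline_corrected=True)
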