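"""Frequency-domain coupling maps and pre/post inference with FWE control.

Fitted mode-space coupling blocks are projected back to the frequency domain
(V·A_block·Vᵀ), giving, per directed connection, a matrix of coupling
strengths from power at an input frequency (columns) to power at an output
frequency (rows), in 1/s.  Per-subject maps are smoothed with an 8-Hz-FWHM
Gaussian kernel and compared pre vs post with a paired t-test at every
frequency pair; family-wise error over the map is controlled by the
max-statistic sign-flip permutation distribution (exhaustive for small n).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from math import factorial

import numpy as np
from scipy import ndimage, stats

from dcmir._exceptions import ParameterError
from dcmir.dcm import DCMFit
from dcmir.tfr import ModeBasis

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass
class CouplingMap:
    """Coupling of one directed connection as a frequency × frequency matrix.

    ``values[f_out, f_in]`` is the influence of power at f_in in the source
    region on power at f_out in the target region (1/s); positive entries mean
    same-direction power changes.
    """

    values: np.ndarray
    freq_grid: np.ndarray
    connection: tuple[str, str]  # (source, target)
    smoothed: bool = False
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        F = self.freq_grid.size
        if self.values.shape != (F, F):
            raise ParameterError("coupling map must be square in |freq_grid|")


@dataclass
class StatMap:
    """Paired-comparison statistics over one connection's frequency pairs."""

    t_values: np.ndarray
    p_fwe: np.ndarray
    fwe_threshold: float
    significant: np.ndarray
    alpha: float
    n_permutations: int
    exhaustive: bool
    connection: tuple[str, str] | None = None
    freq_grid: np.ndarray | None = None


def coupling_to_frequency(fit: DCMFit, basis: ModeBasis) -> dict[tuple[str, str], CouplingMap]:
    """Project every region-pair coupling block back to the frequency domain."""
    K = basis.K
    if fit.K != K:
        raise ParameterError(f"fit has K={fit.K}, basis has K={K}")
    V = basis.V
    maps: dict[tuple[str, str], CouplingMap] = {}
    for i, tgt in enumerate(fit.regions):
        for j, src in enumerate(fit.regions):
            block = fit.A[i * K : (i + 1) * K, j * K : (j + 1) * K]
            maps[(src, tgt)] = CouplingMap(
                values=V @ block @ V.T,
                freq_grid=basis.freq_grid.copy(),
                connection=(src, tgt),
                labels=dict(fit.labels),
            )
    return maps


def _gaussian_kernel_2d(sigma: float) -> np.ndarray:
    """Sampled 2-D Gaussian kernel truncated at 3σ, normalized to sum 1."""
    radius = max(1, int(np.ceil(3.0 * sigma)))
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-0.5 * (x / sigma) ** 2)
    k2 = np.outer(k1, k1)
    return k2 / k2.sum()


def smooth_map(cmap: CouplingMap, fwhm_hz: float = 8.0) -> CouplingMap:
    """Smooth with a 2-D Gaussian (FWHM in Hz), kernel renormalized at edges.

    σ = FWHM / (2√(2 ln 2)) converted to grid units.  Near the map edges the
    kernel is renormalized over the in-map support so a constant map stays
    exactly constant.
    """
    if cmap.smoothed:
        warnings.warn("coupling map is already smoothed", stacklevel=2)
    df = float(np.diff(cmap.freq_grid).mean())
    sigma = fwhm_hz / FWHM_TO_SIGMA / df
    kernel = _gaussian_kernel_2d(sigma)
    num = ndimage.convolve(cmap.values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(cmap.values), kernel, mode="constant",
                           cval=0.0)
    return replace(cmap, values=num / den, smoothed=True)


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 of (n, ...) differences; 0/0 mapped to t=0."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        signed_inf = np.sign(mean) * np.inf
    t = np.where(sd == 0, np.where(mean == 0, 0.0, signed_inf), t)
    return t


def paired_permutation_test(
    pre: list[CouplingMap] | np.ndarray,
    post: list[CouplingMap] | np.ndarray,
    alpha: float = 0.05,
    n_permutations: int = 4096,
    seed: int | None = None,
    exhaustive_limit: int = 4096,
) -> StatMap:
    """Max-statistic sign-flip permutation test on paired (post − pre) maps.

    The per-pair statistic is the paired t on subject differences.  The null
    distribution of the map-wise maximum |t| is built by flipping the signs of
    whole subjects — exhaustively over all 2ⁿ patterns when 2ⁿ ≤
    ``exhaustive_limit`` (256 patterns at n = 8), otherwise by seeded Monte
    Carlo.  ``p_fwe`` of a pair is the fraction of flip patterns whose maximum
    |t| reaches that pair's observed |t|; pairs with p_fwe ≤ alpha are
    significant, equivalently |t| ≥ ``fwe_threshold``.
    """
    def stack(maps):
        if isinstance(maps, np.ndarray):
            return maps
        return np.stack([m.values for m in maps])

    connection = None
    freq_grid = None
    if not isinstance(pre, np.ndarray) and len(pre) > 0:
        connection = pre[0].connection
        freq_grid = pre[0].freq_grid
        subj_pre = [m.labels.get("subject") for m in pre]
        subj_post = [m.labels.get("subject") for m in post]
        if subj_pre != subj_post:
            raise ParameterError(f"subject mismatch: {subj_pre} vs {subj_post}")
    d = stack(post) - stack(pre)
    n = d.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 subjects")
    flat = d.reshape(n, -1)
    t_obs = _paired_t(flat)

    exhaustive = 2**n <= exhaustive_limit
    if exhaustive:
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_permutations, n))
    max_t = np.empty(signs.shape[0])
    for b, s in enumerate(signs):
        tb = _paired_t(flat * s[:, None])
        max_t[b] = np.nanmax(np.abs(tb))
    n_perm = signs.shape[0]

    abs_t = np.abs(t_obs)
    # tail counts of the max-|t| null at each observed |t|
    sorted_max = np.sort(max_t)
    p_fwe = 1.0 - np.searchsorted(sorted_max, abs_t - 1e-12, side="left") / n_perm
    significant = p_fwe <= alpha
    # smallest null value whose tail probability is <= alpha
    tail = 1.0 - np.searchsorted(sorted_max, sorted_max - 1e-12, side="left") / n_perm
    ok = sorted_max[tail <= alpha]
    fwe_threshold = float(ok.min()) if ok.size else np.inf

    shape = d.shape[1:]
    return StatMap(
        t_values=t_obs.reshape(shape),
        p_fwe=p_fwe.reshape(shape),
        fwe_threshold=fwe_threshold,
        significant=significant.reshape(shape),
        alpha=alpha,
        n_permutations=n_perm,
        exhaustive=exhaustive,
        connection=connection,
        freq_grid=freq_grid,
    )


def spearman_link(
    delta_stat: np.ndarray,
    delta_coupling: np.ndarray,
    exact: bool = True,
) -> tuple[float, float]:
    """Spearman rank correlation between two per-subject change scores.

    For n ≤ 8 and ``exact=True`` the two-sided p-value is computed by
    exhaustive permutation of one vector (n! ≤ 40320 rank orders); otherwise
    the t-distribution approximation is used.  Ties are handled by midranks;
    a constant vector has no defined rank correlation and raises an error.
    """
    x = np.asarray(delta_stat, dtype=float)
    y = np.asarray(delta_coupling, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ParameterError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("constant vector: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact and n <= 8:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rho_perm = (rxc[perms] @ ryc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        assert perms.shape[0] == factorial(n)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p
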