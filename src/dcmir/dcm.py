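"""Spectral-dynamics DCM: model space, integration, and Bayesian inversion.

The generative model for induced responses is the linear dynamical system

    tau * dg/dt = A g(t) + C u(t)

where g stacks the spectral power states (frequency modes) of all regions,
A holds the within- and between-region coupling parameters (1/s), C the
weights of the driving input u(t) (the gamma-shaped premotor drive from SMA),
and tau is a scale factor fixed at 1 (it is not identifiable jointly with the
scale of A and C).

Linear coupling is within-mode (diagonal of a K×K block); nonlinear
(cross-frequency) coupling occupies the off-diagonal entries.  The model
space comprises 12 models over 5 motor regions: group 1 (models 1–6)
restricts intrinsic (within-region) coupling to linear terms, group 2
(models 7–12) allows nonlinear intrinsic coupling; within each group five
reduced variants drop one or two premotor efferents and the sixth is fully
connected.

Inversion is Bayesian gradient matching: because dg/dt is linear in (A, C)
given g and u, each state row is a Bayesian linear regression with Gaussian
priors, yielding closed-form posteriors and log model evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from dcmir._exceptions import ParameterError, UnstableSystemError
from dcmir.tfr import ModeBasis, ModeSeries

REGIONS = ("iM1", "cM1", "iPM", "cPM", "SMA")
#: MNI coordinates of the motor network nodes (Human Motor Area Template).
#: The ipsilesional hemisphere is the left one by convention.
MNI_COORDINATES = {
    "iM1": (-37, -26, 60),
    "cM1": (37, -26, 60),
    "iPM": (-35, -4, 60),
    "cPM": (35, -4, 60),
    "SMA": (-2, -7, 60),
}
INPUT_REGION = "SMA"

#: Connections removed from the fully connected graph in the five reduced
#: variants of each model group.  Each entry is a tuple of (source, target)
#: directed region pairs dropped from that variant; all removals take efferents
#: of a premotor area (to the other PM or to an M1).
DEFAULT_REDUCED_PATTERNS: tuple[tuple[tuple[str, str], ...], ...] = (
    (("iPM", "cPM"),),
    (("cPM", "iPM"),),
    (("iPM", "iM1"), ("iPM", "cPM")),
    (("cPM", "cM1"), ("cPM", "iPM")),
    (("iPM", "cM1"), ("cPM", "iM1")),
)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate connectivity model.

    ``extrinsic_mask[i, j]`` is True when region j sends a connection to
    region i (target-row convention).  All models keep the five intrinsic
    self-connections; ``intrinsic_nonlinear`` decides whether those may couple
    across frequencies.
    """

    model_id: int
    regions: tuple[str, ...]
    extrinsic_mask: tuple[tuple[bool, ...], ...]
    intrinsic_nonlinear: bool
    extrinsic_nonlinear: bool = True
    input_region: str = INPUT_REGION
    coordinates: tuple[tuple[int, int, int], ...] = tuple(
        MNI_COORDINATES[r] for r in REGIONS
    )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def extrinsic_array(self) -> np.ndarray:
        return np.array(self.extrinsic_mask, dtype=bool)

    def connection_present(self, source: str, target: str) -> bool:
        i = self.regions.index(target)
        j = self.regions.index(source)
        if i == j:
            return True
        return bool(self.extrinsic_mask[i][j])


def enumerate_model_space(
    reduced_patterns: tuple[tuple[tuple[str, str], ...], ...] | None = None,
) -> list[ModelSpec]:
    """Enumerate the 12-model space.

    Models 1–5 and 7–11 are the reduced variants (missing premotor
    efferents), models 6 and 12 are fully connected; models 1–6 restrict
    intrinsic coupling to linear (within-frequency) terms, models 7–12 allow
    nonlinear intrinsic coupling.  The reduced patterns are configurable.
    """
    if reduced_patterns is None:
        reduced_patterns = DEFAULT_REDUCED_PATTERNS
    if len(reduced_patterns) != 5:
        raise ParameterError("expected exactly 5 reduced-variant patterns")
    J = len(REGIONS)
    specs: list[ModelSpec] = []
    model_id = 0
    for intrinsic_nonlinear in (False, True):
        for pattern in list(reduced_patterns) + [()]:
            model_id += 1
            mask = np.ones((J, J), dtype=bool)
            np.fill_diagonal(mask, False)  # intrinsic handled separately
            for src, tgt in pattern:
                mask[REGIONS.index(tgt), REGIONS.index(src)] = False
            specs.append(
                ModelSpec(
                    model_id=model_id,
                    regions=REGIONS,
                    extrinsic_mask=tuple(tuple(row) for row in mask),
                    intrinsic_nonlinear=intrinsic_nonlinear,
                )
            )
    return specs


@dataclass
class ConstraintSet:
    """Free-parameter masks for one model in mode space.

    ``A_mask`` is (n, n) with n = n_regions*K: True where the coupling
    parameter is free.  Within each K×K region block, linear-only coupling
    frees the diagonal (within-mode) entries; nonlinear coupling frees the
    whole block; absent connections free nothing.  ``C_mask`` frees the input
    weights of the input region at every mode.
    """

    A_mask: np.ndarray
    C_mask: np.ndarray
    K: int
    n_regions: int


def build_constraints(spec: ModelSpec, basis: ModeBasis) -> ConstraintSet:
    """Translate a model's graph into free-parameter masks in mode space."""
    K = basis.K
    if not np.allclose(basis.V.T @ basis.V, np.eye(K), atol=1e-8):
        raise ParameterError("mode basis is not orthonormal")
    J = spec.n_regions
    n = J * K
    A_mask = np.zeros((n, n), dtype=bool)
    ext = spec.extrinsic_array()
    eye = np.eye(K, dtype=bool)
    full = np.ones((K, K), dtype=bool)
    for i in range(J):
        for j in range(J):
            block = slice(i * K, (i + 1) * K), slice(j * K, (j + 1) * K)
            if i == j:
                A_mask[block] = full if spec.intrinsic_nonlinear else eye
            elif ext[i, j]:
                A_mask[block] = full if spec.extrinsic_nonlinear else eye
    C_mask = np.zeros(n, dtype=bool)
    jin = spec.regions.index(spec.input_region)
    C_mask[jin * K : (jin + 1) * K] = True
    return ConstraintSet(A_mask=A_mask, C_mask=C_mask, K=K, n_regions=J)


def integrate(
    A: np.ndarray,
    C: np.ndarray,
    u: np.ndarray,
    t_grid: np.ndarray,
    tau: float = 1.0,
    g0: np.ndarray | None = None,
) -> np.ndarray:
    """Integrate tau*dg/dt = A g + C u with classical RK4 at the data step.

    ``u`` holds input samples on ``t_grid`` (ms); between samples the input is
    taken piecewise linear.  Returns g with shape (n_states, n_times).
    Raises :class:`UnstableSystemError` when trajectories overflow.
    """
    A = np.asarray(A, dtype=float)
    C = np.asarray(C, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    t_grid = np.asarray(t_grid, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ParameterError("A must be square")
    steps = np.diff(t_grid)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-9):
        raise ParameterError("t_grid must be uniform")
    n = A.shape[0]
    T = t_grid.size
    h = steps[0] / 1000.0 if steps.size else 0.0  # seconds
    g = np.zeros((n, T))
    if g0 is not None:
        g[:, 0] = np.asarray(g0, dtype=float)
    Ai = A / tau
    Ci = C / tau
    bound = 1e12
    for k in range(T - 1):
        x = g[:, k]
        u0, u1 = u[k], u[k + 1]
        um = 0.5 * (u0 + u1)
        k1 = Ai @ x + Ci * u0
        k2 = Ai @ (x + 0.5 * h * k1) + Ci * um
        k3 = Ai @ (x + 0.5 * h * k2) + Ci * um
        k4 = Ai @ (x + h * k3) + Ci * u1
        x_next = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(x_next)) or np.max(np.abs(x_next)) > bound:
            raise UnstableSystemError(
                f"trajectory diverged at step {k + 1}/{T - 1} (|g| > {bound:g})"
            )
        g[:, k + 1] = x_next
    return g


@dataclass
class DCMFit:
    """Posterior summary of one inverted model.

    A and C are posterior means on the mode-space parameters; entries outside
    the model's masks are exactly zero with zero posterior variance.
    log_evidence is the closed-form log marginal likelihood (nats) of the
    gradient-matching regression; variance_explained compares the
    re-integrated trajectory with the observed mode series (1 − SSE/SST).
    """

    model_id: int
    A: np.ndarray
    C: np.ndarray
    A_var: np.ndarray
    C_var: np.ndarray
    log_evidence: float
    variance_explained: float
    noise_var: np.ndarray
    K: int
    regions: tuple[str, ...]
    tau: float = 1.0
    rollout_stabilized: bool = False
    labels: dict = field(default_factory=dict)


def estimate_noise_variance(
    series: ModeSeries, u: np.ndarray, constraints: ConstraintSet
) -> np.ndarray:
    """Per-state noise variance from OLS residuals of the given (full) design.

    Intended to be computed once under the fully connected model and then held
    fixed across the model space so log evidences are comparable.
    """
    g, dg, u = _design_series(series, u)
    n, T = g.shape
    out = np.empty(n)
    for i in range(n):
        cols = [g[j] for j in np.flatnonzero(constraints.A_mask[i])]
        if constraints.C_mask[i]:
            cols.append(u)
        X = np.column_stack(cols) if cols else np.zeros((T, 0))
        y = dg[i]
        if X.shape[1]:
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            resid = y
        dof = max(T - X.shape[1], 1)
        out[i] = max(float(resid @ resid) / dof, 1e-12)
    return out


def _design_series(series: ModeSeries, u: np.ndarray):
    """Regression variables for gradient matching.

    The derivative is estimated from the smoothed trajectories, so the state
    and input regressors are smoothed with the same moving average — the
    smoothing is linear and commutes with the dynamics, and matched filtering
    avoids the errors-in-variables attenuation a noisy raw design would
    introduce.
    """
    from dcmir.tfr import moving_average

    u = np.asarray(u, dtype=float).ravel()
    if series.g_smooth is not None and series.smooth_window > 1:
        return (
            series.g_smooth,
            series.dg,
            moving_average(u[None, :], series.smooth_window)[0],
        )
    return series.g, series.dg, u


def _row_evidence(
    y: np.ndarray,
    X: np.ndarray,
    m0: np.ndarray,
    prior_var: float,
    noise_var: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior mean, covariance and log evidence of one Bayesian regression row.

    Model: y = X θ + ε, θ ~ N(m0, prior_var·I), ε ~ N(0, noise_var·I).
    """
    T, p = X.shape
    if p == 0:
        lme = -0.5 * T * np.log(2 * np.pi * noise_var) - 0.5 * (y @ y) / noise_var
        return np.zeros(0), np.zeros((0, 0)), float(lme)
    P = np.eye(p) / prior_var  # prior precision
    M = X.T @ X / noise_var + P  # posterior precision
    c, low = cho_factor(M)
    rhs = X.T @ y / noise_var + P @ m0
    m = cho_solve((c, low), rhs)
    cov = cho_solve((c, low), np.eye(p))
    logdet_M = 2.0 * np.sum(np.log(np.diag(c)))
    logdet_P = -p * np.log(prior_var)
    quad = (y @ y) / noise_var + m0 @ P @ m0 - m @ M @ m
    lme = (
        -0.5 * T * np.log(2 * np.pi * noise_var)
        + 0.5 * (logdet_P - logdet_M)
        - 0.5 * quad
    )
    return m, cov, float(lme)


def invert(
    series: ModeSeries,
    u: np.ndarray,
    spec: ModelSpec,
    basis: ModeBasis,
    prior_var: float = 1.0,
    noise_var: np.ndarray | float | None = None,
    prior_mean_decay: float = -1.0,
    tau: float = 1.0,
) -> DCMFit:
    """Invert one model by Bayesian gradient matching.

    Each state row i solves dg_i = Σ_j A_ij g_j + C_i u + ε with a Gaussian
    prior N(0, prior_var) on every free parameter except the intrinsic
    within-mode decay terms, which get prior mean ``prior_mean_decay`` (a
    negative value encodes the expectation that power deviations dissipate).
    ``noise_var`` may be a scalar, a per-state vector, or None (then estimated
    per row under this model's own design).  The total log evidence is the sum
    of the per-row closed-form log marginal likelihoods.
    """
    cons = build_constraints(spec, basis)
    u_raw = np.asarray(u, dtype=float).ravel()
    g, dg, u = _design_series(series, u_raw)
    n, T = g.shape
    if cons.A_mask.shape[0] != n:
        raise ParameterError(
            f"model expects {cons.A_mask.shape[0]} states, series has {n}"
        )
    if u.size != T:
        raise ParameterError("input length must match series time axis")
    if noise_var is None:
        nv = estimate_noise_variance(series, u_raw, cons)
    else:
        nv = np.broadcast_to(np.asarray(noise_var, dtype=float), (n,)).copy()
    if np.any(nv <= 0):
        raise ParameterError("noise variance must be positive")

    K = cons.K
    A = np.zeros((n, n))
    A_var = np.zeros((n, n))
    C = np.zeros(n)
    C_var = np.zeros(n)
    total_lme = 0.0
    for i in range(n):
        a_idx = np.flatnonzero(cons.A_mask[i])
        cols = [g[j] for j in a_idx]
        has_c = bool(cons.C_mask[i])
        if has_c:
            cols.append(u)
        X = np.column_stack(cols) if cols else np.zeros((T, 0))
        m0 = np.zeros(X.shape[1])
        for pos, j in enumerate(a_idx):
            if j == i:  # intrinsic within-mode decay
                m0[pos] = prior_mean_decay
        m, cov, lme = _row_evidence(dg[i], X, m0, prior_var, float(nv[i]))
        total_lme += lme
        for pos, j in enumerate(a_idx):
            A[i, j] = m[pos]
            A_var[i, j] = cov[pos, pos]
        if has_c:
            C[i] = m[-1]
            C_var[i] = cov[-1, -1]

    # variance explained by re-integrating the fitted system; a posterior
    # mean on the unstable side (finite-sample artifact — the true power
    # dynamics dissipate) is rolled out at the nearest uniformly damped
    # system and flagged
    A_roll, stabilized = stabilize(A, margin=0.05)
    try:
        g_pred = integrate(A_roll, C, u_raw, series.t_grid, tau=tau)
        g_obs = series.g
        sse = float(((g_obs - g_pred) ** 2).sum())
        sst = float(((g_obs - g_obs.mean()) ** 2).sum())
        ve = 1.0 - sse / sst if sst > 0 else 0.0
    except UnstableSystemError:
        ve = -np.inf
    return DCMFit(
        model_id=spec.model_id,
        A=A,
        C=C,
        A_var=A_var,
        C_var=C_var,
        log_evidence=total_lme,
        variance_explained=ve,
        noise_var=nv,
        K=K,
        regions=spec.regions,
        tau=tau,
        rollout_stabilized=stabilized,
        labels=dict(series.labels),
    )


def stabilize(A: np.ndarray, margin: float = 0.05) -> tuple[np.ndarray, bool]:
    """Shift the spectrum left so max Re(eig) ≤ −margin, if necessary."""
    lam = float(np.linalg.eigvals(A).real.max())
    if lam <= -margin:
        return A, False
    return A - (lam + margin) * np.eye(A.shape[0]), True


def variance_explained(
    fit: DCMFit,
    observed,
    basis: ModeBasis,
    u: np.ndarray,
) -> float:
    """Fraction of observed spectral variance captured by the fitted system.

    The fitted model is integrated, back-projected to the frequency domain,
    and compared with the observed (cropped, baseline-corrected) spectrogram:
    1 − SSE/SST.
    """
    from dcmir.tfr import back_project

    A_roll, _ = stabilize(fit.A, margin=0.05)
    g_pred = integrate(A_roll, fit.C, u, observed.t_grid, tau=fit.tau)
    pred = back_project(g_pred, basis, observed.n_sources)
    obs = observed.power
    if pred.shape != obs.shape:
        raise ParameterError(f"shape mismatch: predicted {pred.shape}, "
                             f"observed {obs.shape}")
    sse = float(((obs - pred) ** 2).sum())
    sst = float(((obs - obs.mean()) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 0.0
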