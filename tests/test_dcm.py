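"""Model space, integrator, and gradient-matching inversion tests."""

import numpy as np
import pytest
from scipy.linalg import expm

from dcmir import dcm
from dcmir._exceptions import ParameterError, UnstableSystemError
from dcmir.dcm import (
    ModelSpec,
    build_constraints,
    enumerate_model_space,
    estimate_noise_variance,
    integrate,
    invert,
)
from dcmir.tfr import ModeBasis, ModeSeries


def _basis(F, K, seed=0):
    rng = np.random.default_rng(seed)
    V = np.linalg.qr(rng.standard_normal((F, K)))[0]
    # apply the deterministic sign convention
    for k in range(K):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return ModeBasis(V=V, variance_preserved=1.0,
                     singular_values=np.ones(K),
                     freq_grid=np.arange(4.0, 4.0 + F))


class TestModelSpace:
    def test_twelve_models(self, model_space):
        assert len(model_space) == 12
        assert [m.model_id for m in model_space] == list(range(1, 13))

    def test_group_structure(self, model_space):
        for m in model_space[:6]:
            assert not m.intrinsic_nonlinear
        for m in model_space[6:]:
            assert m.intrinsic_nonlinear
        for m in model_space:
            assert m.extrinsic_nonlinear
            assert m.input_region == "SMA"

    def test_model_12_fully_connected(self, model_space):
        ext = model_space[11].extrinsic_array()
        assert np.all(ext | np.eye(5, dtype=bool))
        # model 6 is the fully connected linear-intrinsic variant
        assert np.all(model_space[5].extrinsic_array() | np.eye(5, dtype=bool))

    def test_reduced_variants_drop_premotor_efferents(self, model_space):
        for m in model_space:
            removed = [
                (src, tgt)
                for i, tgt in enumerate(m.regions)
                for j, src in enumerate(m.regions)
                if i != j and not m.extrinsic_mask[i][j]
            ]
            assert len(removed) <= 2
            for src, tgt in removed:
                assert src in ("iPM", "cPM")
                assert tgt in ("iM1", "cM1", "iPM", "cPM")

    def test_custom_reduction_patterns_respected(self):
        patterns = tuple(
            (pair,) for pair in [("iPM", "cM1"), ("cPM", "iM1"), ("iPM", "iM1"),
                                 ("cPM", "cM1"), ("iPM", "cPM")]
        )
        space = enumerate_model_space(patterns)
        assert not space[0].connection_present("iPM", "cM1")
        assert space[0].connection_present("cPM", "iM1")

    def test_mni_coordinates_attached(self, model_space):
        spec = model_space[0]
        coords = dict(zip(spec.regions, spec.coordinates))
        assert coords["iM1"] == (-37, -26, 60)
        assert coords["SMA"] == (-2, -7, 60)


class TestConstraints:
    def test_absent_connection_fully_masked(self, model_space):
        basis = _basis(F=10, K=3)
        spec = model_space[0]  # missing iPM→cPM
        cons = build_constraints(spec, basis)
        i = spec.regions.index("cPM")
        j = spec.regions.index("iPM")
        block = cons.A_mask[i * 3 : (i + 1) * 3, j * 3 : (j + 1) * 3]
        assert not block.any()

    def test_linear_intrinsic_is_within_mode(self, model_space):
        basis = _basis(F=10, K=3)
        cons = build_constraints(model_space[0], basis)  # group 1
        blk = cons.A_mask[:3, :3]
        assert np.array_equal(blk, np.eye(3, dtype=bool))
        cons2 = build_constraints(model_space[6], basis)  # group 2
        assert cons2.A_mask[:3, :3].all()

    def test_full_rank_identity_basis_gives_diagonal_frequency_block(self):
        # with modes = frequencies, a linear-only block projects to an
        # exactly diagonal frequency-frequency coupling
        F = 6
        basis = ModeBasis(V=np.eye(F), variance_preserved=1.0,
                          singular_values=np.ones(F),
                          freq_grid=np.arange(4.0, 4.0 + F))
        space = enumerate_model_space()
        cons = build_constraints(space[0], basis)
        rng = np.random.default_rng(0)
        A = np.where(cons.A_mask, rng.standard_normal(cons.A_mask.shape), 0.0)
        blk = A[:F, :F]
        proj = basis.V @ blk @ basis.V.T
        off = proj[~np.eye(F, dtype=bool)]
        assert np.abs(off).max() == 0.0

    def test_input_only_at_sma(self, model_space):
        basis = _basis(F=8, K=2)
        cons = build_constraints(model_space[11], basis)
        jin = model_space[11].regions.index("SMA")
        expected = np.zeros(10, dtype=bool)
        expected[jin * 2 : (jin + 1) * 2] = True
        assert np.array_equal(cons.C_mask, expected)

    def test_non_orthonormal_basis_rejected(self, model_space):
        V = np.ones((5, 2))
        basis = ModeBasis(V=V, variance_preserved=1.0,
                          singular_values=np.ones(2),
                          freq_grid=np.arange(5.0))
        with pytest.raises(ParameterError):
            build_constraints(model_space[0], basis)


def _expm_oracle(A, C, u, t_grid):
    n = A.shape[0]
    h = (t_grid[1] - t_grid[0]) / 1000.0
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = A
    M[:n, n] = C
    M[n, n + 1] = 1.0
    Phi = expm(M * h)
    g = np.zeros((n, t_grid.size))
    for k in range(t_grid.size - 1):
        z = np.concatenate([g[:, k], [u[k], (u[k + 1] - u[k]) / h]])
        g[:, k + 1] = (Phi @ z)[:n]
    return g


def _random_stable_system(n, rng, decay=(1.0, 3.0), coupling_sd=0.3):
    while True:
        A = coupling_sd * rng.standard_normal((n, n))
        A -= np.diag(np.diag(A))
        A -= np.diag(rng.uniform(*decay, size=n))
        if np.linalg.eigvals(A).real.max() < -0.05:
            return A


class TestIntegrate:
    def test_zero_system_stays_zero(self):
        t = np.linspace(0.0, 1000.0, 100)
        g = integrate(np.zeros((3, 3)), np.zeros(3), np.ones_like(t), t)
        assert np.all(g == 0.0)

    def test_scalar_closed_form(self):
        a, c = 2.0, 1.5
        t = np.arange(0.0, 1000.0, 2.0)
        g = integrate(np.array([[-a]]), np.array([c]), np.ones_like(t), t)
        ts = t / 1000.0
        expected = (c / a) * (1.0 - np.exp(-a * ts))
        rel = np.abs(g[0, 1:] - expected[1:]) / np.abs(expected[1:])
        assert rel.max() < 1e-6

    def test_random_20dim_matches_expm_oracle(self):
        rng = np.random.default_rng(7)
        n = 20
        A = _random_stable_system(n, rng)
        C = rng.uniform(0.0, 1.0, size=n)
        t = np.arange(-1000.0, 1.0, 1000.0 / 256.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        g = integrate(A, C, u, t)
        oracle = _expm_oracle(A, C, u, t)
        assert np.abs(g - oracle).max() < 1e-8

    def test_divergence_flagged(self):
        t = np.arange(0.0, 30000.0, 4.0)
        with pytest.raises(UnstableSystemError):
            integrate(np.array([[5.0]]), np.array([1.0]), np.ones_like(t), t)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 1.0, 3.0])
        with pytest.raises(ParameterError):
            integrate(np.eye(1) * -1, np.ones(1), np.ones(3), t)


def _toy_model_1region(F=1):
    return ModelSpec(
        model_id=0,
        regions=("iM1",),
        extrinsic_mask=((False,),),
        intrinsic_nonlinear=False,
        input_region="iM1",
        coordinates=((0, 0, 0),),
    )


def _quadrature_evidence(y, X, m0, prior_var, noise_var, half_width=8.0, n=801):
    """Brute-force log marginal likelihood on a 2-D parameter grid."""
    from scipy.special import logsumexp

    sd = np.sqrt(prior_var)
    axes = [np.linspace(m - half_width * sd, m + half_width * sd, n) for m in m0]
    t1, t2 = np.meshgrid(axes[0], axes[1], indexing="ij")
    theta = np.stack([t1.ravel(), t2.ravel()])  # (2, n*n)
    resid = y[:, None] - X @ theta
    loglik = -0.5 * (resid**2).sum(axis=0) / noise_var - 0.5 * y.size * np.log(
        2 * np.pi * noise_var
    )
    logprior = -0.5 * ((theta - np.array(m0)[:, None]) ** 2).sum(axis=0) / prior_var \
        - np.log(2 * np.pi * prior_var)
    dA = (axes[0][1] - axes[0][0]) * (axes[1][1] - axes[1][0])
    return logsumexp(loglik + logprior) + np.log(dA)


class TestInvert:
    def test_evidence_matches_quadrature_on_two_parameter_toy(self):
        # one region, one mode: free parameters are the decay A and gain C
        rng = np.random.default_rng(11)
        t = np.arange(-1000.0, 1.0, 1000.0 / 64.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        a_true, c_true = -1.5, 0.8
        g = integrate(np.array([[a_true]]), np.array([c_true]), u, t)
        dg = a_true * g + c_true * u[None, :]
        noise_var = 0.05
        dg_noisy = dg + np.sqrt(noise_var) * rng.standard_normal(dg.shape)
        series = ModeSeries(g=g, dg=dg_noisy, t_grid=t, n_sources=1, K=1)
        basis = ModeBasis(V=np.eye(1), variance_preserved=1.0,
                          singular_values=np.ones(1),
                          freq_grid=np.array([10.0]))
        prior_var = 1.0
        fit = invert(series, u, _toy_model_1region(), basis,
                     prior_var=prior_var, noise_var=noise_var)
        X = np.column_stack([g[0], u])
        lme_quad = _quadrature_evidence(dg_noisy[0], X, [-1.0, 0.0],
                                        prior_var, noise_var)
        assert abs(fit.log_evidence - lme_quad) < 1e-4

    def test_noise_free_ode_data_predicted_almost_exactly(self, model_space):
        # data generated from a model-12-structured truth: the fitted system
        # must reproduce the trajectories (prediction is identified even
        # though single-input dynamics leave parameter null spaces)
        rng = np.random.default_rng(3)
        spec = model_space[11]
        K, J = 3, 5
        basis = _basis(F=12, K=K, seed=1)
        cons = build_constraints(spec, basis)
        n = J * K
        while True:
            A_true = np.where(cons.A_mask,
                              0.25 * rng.standard_normal((n, n)), 0.0)
            A_true -= 1.5 * np.eye(n)
            if np.linalg.eigvals(A_true).real.max() < -0.05:
                break
        C_true = np.where(cons.C_mask, rng.uniform(0.5, 1.0, size=n), 0.0)
        t = np.arange(-1000.0, 1.0, 1000.0 / 128.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        g = integrate(A_true, C_true, u, t)
        dg = A_true @ g + C_true[:, None] * u[None, :]
        series = ModeSeries(g=g, dg=dg, t_grid=t, n_sources=J, K=K)
        fit = invert(series, u, spec, basis, prior_var=10.0, noise_var=1e-6)
        assert fit.variance_explained >= 0.99
        # the well-identified intrinsic decay terms keep their sign
        assert np.all(np.diag(fit.A) < 0.0)

    def test_exact_parameter_recovery_with_full_rank_design(self, model_space):
        # independent smooth state trajectories make the gradient-matching
        # design full rank: every free parameter is recovered exactly
        rng = np.random.default_rng(13)
        spec = model_space[11]
        K, J = 3, 5
        basis = _basis(F=12, K=K, seed=1)
        cons = build_constraints(spec, basis)
        n = J * K
        A_true = np.where(cons.A_mask, 0.25 * rng.standard_normal((n, n)), 0.0)
        A_true -= 1.5 * np.eye(n)
        C_true = np.where(cons.C_mask, rng.uniform(0.5, 1.0, size=n), 0.0)
        t = np.arange(-1000.0, 1.0, 1000.0 / 128.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        # band-limited random trajectories, independent across states
        from scipy.ndimage import gaussian_filter1d

        g = gaussian_filter1d(rng.standard_normal((n, t.size)), sigma=10.0,
                              axis=1)
        dg = A_true @ g + C_true[:, None] * u[None, :]
        series = ModeSeries(g=g, dg=dg, t_grid=t, n_sources=J, K=K)
        fit = invert(series, u, spec, basis, prior_var=100.0, noise_var=1e-8)
        assert np.abs(fit.A - A_true).max() < 1e-4
        assert np.abs(fit.C - C_true).max() < 1e-4
        strong = np.abs(A_true) > 0.05
        assert np.all(np.sign(fit.A[strong]) == np.sign(A_true[strong]))

    def test_masked_parameters_exactly_zero(self, model_space):
        rng = np.random.default_rng(5)
        spec = model_space[0]
        basis = _basis(F=10, K=2, seed=2)
        n = 10
        t = np.arange(-1000.0, 1.0, 1000.0 / 64.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        g = rng.standard_normal((n, t.size))
        dg = rng.standard_normal((n, t.size))
        series = ModeSeries(g=g, dg=dg, t_grid=t, n_sources=5, K=2)
        fit = invert(series, u, spec, basis, noise_var=1.0)
        cons = build_constraints(spec, basis)
        assert np.all(fit.A[~cons.A_mask] == 0.0)
        assert np.all(fit.A_var[~cons.A_mask] == 0.0)
        assert np.all(fit.C[~cons.C_mask] == 0.0)

    def test_vanishing_prior_shrinks_to_prior_mean(self, model_space):
        rng = np.random.default_rng(6)
        spec = model_space[11]
        basis = _basis(F=8, K=2, seed=3)
        n = 10
        t = np.arange(-1000.0, 1.0, 1000.0 / 64.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        series = ModeSeries(
            g=rng.standard_normal((n, t.size)),
            dg=rng.standard_normal((n, t.size)),
            t_grid=t, n_sources=5, K=2,
        )
        fit = invert(series, u, spec, basis, prior_var=1e-12, noise_var=1.0,
                     prior_mean_decay=0.0)
        assert np.abs(fit.A).max() < 1e-6
        assert np.abs(fit.C).max() < 1e-6

    def test_scale_identifiability(self, model_space):
        # scaling the data rescales C but leaves A invariant
        rng = np.random.default_rng(8)
        spec = model_space[11]
        K, J = 2, 5
        basis = _basis(F=8, K=K, seed=4)
        cons = build_constraints(spec, basis)
        n = J * K
        A_true = np.where(cons.A_mask, 0.2 * rng.standard_normal((n, n)), 0.0)
        A_true -= 1.5 * np.eye(n)
        C_true = np.where(cons.C_mask, 1.0, 0.0)
        t = np.arange(-1000.0, 1.0, 1000.0 / 64.0)
        u = np.exp(-0.5 * ((t + 400.0) / 200.0) ** 2)
        # full-rank design so the estimate is likelihood-dominated
        from scipy.ndimage import gaussian_filter1d

        g = gaussian_filter1d(rng.standard_normal((n, t.size)), sigma=8.0,
                              axis=1)
        dg = A_true @ g + C_true[:, None] * u[None, :]
        fits = []
        for s in (1.0, 7.0):
            series = ModeSeries(g=s * g, dg=s * dg, t_grid=t,
                                n_sources=J, K=K)
            fits.append(invert(series, u, spec, basis, prior_var=100.0,
                               noise_var=1e-8))
        assert np.allclose(fits[0].A, fits[1].A, atol=1e-5)
        assert np.allclose(7.0 * fits[0].C, fits[1].C, rtol=1e-4)

    def test_nonpositive_noise_variance_rejected(self, model_space):
        basis = _basis(F=8, K=2, seed=3)
        t = np.arange(-1000.0, 1.0, 1000.0 / 64.0)
        series = ModeSeries(
            g=np.ones((10, t.size)), dg=np.zeros((10, t.size)),
            t_grid=t, n_sources=5, K=2,
        )
        with pytest.raises(ParameterError):
            invert(series, np.ones(t.size), enumerate_model_space()[0],
                   basis, noise_var=0.0)


class TestEvidenceRanking:
    def test_true_model_beats_reduced_variants_at_high_snr(self, model_space):
        from dcmir import synthgen, tfr

        cfg = synthgen.SimConfig(n_subjects=2, seed=0, snr_db=25.0)
        specs, _ = synthgen.simulate_cohort_spectra(
            model_space[11], cfg, sessions=("pre",)
        )
        basis = tfr.fit_modes(specs, K=4)
        wave = synthgen.make_input_waveform(cfg.sim_t_grid())
        wins = 0
        for sp in specs:
            series = tfr.project_modes(sp, basis)
            nv = estimate_noise_variance(
                series, wave.u, build_constraints(model_space[11], basis)
            )
            L = [invert(series, wave.u, m, basis, noise_var=nv).log_evidence
                 for m in model_space]
            wins += int(np.argmax(L) == 11)
        assert wins == len(specs)


class TestVarianceExplained:
    def test_self_consistent_fit_explains_its_own_data(self, model_space):
        from dcmir import synthgen, tfr
        from dcmir.dcm import variance_explained

        cfg = synthgen.SimConfig(n_subjects=2, seed=1, snr_db=60.0)
        specs, _ = synthgen.simulate_cohort_spectra(
            model_space[11], cfg, sessions=("pre",)
        )
        basis = tfr.fit_modes(specs, K=4)
        wave = synthgen.make_input_waveform(cfg.sim_t_grid())
        series = tfr.project_modes(specs[0], basis)
        fit = invert(series, wave.u, model_space[11], basis)
        assert fit.variance_explained >= 0.95
        ve_freq = variance_explained(fit, specs[0], basis, wave.u)
        assert 0.0 < ve_freq <= 1.0

    def test_cohort_variance_explained_in_expected_band(self, model_space):
        # 8 subjects at 10 dB, seed 0: the fully connected model should
        # account for most but not all spectral variance
        from dcmir import synthgen, tfr

        cfg = synthgen.SimConfig(n_subjects=8, seed=0, snr_db=10.0)
        specs, _ = synthgen.simulate_cohort_spectra(
            model_space[11], cfg, sessions=("pre",)
        )
        basis = tfr.fit_modes(specs, K=4)
        wave = synthgen.make_input_waveform(cfg.sim_t_grid())
        cons = build_constraints(model_space[11], basis)
        ves = []
        for sp in specs:
            series = tfr.project_modes(sp, basis)
            nv = estimate_noise_variance(series, wave.u, cons)
            ves.append(
                invert(series, wave.u, model_space[11], basis,
                       noise_var=nv).variance_explained
            )
        assert 0.6 <= np.mean(ves) <= 0.99

    def test_zero_fit_explains_nothing(self, model_space):
        from dcmir import synthgen, tfr
        from dcmir.dcm import DCMFit, variance_explained

        cfg = synthgen.SimConfig(n_subjects=2, seed=2, snr_db=30.0)
        specs, _ = synthgen.simulate_cohort_spectra(
            model_space[11], cfg, sessions=("pre",)
        )
        basis = tfr.fit_modes(specs, K=4)
        wave = synthgen.make_input_waveform(cfg.sim_t_grid())
        n = 5 * basis.K
        fit = DCMFit(
            model_id=12, A=-np.eye(n), C=np.zeros(n),
            A_var=np.zeros((n, n)), C_var=np.zeros(n),
            log_evidence=0.0, variance_explained=0.0,
            noise_var=np.ones(n), K=basis.K, regions=dcm.REGIONS,
        )
        assert variance_explained(fit, specs[0], basis, wave.u) <= 0.0
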