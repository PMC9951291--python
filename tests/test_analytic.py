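"""Closed-form mapping scores: CG model, VAMP, S_map, VP, RE, timescales."""

import numpy as np
import pytest

from cgmapopt import (
    ParameterError,
    analytic_timescales,
    build_chain,
    default_lag_time,
    effective_cg_matrix,
    enumerate_two_bead_candidates,
    equilibrium_covariance,
    identity_map,
    mapping_entropy,
    mapping_entropy_full,
    omega_tau,
    reconstruction_error_gaussian,
    score_mapping,
    simulate_harmonic,
    slicing_map,
    spectral_decompose,
    time_lagged_covariance_analytic,
    vamp_score,
    vibrational_power,
)
from conftest import assert_within_se


class TestEffectiveCGMatrix:
    def test_identity_mapping_recovers_c00(self, chain_uniform):
        model = effective_cg_matrix(chain_uniform, identity_map(4))
        np.testing.assert_allclose(
            model.cg_covariance, equilibrium_covariance(chain_uniform), atol=1e-12
        )

    def test_effective_K_annihilates_uniform(self, chain_soft_edges):
        from cgmapopt import averaging_map

        model = effective_cg_matrix(
            chain_soft_edges, averaging_map(4, [(0,), (1, 2, 3)])
        )
        np.testing.assert_allclose(model.effective_K @ np.ones(2), 0.0, atol=1e-10)

    def test_covariance_is_pseudo_inverse_of_K(self, chain_stiff_edges):
        for m in enumerate_two_bead_candidates(4):
            model = effective_cg_matrix(chain_stiff_edges, m)
            c, k = model.cg_covariance, model.effective_K
            np.testing.assert_allclose(
                c @ (chain_stiff_edges.beta * k) @ c, c, atol=1e-10
            )

    def test_mapped_covariance_matches_monte_carlo(self, chain_uniform):
        mapping = slicing_map(4, [0, 3])
        model = effective_cg_matrix(chain_uniform, mapping)
        entries = {(0, 0): [], (0, 1): [], (1, 1): []}
        for seed in range(8):
            traj = simulate_harmonic(
                chain_uniform, 200_000, 0.05, 5, seed=seed, propagator="exact"
            )
            dx = traj.frames[:, :, 0] - chain_uniform.reference_coords
            x = mapping.apply(dx)
            cov = np.cov(x.T, ddof=0)
            for key in entries:
                entries[key].append(cov[key])
        for (i, j), vals in entries.items():
            assert_within_se(vals, model.mapped_covariance[i, j], msg=f"C[{i}{j}]")


class TestOmegaTau:
    def test_zero_lag_equals_equilibrium_covariance(self, chain_soft_edges):
        spec = spectral_decompose(chain_soft_edges)
        om = omega_tau(spec, 0.0, 1.0, chain_soft_edges.beta)
        np.testing.assert_allclose(
            om, equilibrium_covariance(chain_soft_edges), atol=1e-12
        )

    def test_long_lag_decays_to_zero(self, chain_soft_edges):
        spec = spectral_decompose(chain_soft_edges)
        om = omega_tau(spec, 1e4, 1.0, 1.0)
        np.testing.assert_allclose(om, 0.0, atol=1e-12)

    def test_single_spring_closed_form(self):
        # single non-zero mode lambda=2, u=(1,-1)/sqrt(2):
        # Omega_1 = exp(-2)/2 * u u^T = (exp(-2)/4) [[1,-1],[-1,1]]
        spec = spectral_decompose(build_chain(2, [1.0]))
        om = omega_tau(spec, 1.0, 1.0, 1.0)
        expected = (np.exp(-2.0) / 4.0) * np.array([[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(om, expected, atol=1e-14)

    def test_negative_lag_rejected(self, chain_soft_edges):
        spec = spectral_decompose(chain_soft_edges)
        with pytest.raises(ParameterError):
            omega_tau(spec, -0.5, 1.0, 1.0)


class TestTimeLaggedCovariance:
    def test_zero_lag_equals_cg_covariance(self, chain_soft_edges):
        for m in enumerate_two_bead_candidates(4):
            model = effective_cg_matrix(chain_soft_edges, m)
            c0 = time_lagged_covariance_analytic(chain_soft_edges, m, 0.0)
            np.testing.assert_allclose(c0, model.cg_covariance, atol=1e-12)

    def test_identity_map_equals_projected_omega(self, chain_uniform):
        spec = spectral_decompose(chain_uniform)
        om = omega_tau(spec, 0.7, 1.0, 1.0)
        c0t = time_lagged_covariance_analytic(chain_uniform, identity_map(4), 0.7)
        np.testing.assert_allclose(c0t, om, atol=1e-12)  # Q Omega Q = Omega

    def test_matches_trajectory_estimate(self, chain_uniform):
        from cgmapopt import estimate_covariances, featurize, slicing_map
        from cgmapopt.empirical import remove_cg_translation

        mapping = slicing_map(4, [1, 3])
        tau_frames, dt, stride = 4, 0.05, 5
        tau = tau_frames * dt * stride
        expected = time_lagged_covariance_analytic(chain_uniform, mapping, tau)
        vals = []
        for seed in range(8):
            traj = simulate_harmonic(
                chain_uniform, 300_000, dt, stride, seed=seed, propagator="exact"
            )
            feats = remove_cg_translation(featurize(traj, mapping), 2)
            cov = estimate_covariances(feats, tau_frames)
            vals.append(cov.c0tau_hat[0, 1])
        assert_within_se(vals, expected[0, 1], msg="C0tau[01]")


class TestVampScore:
    def test_zero_lag_score_equals_rank(self, chain_soft_edges):
        for m in enumerate_two_bead_candidates(4):
            model = effective_cg_matrix(chain_soft_edges, m)
            score = vamp_score(model.cg_covariance, model.cg_covariance)
            assert score == pytest.approx(m.n_beads - 1, abs=1e-9)

    def test_identity_dominates_every_mapping(self, chain_soft_edges):
        tau = default_lag_time(chain_soft_edges)
        full = score_mapping(chain_soft_edges, identity_map(4), tau).vamp
        for m in enumerate_two_bead_candidates(4):
            assert score_mapping(chain_soft_edges, m, tau).vamp <= full + 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            vamp_score(np.eye(3), np.eye(2))

    def test_argmax_stable_over_lag_decade(self, chain_stiff_edges):
        spec = spectral_decompose(chain_stiff_edges)
        t_slow = 1.0 / spec.nonzero_eigenvalues[0]
        winners = set()
        for tau in t_slow * np.geomspace(0.3, 3.0, 6):
            scores = {
                m.label: score_mapping(chain_stiff_edges, m, tau).vamp
                for m in enumerate_two_bead_candidates(4)
            }
            winners.add(max(scores, key=scores.get))
        assert winners == {"0+1|2+3"}


class TestMappingEntropy:
    def test_identity_loses_nothing(self, chain_soft_edges):
        assert mapping_entropy(chain_soft_edges, identity_map(4)) == pytest.approx(
            0.0, abs=1e-10
        )
        assert mapping_entropy_full(
            chain_soft_edges, identity_map(4)
        ) == pytest.approx(0.0, abs=1e-10)

    def test_full_entropy_nonpositive_on_random_chains(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(3, 8))
            ks = rng.uniform(0.2, 5.0, size=n - 1)
            system = build_chain(n, ks)
            for N in (2, min(3, n - 1)):
                from cgmapopt import contiguous_averaging_maps

                for m in contiguous_averaging_maps(n, N):
                    assert mapping_entropy_full(system, m) <= 1e-10


class TestVibrationalPower:
    def test_identity_equals_total_variance(self, chain_soft_edges):
        c00 = equilibrium_covariance(chain_soft_edges)
        assert vibrational_power(
            chain_soft_edges, identity_map(4)
        ) == pytest.approx(np.trace(c00))

    def test_matches_trajectory_variances(self, chain_stiff_edges):
        from cgmapopt import averaging_map

        mapping = averaging_map(4, [(0, 1), (2, 3)])
        expected = vibrational_power(chain_stiff_edges, mapping)
        vals = []
        for seed in range(8):
            traj = simulate_harmonic(
                chain_stiff_edges, 200_000, 0.02, 5, seed=seed, propagator="exact"
            )
            x = mapping.apply(traj.frames[:, :, 0])
            vals.append(np.var(x, axis=0).sum())
        assert_within_se(vals, expected, msg="VP")


class TestReconstructionError:
    def test_identity_is_exact(self, chain_soft_edges):
        assert reconstruction_error_gaussian(
            chain_soft_edges, identity_map(4)
        ) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_total_variance(self, chain_stiff_edges):
        c00 = equilibrium_covariance(chain_stiff_edges)
        bound = np.trace(c00) / 4
        for m in enumerate_two_bead_candidates(4):
            re = reconstruction_error_gaussian(chain_stiff_edges, m)
            assert 0.0 <= re <= bound + 1e-12

    def test_monotone_under_nested_mappings(self):
        system = build_chain(8, [1.0, 3.0, 0.5, 2.0, 1.0, 4.0, 1.5])
        kept = [0, 7]
        previous = np.inf
        for extra in [3, 5, 1, 6, 2, 4]:
            kept.append(extra)
            re = reconstruction_error_gaussian(system, slicing_map(8, kept))
            assert re <= previous + 1e-12
            previous = re
        assert previous == pytest.approx(0.0, abs=1e-10)


class TestAnalyticTimescales:
    def test_identity_closed_form(self):
        k = 1.0
        system = build_chain(4, [k, k, k])
        times = analytic_timescales(system, identity_map(4))
        lam = np.array([k * (2 - np.sqrt(2)), 2 * k, k * (2 + np.sqrt(2))])
        np.testing.assert_allclose(times, np.sort(1.0 / lam)[::-1], rtol=1e-10)

    def test_variational_bound_all_candidates(self, chain_soft_edges):
        reference = analytic_timescales(chain_soft_edges, identity_map(4))
        for m in enumerate_two_bead_candidates(4):
            for i, t in enumerate(analytic_timescales(chain_soft_edges, m)):
                assert t <= reference[i] + 1e-9

    def test_lag_invariance_of_markovian_full_model(self, chain_stiff_edges):
        # the full-resolution dynamics is exactly Markov, so its implied
        # timescales are lag-independent; projected CG dynamics is not, so
        # the guarantee is specific to the identity map
        m = identity_map(4)
        tau = default_lag_time(chain_stiff_edges)
        t1 = analytic_timescales(chain_stiff_edges, m, tau)
        t2 = analytic_timescales(chain_stiff_edges, m, 2 * tau)
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_count_too_large_rejected(self, chain_soft_edges):
        with pytest.raises(ParameterError):
            analytic_timescales(chain_soft_edges, slicing_map(4, [0, 3]), count=3)
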