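"""Plume solver physics and the monitoring-design sampler."""

import numpy as np
import pytest

from plumespline.simulate import (
    FlowField,
    NoiseModel,
    default_flow,
    gaussian_initial,
    make_scenario,
    sample_observations,
    simulate_dataset,
    solve_plume,
)


def still_water(diffusion):
    zero = lambda s1, s2: np.zeros_like(s1)
    return FlowField(diffusion=diffusion, psi1=zero, psi2=zero)


class TestSolverPhysics:
    def test_mass_conserved_under_pure_diffusion(self):
        truth = solve_plume(still_water(0.004), grid_n=(80, 80), n_t_out=40)
        cell = (truth.s1[1] - truth.s1[0]) ** 2
        mass = truth.values.sum(axis=(1, 2)) * cell
        assert (mass.max() - mass.min()) / mass[0] < 1e-3

    def test_matches_spreading_gaussian(self):
        """Pure diffusion of a Gaussian follows the heat kernel: var += 2Dt."""
        D = 0.002
        init = gaussian_initial(center=(0.5, 0.5), sd=0.05, amplitude=1.0)
        truth = solve_plume(
            still_water(D), init, grid_n=(100, 100), n_t_out=11, t_span=(0, 0.5)
        )
        S1, S2 = np.meshgrid(truth.s1, truth.s2, indexing="ij")
        for it in (3, 6, 10):
            t = truth.t[it]
            var_expected = 0.05**2 + 2 * D * t
            w = truth.values[it] / truth.values[it].sum()
            var_emp = float((w * (S1 - 0.5) ** 2).sum())
            assert var_emp == pytest.approx(var_expected, rel=0.01)
            # pointwise agreement with the closed-form kernel at interior points
            amp = 0.05**2 / var_expected
            analytic = amp * np.exp(
                -((S1 - 0.5) ** 2 + (S2 - 0.5) ** 2) / (2 * var_expected)
            )
            interior = (np.abs(S1 - 0.5) < 0.3) & (np.abs(S2 - 0.5) < 0.3)
            err = np.abs(truth.values[it] - analytic)[interior].max()
            assert err < 0.01 * analytic.max()

    def test_centroid_advects_at_minus_psi(self):
        """With D=0 and constant ψ the plume drifts at −ψ, within one cell."""
        flow = FlowField(
            diffusion=0.0,
            psi1=lambda a, b: np.full_like(a, 0.4),
            psi2=lambda a, b: np.full_like(a, -0.2),
        )
        init = gaussian_initial(center=(0.6, 0.4), sd=0.06, amplitude=1.0)
        truth = solve_plume(flow, init, grid_n=(100, 100), n_t_out=6, t_span=(0, 0.5))
        S1, S2 = np.meshgrid(truth.s1, truth.s2, indexing="ij")
        w = truth.values[-1] / truth.values[-1].sum()
        c1, c2 = float((w * S1).sum()), float((w * S2).sum())
        cell = truth.s1[1] - truth.s1[0]
        assert abs(c1 - (0.6 - 0.4 * 0.5)) <= cell
        assert abs(c2 - (0.4 + 0.2 * 0.5)) <= cell

    def test_nonnegative_and_finite(self, cached_truth):
        assert np.all(np.isfinite(cached_truth.values))
        assert cached_truth.values.min() >= 0.0

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            solve_plume(default_flow(), grid_n=(2, 2))
        with pytest.raises(ValueError):
            FlowField(diffusion=-1.0)


class TestScenarios:
    @pytest.mark.parametrize(
        "sid,n_wells,n_obs", [(1, 29, 1402), (2, 280, 1402), (3, 29, 100)]
    )
    def test_sizes(self, sid, n_wells, n_obs):
        scen = make_scenario(sid)
        assert scen.n_wells == n_wells
        assert scen.n_obs == n_obs
        assert len(np.unique(scen.obs_well_index)) == n_wells  # every well sampled

    def test_scenarios_1_and_3_share_wells(self):
        assert np.array_equal(make_scenario(1).wells, make_scenario(3).wells)

    def test_scenario3_sparse_in_time(self):
        scen = make_scenario(3)
        per_well = scen.n_obs / scen.n_wells
        assert 3.0 < per_well < 4.0  # "about four" samples per well

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            make_scenario(4)


class TestNoise:
    def test_infinite_snr_recovers_truth(self, cached_truth):
        scen = make_scenario(3)
        data = sample_observations(
            cached_truth, scen, NoiseModel(snr=np.inf), seed=0
        )
        signal = cached_truth.interp(data.s1, data.s2, data.t)
        assert np.allclose(data.raw, signal, atol=1e-12)

    def test_determinism_byte_for_byte(self, cached_truth):
        a, _, _ = simulate_dataset(1, seed=42, truth=cached_truth)
        b, _, _ = simulate_dataset(1, seed=42, truth=cached_truth)
        assert a.checksum() == b.checksum()
        c, _, _ = simulate_dataset(1, seed=43, truth=cached_truth)
        assert a.checksum() != c.checksum()

    def test_within_well_correlation_near_nominal(self, cached_truth):
        """Empirical same-well multiplicative-noise correlation ≈ ρ.

        Measured on the log of the raw concentrations restricted to
        observations with substantial signal (where the multiplicative
        log-noise is observable; exact zeros carry no noise by design).
        """
        scen = make_scenario(1)
        raw_signal = None
        rho_hats = []
        for seed in range(120):
            data = sample_observations(cached_truth, scen, NoiseModel(), seed=seed)
            if raw_signal is None:
                raw_signal = cached_truth.interp(data.s1, data.s2, data.t)
                strong = raw_signal > 1.0
                labels = np.asarray([str(w) for w in data.well])[strong]
            noise = np.log(data.raw[strong]) - np.log(raw_signal[strong])
            grand = noise.var()
            pair_sum = 0.0
            npairs = 0
            for w in np.unique(labels):
                sub = noise[labels == w]
                k = len(sub)
                if k > 1:
                    pair_sum += sub.sum() ** 2 - (sub**2).sum()
                    npairs += k * (k - 1)
            rho_hats.append(pair_sum / npairs / grand)
        rho_hat = float(np.mean(rho_hats))
        assert rho_hat == pytest.approx(0.05, abs=0.03)

    def test_noise_scale_matches_snr(self, cached_truth):
        """Multiplicative log-noise SD ≈ SD(transformed signal)/SNR."""
        scen = make_scenario(1)
        reps = [
            sample_observations(cached_truth, scen, NoiseModel(), seed=s)
            for s in range(20)
        ]
        raw_signal = cached_truth.interp(reps[0].s1, reps[0].s2, reps[0].t)
        strong = raw_signal > 1.0
        target = np.std(reps[0].transform.forward(raw_signal)) / 10.0
        sd_noise = float(
            np.mean(
                [
                    np.std(np.log(d.raw[strong]) - np.log(raw_signal[strong]))
                    for d in reps
                ]
            )
        )
        assert sd_noise == pytest.approx(target, rel=0.1)

    def test_raw_concentrations_nonnegative(self, cached_truth):
        data, _, _ = simulate_dataset(1, seed=7, truth=cached_truth)
        assert data.raw.min() >= 0.0

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(snr=0.0)
        with pytest.raises(ValueError):
            NoiseModel(rho=1.0)
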