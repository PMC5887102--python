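"""Stochastic hole propagation: noise, unitary steps, response, localization."""

import numpy as np
import pytest

import triadet as td
from triadet.constants import HBAR_EV_PS
from triadet.errors import InputError


class TestOUSampling:
    def test_zero_sd_is_identically_zero(self):
        assert np.all(td.sample_ou(0.0, 0.1, 1.0, 1000, seed=1) == 0.0)

    def test_stationary_variance(self):
        series = td.sample_ou(0.2, 0.1, 1.0, 100_000, seed=2)
        assert np.var(series) == pytest.approx(0.04, rel=0.05)

    def test_lag_tau_autocorrelation(self):
        sd, tau_ps, dt_fs = 0.2, 0.1, 1.0
        series = td.sample_ou(sd, tau_ps, dt_fs, 100_000, seed=3)
        lag = int(round(tau_ps / (dt_fs * 1e-3)))
        x = series - series.mean()
        acf = np.dot(x[:-lag], x[lag:]) / np.dot(x, x)
        assert acf == pytest.approx(np.exp(-1.0), rel=0.10)

    def test_invalid_parameters(self):
        with pytest.raises(InputError):
            td.sample_ou(0.1, -1.0, 1.0, 10)


class TestWavefunctionStep:
    def test_diagonal_hamiltonian_only_rotates_phases(self):
        h = np.diag([-5.8, -6.3])
        psi = td.WaveState(np.array([0.6, 0.8], dtype=complex))
        out = td.step_wavefunction(h, psi, 1.0)
        assert np.allclose(out.occupations(), psi.occupations(), atol=1e-12)

    def test_resonant_rabi_period(self):
        """Full population transfer of a resonant 4 meV two-site system first
        completes at t = pi*hbar/(2H) = 0.2585 ps."""
        coupling = 0.004
        h = np.array([[0.0, coupling], [coupling, 0.0]])
        dt_fs = 0.5
        psi = np.array([1.0, 0.0], dtype=complex)
        occ1 = []
        for _ in range(1200):
            psi = td.step_wavefunction(h, psi, dt_fs)
            occ1.append(abs(psi[1]) ** 2)
        t_full = (np.argmax(occ1) + 1) * dt_fs * 1e-3
        expected = np.pi * HBAR_EV_PS / (2 * coupling)
        assert t_full == pytest.approx(expected, rel=1e-3)
        assert max(occ1) > 1.0 - 1e-6  # grid does not land exactly on the peak

    def test_unitarity_over_many_steps(self):
        rng = np.random.default_rng(8)
        h = rng.normal(size=(3, 3))
        h = (h + h.T) / 2
        psi = np.array([1.0, 0.0, 0.0], dtype=complex)
        for _ in range(1000):
            psi = td.step_wavefunction(h, psi, 1.0)
        assert abs(np.sum(np.abs(psi) ** 2) - 1.0) < 1e-8

    def test_non_symmetric_rejected(self):
        with pytest.raises(InputError, match="symmetric"):
            td.step_wavefunction(np.array([[0.0, 0.1], [0.2, 0.0]]),
                                 np.array([1.0, 0.0], dtype=complex), 1.0)


class TestChargeResponse:
    def _config(self, **kw):
        defaults = dict(total_time_ps=1.0, lambda_reorg=(0.7, 0.7, 0.7),
                        solvent_relax_time_ps=1.0, polarization_scale=1.4)
        defaults.update(kw)
        return td.PropagationConfig(**defaults)

    def test_zero_lambda_leaves_energies(self):
        cfg = self._config(lambda_reorg=(0.0, 0.0, 0.0))
        base = np.array([0.0, -0.4, -0.8])
        energies, _ = td.apply_charge_response(
            base, np.array([1.0, 0, 0]), np.zeros(3), cfg)
        assert np.allclose(energies, base)

    def test_pinned_hole_asymptotic_stabilization(self):
        cfg = self._config()
        base = np.zeros(3)
        qbar = np.zeros(3)
        occ = np.array([1.0, 0.0, 0.0])
        for _ in range(20_000):  # 20 ps at 1 fs: >> solvent relax time
            energies, qbar = td.apply_charge_response(base, occ, qbar, cfg)
        assert energies[0] == pytest.approx(-0.7 / 1.4, rel=1e-6)
        assert np.allclose(energies[1:], 0.0)

    def test_polarization_scale_halves_depth(self):
        occ = np.array([1.0, 0.0, 0.0])
        depths = []
        for scale in (1.4, 2.8):
            cfg = self._config(polarization_scale=scale)
            qbar = np.ones(3) * occ  # fully relaxed
            energies, _ = td.apply_charge_response(np.zeros(3), occ, qbar, cfg)
            depths.append(-energies[0])
        assert depths[0] == pytest.approx(2 * depths[1], rel=1e-9)


class TestDecoherence:
    def test_infinite_time_is_identity(self):
        rho = np.array([[0.6, 0.2 + 0.1j], [0.2 - 0.1j, 0.4]])
        assert np.allclose(td.apply_decoherence(rho, 1.0, None), rho)
        assert np.allclose(td.apply_decoherence(rho, 1.0, np.inf), rho)

    def test_localized_state_is_fixed_point(self):
        rho = np.diag([1.0, 0.0, 0.0]).astype(complex)
        out = td.apply_decoherence(rho, 1.0, 10.0)
        assert np.allclose(out, rho)

    def test_strong_damping_gives_exponential_transfer(self):
        """Resonant two-site density-matrix propagation with fast coherence
        damping relaxes exponentially at the golden-rule rate
        2 H^2 tau_d / hbar^2 instead of oscillating."""
        coupling, tau_d_fs, dt_fs = 0.004, 2.0, 0.5
        h = np.array([[0.0, coupling], [coupling, 0.0]])
        w, v = np.linalg.eigh(h)
        u = (v * np.exp(-1j * w * dt_fs * 1e-3 / HBAR_EV_PS)) @ v.conj().T
        rho = np.diag([1.0, 0.0]).astype(complex)
        pops = [1.0]
        for _ in range(4000):
            rho = u @ rho @ u.conj().T
            rho = td.apply_decoherence(rho, dt_fs, tau_d_fs)
            pops.append(rho[0, 0].real)
        pops = np.asarray(pops)
        t = np.arange(pops.size) * dt_fs * 1e-3  # ps
        # no oscillation below 1/2
        assert pops.min() > 0.49
        # exponential relaxation toward 1/2 at rate 2*gamma with
        # gamma = 2 H^2 tau_d / hbar^2 (per-direction hopping rate)
        gamma = 2 * coupling**2 * (tau_d_fs * 1e-3) / HBAR_EV_PS**2
        expected = 0.5 * (1 + np.exp(-2 * gamma * t))
        assert np.sqrt(np.mean((pops - expected) ** 2)) < 0.02


class TestRunTrajectory:
    def _system(self, downhill_hamiltonian):
        fluct = td.FluctuationModel(site_sd=(0.15,) * 3,
                                    site_corr_time_ps=(0.1,) * 3)
        return downhill_hamiltonian, fluct

    def test_zero_couplings_keep_hole_in_place(self):
        sites = [td.ChargeSite("A", 0.0), td.ChargeSite("B", -0.4),
                 td.ChargeSite("C", -0.8)]
        h = td.assemble_hamiltonian(sites)
        fluct = td.FluctuationModel(site_sd=(0.1,) * 3,
                                    site_corr_time_ps=(0.1,) * 3)
        cfg = td.PropagationConfig(total_time_ps=5.0, seed=1)
        traj = td.run_trajectory(h, fluct, cfg, "A")
        assert np.allclose(traj.occupations[:, 0], 1.0, atol=1e-9)

    def test_seeded_determinism_is_bitwise(self, downhill_hamiltonian):
        h, fluct = self._system(downhill_hamiltonian)
        cfg = td.PropagationConfig(total_time_ps=3.0, seed=77)
        t1 = td.run_trajectory(h, fluct, cfg, "A")
        t2 = td.run_trajectory(h, fluct, cfg, "A")
        assert np.array_equal(t1.occupations, t2.occupations)

    def test_occupation_rows_sum_to_one(self, downhill_hamiltonian):
        h, fluct = self._system(downhill_hamiltonian)
        cfg = td.PropagationConfig(total_time_ps=5.0, seed=5)
        traj = td.run_trajectory(h, fluct, cfg, "A")
        assert np.max(np.abs(traj.occupations.sum(axis=1) - 1)) < 1e-6

    def test_cofactor_site_rejected(self):
        sites = [td.ChargeSite("FAD", -8.0, residue_name="FAD",
                               role="cofactor"),
                 td.ChargeSite("A", -6.3)]
        h = td.assemble_hamiltonian(sites, {("FAD", "A"): 0.001})
        fluct = td.FluctuationModel(site_sd=(0.1, 0.1),
                                    site_corr_time_ps=(0.1, 0.1))
        cfg = td.PropagationConfig(total_time_ps=1.0,
                                   lambda_reorg=(0.7, 0.7), seed=1)
        with pytest.raises(InputError, match="cofactor"):
            td.run_trajectory(h, fluct, cfg, "A")

    def test_coherent_limit_reproduces_rabi_period(self):
        """lambda = 0, no noise, no decoherence: the trajectory is the
        closed-form coherent oscillation."""
        sites = [td.ChargeSite("A", 0.0), td.ChargeSite("B", 0.0)]
        h = td.assemble_hamiltonian(sites, {("A", "B"): 0.004})
        fluct = td.FluctuationModel(site_sd=(0.0, 0.0),
                                    site_corr_time_ps=(0.1, 0.1))
        cfg = td.PropagationConfig(
            total_time_ps=0.6, dt_fs=0.5, lambda_reorg=(0.0, 0.0),
            decoherence_time_fs=None, seed=1, output_dt_ps=0.0005,
        )
        traj = td.run_trajectory(h, fluct, cfg, "A")
        period = np.pi * HBAR_EV_PS / (2 * 0.004)
        k = int(round(period / traj.dt_ps))
        assert traj.occupations[k, 1] == pytest.approx(1.0, abs=1e-3)
        expected = np.cos(0.004 * traj.time_ps / HBAR_EV_PS) ** 2
        assert np.max(np.abs(traj.occupations[:, 0] - expected)) < 1e-3

    def test_downhill_ensemble_localizes_on_terminal_site(
            self, downhill_hamiltonian):
        """Strong decoherence + strongly downhill energetics: >= 95% of the
        ensemble charge sits on the terminal site by 1 ns."""
        h, fluct = self._system(downhill_hamiltonian)
        finals = []
        for seed in range(3):
            cfg = td.PropagationConfig(total_time_ps=1000.0, dt_fs=5.0,
                                       seed=seed, output_dt_ps=1.0)
            traj = td.run_trajectory(h, fluct, cfg, "A")
            finals.append(traj.occupations[-1])
        assert np.mean([f[2] for f in finals]) >= 0.95

    def test_ensemble_mean_matches_fitted_master_equation(
            self, downhill_hamiltonian):
        """Cross-module consistency: the ensemble-averaged surrogate
        dynamics is described by the three-state hopping model with fitted
        rates (RMS < 0.05)."""
        h, fluct = self._system(downhill_hamiltonian)
        trajs = []
        for seed in range(120):
            cfg = td.PropagationConfig(
                total_time_ps=8.0, dt_fs=2.0, seed=seed,
                solvent_relax_time_ps=0.15, output_dt_ps=0.25,
            )
            trajs.append(td.run_trajectory(h, fluct, cfg, "A"))
        ens = td.ensemble_average(trajs)
        fit = td.fit_rates(ens)
        model = td.propagate_master(fit.rates, (1, 0, 0), ens.time_ps)
        rms = float(np.sqrt(np.mean((model - ens.mean) ** 2)))
        assert rms < 0.05


class TestEnsembleAverage:
    def test_single_trajectory_is_itself(self, downhill_hamiltonian):
        fluct = td.FluctuationModel(site_sd=(0.1,) * 3,
                                    site_corr_time_ps=(0.1,) * 3)
        cfg = td.PropagationConfig(total_time_ps=2.0, seed=3)
        traj = td.run_trajectory(downhill_hamiltonian, fluct, cfg, "A")
        ens = td.ensemble_average([traj])
        assert np.allclose(ens.mean, traj.occupations)
        assert np.allclose(ens.sd, 0.0)

    def test_permutation_symmetry_of_mean(self):
        t = np.linspace(0, 1, 11)
        occ = np.random.default_rng(1).dirichlet((1, 1, 1), 11)
        tr1 = td.OccupationTrajectory(t, occ, ("A", "B", "C"))
        tr2 = td.OccupationTrajectory(t, occ[:, [1, 0, 2]], ("A", "B", "C"))
        ens = td.ensemble_average([tr1, tr2])
        swapped = td.ensemble_average([tr2, tr1])
        assert np.allclose(ens.mean, swapped.mean)
        assert np.allclose(ens.mean[:, 0], ens.mean[:, 1])

    def test_grid_mismatch_rejected(self):
        t1 = np.linspace(0, 1, 11)
        t2 = np.linspace(0, 2, 11)
        occ = np.tile([1.0, 0, 0], (11, 1))
        tr1 = td.OccupationTrajectory(t1, occ, ("A", "B", "C"))
        tr2 = td.OccupationTrajectory(t2, occ, ("A", "B", "C"))
        with pytest.raises(InputError):
            td.ensemble_average([tr1, tr2])

    def test_trajectory_csv_round_trip(self, tmp_path):
        t = np.linspace(0, 1, 11)
        occ = np.random.default_rng(2).dirichlet((1, 1, 1), 11)
        traj = td.OccupationTrajectory(t, occ, ("A", "B", "C"))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = td.OccupationTrajectory.from_csv(path)
        assert np.allclose(back.occupations, occ)
        assert back.site_ids == ("A", "B", "C")
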