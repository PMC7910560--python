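"""Dividing-surface sampling, the Langevin integrator and the flux-side
transmission-coefficient estimator."""

import numpy as np
import pytest
from scipy import stats

import cavikin as ck
from cavikin.cavity import effective_couplings

from conftest import kappa_kramers

WC_REF = ck.units.energy(170.6, "mev", "hartree")


def ref_cavity(model, sp, eta):
    if eta == 0.0:
        return ck.CavityParams(omega_c=WC_REF, chi=0.0, mass=model.mass)
    return ck.CavityParams.from_eta(WC_REF, eta, mass=model.mass,
                                    omega0=sp.omega0,
                                    mu0_prime=sp.mu0_prime)


class TestDividingSurfaceSampling:
    def test_decoupled_gaussian_moments(self, ref_model, ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.0)
        cfg = ck.SimConfig(n_traj=10000, seed=5)
        state = ck.sample_dividing_surface(ref_model, cav, cfg,
                                           sp=ref_model_sp)
        kT = 1.0 / cfg.beta
        n = cfg.n_traj
        # 3-sigma statistical bounds on mean and variance
        sd_qc = np.sqrt(kT) / cav.omega_c
        assert abs(state.qc.mean()) < 3 * sd_qc / np.sqrt(n)
        assert state.qc.var() == pytest.approx(sd_qc**2,
                                               rel=3 * np.sqrt(2 / n))
        assert state.P.var() == pytest.approx(ref_model.mass * kT,
                                              rel=3 * np.sqrt(2 / n))
        assert state.pc.var() == pytest.approx(kT, rel=3 * np.sqrt(2 / n))
        assert np.all(state.R == ref_model_sp.R_ddag)

    def test_coupled_mean_matches_analytic_shift(self, ref_model,
                                                 ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.188)
        cfg = ck.SimConfig(n_traj=10000, seed=6)
        state = ck.sample_dividing_surface(ref_model, cav, cfg,
                                           sp=ref_model_sp)
        kT = 1.0 / cfg.beta
        shift = float(ck.photon_displacement(ref_model, cav,
                                             ref_model_sp.R_ddag))
        sd = np.sqrt(kT) / cav.omega_c
        assert state.qc.mean() == pytest.approx(
            shift, abs=3 * sd / np.sqrt(cfg.n_traj))

    def test_constrained_md_mode_statistically_equivalent(self, ref_model,
                                                          ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.094)
        qc = {}
        for mode in ("gaussian", "constrained_md"):
            cfg = ck.SimConfig(n_traj=10000, seed=7, sampling_mode=mode,
                               sampling_interval_fs=30.0)
            qc[mode] = ck.sample_dividing_surface(ref_model, cav, cfg,
                                                  sp=ref_model_sp).qc
        ks = stats.ks_2samp(qc["gaussian"], qc["constrained_md"])
        assert ks.pvalue > 1e-3


class TestIntegrator:
    def test_symplectic_limit_energy_drift(self, harmonic_model):
        # gamma = 0, chi = 0: windowed-mean total-energy drift stays tiny
        cav = ck.CavityParams(omega_c=0.012, chi=0.0)
        cfg = ck.SimConfig(dt=1.0, n_traj=64, seed=1, gamma=0.0,
                           t_max_fs=200.0, save_stride=2)
        rng = np.random.default_rng(2)
        kT = 1.0 / cfg.beta
        state = ck.PhaseState(
            R=rng.uniform(-0.2, 0.2, 64),
            P=rng.standard_normal(64) * np.sqrt(harmonic_model.mass * kT),
            qc=rng.standard_normal(64) * np.sqrt(kT) / cav.omega_c,
            pc=rng.standard_normal(64) * np.sqrt(kT),
        )
        traj = ck.propagate(state, harmonic_model, cav, cfg)
        energy = (traj.P**2 / (2 * harmonic_model.mass)
                  + np.asarray(harmonic_model.energy(traj.R))
                  + traj.pc**2 / 2 + 0.5 * cav.omega_c**2 * traj.qc**2
                  ).sum(axis=1)
        n = energy.size
        drift = abs(energy[-n // 4:].mean() - energy[: n // 4].mean())
        assert drift / abs(energy[0]) < 1e-6

    def test_velocity_autocorrelation_ornstein_uhlenbeck(self):
        # free particle with friction: <v(0)v(t)> / <v^2> = exp(-gamma t)
        R = np.linspace(-1e4, 1e4, 32)
        flat = ck.PotentialModel(R, np.zeros_like(R), np.zeros_like(R),
                                 1836.0)
        cav = ck.CavityParams(omega_c=0.01, chi=0.0)
        gamma = ck.units.wavenumber_to_angular_frequency(400.0)
        cfg = ck.SimConfig(n_traj=4000, seed=9, gamma=gamma, t_max_fs=40.0,
                           save_stride=10)
        kT = 1.0 / cfg.beta
        rng = np.random.default_rng(10)
        n = cfg.n_traj
        state = ck.PhaseState(
            R=np.zeros(n),
            P=rng.standard_normal(n) * np.sqrt(flat.mass * kT),
            qc=np.zeros(n), pc=np.zeros(n))
        traj = ck.propagate(state, flat, cav, cfg)
        v = traj.P / flat.mass
        vacf = (v * v[0]).mean(axis=1) / (v[0]**2).mean()
        t_au = ck.units.time(traj.times_fs, "fs", "au")
        assert np.allclose(vacf, np.exp(-gamma * t_au), atol=0.06)

    def test_thermalization_to_boltzmann_positions(self, harmonic_model):
        # long friction run in a harmonic well: positions ~ N(0, kT/(M w0^2))
        cav = ck.CavityParams(omega_c=0.012, chi=0.0)
        cfg = ck.SimConfig(n_traj=4000, seed=11, t_max_fs=300.0,
                           save_stride=500)
        kT = 1.0 / cfg.beta
        n = cfg.n_traj
        state = ck.PhaseState(R=np.zeros(n), P=np.zeros(n),
                              qc=np.zeros(n), pc=np.zeros(n))
        traj = ck.propagate(state, harmonic_model, cav, cfg)
        R_final = traj.R[-1]
        sigma = np.sqrt(kT / (harmonic_model.mass * 0.01**2))
        ks = stats.kstest(R_final / sigma, "norm")
        assert ks.pvalue > 1e-3


class TestKappaEstimator:
    def test_short_time_limit_is_exactly_one(self, ref_model, ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.047)
        cfg = ck.SimConfig(n_traj=500, seed=1, t_max_fs=20.0)
        trace = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
        assert trace.times_fs[0] == 0.0
        assert trace.kappa[0] == 1.0

    def test_decoupled_plateau_matches_kramers(self, ref_model,
                                               ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.0)
        cfg = ck.SimConfig(n_traj=10000, seed=12)
        trace = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
        expected = kappa_kramers(ref_model_sp.omega_b, cfg.gamma)
        assert not trace.flagged
        assert abs(trace.kappa_plateau - expected) < \
            2 * max(trace.plateau_stderr, 0.005)

    @pytest.mark.parametrize("eta", [0.047, 0.188])
    def test_plateau_agrees_with_gh_theory(self, ref_model, ref_model_sp,
                                           eta):
        cav = ref_cavity(ref_model, ref_model_sp, eta)
        cfg = ck.SimConfig(n_traj=10000, seed=13)
        trace = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
        eff = effective_couplings(ref_model_sp, cav, mass=ref_model.mass)
        kappa_gh = ck.gh_lambda_markovian(ref_model_sp.omega_b, cav.omega_c,
                                          eff.C_ddag, cfg.gamma) \
            / ref_model_sp.omega_b
        rel = abs(trace.kappa_plateau - kappa_gh) / kappa_gh
        assert rel < 0.10 or \
            abs(trace.kappa_plateau - kappa_gh) < 2 * trace.plateau_stderr

    def test_plateau_decreases_with_coupling_at_resonance(self, ref_model,
                                                          ref_model_sp):
        plateaus, errs = [], []
        for eta, seed in [(0.047, 21), (0.094, 22), (0.188, 23)]:
            cav = ref_cavity(ref_model, ref_model_sp, eta)
            cfg = ck.SimConfig(n_traj=10000, seed=seed)
            tr = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
            plateaus.append(tr.kappa_plateau)
            errs.append(tr.plateau_stderr)
        for i in range(2):
            gap = plateaus[i] - plateaus[i + 1]
            assert gap > 2 * np.hypot(errs[i], errs[i + 1])

    def test_caging_vs_weak_coupling_trace_shape(self, ref_model,
                                                 ref_model_sp):
        # strong coupling: oscillatory kappa(t) with a low plateau;
        # weak coupling: near-monotone decay to a high plateau
        shapes = {}
        for eta, seed in [(0.047, 31), (0.376, 32)]:
            cav = ref_cavity(ref_model, ref_model_sp, eta)
            cfg = ck.SimConfig(n_traj=4000, seed=seed, save_stride=2)
            tr = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
            early = tr.kappa[tr.times_fs <= 60.0]
            smooth = np.convolve(early, np.ones(9) / 9, mode="valid")
            d = np.diff(smooth)
            n_turns = int(np.sum(np.diff(np.sign(d[d != 0])) != 0))
            shapes[eta] = dict(plateau=tr.kappa_plateau, turns=n_turns,
                               amp=early.max() - early.min(),
                               lowest=early.min())
        caged, weak = shapes[0.376], shapes[0.047]
        assert caged["plateau"] < 0.3 < weak["plateau"]
        # deep recrossing oscillations drive the caged trace below zero
        assert caged["lowest"] < 0.0 < weak["lowest"]
        assert caged["amp"] > 2 * weak["amp"]
        assert caged["turns"] > weak["turns"]

    def test_seeded_determinism_and_seed_independence(self, ref_model,
                                                      ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.094)
        cfg = ck.SimConfig(n_traj=2000, seed=41)
        t1 = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
        t2 = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp)
        assert np.array_equal(t1.kappa, t2.kappa)  # bit-identical
        t3 = ck.kappa_of_t(ref_model, cav,
                           ck.SimConfig(n_traj=2000, seed=42),
                           sp=ref_model_sp)
        assert abs(t1.kappa_plateau - t3.kappa_plateau) < \
            3 * np.hypot(t1.plateau_stderr, t3.plateau_stderr)

    def test_invariant_under_velocity_reflection(self, ref_model,
                                                 ref_model_sp):
        cav = ref_cavity(ref_model, ref_model_sp, 0.094)
        cfg = ck.SimConfig(n_traj=4000, seed=51)
        state = ck.sample_dividing_surface(ref_model, cav, cfg,
                                           sp=ref_model_sp)
        mirrored = state.copy()
        mirrored.P = -mirrored.P
        mirrored.pc = -mirrored.pc
        t1 = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp, state=state)
        t2 = ck.kappa_of_t(ref_model, cav, cfg, sp=ref_model_sp,
                           state=mirrored)
        assert abs(t1.kappa_plateau - t2.kappa_plateau) < \
            3 * np.hypot(t1.plateau_stderr, t2.plateau_stderr)
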