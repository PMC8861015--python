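import numpy as np
import pytest

from swnforce.neuron import noise_drive, sample_params, simulate
from swnforce.synapse import SynapseConfig, SynapticTrace, update_trace
from swnforce.topology import ModularNetworkConfig, build_modular_swn
from swnforce.training import (
    ReadoutState,
    TrainingConfig,
    pink_noise,
    replay,
    rls_update,
    rmse,
    sample_static_weights,
    train,
)


class TestPinkNoise:
    def test_zero_amplitude_is_zero(self):
        assert np.all(pink_noise(256, 3, 0.0, seed=1) == 0)

    def test_deterministic_per_seed(self):
        assert np.array_equal(pink_noise(512, 2, 1.0, seed=4), pink_noise(512, 2, 1.0, seed=4))

    def test_zero_mean_unit_scale(self):
        x = pink_noise(4096, 4, 2.5, seed=0)
        assert np.allclose(x.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(x.std(axis=1), 2.5, rtol=1e-10)

    def test_psd_slope_near_minus_one(self):
        """Log-log periodogram regression over two decades gives a slope
        in [-1.2, -0.8]."""
        x = pink_noise(2**14, 1, 1.0, seed=3)[0]
        psd = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x))
        sel = (f > 1e-3) & (f < 0.4)
        slope = np.polyfit(np.log(f[sel]), np.log(psd[sel]), 1)[0]
        assert -1.2 <= slope <= -0.8


class TestRLS:
    def test_zero_error_leaves_phi_unchanged(self):
        st = ReadoutState.initial(3, alpha=1.0)
        st.phi = np.array([1.0, -2.0, 0.5])
        r = np.array([0.2, 0.1, 0.4])
        y = float(st.phi @ r)
        phi_before = st.phi.copy()
        e = rls_update(st, r, y)
        assert e == 0.0
        assert np.array_equal(st.phi, phi_before)

    def test_first_update_closed_form(self):
        """From P = I/alpha with r = e1, y = 1: phi_1 = 1/(lambda*alpha + 1)
        on the first coordinate, 0 elsewhere."""
        alpha, lam = 2.0, 0.9
        st = ReadoutState.initial(2, alpha=alpha, lambda_f=lam)
        rls_update(st, np.array([1.0, 0.0]), 1.0)
        assert st.phi[0] == pytest.approx(1.0 / (lam * alpha + 1.0), abs=1e-14)
        assert st.phi[1] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_growing_window_equals_batch_ridge(self, seed):
        """lambda_f = 1 RLS is batch ridge regression via the matrix
        inversion lemma: agreement to 1e-8 on random fixtures."""
        rng = np.random.default_rng(seed)
        n_feat, n_samp = 5, 50
        R = rng.standard_normal((n_samp, n_feat))
        y = rng.standard_normal(n_samp)
        alpha = 0.7
        st = ReadoutState.initial(n_feat, alpha=alpha)
        for t in range(n_samp):
            rls_update(st, R[t], y[t])
        batch = np.linalg.solve(R.T @ R + alpha * np.eye(n_feat), R.T @ y)
        assert np.allclose(st.phi, batch, atol=1e-8)

    def test_divergence_aborts(self):
        st = ReadoutState.initial(2, alpha=1.0)
        with pytest.raises(FloatingPointError):
            rls_update(st, np.array([np.nan, 0.0]), 1.0)

    def test_initial_p_is_identity_over_alpha(self):
        st = ReadoutState.initial(4, alpha=5.0)
        assert np.array_equal(st.P, np.eye(4) / 5.0)
        with pytest.raises(ValueError):
            ReadoutState.initial(4, alpha=0.0)


class TestRmse:
    def test_examples(self):
        assert rmse(np.arange(5.0), np.arange(5.0)) == 0.0
        assert rmse(np.arange(5.0) + 1.0, np.arange(5.0)) == 1.0
        assert rmse(np.zeros(2), np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))


@pytest.fixture(scope="module")
def train_network():
    net = build_modular_swn(
        ModularNetworkConfig(n_modules=2, module_size=80, n_inhibitory=40, seed=21)
    )
    params = sample_params(net.neuron_type, seed=22)
    return net, params


class TestTrain:
    def test_rmse_decreases_across_epochs(self, train_network):
        """Repeated presentation of the same sinusoid refines phi."""
        net, params = train_network
        y = 30.0 * np.sin(2 * np.pi * np.arange(800) / 250.0)
        cfg = TrainingConfig(chaos_steps=150, epochs=3, alpha=50.0, stimulus_seed=1)
        fit = train(net, params, y, cfg)
        assert fit.rmse_per_epoch[1] < fit.rmse_per_epoch[0]
        assert fit.rmse_per_epoch[2] <= fit.rmse_per_epoch[1]
        assert fit.rmse == fit.rmse_per_epoch[-1]

    def test_zero_target_zero_stimulus_gives_zero_output(self, train_network):
        net, params = train_network
        cfg = TrainingConfig(chaos_steps=50, stimulus_amplitude=0.0, alpha=10.0)
        fit = train(net, params, np.zeros(200), cfg)
        assert np.all(fit.z == 0.0)
        assert fit.rmse == 0.0

    def test_modified_mode_raster_invariant_to_readout(self, train_network):
        """The readout is a pure observer: the training-phase raster is
        bit-for-bit the raster of a plain simulation with the same
        stimulus."""
        net, params = train_network
        y = 20.0 * np.sin(2 * np.pi * np.arange(400) / 100.0)
        cfg = TrainingConfig(chaos_steps=100, alpha=50.0, stimulus_seed=9)
        fit = train(net, params, y, cfg)
        stim = fit.replay_bundle["stimulus"]
        sim = simulate(net, params, stim, stim.shape[1])
        keep = sim.raster.steps >= cfg.chaos_steps
        assert np.array_equal(sim.raster.steps[keep] - cfg.chaos_steps, fit.raster.steps)
        assert np.array_equal(sim.raster.neurons[keep], fit.raster.neurons)

    def test_full_force_feedback_changes_dynamics(self, train_network):
        net, params = train_network
        y = 20.0 * np.sin(2 * np.pi * np.arange(400) / 100.0)
        base = dict(chaos_steps=100, alpha=50.0, stimulus_seed=9)
        fit_mod = train(net, params, y, TrainingConfig(mode="modified", **base))
        fit_ff = train(net, params, y, TrainingConfig(mode="full_force", Q=1.0, **base))
        same = len(fit_mod.raster.steps) == len(fit_ff.raster.steps) and np.array_equal(
            fit_mod.raster.steps, fit_ff.raster.steps
        )
        assert not same

    def test_tikhonov_limit_shrinks_phi(self, train_network):
        """On a fixed fixture, ||phi|| decreases monotonically in alpha."""
        net, params = train_network
        y = 25.0 * np.sin(2 * np.pi * np.arange(300) / 120.0)
        norms = []
        for alpha in (1.0, 100.0, 10000.0, 1e6):
            cfg = TrainingConfig(chaos_steps=100, alpha=alpha, stimulus_seed=2)
            norms.append(np.linalg.norm(train(net, params, y, cfg).readout.phi))
        assert norms[0] > norms[1] > norms[2] > norms[3]

    def test_parameter_recovery(self, train_network):
        """A target built as phi*^T r(t) from the frozen dynamics is
        recovered to relative L2 error below 1e-3."""
        net, params = train_network
        cfg = TrainingConfig(
            chaos_steps=150, update_interval=1, alpha=1e-8, stimulus_seed=30
        )
        syn = SynapseConfig()
        # generate features by running the identical pipeline once
        probe = train(net, params, np.zeros(900), cfg, syn)
        stim = probe.replay_bundle["stimulus"]
        sim = simulate(net, params, stim, stim.shape[1])
        dense = sim.raster.to_dense()
        tr = SynapticTrace.zeros(net.n_neurons)
        R = np.empty((900, net.n_neurons))
        for t in range(stim.shape[1]):
            update_trace(tr, dense[:, t], syn)
            if t >= cfg.chaos_steps:
                R[t - cfg.chaos_steps] = tr.r
        active = R.sum(axis=0) > 0
        rng = np.random.default_rng(0)
        phi_star = np.where(active, rng.standard_normal(net.n_neurons), 0.0)
        y = R @ phi_star
        fit = train(net, params, y, cfg, syn)
        err = np.linalg.norm(fit.readout.phi - phi_star) / np.linalg.norm(phi_star)
        assert err < 1e-3

    def test_undirected_large_alpha_warns(self):
        net = build_modular_swn(
            ModularNetworkConfig(n_modules=2, module_size=40, n_inhibitory=20,
                                 directed=False, seed=31)
        )
        params = sample_params(net.neuron_type, seed=32)
        with pytest.warns(UserWarning, match="alpha"):
            train(net, params, np.zeros(64),
                  TrainingConfig(chaos_steps=0, alpha=2200.0))


class TestReplay:
    def test_replay_reproduces_training_output_bitwise(self, train_network):
        net, params = train_network
        y = 20.0 * np.sin(2 * np.pi * np.arange(500) / 180.0)
        cfg = TrainingConfig(chaos_steps=120, alpha=30.0, stimulus_seed=3)
        fit = train(net, params, y, cfg)
        rep = replay(net, params, fit, target=y)
        assert np.array_equal(rep.z, fit.z)
        assert rep.rmse == fit.rmse

    def test_replay_with_other_stimulus_diverges(self, train_network):
        net, params = train_network
        y = 20.0 * np.sin(2 * np.pi * np.arange(500) / 180.0)
        cfg = TrainingConfig(chaos_steps=120, alpha=30.0, stimulus_seed=3)
        fit = train(net, params, y, cfg)
        other = pink_noise(620, net.n_neurons, cfg.stimulus_amplitude, seed=999)
        rep = replay(net, params, fit, target=y, stimulus=other)
        assert not np.array_equal(rep.z, fit.z)
        assert rep.rmse > fit.rmse

    def test_horizon_beyond_training_reuses_final_window(self, train_network):
        net, params = train_network
        y = 20.0 * np.sin(2 * np.pi * np.arange(300) / 100.0)
        cfg = TrainingConfig(chaos_steps=80, alpha=30.0, stimulus_seed=5)
        fit = train(net, params, y, cfg)
        rep = replay(net, params, fit, horizon=450)
        assert len(rep.z) == 450
        assert np.array_equal(rep.z[:300], fit.z)

    def test_replay_requires_history(self, train_network):
        net, params = train_network
        from swnforce.training import FitResult
        from swnforce.neuron import SpikeRaster
        empty = FitResult(
            z=np.zeros(1), rmse=0.0, rmse_per_epoch=[0.0], weight_history=[],
            dphi_mean=np.zeros(1), dphi_sd=np.zeros(1),
            raster=SpikeRaster(np.empty(0, int), np.empty(0, int), 1, net.n_neurons),
        )
        with pytest.raises(ValueError):
            replay(net, params, empty)


def test_static_weights_decomposition_roundtrip():
    sw = sample_static_weights(50, p=0.1, G=1.5, Q=2.0, seed=8)
    phi = np.random.default_rng(9).standard_normal(50)
    xi = sw.compose(phi)
    assert np.allclose(xi, 1.5 * sw.xi0 + 2.0 * np.outer(sw.eta, phi))
    assert sw.xi0.std() == pytest.approx(np.sqrt(1 / (50 * 0.1)), rel=0.1)
    assert -1 <= sw.u <= 1
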