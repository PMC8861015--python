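"""Feedback-free FORCE training of a linear readout on a spiking network.

The readout z(t) = phi(t)^T r(t) maps the synapse-filtered spike trains
r(t) of the recurrent network onto a scalar target y(t).  phi is learned
online by recursive least squares (RLS) with Tikhonov regularisation
alpha and forgetting factor lambda_f, updated every ``update_interval``
steps:

    e    = y_t - phi^T r
    k    = P r / (lambda_f + r^T P r)
    phi <- phi + k e
    P   <- (P - k r^T P) / lambda_f,         P(0) = I / alpha

In the *modified* mode (the default) the readout never re-enters the
network: phi is a pure observer, so the spiking dynamics are identical
whether or not the readout is computed, and silent neurons (whose traces
stay at zero) contribute nothing to the updates.  The *full_force* mode
adds the classical rank-one feedback current Q * eta * z(t) to every
neuron's input, reproducing the original feedback-driven algorithm for
comparison.

Training runs in three phases: a chaos warm-up with no learning (the
network is driven into its high-dimensional chaotic regime by a pink
noise stimulus), the training phase with per-window snapshots of phi,
and an optional replay phase that restores the post-warm-up state and
the identical stimulus and free-runs with the stored weights, with no
optimisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neuron import (
    DelayBuffer,
    IzhikevichParams,
    NeuronState,
    SpikeRaster,
    initial_state,
    step,
)
from .synapse import SynapseConfig, SynapticTrace, update_trace
from .topology import WeightedNetwork

__all__ = [
    "StaticWeights",
    "ReadoutState",
    "TrainingConfig",
    "FitResult",
    "pink_noise",
    "sample_static_weights",
    "rls_update",
    "rmse",
    "train",
    "replay",
]


def pink_noise(
    n_steps: int,
    n_series: int = 1,
    amplitude: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean 1/f ("pink") noise, the canonical neuronal drive.

    Returns an (n_series, n_steps) array; each row has RMS ``amplitude``
    and a power spectral density falling as 1/f (log-log slope -1).
    Deterministic per seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if amplitude == 0:
        return np.zeros((n_series, n_steps))
    white = rng.standard_normal((n_series, n_steps))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_steps)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n_steps, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return amplitude * x / sd


@dataclass
class StaticWeights:
    """Decomposition xi = G*xi0 + Q*eta*phi^T of a generic reservoir.

    xi0 holds the baseline chaotic weights (entries N(0, 1/(N p))), G
    scales the chaos, and the rank-one term Q*eta*phi^T is the feedback
    loop; the modified (feedback-free) mode fixes Q = 0.  ``u`` is the
    dimensionless uniform(-1, 1) scalar weighting the target-network
    output in the learning objective.
    """

    xi0: np.ndarray
    G: float
    Q: float
    eta: np.ndarray
    u: float

    def compose(self, phi: np.ndarray) -> np.ndarray:
        return self.G * self.xi0 + self.Q * np.outer(self.eta, phi)


def sample_static_weights(
    n: int, p: float, G: float = 1.0, Q: float = 1.0, seed: int = 0
) -> StaticWeights:
    """Draw a generic chaotic reservoir decomposition for N neurons."""
    if not 0 < p <= 1:
        raise ValueError("connection randomness p must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    xi0 = rng.normal(0.0, np.sqrt(1.0 / (n * p)), size=(n, n))
    return StaticWeights(
        xi0=xi0,
        G=G,
        Q=Q,
        eta=rng.uniform(-1.0, 1.0, size=n),
        u=float(rng.uniform(-1.0, 1.0)),
    )


@dataclass
class ReadoutState:
    """Decoder weights and inverse-correlation estimate of the RLS filter."""

    phi: np.ndarray
    P: np.ndarray
    alpha: float
    lambda_f: float = 1.0
    weight_history: list = field(default_factory=list)

    @classmethod
    def initial(cls, n: int, alpha: float, lambda_f: float = 1.0) -> "ReadoutState":
        if alpha <= 0:
            raise ValueError("Tikhonov alpha must be strictly positive")
        if not 0 < lambda_f <= 1:
            raise ValueError("forgetting factor must lie in (0, 1]")
        return cls(
            phi=np.zeros(n), P=np.eye(n) / alpha, alpha=alpha, lambda_f=lambda_f
        )


def rls_update(state: ReadoutState, r: np.ndarray, y_t: float) -> float:
    """One recursive-least-squares update of phi and P; returns the error.

    With lambda_f = 1 (growing window) the sequence of updates is
    algebraically identical to batch ridge regression
    phi = (sum r r^T + alpha I)^(-1) sum r y via the matrix-inversion
    lemma.
    """
    if not (np.all(np.isfinite(r)) and np.isfinite(y_t)):
        raise FloatingPointError("non-finite RLS inputs (features or target)")
    e = float(y_t - state.phi @ r)
    pr = state.P @ r
    k = pr / (state.lambda_f + float(r @ pr))
    state.phi = state.phi + k * e
    p_new = (state.P - np.outer(k, pr)) / state.lambda_f
    state.P = 0.5 * (p_new + p_new.T)  # enforce symmetry against drift
    if not np.all(np.isfinite(state.phi)):
        raise FloatingPointError("RLS diverged: non-finite readout weights")
    return e


def rmse(z: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error between two equal-length series."""
    z, y = np.asarray(z), np.asarray(y)
    if z.shape != y.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((z - y) ** 2)))


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the training procedure.

    alpha defaults to 2200 (the directed-network setting); undirected
    networks require alpha << N and trigger a warning otherwise.  The
    update cadence of every 2 steps is the finest non-overlapping window
    the two-step objective admits.
    """

    chaos_steps: int = 500
    update_interval: int = 2
    epochs: int = 1
    alpha: float = 2200.0
    lambda_f: float = 1.0
    mode: str = "modified"
    stimulus_amplitude: float = 20.0
    stimulus_seed: int = 0
    dt: float = 1.0
    G: float = 1.0
    Q: float = 1.0
    use_target_network: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("modified", "full_force"):
            raise ValueError(f"unknown training mode {self.mode!r}")
        if self.update_interval < 1:
            raise ValueError("update_interval must be >= 1")
        if self.chaos_steps < 0:
            raise ValueError("chaos_steps must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be strictly positive")
        if not 0 < self.lambda_f <= 1:
            raise ValueError("lambda_f must lie in (0, 1]")


@dataclass
class FitResult:
    """Outcome of a training or replay run."""

    z: np.ndarray
    rmse: float
    rmse_per_epoch: list
    weight_history: list
    dphi_mean: np.ndarray
    dphi_sd: np.ndarray
    raster: SpikeRaster
    readout: ReadoutState | None = None
    replay_bundle: dict | None = None


class _NetworkRunner:
    """Steps one spiking network + synaptic trace with shared ordering.

    The consume -> integrate -> deposit -> filter sequence is identical
    to :func:`swnforce.neuron.simulate`, which is what makes the
    modified mode's raster provably independent of the readout.
    """

    def __init__(self, network, params, syn_config):
        self.network = network
        self.params = params
        self.syn = syn_config
        self.buffer = DelayBuffer(network)
        self.state = initial_state(params)
        self.trace = SynapticTrace.zeros(network.n_neurons)

    def snapshot(self) -> dict:
        return {
            "state": self.state.copy(),
            "trace": self.trace.copy(),
            "slots": self.buffer._slots.copy(),
        }

    def restore(self, snap: dict) -> None:
        self.state = snap["state"].copy()
        self.trace = snap["trace"].copy()
        self.buffer._slots = snap["slots"].copy()

    def advance(self, external: np.ndarray, dt: float) -> np.ndarray:
        syn = self.buffer.consume(self.state.t)
        fired = step(self.state, self.params, syn + external, dt)
        if fired.any():
            self.buffer.deposit(self.state.t - 1, fired)
        update_trace(self.trace, fired, self.syn, dt)
        return fired


def train(
    network: WeightedNetwork,
    params: IzhikevichParams,
    target: np.ndarray,
    config: TrainingConfig = TrainingConfig(),
    syn_config: SynapseConfig = SynapseConfig(),
) -> FitResult:
    """Learn the readout for ``target`` with modified (or full) FORCE.

    The task network is driven by a seeded pink-noise stimulus; after
    ``chaos_steps`` of warm-up with no learning, RLS updates run every
    ``update_interval`` steps against the target sample, with phi
    snapshotted per update window.  Each epoch restores the post-warm-up
    state and replays the same stimulus, so with lambda_f = 1 the
    accumulated correlation matrix sees the same features repeatedly and
    phi converges across epochs.

    In ``modified`` mode the readout is a pure observer.  In
    ``full_force`` mode the feedback current Q * eta * z(t) is injected
    into every neuron each step; with ``use_target_network=True`` a
    second, identically structured network is driven by the target
    signal (input current eta_tgt * u * y(t)) and its fixed random
    readout z_target enters the learning signal as y(t) + u * z_target,
    the two-network form of the objective.
    """
    target = np.asarray(target, dtype=np.float64)
    t_train = len(target)
    n = network.n_neurons
    if not network.directed and config.alpha > 0.1 * n:
        warnings.warn(
            f"undirected network with alpha={config.alpha:g} not << N={n}: "
            "RLS may diverge; use a small alpha (e.g. 2)",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.stimulus_seed)
    stimulus = pink_noise(
        config.chaos_steps + t_train, n, config.stimulus_amplitude, rng
    )
    eta = rng.uniform(-1.0, 1.0, size=n)
    u = float(rng.uniform(-1.0, 1.0))

    runner = _NetworkRunner(network, params, syn_config)
    tgt_runner = (
        _NetworkRunner(network, params, syn_config)
        if config.use_target_network
        else None
    )
    eta_tgt = rng.uniform(-1.0, 1.0, size=n)

    for t in range(config.chaos_steps):
        runner.advance(stimulus[:, t], config.dt)
        if tgt_runner is not None:
            tgt_runner.advance(stimulus[:, t], config.dt)
    snap0 = runner.snapshot()
    tgt_snap0 = tgt_runner.snapshot() if tgt_runner is not None else None

    readout = ReadoutState.initial(n, config.alpha, config.lambda_f)
    z = np.empty(t_train)
    rmse_per_epoch: list[float] = []
    dphi: list[float] = []
    hist: list[np.ndarray] = []
    ev_steps: list[np.ndarray] = []
    ev_neurons: list[np.ndarray] = []

    for epoch in range(config.epochs):
        runner.restore(snap0)
        if tgt_runner is not None:
            tgt_runner.restore(tgt_snap0)
        last = epoch == config.epochs - 1
        if last:
            hist = []
        z_prev = 0.0
        for t in range(t_train):
            ext = stimulus[:, config.chaos_steps + t].copy()
            if config.mode == "full_force":
                ext += config.Q * eta * z_prev
            fired = runner.advance(ext, config.dt)
            if last and fired.any():
                idx = np.flatnonzero(fired)
                ev_steps.append(np.full(len(idx), t, dtype=np.int64))
                ev_neurons.append(idx.astype(np.int64))
            d_t = target[t]
            if tgt_runner is not None:
                tgt_runner.advance(
                    stimulus[:, config.chaos_steps + t] + eta_tgt * (u * target[t]),
                    config.dt,
                )
                d_t = target[t] + u * float(eta_tgt @ tgt_runner.trace.r) / n
            if t % config.update_interval == 0:
                phi_before = readout.phi
                rls_update(readout, runner.trace.r, d_t)
                dphi.append(float(np.linalg.norm(readout.phi - phi_before)))
                if last:
                    hist.append(readout.phi.copy())
            z[t] = float(readout.phi @ runner.trace.r)
            z_prev = z[t]
        rmse_per_epoch.append(rmse(z, target))

    readout.weight_history = hist
    raster = SpikeRaster(
        steps=np.concatenate(ev_steps) if ev_steps else np.empty(0, dtype=np.int64),
        neurons=np.concatenate(ev_neurons) if ev_neurons else np.empty(0, dtype=np.int64),
        duration=t_train,
        n_neurons=n,
    )
    dphi_arr = np.asarray(dphi)
    n_upd = len(hist)
    return FitResult(
        z=z,
        rmse=rmse_per_epoch[-1],
        rmse_per_epoch=rmse_per_epoch,
        weight_history=hist,
        dphi_mean=dphi_arr.reshape(config.epochs, n_upd).mean(axis=1),
        dphi_sd=dphi_arr.reshape(config.epochs, n_upd).std(axis=1),
        raster=raster,
        readout=readout,
        replay_bundle={
            "snapshot": snap0,
            "stimulus": stimulus,
            "chaos_steps": config.chaos_steps,
            "update_interval": config.update_interval,
            "dt": config.dt,
            "stimulus_seed": config.stimulus_seed,
            "stimulus_amplitude": config.stimulus_amplitude,
        },
    )


def replay(
    network: WeightedNetwork,
    params: IzhikevichParams,
    fit: FitResult,
    horizon: int | None = None,
    target: np.ndarray | None = None,
    syn_config: SynapseConfig = SynapseConfig(),
    stimulus: np.ndarray | None = None,
) -> FitResult:
    """Free-run the trained system with stored per-window weights.

    Restores the post-warm-up state of the training run and re-injects
    the identical stimulus; at each step the readout uses the phi
    snapshot of the corresponding update window, with no RLS updates.
    With the same network, parameters and stimulus, the replayed output
    over the training horizon is bit-for-bit the training-phase output.
    Beyond the stored horizon the final window's weights are reused and
    the stimulus is extended with fresh pink noise (seeded from the
    training stimulus seed + 1).
    """
    bundle = fit.replay_bundle
    if bundle is None or not fit.weight_history:
        raise ValueError("fit carries no replay bundle / weight history")
    chaos = bundle["chaos_steps"]
    interval = bundle["update_interval"]
    stim = stimulus if stimulus is not None else bundle["stimulus"]
    t_stored = stim.shape[1] - chaos
    horizon = t_stored if horizon is None else horizon
    if horizon > t_stored:
        extra = pink_noise(
            horizon - t_stored,
            network.n_neurons,
            bundle["stimulus_amplitude"],
            seed=bundle["stimulus_seed"] + 1,
        )
        stim = np.concatenate([stim, extra], axis=1)

    runner = _NetworkRunner(network, params, syn_config)
    runner.restore(bundle["snapshot"])
    hist = fit.weight_history
    z = np.empty(horizon)
    ev_steps, ev_neurons = [], []
    for t in range(horizon):
        fired = runner.advance(stim[:, chaos + t], bundle["dt"])
        if fired.any():
            idx = np.flatnonzero(fired)
            ev_steps.append(np.full(len(idx), t, dtype=np.int64))
            ev_neurons.append(idx.astype(np.int64))
        phi = hist[min(t // interval, len(hist) - 1)]
        z[t] = float(phi @ runner.trace.r)

    raster = SpikeRaster(
        steps=np.concatenate(ev_steps) if ev_steps else np.empty(0, dtype=np.int64),
        neurons=np.concatenate(ev_neurons) if ev_neurons else np.empty(0, dtype=np.int64),
        duration=horizon,
        n_neurons=network.n_neurons,
    )
    err = rmse(z[: len(target)], np.asarray(target)[: horizon]) if target is not None else float("nan")
    return FitResult(
        z=z,
        rmse=err,
        rmse_per_epoch=[err],
        weight_history=hist,
        dphi_mean=np.zeros(1),
        dphi_sd=np.zeros(1),
        raster=raster,
        readout=None,
        replay_bundle=None,
    )
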