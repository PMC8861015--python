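"""Izhikevich spiking neurons over a delay-annotated network.

The two-variable Izhikevich model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + S
    du/dt = a (b v - u)
    if v >= 30 mV:  v <- c,  u <- u + d

is integrated with forward Euler at 1 ms resolution (two 0.5 ms substeps
for the stiff voltage equation, one full step for the recovery variable
— the standard published scheme for Izhikevich network simulations).
Synaptic transmission is event-based: a spike of neuron j at step t
deposits weight w_ij into postsynaptic neuron i's input current at step
t + delay_ij, via a ring buffer.

Heterogeneity follows the canonical cortical parameterisation: excitatory
neurons interpolate between regular-spiking and chattering types via a
squared-uniform draw, inhibitory neurons between fast-spiking and
low-threshold-spiking types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array

from .topology import WeightedNetwork

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "SpikeRaster",
    "DelayBuffer",
    "sample_params",
    "step",
    "simulate",
    "noise_drive",
    "write_raster",
    "read_raster",
]

SPIKE_THRESHOLD_MV = 30.0


@dataclass
class IzhikevichParams:
    """Per-neuron Izhikevich parameters (length-N vectors).

    a : recovery time constant (1/ms); b : recovery sensitivity
    (1e-9/Ohm); c : after-spike reset potential (mV); d : after-spike
    recovery increment (pA).
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    @property
    def n_neurons(self) -> int:
        return len(self.a)


@dataclass
class NeuronState:
    """Membrane potential v (mV), recovery u (pA), and current step t (ms)."""

    v: np.ndarray
    u: np.ndarray
    t: int = 0

    def copy(self) -> "NeuronState":
        return NeuronState(self.v.copy(), self.u.copy(), self.t)


@dataclass
class SpikeRaster:
    """Spike events as parallel (step, neuron) index arrays."""

    steps: np.ndarray
    neurons: np.ndarray
    duration: int
    n_neurons: int

    def __len__(self) -> int:
        return len(self.steps)

    def to_dense(self) -> np.ndarray:
        """Boolean (n_neurons, duration) spike matrix."""
        dense = np.zeros((self.n_neurons, self.duration), dtype=bool)
        dense[self.neurons, self.steps] = True
        return dense

    def spike_counts(self) -> np.ndarray:
        return np.bincount(self.neurons, minlength=self.n_neurons)


def sample_params(
    neuron_type: np.ndarray, seed: int | np.random.Generator = 0
) -> IzhikevichParams:
    """Draw heterogeneous Izhikevich parameters per neuron type.

    Excitatory: a = 0.02, b = 0.2, c = -65 + 15 U^2, d = 8 - 6 U^2 with
    U ~ uniform(0, 1) — U = 0 gives the regular-spiking type (-65, 8),
    U = 1 the chattering type (-50, 2).  Inhibitory: a = 0.02 + 0.08 U^2,
    b = 0.25 - 0.05 U^2, c = -65, d = 2.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    exc = np.asarray(neuron_type) == "excitatory"
    n = len(exc)
    re = rng.uniform(0.0, 1.0, size=n) ** 2
    a = np.where(exc, 0.02, 0.02 + 0.08 * re)
    b = np.where(exc, 0.2, 0.25 - 0.05 * re)
    c = np.where(exc, -65.0 + 15.0 * re, -65.0)
    d = np.where(exc, 8.0 - 6.0 * re, 2.0)
    return IzhikevichParams(a=a, b=b, c=c, d=d)


def initial_state(params: IzhikevichParams) -> NeuronState:
    """Resting initial conditions v = -65 mV, u = b*v."""
    v = np.full(params.n_neurons, -65.0)
    return NeuronState(v=v, u=params.b * v, t=0)


def step(
    state: NeuronState,
    params: IzhikevichParams,
    input_current: np.ndarray,
    dt: float = 1.0,
    voltage_out: np.ndarray | None = None,
) -> np.ndarray:
    """Advance one dt-millisecond step in place; return the spike mask.

    The voltage equation is integrated in two dt/2 Euler substeps for
    numerical stability, the recovery variable in one full step.  After
    integration, neurons with v >= 30 mV are flagged, then reset
    (v <- c, u <- u + d).  If ``voltage_out`` is given, the pre-reset
    voltages (unclipped spike peaks) are written into it.  Raises
    FloatingPointError on numerical blow-up (non-finite state).
    """
    v, u = state.v, state.u
    for _ in range(2):
        v += 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + input_current)
    u += dt * params.a * (params.b * v - u)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise FloatingPointError(
            f"non-finite neuron state at step {state.t}: check input currents"
        )
    if voltage_out is not None:
        voltage_out[:] = v
    fired = v >= SPIKE_THRESHOLD_MV
    v[fired] = params.c[fired]
    u[fired] += params.d[fired]
    state.t += 1
    return fired


class DelayBuffer:
    """Ring buffer of pending synaptic currents.

    A spike of neuron j at step t deposits ``weights[:, j]`` into slot
    ``(t + delay_ij) mod L`` for every postsynaptic i; the slot for the
    current step is consumed (and cleared) before integration.  Synapses
    are grouped by delay so each deposit is a sparse matrix-vector
    product per distinct delay value.
    """

    def __init__(self, network: WeightedNetwork):
        delays = network.delays
        present = network.weights != 0
        self.max_delay = int(delays.max()) if present.any() else 1
        self._slots = np.zeros((self.max_delay + 1, network.n_neurons))
        self._by_delay: list[tuple[int, csr_array]] = []
        for d in np.unique(delays[present]):
            w_d = np.where(delays == d, network.weights, 0.0)
            self._by_delay.append((int(d), csr_array(w_d)))

    def deposit(self, t: int, fired: np.ndarray) -> None:
        """Queue the synaptic currents caused by the spikes at step t."""
        if not fired.any():
            return
        x = fired.astype(np.float64)
        for d, w_d in self._by_delay:
            self._slots[(t + d) % len(self._slots)] += w_d @ x

    def consume(self, t: int) -> np.ndarray:
        """Return and clear the current arriving at step t."""
        slot = (t % len(self._slots))
        current = self._slots[slot].copy()
        self._slots[slot] = 0.0
        return current

    def reset(self) -> None:
        self._slots[:] = 0.0


@dataclass
class SimulationResult:
    raster: SpikeRaster
    voltages: np.ndarray | None = None
    synaptic_currents: np.ndarray | None = None
    final_state: NeuronState | None = None


def simulate(
    network: WeightedNetwork,
    params: IzhikevichParams,
    stimulus: np.ndarray,
    duration_ms: int,
    state: NeuronState | None = None,
    record_voltages: bool = False,
    record_currents: bool = False,
) -> SimulationResult:
    """Integrate the network for ``duration_ms`` 1 ms steps.

    Parameters
    ----------
    stimulus : (n_neurons, duration) array
        External input current in pA added to the synaptic current each
        step (e.g. noise drive or pink-noise stimulus).
    state : optional initial NeuronState (default: rest, v=-65, u=b*v).

    Returns the spike raster, optionally the (unclipped) voltage traces
    and per-step delivered synaptic currents, and the final state.
    """
    n = network.n_neurons
    stimulus = np.asarray(stimulus)
    if stimulus.shape[0] != n or stimulus.shape[1] < duration_ms:
        raise ValueError(
            f"stimulus must be (n_neurons, >= duration); got {stimulus.shape}"
        )
    if params.n_neurons != n:
        raise ValueError("params and network disagree on neuron count")

    st = state.copy() if state is not None else initial_state(params)
    buf = DelayBuffer(network)
    volts = np.empty((n, duration_ms)) if record_voltages else None
    currents = np.empty((n, duration_ms)) if record_currents else None

    ev_steps: list[np.ndarray] = []
    ev_neurons: list[np.ndarray] = []
    for t in range(duration_ms):
        syn = buf.consume(st.t)
        if record_currents:
            currents[:, t] = syn
        total = syn + stimulus[:, t]
        vout = volts[:, t] if record_voltages else None
        fired = step(st, params, total, voltage_out=vout)
        if fired.any():
            idx = np.flatnonzero(fired)
            ev_steps.append(np.full(len(idx), t, dtype=np.int64))
            ev_neurons.append(idx.astype(np.int64))
            buf.deposit(st.t - 1, fired)

    raster = SpikeRaster(
        steps=np.concatenate(ev_steps) if ev_steps else np.empty(0, dtype=np.int64),
        neurons=np.concatenate(ev_neurons) if ev_neurons else np.empty(0, dtype=np.int64),
        duration=duration_ms,
        n_neurons=n,
    )
    return SimulationResult(
        raster=raster, voltages=volts, synaptic_currents=currents, final_state=st
    )


def noise_drive(
    neuron_type: np.ndarray,
    duration_ms: int,
    seed: int | np.random.Generator = 0,
    sigma_exc: float = 5.0,
    sigma_inh: float = 2.0,
) -> np.ndarray:
    """Per-step Gaussian background drive (pA), the canonical cortical
    noise input: sigma 5 for excitatory neurons, 2 for inhibitory.

    Returns an (n_neurons, duration_ms) stimulus array.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exc = np.asarray(neuron_type) == "excitatory"
    sigma = np.where(exc, sigma_exc, sigma_inh)
    return sigma[:, None] * rng.standard_normal((len(exc), duration_ms))


def write_raster(raster: SpikeRaster, path: str) -> None:
    """Two-column text file: step_ms neuron_index (one spike per line)."""
    with open(path, "w") as fh:
        fh.write(f"# duration={raster.duration} n_neurons={raster.n_neurons}\n")
        for t, i in zip(raster.steps, raster.neurons):
            fh.write(f"{t} {i}\n")


def read_raster(path: str) -> SpikeRaster:
    steps, neurons = [], []
    duration = n_neurons = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                meta = dict(kv.split("=") for kv in line[1:].split())
                duration = int(meta.get("duration", 0))
                n_neurons = int(meta.get("n_neurons", 0))
                continue
            if not line.strip():
                continue
            try:
                t_s, i_s = line.split()
                steps.append(int(t_s))
                neurons.append(int(i_s))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed raster row") from exc
    return SpikeRaster(
        steps=np.asarray(steps, dtype=np.int64),
        neurons=np.asarray(neurons, dtype=np.int64),
        duration=duration or (max(steps) + 1 if steps else 0),
        n_neurons=n_neurons or (max(neurons) + 1 if neurons else 0),
    )
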