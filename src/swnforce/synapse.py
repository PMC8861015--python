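"""Synaptic filtering of spike trains.

Turns binary spike events into continuous activity traces r(t) — the
regression features of the readout — and into postsynaptic currents.
Three linear kernels are supported:

single exponential   dr/dt = -r/tau_s + (1/(tau_s tau_d)) * sum_k delta(t - t_k)
double exponential   dr/dt = -r/tau_d + h
                     dh/dt = -h/tau_r + (1/(tau_r tau_d)) * sum_k delta(t - t_k)
alpha                double exponential with tau_r = tau_d

Because the kernels are linear ODEs with known solutions, the per-step
update uses the exact matrix exponential of the two-state system (plain
exponential decay for the single kernel) rather than Euler stepping, so
a single-spike response matches its closed form to machine precision at
any dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SynapseConfig", "SynapticTrace", "update_trace", "synaptic_current"]


@dataclass(frozen=True)
class SynapseConfig:
    """Kernel kind and time constants (ms).

    ``single`` decays with ``tau_s`` and injects impulses with gain
    1/(tau_s*tau_d).  ``double`` uses rise ``tau_r`` and decay ``tau_d``;
    ``alpha`` forces tau_r == tau_d.
    """

    kind: str = "double"
    tau_s: float = 10.0
    tau_r: float = 2.0
    tau_d: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("single", "double", "alpha"):
            raise ValueError(f"unknown synapse kind {self.kind!r}")
        if min(self.tau_s, self.tau_r, self.tau_d) <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.kind == "alpha" and self.tau_r != self.tau_d:
            object.__setattr__(self, "tau_r", self.tau_d)


@dataclass
class SynapticTrace:
    """Filtered activity r (1/ms) and auxiliary state h (1/ms^2)."""

    r: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SynapticTrace":
        return cls(r=np.zeros(n), h=np.zeros(n))

    def copy(self) -> "SynapticTrace":
        return SynapticTrace(self.r.copy(), self.h.copy())


def update_trace(
    trace: SynapticTrace,
    spikes: np.ndarray,
    config: SynapseConfig,
    dt: float = 1.0,
) -> SynapticTrace:
    """Advance the trace by one step of length dt, in place.

    Spikes are treated as unit impulses at the start of the step: they
    are injected (into r for the single kernel with gain 1/(tau_s*tau_d),
    into h for double/alpha with gain 1/(tau_r*tau_d)), then the state is
    propagated exactly over dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s = np.asarray(spikes, dtype=np.float64)
    if config.kind == "single":
        trace.r += s / (config.tau_s * config.tau_d)
        trace.r *= np.exp(-dt / config.tau_s)
        return trace

    tau_r, tau_d = config.tau_r, config.tau_d
    trace.h += s / (tau_r * tau_d)
    cd = np.exp(-dt / tau_d)
    cr = np.exp(-dt / tau_r)
    if tau_r == tau_d:  # alpha kernel: degenerate eigenvalues
        trace.r = trace.r * cd + trace.h * dt * cd
    else:
        coupling = (cd - cr) / (1.0 / tau_r - 1.0 / tau_d)
        trace.r = trace.r * cd + trace.h * coupling
    trace.h *= cr
    return trace


def synaptic_current(weights: np.ndarray, trace: SynapticTrace) -> np.ndarray:
    """Postsynaptic currents z = W r (pA), rows postsynaptic."""
    weights = np.asarray(weights)
    if weights.shape[-1] != trace.r.shape[0]:
        raise ValueError(
            f"weight columns ({weights.shape[-1]}) must match trace length "
            f"({trace.r.shape[0]})"
        )
    return weights @ trace.r
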