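"""Dynamical complexity of modular spiking activity.

Quantifies the balance of segregation and integration in the network's
activity, in the Tononi-Sporns-Edelman tradition: per-module mean firing
rates are computed in sliding windows, detrended by second-order
differencing, and treated as a multivariate Gaussian system S of M
components.  With H(.) the Gaussian (differential) entropy in nats,

    H(S)   = 1/2 ln((2 pi e)^M |COV(S)|)
    I(S)   = sum_i H(X_i) - H(S)                       (integration)
    MI_i   = H(X_i) + H(S - {X_i}) - H(S)              (mutual information)
    C(S)   = sum_i MI_i - I(S)                         (dynamical complexity)

C(S) vanishes both for fully independent modules (all MI_i and I zero)
and for fully interlocked activity, and peaks when modules act partly
independently while still exchanging information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .neuron import SpikeRaster

__all__ = [
    "MFRSeries",
    "ComplexityReport",
    "mean_firing_rate",
    "second_difference",
    "gaussian_entropy",
    "dynamical_complexity",
    "complexity_from_raster",
]

#: relative ridge added to a covariance whose determinant is not positive
RIDGE_FACTOR = 1e-9


@dataclass
class MFRSeries:
    """Module-by-window mean firing rates (spikes per neuron per ms).

    ``rates[m, w]`` is the spike count of module m inside window w
    divided by (module size x window length).  Windows of ``window_ms``
    start every ``slide_ms``, so with duration T there are
    W = floor((T - window)/slide) + 1 windows (overlapping when
    slide < window).
    """

    rates: np.ndarray
    window_ms: int = 50
    slide_ms: int = 20
    module_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_modules(self) -> int:
        return self.rates.shape[0]

    @property
    def n_windows(self) -> int:
        return self.rates.shape[1]


@dataclass
class ComplexityReport:
    """Entropy decomposition of the module-rate system (all in nats)."""

    H_S: float
    H_i: np.ndarray
    I_S: float
    MI_i: np.ndarray
    C_S: float
    ridge_applied: bool = False


def mean_firing_rate(
    raster: SpikeRaster,
    module_id: np.ndarray,
    window_ms: int = 50,
    slide_ms: int = 20,
    modules: np.ndarray | None = None,
) -> MFRSeries:
    """Sliding-window mean firing rate per module.

    ``modules`` selects which labels enter the series (default: all
    positive labels, i.e. the excitatory modules; the inhibitory pool,
    label 0, is excluded).  The window should be at least as long as the
    maximum conduction delay so each window sees complete synaptic
    interactions.
    """
    module_id = np.asarray(module_id)
    if modules is None:
        modules = np.unique(module_id[module_id > 0])
    modules = np.asarray(modules)
    if window_ms > raster.duration:
        raise ValueError("window_ms exceeds raster duration")
    if slide_ms < 1:
        raise ValueError("slide_ms must be >= 1")

    n_windows = (raster.duration - window_ms) // slide_ms + 1
    label_of = {int(m): k for k, m in enumerate(modules)}
    # per-step spike counts per module
    per_step = np.zeros((len(modules), raster.duration))
    for t, i in zip(raster.steps, raster.neurons):
        k = label_of.get(int(module_id[i]))
        if k is not None:
            per_step[k, t] += 1.0
    csum = np.concatenate(
        [np.zeros((len(modules), 1)), np.cumsum(per_step, axis=1)], axis=1
    )
    starts = np.arange(n_windows) * slide_ms
    counts = csum[:, starts + window_ms] - csum[:, starts]
    sizes = np.array([(module_id == m).sum() for m in modules], dtype=float)
    rates = counts / (sizes[:, None] * window_ms)
    return MFRSeries(
        rates=rates, window_ms=window_ms, slide_ms=slide_ms, module_labels=modules
    )


def second_difference(series: np.ndarray) -> np.ndarray:
    """Second-order difference y''_t = y_t - 2 y_{t-1} + y_{t-2}.

    Applied along the last axis; output is two samples shorter.  Removes
    linear trends exactly, stabilising the mean before covariance
    estimation.
    """
    series = np.asarray(series)
    if series.shape[-1] < 3:
        raise ValueError("second difference needs a series of length >= 3")
    return series[..., 2:] - 2.0 * series[..., 1:-1] + series[..., :-2]


def gaussian_entropy(cov: np.ndarray, ridge: float | None = None) -> float:
    """Differential entropy (nats) of a Gaussian with covariance ``cov``.

    H = 1/2 ln((2 pi e)^M |cov|).  If the determinant is not strictly
    positive (singular covariance), a ridge eps*I with
    eps = 1e-9 * trace/M (or the supplied ``ridge``) is added and a
    warning emitted, keeping the value finite.
    """
    cov = np.atleast_2d(np.asarray(cov, dtype=np.float64))
    if cov.shape[0] != cov.shape[1] or not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be a symmetric square matrix")
    m = cov.shape[0]
    eps = ridge if ridge is not None else RIDGE_FACTOR * np.trace(cov) / m
    if eps <= 0:
        eps = RIDGE_FACTOR
    if np.linalg.eigvalsh(cov).min() <= eps:
        warnings.warn(
            f"singular covariance: applying ridge {eps:.3g} before log-det",
            stacklevel=2,
        )
        cov = cov + eps * np.eye(m)
    _, logdet = np.linalg.slogdet(cov)
    return 0.5 * (m * np.log(2.0 * np.pi * np.e) + logdet)


def dynamical_complexity(detrended: np.ndarray | MFRSeries) -> ComplexityReport:
    """Entropy, integration, mutual information and C(S) of module rates.

    Parameters
    ----------
    detrended : (M, W) array or MFRSeries
        Detrended module rate series (the caller applies
        :func:`second_difference`); rows are modules, columns windows.

    Notes
    -----
    Requires M >= 2 and more windows than M (otherwise the covariance is
    rank deficient and an error is raised).  C(S) is computed exactly as
    sum_i MI_i - I(S).
    """
    x = detrended.rates if isinstance(detrended, MFRSeries) else np.asarray(detrended)
    m, w = x.shape
    if m < 2:
        raise ValueError("dynamical complexity needs at least 2 modules")
    if w < m + 1:
        raise ValueError(
            f"covariance of {m} modules needs more than {m} windows, got {w}"
        )
    cov = np.cov(x)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        h_s = gaussian_entropy(cov)
        h_i = np.array([gaussian_entropy(cov[i : i + 1, i : i + 1]) for i in range(m)])
        h_rest = np.empty(m)
        for i in range(m):
            keep = np.arange(m) != i
            h_rest[i] = gaussian_entropy(cov[np.ix_(keep, keep)])
        ridge_applied = any("ridge" in str(c.message) for c in caught)
    for c in caught:  # re-emit anything unrelated to the ridge
        if "ridge" not in str(c.message):
            warnings.warn_explicit(c.message, c.category, c.filename, c.lineno)

    i_s = float(h_i.sum() - h_s)
    mi = h_i + h_rest - h_s
    c_s = float(mi.sum() - i_s)
    return ComplexityReport(
        H_S=float(h_s), H_i=h_i, I_S=i_s, MI_i=mi, C_S=c_s, ridge_applied=ridge_applied
    )


def complexity_from_raster(
    raster: SpikeRaster,
    module_id: np.ndarray,
    window_ms: int = 50,
    slide_ms: int = 20,
) -> ComplexityReport:
    """MFR -> second difference -> C(S), the full scoring pipeline."""
    mfr = mean_firing_rate(raster, module_id, window_ms=window_ms, slide_ms=slide_ms)
    return dynamical_complexity(second_difference(mfr.rates))
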