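"""Time-series targets: file I/O, lowpass interpolation, synthetic EEG.

The training target can be any single-channel real-valued series (for
EEG, microvolts at a stated sampling rate).  Lowpass interpolation
up-samples a target so the simulation can run at finer integration steps
than the recording's sample period; the synthetic-EEG generator produces
band-limited EEG-like fixtures (theta/alpha/beta sinusoids plus 1/f
noise) so the whole pipeline is testable without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import upfirdn

__all__ = [
    "TargetSignal",
    "lowpass_interpolate",
    "synth_eeg",
    "read_timeseries",
    "write_timeseries",
]


@dataclass
class TargetSignal:
    """A sampled real-valued target (e.g. one EEG channel, in uV)."""

    samples: np.ndarray
    fs: float
    channel: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)


def _interp_filter(l: int, p: int) -> np.ndarray:
    """Symmetric windowed-sinc lowpass interpolation filter.

    Length 2*p*l + 1.  The sinc has zeros at every nonzero multiple of
    the upsampling factor l and value 1 at the centre, so original
    samples pass through unchanged regardless of the window; the Kaiser
    window controls the truncation (stop-band) error of the new points.
    """
    n = np.arange(-p * l, p * l + 1)
    h = np.sinc(n / l) * np.kaiser(2 * p * l + 1, 8.0)
    return h


def lowpass_interpolate(signal: TargetSignal, l: int, p: int = 8) -> TargetSignal:
    """Bandlimited upsampling by an integer factor l.

    The signal is zero-stuffed (l - 1 zeros between samples) and passed
    through a symmetric FIR lowpass filter that (a) leaves the original
    samples exactly unchanged at stride-l positions and (b) fills the
    new points by ideal bandlimited interpolation from the nearest 2p
    original samples.  Edges are handled by reflecting the signal p
    samples outward before filtering.

    Returns a TargetSignal of length l * len(signal) at sampling rate
    l * fs.
    """
    if l < 2:
        raise ValueError("upsampling factor l must be >= 2")
    if p < 1:
        raise ValueError("half-support p must be >= 1")
    x = signal.samples
    if len(x) < 2 * p:
        raise ValueError(f"signal of length {len(x)} shorter than 2p = {2 * p}")
    # reflect p samples on each side to avoid edge roll-off
    xpad = np.concatenate([x[p:0:-1], x, x[-2 : -p - 2 : -1]])
    y = upfirdn(_interp_filter(l, p), xpad, up=l)
    start = p * l + p * l  # filter group delay + reflected prefix
    y = y[start : start + l * len(x)]
    return replace(signal, samples=y, fs=signal.fs * l)


_DEFAULT_BANDS = {
    # band (Hz range): amplitude (uV) — a plausible resting-EEG mixture
    "theta": ((4.0, 8.0), 20.0),
    "alpha": ((8.0, 13.0), 45.0),
    "beta": ((13.0, 30.0), 10.0),
}


def synth_eeg(
    duration_s: float = 3.0,
    fs: float = 128.0,
    bands: dict | None = None,
    noise_amp: float = 10.0,
    seed: int = 0,
    channel: str = "synthetic",
) -> TargetSignal:
    """Synthetic EEG-like fixture: band sinusoids plus 1/f noise.

    One sinusoid per named band at a seeded random frequency within the
    band (random phase), plus pink noise of RMS ``noise_amp`` uV.
    Deterministic per seed.  Defaults give a series with standard
    deviation of a few tens of uV, the scale of scalp EEG.
    """
    rng = np.random.default_rng(seed)
    bands = _DEFAULT_BANDS if bands is None else bands
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for (lo, hi), amp in bands.values():
        if hi * 2 > fs:
            raise ValueError(f"band edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
        f = rng.uniform(lo, hi)
        x += amp * np.sin(2.0 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if noise_amp > 0:
        x += noise_amp * _pink(n, rng)
    return TargetSignal(samples=x, fs=fs, channel=channel)


def _pink(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n)
    x -= x.mean()
    return x / x.std()


def read_timeseries(path: str, fs: float = 1.0) -> list[TargetSignal]:
    """Read delimited text (one column per channel, optional header).

    Accepts comma- or whitespace-separated values; a first row that does
    not parse as numbers is taken as channel labels.  Malformed rows
    raise a ValueError naming the line number.  Returns one TargetSignal
    per column.
    """
    rows: list[list[float]] = []
    labels: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                if lineno == 1 and labels is None and not rows:
                    labels = parts
                    continue
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if rows and len(rows[-1]) != len(rows[0]):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(rows[0])} columns, "
                    f"got {len(rows[-1])}"
                )
    if not rows:
        raise ValueError(f"{path}: no samples found")
    data = np.asarray(rows)
    n_ch = data.shape[1]
    if labels is None or len(labels) != n_ch:
        labels = [f"ch{k}" for k in range(n_ch)]
    return [
        TargetSignal(samples=data[:, k], fs=fs, channel=labels[k])
        for k in range(n_ch)
    ]


def write_timeseries(signals: TargetSignal | list[TargetSignal], path: str) -> None:
    """Write one or more equal-length channels as headered CSV.

    Full float precision, so a write -> read round trip is lossless.
    """
    if isinstance(signals, TargetSignal):
        signals = [signals]
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError("all channels must have the same length")
    with open(path, "w") as fh:
        fh.write(",".join(s.channel for s in signals) + "\n")
        cols = np.stack([s.samples for s in signals], axis=1)
        for row in cols:
            fh.write(",".join(f"{v:.17g}" for v in row) + "\n")
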