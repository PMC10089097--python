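"""Band-limited decomposition and FFT power spectra.

The filter bank is a set of narrow zero-phase Butterworth band-pass
filters (fourth order, applied forward and reverse, center frequency
+/- 0.5 Hz by default) spanning 0.5-50 Hz in 0.5 Hz steps.  Phase and
amplitude dynamics are extracted from the analytic (Hilbert) signal of
each band, with a symmetric edge trim to discard filter transients.
Power spectra are plain periodograms of 2 s epochs (0.5 Hz resolution)
averaged across epochs, used for the gamma-band (25-40 Hz) power
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps


@lru_cache(maxsize=512)
def _design_sos(order: int, lo: float, hi: float, fs: float) -> np.ndarray:
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _default_phase_centers() -> np.ndarray:
    return np.arange(0.5, 10.0 + 1e-9, 0.5)


def _default_amp_centers() -> np.ndarray:
    return np.arange(10.0, 50.0 + 1e-9, 0.5)


@dataclass
class FilterBankSpec:
    """Filter-bank definition for phase/amplitude extraction.

    ``centers_phase`` covers the slow (phase-providing) bands, 0.5-10 Hz
    in 0.5 Hz steps by default (20 centers); ``centers_amp`` the fast
    (amplitude-providing) bands, 10-50 Hz by default (81 centers).  Each
    band is a Butterworth filter of the given order in second-order
    sections, applied forward and reverse (zero phase, squared magnitude
    response).  Phase bands are ``center +/- half_bandwidth`` (narrow, so
    instantaneous phase is well defined); amplitude bands are ``center
    +/- amp_half_bandwidth`` and must be wider than the modulation rates
    of interest, because an amplitude envelope can only carry
    fluctuations slower than the filter bandwidth — a +/-0.5 Hz band
    cannot transmit theta-rate (3-7.5 Hz) amplitude modulation at all.
    """

    fs: float
    centers_phase: np.ndarray = field(default_factory=_default_phase_centers)
    centers_amp: np.ndarray = field(default_factory=_default_amp_centers)
    half_bandwidth: float = 0.5
    amp_half_bandwidth: float = 5.0
    order: int = 4

    def __post_init__(self) -> None:
        self.centers_phase = np.asarray(self.centers_phase, dtype=float)
        self.centers_amp = np.asarray(self.centers_amp, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.half_bandwidth <= 0 or self.amp_half_bandwidth <= 0:
            raise ValueError("half bandwidths must be positive")
        for centers, kind in ((self.centers_phase, "phase"), (self.centers_amp, "amp")):
            if centers.size == 0:
                raise ValueError("empty center list")
            if np.any(np.diff(centers) <= 0):
                raise ValueError("centers must be strictly increasing")
            self._check_band(centers[0], kind)
            self._check_band(centers[-1], kind)

    def band_edges(self, center: float, kind: str = "phase") -> tuple[float, float]:
        """Passband edges; the low edge is floored at center/4 so the
        lowest band (center <= half bandwidth) keeps a valid passband."""
        hb = self.half_bandwidth if kind == "phase" else self.amp_half_bandwidth
        lo = max(center - hb, center / 4.0)
        return lo, center + hb

    def _check_band(self, center: float, kind: str = "phase") -> None:
        lo, hi = self.band_edges(center, kind)
        if center <= 0 or lo <= 0 or hi >= self.fs / 2:
            raise ValueError(
                f"passband [{lo}, {hi}] Hz outside (0, {self.fs / 2}) at fs={self.fs}"
            )

    def sos(self, center: float, kind: str = "phase") -> np.ndarray:
        """Second-order-section coefficients for one band."""
        self._check_band(center, kind)
        lo, hi = self.band_edges(center, kind)
        return _design_sos(self.order, lo, hi, self.fs)


def bandpass(
    trial: np.ndarray, center: float, spec: FilterBankSpec, kind: str = "phase"
) -> np.ndarray:
    """Zero-phase band-pass filter of one trial.

    ``kind`` selects the phase-band or amplitude-band bandwidth of the
    filter bank.  Forward-reverse application squares the magnitude
    response and zeroes the phase response; output length equals input
    length.
    """
    trial = np.asarray(trial, dtype=float)
    sos = spec.sos(center, kind)
    n = trial.shape[0]
    # sosfiltfilt's default padding; transients beyond it are handled by
    # the caller's edge trim.
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))
    if n <= 3 * padlen:
        raise ValueError(f"trial of {n} samples too short for the filter (need > {3 * padlen})")
    return sps.sosfiltfilt(sos, trial, axis=0)


def analytic(
    filtered: np.ndarray, fs: float, edge_trim_s: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase and amplitude of a band-limited signal.

    Returns ``(phase, amplitude)``: the argument (wrapped to (-pi, pi])
    and modulus of the analytic signal, with ``edge_trim_s`` seconds
    discarded from each end to remove filter/Hilbert edge artifacts.
    """
    filtered = np.asarray(filtered, dtype=float)
    n = filtered.shape[0]
    k = int(round(edge_trim_s * fs))
    if 2 * k >= n:
        raise ValueError(f"edge trim of {k} samples per side exceeds trial length {n}")
    z = sps.hilbert(filtered, axis=0)
    sl = slice(k, n - k) if k > 0 else slice(None)
    return np.angle(z[sl]), np.abs(z[sl])


def epoch(trial: np.ndarray, fs: float, window_s: float = 2.0, step_s: float = 1.0) -> list[np.ndarray]:
    """Segment a trial into sliding windows (2 s window, 1 s step default).

    Epochs start at multiples of ``step_s``; a trailing remainder shorter
    than the window is dropped.
    """
    trial = np.asarray(trial, dtype=float)
    win = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if win <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    n = trial.shape[0]
    if n < win:
        raise ValueError(f"trial of {n} samples shorter than the {win}-sample window")
    return [trial[s : s + win] for s in range(0, n - win + 1, step)]


@dataclass
class PowerSpectrum:
    """One-sided periodogram averaged over epochs (Parseval-scaled)."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")


def power_spectrum(epochs: list[np.ndarray], fs: float) -> PowerSpectrum:
    """Rectangular-taper periodogram of each epoch, averaged over epochs.

    Scaled so the one-sided power sums to the epoch mean square
    (Parseval); with 2 s epochs the frequency resolution is 0.5 Hz.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    n = np.asarray(epochs[0]).shape[0]
    if any(np.asarray(e).shape[0] != n for e in epochs):
        raise ValueError("all epochs must have the same length")
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    acc = np.zeros(freqs.size)
    for e in epochs:
        spec = np.fft.rfft(np.asarray(e, dtype=float))
        p = np.abs(spec) ** 2 / n**2
        p[1:] *= 2.0
        if n % 2 == 0:
            p[-1] /= 2.0  # Nyquist bin is not duplicated
        acc += p
    return PowerSpectrum(freqs=freqs, power=acc / len(epochs))


def band_power(ps: PowerSpectrum, lo: float = 25.0, hi: float = 40.0) -> float:
    """Mean power over bins with lo <= f <= hi (both endpoints inclusive)."""
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    if lo < ps.freqs[0] - 1e-9 or hi > ps.freqs[-1] + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] outside spectrum range")
    mask = (ps.freqs >= lo - 1e-9) & (ps.freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"no frequency bins inside [{lo}, {hi}]")
    return float(ps.power[mask].mean())
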