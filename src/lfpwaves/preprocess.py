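"""Raw LFP to band-limited analytic phase/amplitude maps on the grid.

The chain follows the standard traveling-wave recipe: zero-phase band-pass
(4th-order Butterworth, applied forward and reverse), spatial interpolation
of missing electrodes (4-neighbour averaging, exact for planar gradients),
then a Hilbert transform per electrode.  The instantaneous phase of every
site at one sample is the *phase map*; zero phase is the oscillation peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, InvalidBandError
from .geometry import GRID_N
from .session import BandDefinition, LfpSession


@dataclass
class PhaseMapSeries:
    """Per-band instantaneous phase and amplitude on the grid.

    ``phase`` and ``amplitude`` have shape (T, 8, 8).  Phase lies in
    (-pi, pi] with 0 at the oscillation peak; sites where the amplitude is
    zero carry no phase information (undefined-phase flag, not an error).
    """

    phase: np.ndarray = field(repr=False)
    amplitude: np.ndarray = field(repr=False)
    fs: float
    band: BandDefinition | None = None

    @property
    def n_samples(self) -> int:
        return self.phase.shape[0]

    def undefined(self) -> np.ndarray:
        return self.amplitude == 0


def bandpass_filter(
    voltage: np.ndarray, band: BandDefinition, fs: float
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    Applied forward and reverse so in-band components keep their peak
    times exactly (no phase lag).
    """
    band.validate(fs)
    sos = sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=fs, output="sos")
    # sosfiltfilt pads with 3x the section-wise impulse-response heuristic
    n_pad = 3 * (2 * sos.shape[0] + 1)
    if np.asarray(voltage).shape[-1] <= 3 * n_pad:
        raise InsufficientDataError(
            f"signal of {np.asarray(voltage).shape[-1]} samples too short to filter"
        )
    return sps.sosfiltfilt(sos, np.asarray(voltage, dtype=float), axis=-1)


def interpolate_missing(grid_series: np.ndarray, missing=()) -> np.ndarray:
    """Fill missing lattice sites with the mean of available 4-neighbours.

    ``grid_series`` is (T, 8, 8) with NaN at missing sites (or any shape
    ending in (8, 8)).  Non-missing sites are untouched; the operation is
    idempotent and exact for affine functions of the grid coordinates.
    """
    out = np.array(grid_series, dtype=float, copy=True)
    single = out.ndim == 2
    if single:
        out = out[None]
    miss = {tuple(m) for m in missing}
    if not miss:
        nan_sites = np.argwhere(np.isnan(out[0]))
        miss = {(int(c) + 1, int(r) + 1) for r, c in nan_sites}
    if not miss:
        return out[0] if single else out
    if len(miss) > GRID_N * GRID_N // 2:
        raise ValueError("more than half the grid is missing; map uninterpretable")
    for x, y in sorted(miss):
        r, c = y - 1, x - 1
        neigh = []
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < GRID_N and 0 <= cc < GRID_N and (cc + 1, rr + 1) not in miss:
                neigh.append(out[:, rr, cc])
        if len(neigh) < 2:
            raise ValueError(f"missing site {(x, y)} has fewer than 2 available neighbours")
        out[:, r, c] = np.mean(neigh, axis=0)
    return out[0] if single else out


def analytic_phase(
    grid_series: np.ndarray, fs: float, band: BandDefinition | None = None
) -> PhaseMapSeries:
    """Hilbert-transform a (T, 8, 8) band-limited series into phase/amplitude.

    Phase is the argument and amplitude the modulus of the analytic signal
    per site.  A pure cosine has phase 0 at its peaks.
    """
    g = np.asarray(grid_series, dtype=float)
    analytic = sps.hilbert(g, axis=0)
    amplitude = np.abs(analytic)
    phase = np.angle(analytic)
    return PhaseMapSeries(phase=phase, amplitude=amplitude, fs=fs, band=band)


def phase_maps(session: LfpSession, band: BandDefinition) -> PhaseMapSeries:
    """Full chain: band-pass -> grid -> interpolate missing -> Hilbert."""
    filt = bandpass_filter(session.voltage, band, session.fs)
    grid = session.to_grid(filt)
    grid = interpolate_missing(grid, session.missing)
    return analytic_phase(grid, session.fs, band)


def morlet_power(
    session: LfpSession,
    frequencies: np.ndarray,
    n_cycles: float = 7.0,
    baseline_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Morlet-wavelet power timecourse, averaged across electrodes.

    Returns (n_frequencies, T).  Power is the squared modulus of the
    convolution with complex Morlet wavelets of ``n_cycles`` cycles.  If
    ``baseline_window`` (seconds) is given, power is expressed per
    electrode as change from the mean over that window before averaging.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(freqs <= 0) or np.any(freqs >= session.fs / 2):
        raise InvalidBandError("frequencies must lie in (0, fs/2)")
    v = session.voltage
    out = np.zeros((freqs.size, v.shape[1]))
    for i, f0 in enumerate(freqs):
        # complex Morlet: Gaussian envelope of n_cycles cycles at f0
        s_t = n_cycles / (2 * np.pi * f0)  # seconds
        half = min(int(5 * s_t * session.fs), (v.shape[1] - 1) // 2)
        t = np.arange(-half, half + 1) / session.fs
        w = np.exp(2j * np.pi * f0 * t) * np.exp(-(t**2) / (2 * s_t**2))
        w /= np.sqrt(np.sum(np.abs(w) ** 2))
        power = np.empty_like(v)
        for e in range(v.shape[0]):
            power[e] = np.abs(sps.fftconvolve(v[e], w, mode="same")) ** 2
        if baseline_window is not None:
            i0 = int(baseline_window[0] * session.fs)
            i1 = int(baseline_window[1] * session.fs)
            base = power[:, i0:i1].mean(axis=1, keepdims=True)
            power = power - base
        out[i] = power.mean(axis=0)
    return out


def band_power(
    session: LfpSession,
    band: BandDefinition,
    n_freqs: int = 5,
    n_cycles: float = 7.0,
    baseline_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Band-averaged Morlet power timecourse (T,)."""
    freqs = np.linspace(band.lo, band.hi, n_freqs)
    return morlet_power(session, freqs, n_cycles, baseline_window).mean(axis=0)
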