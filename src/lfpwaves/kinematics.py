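"""Wave propagation speed from temporal vs spatial phase gradients.

Speed at an instant is the ratio of how fast the oscillation cycle
advances in time (dp/dt, rad/s) to how fast it advances in space
(|grad p|, rad/m): a fast wave has a shallow spatial gradient.  Gradients
are taken with circular differencing (angle of the complex ratio) to
avoid 2*pi wrap artifacts, averaged across electrodes before the ratio,
and the result converted to cm/s using the electrode pitch.  The estimate
is meaningful only for long-wavelength instants, where the spatial
frequency is consistent across the array.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DEFAULT_PITCH_UM, wrap_angle
from .preprocess import PhaseMapSeries


@dataclass(frozen=True)
class SpeedEstimate:
    t: float
    speed_cm_s: float
    n_sites_used: int
    valid: bool
    band: str | None = None


def _gradients(phase: np.ndarray, i: int, fs: float) -> tuple[float, float]:
    """Mean |temporal| (rad/s) and mean |spatial| (rad/grid-unit) gradient."""
    p = phase
    i0, i1 = max(i - 1, 0), min(i + 1, p.shape[0] - 1)
    dt_samples = i1 - i0
    dpdt = wrap_angle(p[i1] - p[i0]) / dt_samples * fs
    gx = wrap_angle(np.diff(p[i], axis=1))
    gy = wrap_angle(np.diff(p[i], axis=0))
    # central-difference magnitude per interior site
    gxc = 0.5 * (gx[:, :-1] + gx[:, 1:])
    gyc = 0.5 * (gy[:-1, :] + gy[1:, :])
    mag = np.sqrt(gxc[1:-1, :] ** 2 + gyc[:, 1:-1] ** 2)
    return float(np.abs(np.nanmean(dpdt))), float(np.nanmean(mag))


def wave_speed(
    series: PhaseMapSeries,
    t: float,
    pitch_um: float = DEFAULT_PITCH_UM,
    valid: bool = True,
) -> SpeedEstimate:
    """Speed estimate at time ``t`` (seconds) in cm/s.

    ``valid`` marks whether the instant met the long-wavelength criterion
    (classifier wavelength class 'long'); speeds at short-wavelength
    instants are flagged invalid but still computed.  A near-zero spatial
    gradient (standing or fully synchronous oscillation) yields an
    invalid estimate.
    """
    i = int(round(t * series.fs))
    if not (0 <= i < series.n_samples):
        raise ValueError(f"time {t} s outside the series")
    temporal, spatial = _gradients(series.phase, i, series.fs)
    n_sites = int(np.isfinite(series.phase[i]).sum())
    if spatial < 1e-6:
        return SpeedEstimate(t=t, speed_cm_s=np.nan, n_sites_used=n_sites,
                             valid=False, band=series.band.name if series.band else None)
    units_per_s = temporal / spatial
    cm_per_unit = pitch_um * 1e-4
    return SpeedEstimate(
        t=t,
        speed_cm_s=units_per_s * cm_per_unit,
        n_sites_used=n_sites,
        valid=bool(valid),
        band=series.band.name if series.band else None,
    )


def speed_series(
    series: PhaseMapSeries,
    times: np.ndarray,
    pitch_um: float = DEFAULT_PITCH_UM,
) -> np.ndarray:
    """Speeds (cm/s) at an array of times; NaN where invalid."""
    return np.array(
        [wave_speed(series, float(t), pitch_um).speed_cm_s for t in np.atleast_1d(times)]
    )
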