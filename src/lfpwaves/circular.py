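"""Circular-circular correlation against rotation maps; planar/rotating classification.

The central statistic is the Fisher-Lee circular correlation between an
instantaneous phase map ``phi`` and a *rotation map* ``theta`` (the polar
angle of every electrode about a chosen origin)::

    rho_c = sum sin(phi - phi_m) sin(theta - theta_m)
            / sqrt( sum sin^2(phi - phi_m) * sum sin^2(theta - theta_m) )

with ``phi_m``, ``theta_m`` the circular means.  A planar wave moving toward
the rotation map's *net direction* yields rho_c near +1, the opposite
direction near -1, and directions along the orthogonal *bisecting axis*
stay inside the chance zone (|rho_c| <= 0.3, calibrated by site shuffling).
Three origins -- (4,4), (1,4) and (4,1) -- give a three-coefficient
fingerprint that separates planar from rotating waves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import ConfigurationError, UndefinedCorrelationError
from .geometry import (
    circular_mean,
    grid_coords,
    index_angle_to_visual_deg,
    wrap_angle,
)

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ReferenceLibrary

#: Origins used for the three-coefficient fingerprint.
CANONICAL_ORIGINS: tuple[tuple[float, float], ...] = ((4, 4), (1, 4), (4, 1))

#: Chance-zone half width: 99th percentile of |rho_c| under site shuffling.
CHANCE_THRESHOLD = 0.3


def rotation_map(origin: tuple[float, float]) -> np.ndarray:
    """Polar angle of every grid site about ``origin`` (index-space, (8, 8)).

    If the origin coincides exactly with a grid node the angle there is
    undefined; that site is returned as NaN and excluded downstream.
    """
    ox, oy = origin
    x, y = grid_coords()
    dx, dy = x - ox, y - oy
    theta = np.arctan2(dy, dx)
    singular = (dx == 0) & (dy == 0)
    if singular.any():
        theta = theta.copy()
        theta[singular] = np.nan
    return theta


def circ_corr(phi: np.ndarray, theta: np.ndarray) -> float:
    """Fisher-Lee circular correlation between two angle maps.

    NaN sites in either map are excluded.  Raises
    :class:`UndefinedCorrelationError` when either map has (numerically)
    zero circular variance.
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    ok = ~(np.isnan(phi) | np.isnan(theta))
    p, t = phi[ok], theta[ok]
    sp = np.sin(p - circular_mean(p))
    st = np.sin(t - circular_mean(t))
    den = np.sqrt((sp**2).sum() * (st**2).sum())
    if den < 1e-12:
        raise UndefinedCorrelationError("zero circular variance in a phase map")
    return float((sp * st).sum() / den)


def circ_corr_series(phase: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Vectorised rho_c of a (T, 8, 8) phase series against one rotation map.

    Instants with zero circular variance return NaN instead of raising.
    """
    phase = np.asarray(phase, dtype=float)
    T = phase.shape[0]
    flat = phase.reshape(T, -1)
    tflat = np.asarray(theta, dtype=float).ravel()
    ok = ~np.isnan(tflat)
    flat, tflat = flat[:, ok], tflat[ok]
    pm = np.angle(np.exp(1j * flat).sum(axis=1))
    sp = np.sin(flat - pm[:, None])
    st = np.sin(tflat - circular_mean(tflat))
    den = np.sqrt((sp**2).sum(axis=1) * (st**2).sum())
    num = sp @ st
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 1e-12, num / np.where(den > 0, den, 1.0), np.nan)
    return out


def net_direction(theta_map: np.ndarray) -> tuple[float, float]:
    """Net direction and bisecting axis of a rotation map, visual degrees.

    Circular-adjusted phase gradients (circular forward differences along x
    and y) are summed as complex vectors; the resultant's azimuth is the net
    direction.  A planar wave toward it gives rho_c > 0, away gives < 0,
    and along the orthogonal bisecting axis |rho_c| falls into the chance
    zone.  Returns ``(net_direction_deg, bisecting_axis_deg)``.
    """
    th = np.asarray(theta_map, dtype=float)
    gx = wrap_angle(np.diff(th, axis=1))
    gy = wrap_angle(np.diff(th, axis=0))
    resultant = np.nansum(gx) + 1j * np.nansum(gy)
    # The phase map of a wave is -k * theta: the wave's gradient opposes the
    # map's own angular gradient, so the net direction flips sign.
    ang = float(np.angle(-resultant))
    net = float(index_angle_to_visual_deg(ang))
    return net, (net + 90.0) % 360.0


@dataclass(frozen=True)
class RotationMap:
    """A rotation template about one origin, with its direction geometry."""

    origin: tuple[float, float]
    theta: np.ndarray = field(repr=False)
    net_direction_deg: float
    bisecting_axis_deg: float

    @classmethod
    def at(cls, origin: tuple[float, float]) -> "RotationMap":
        th = rotation_map(origin)
        net, bis = net_direction(th)
        return cls(origin=tuple(origin), theta=th, net_direction_deg=net, bisecting_axis_deg=bis)


@dataclass(frozen=True)
class WaveFingerprint:
    """rho_c values at the canonical origins (4,4), (1,4), (4,1)."""

    rho_44: float
    rho_14: float
    rho_41: float

    def as_array(self) -> np.ndarray:
        return np.array([self.rho_44, self.rho_14, self.rho_41])

    @property
    def max_abs(self) -> float:
        return float(np.nanmax(np.abs(self.as_array())))


@dataclass(frozen=True)
class WaveClassification:
    kind: str  # 'planar' | 'rotating' | 'none'
    direction_deg: float | None
    wavelength_class: str | None  # 'short' | 'long'
    matched_template: str | None
    euclid_dist: float


def fingerprint(
    phase_map: np.ndarray,
    origins: Sequence[tuple[float, float]] = CANONICAL_ORIGINS,
) -> WaveFingerprint:
    """Three-coefficient fingerprint of one phase map.

    Alternative origin triples are supported for robustness checks; the
    result fields keep their canonical names in origin order.
    """
    vals = [circ_corr(phase_map, rotation_map(o)) for o in origins]
    return WaveFingerprint(*vals)


def fingerprint_series(
    phase: np.ndarray,
    origins: Sequence[tuple[float, float]] = CANONICAL_ORIGINS,
) -> np.ndarray:
    """Fingerprints of a (T, 8, 8) series; returns (T, len(origins))."""
    return np.stack(
        [circ_corr_series(phase, rotation_map(o)) for o in origins], axis=1
    )


def classify(
    fp: WaveFingerprint | np.ndarray,
    library: "ReferenceLibrary",
    threshold: float = CHANCE_THRESHOLD,
) -> WaveClassification:
    """Nearest-template classification in three-dimensional fingerprint space.

    If no coefficient exceeds the chance threshold the instant is labelled
    ``none``.  Otherwise the library entry at minimum Euclidean distance
    wins; exact ties are broken toward the planar entry.
    """
    vec = fp.as_array() if isinstance(fp, WaveFingerprint) else np.asarray(fp, float)
    if len(library) == 0:
        raise ConfigurationError("reference library is empty")
    if not np.any(np.abs(vec) > threshold):
        return WaveClassification("none", None, None, None, np.inf)
    fps = library.fingerprint_matrix()
    d = np.sqrt(((fps - vec[None, :]) ** 2).sum(axis=1))
    order = np.lexsort((library.planar_rank(), d))  # ties -> planar first
    i = int(order[0])
    entry = library.entries[i]
    return WaveClassification(
        kind=entry.template.kind,
        direction_deg=entry.template.direction_deg,
        wavelength_class=entry.wavelength_class,
        matched_template=entry.name,
        euclid_dist=float(d[i]),
    )


def movie_fingerprint(
    phase: np.ndarray,
    origins: Sequence[tuple[float, float]] = CANONICAL_ORIGINS,
) -> np.ndarray:
    """Time-averaged fingerprint of a wave movie (T, 8, 8).

    Averaging over a wave's instants suppresses per-sample noise the same
    way the reference library's noise-realization averaging does, so event
    classification compares like with like.
    """
    return np.nanmean(fingerprint_series(phase, origins), axis=0)


def classify_series(
    fps: np.ndarray,
    library: "ReferenceLibrary",
    threshold: float = CHANCE_THRESHOLD,
) -> list[WaveClassification]:
    return [classify(f, library, threshold) for f in np.asarray(fps, float)]


def direction_sign(rho: float, threshold: float = CHANCE_THRESHOLD) -> str:
    """Direction call from a single rho_c: 'positive', 'negative' or 'chance'."""
    if rho > threshold:
        return "positive"
    if rho < -threshold:
        return "negative"
    return "chance"
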