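"""Synthetic traveling waves: single-wave movies, the planar/rotating
reference library, and full multi-trial LFP sessions with ground truth.

A wave movie on the 8x8 grid is generated from the complex field

    g(t, phi) = A * exp(i * (w t - k phi)) + sigma * gamma(t)

where ``phi`` is the spatial *input map* (a planar distance map or the
polar angle about a rotation centre), ``w`` the temporal angular frequency
(rad/s), ``k`` the spatial wavenumber (radians per grid unit for planar
maps, per radian of polar angle for rotating maps; 1/wavelength scale) and
``gamma`` i.i.d. standard complex Gaussian noise per site and sample.
The voltage movie is Re(g); the noise-free instantaneous phase at a site
equals (w t - k phi) wrapped to (-pi, pi].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import circular
from .errors import LibraryDegeneracyError
from .geometry import (
    GRID_N,
    grid_coords,
    index_angle_to_visual_deg,
    visual_unit_vector,
    wrap_angle,
)

#: Default noise scale relative to wave amplitude.
DEFAULT_SIGMA_RATIO = 0.25
#: Default planar-library wavenumber: wavelength 2*pi/0.5 ~ 12.6 electrode
#: pitches, roughly 1.8x the array span ("long" relative to the array).
PLANAR_K = 0.5
#: Wavenumber boundary between 'short' and 'long' rotating wavelengths.
SHORT_WAVELENGTH_K = 0.5


def phase_input_planar(direction_deg: float) -> np.ndarray:
    """Planar input map: zero-centred projection onto the direction vector.

    ``direction_deg`` is the visual azimuth of propagation (0 = rightward,
    90 = visually up).  The wave crest advances toward increasing map value.
    """
    ux, uy = visual_unit_vector(direction_deg)
    x, y = grid_coords()
    m = x * ux + y * uy
    return m - m.mean()


def phase_input_rotating(
    center: tuple[float, float], chirality: str = "ccw"
) -> np.ndarray:
    """Rotating input map: signed polar angle of each site about ``center``.

    ``chirality`` is the visual rotation sense ('ccw' or 'cw').  The centre
    may lie off-grid; a centre exactly on a grid node leaves that node's
    angle undefined (NaN).  The wavelength of the resulting wave grows with
    distance from the centre, purely geometrically.
    """
    if chirality not in ("ccw", "cw"):
        raise ValueError(f"chirality must be 'ccw' or 'cw', got {chirality!r}")
    cx, cy = center
    x, y = grid_coords()
    dx, dy = x - cx, y - cy
    theta = np.arctan2(dy, dx)
    singular = (dx == 0) & (dy == 0)
    if singular.any():
        theta = theta.copy()
        theta[singular] = np.nan
    # index-space angle increases visually clockwise (y runs downward)
    return -theta if chirality == "ccw" else theta


@dataclass(frozen=True)
class WaveTemplate:
    """One simulated wave type.

    ``direction_deg`` is the net propagation direction in visual degrees
    (for rotating templates: the resultant direction of the phase-gradient
    field over the array).
    """

    name: str
    kind: str  # 'planar' | 'rotating'
    k: float
    w: float = 2 * np.pi * 20.0
    A: float = 1.0
    sigma: float = DEFAULT_SIGMA_RATIO
    direction_deg: float | None = None
    center: tuple[float, float] | None = None
    chirality: str | None = None

    def __post_init__(self):
        if self.A <= 0 or self.sigma < 0:
            raise ValueError("require A > 0 and sigma >= 0")
        if self.kind not in ("planar", "rotating"):
            raise ValueError(f"unknown wave kind {self.kind!r}")

    def phase_input(self) -> np.ndarray:
        if self.kind == "planar":
            return phase_input_planar(self.direction_deg)
        return phase_input_rotating(self.center, self.chirality or "ccw")

    @property
    def wavelength_class(self) -> str:
        """'short'/'long'.  Planar library waves are long by construction;
        rotating waves are split at k = 0.5."""
        if self.kind == "planar":
            return "long"
        return "short" if self.k >= SHORT_WAVELENGTH_K else "long"


def noise_free_phase(template: WaveTemplate, t: float = 0.0) -> np.ndarray:
    """Closed-form instantaneous phase map (w t - k phi) wrapped to (-pi, pi]."""
    return wrap_angle(template.w * t - template.k * template.phase_input())


def propagation_direction(phase_map: np.ndarray) -> float:
    """Net propagation direction of a phase map, visual degrees.

    The wave moves opposite the spatial phase gradient (later-peaking sites
    have lower instantaneous phase), so the resultant of circular forward
    differences is negated before conversion.
    """
    p = np.asarray(phase_map, dtype=float)
    gx = wrap_angle(np.diff(p, axis=1))
    gy = wrap_angle(np.diff(p, axis=0))
    res = np.nansum(gx) + 1j * np.nansum(gy)
    return float(index_angle_to_visual_deg(float(np.angle(-res))))


def simulate_wave(
    template: WaveTemplate,
    duration: float,
    fs: float = 1000.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a wave movie; returns ``(g, voltage)`` of shape (T, 8, 8).

    ``g`` is the complex field A exp(i(w t - k phi)) + sigma*gamma and
    ``voltage = Re(g)``.  Requires at least two temporal cycles.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if duration * template.w / (2 * np.pi) < 2:
        raise ValueError("duration must cover at least two temporal cycles")
    rng = np.random.default_rng(rng)
    T = int(round(duration * fs))
    t = np.arange(T) / fs
    phi = template.phase_input()
    g = template.A * np.exp(
        1j * (template.w * t[:, None, None] - template.k * phi[None, :, :])
    )
    if template.sigma > 0:
        s = template.sigma * template.A
        g = g + s * (
            rng.standard_normal(g.shape) + 1j * rng.standard_normal(g.shape)
        ) / np.sqrt(2)
    return g, g.real


def template_fingerprint(
    template: WaveTemplate,
    n_noise_reps: int = 20,
    rng: np.random.Generator | int | None = None,
    origins: Sequence[tuple[float, float]] = circular.CANONICAL_ORIGINS,
) -> np.ndarray:
    """Mean three-coefficient fingerprint over noise realizations.

    One phase map per realization, taken at a fixed instant; rho_c of the
    noise-free field is time-invariant so the instant is immaterial.
    """
    rng = np.random.default_rng(rng)
    clean = np.exp(1j * (0.3 - template.k * template.phase_input()))
    acc = np.zeros(len(origins))
    reps = max(1, n_noise_reps) if template.sigma > 0 else 1
    for _ in range(reps):
        g = clean
        if template.sigma > 0:
            s = template.sigma * template.A
            g = clean + s / template.A * (
                rng.standard_normal(clean.shape)
                + 1j * rng.standard_normal(clean.shape)
            ) / np.sqrt(2)
        fp = circular.fingerprint(np.angle(g), origins)
        acc += fp.as_array()
    return acc / reps


@dataclass(frozen=True)
class LibraryEntry:
    template: WaveTemplate
    fingerprint: np.ndarray = field(repr=False)

    @property
    def name(self) -> str:
        return self.template.name

    @property
    def wavelength_class(self) -> str:
        return self.template.wavelength_class


@dataclass
class ReferenceLibrary:
    """32 planar + 40 rotating reference wave types with fingerprints."""

    entries: list[LibraryEntry]
    seed: int
    n_noise_reps: int = 20
    origins: tuple[tuple[float, float], ...] = circular.CANONICAL_ORIGINS

    def __len__(self) -> int:
        return len(self.entries)

    def fingerprint_matrix(self) -> np.ndarray:
        return np.stack([e.fingerprint for e in self.entries])

    def planar_rank(self) -> np.ndarray:
        return np.array([0 if e.template.kind == "planar" else 1 for e in self.entries])

    @property
    def n_planar(self) -> int:
        return int((self.planar_rank() == 0).sum())

    @property
    def n_rotating(self) -> int:
        return len(self) - self.n_planar

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n_noise_reps": self.n_noise_reps,
            "origins": [list(o) for o in self.origins],
            "entries": [
                {"template": asdict(e.template), "fingerprint": list(e.fingerprint)}
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceLibrary":
        with open(path) as fh:
            payload = json.load(fh)
        entries = []
        for e in payload["entries"]:
            td = e["template"]
            if td.get("center") is not None:
                td["center"] = tuple(td["center"])
            entries.append(
                LibraryEntry(WaveTemplate(**td), np.asarray(e["fingerprint"]))
            )
        return cls(
            entries=entries,
            seed=payload["seed"],
            n_noise_reps=payload["n_noise_reps"],
            origins=tuple(tuple(o) for o in payload["origins"]),
        )


#: Rotation-centre placements for the rotating library: distances 0-2
#: electrode pitches from the array centre in varied directions.  Far
#: centres at low k leave too little phase range across the array for the
#: fingerprint to clear the chance threshold, so curvature is varied over
#: nearby centres only.
ROTATING_CENTERS: tuple[tuple[float, float], ...] = (
    (4.5, 4.5),
    (3.79, 5.21),
    (3.09, 5.91),
    (3.09, 3.09),
    (5.91, 5.91),
)


def build_reference_library(
    seed: int = 0,
    n_noise_reps: int = 20,
    sigma: float = DEFAULT_SIGMA_RATIO,
    planar_k: float = PLANAR_K,
    origins: Sequence[tuple[float, float]] = circular.CANONICAL_ORIGINS,
) -> ReferenceLibrary:
    """Build the 72-entry reference library (32 planar + 40 rotating).

    Planar directions are spaced 360/32 = 11.25 degrees apart; rotating
    entries cover 5 centre placements x 8 wavenumbers evenly spaced in
    [0.1, 0.9].  Each fingerprint is averaged over ``n_noise_reps`` noise
    realizations.  Raises :class:`LibraryDegeneracyError` if any entry's
    strongest coefficient fails to exceed the chance threshold.
    """
    rng = np.random.default_rng(seed)
    templates: list[WaveTemplate] = []
    for i in range(32):
        d = 360.0 * i / 32
        templates.append(
            WaveTemplate(
                name=f"planar_{d:06.2f}",
                kind="planar",
                k=planar_k,
                sigma=sigma,
                direction_deg=d,
            )
        )
    ks = np.linspace(0.1, 0.9, 8)
    for ci, c in enumerate(ROTATING_CENTERS):
        for k in ks:
            tpl = WaveTemplate(
                name=f"rotating_c{ci}_k{k:.3f}",
                kind="rotating",
                k=float(k),
                sigma=sigma,
                center=c,
                chirality="ccw",
            )
            d = propagation_direction(noise_free_phase(tpl))
            object.__setattr__(tpl, "direction_deg", d)
            templates.append(tpl)
    entries = []
    for tpl in templates:
        fp = template_fingerprint(tpl, n_noise_reps, rng, origins)
        if np.nanmax(np.abs(fp)) <= circular.CHANCE_THRESHOLD:
            raise LibraryDegeneracyError(
                f"library entry {tpl.name} has max |fingerprint| "
                f"{np.nanmax(np.abs(fp)):.3f} <= {circular.CHANCE_THRESHOLD}"
            )
        entries.append(LibraryEntry(tpl, fp))
    return ReferenceLibrary(entries=entries, seed=seed, n_noise_reps=n_noise_reps,
                            origins=tuple(tuple(o) for o in origins))


# ---------------------------------------------------------------------------
# worked-example fingerprints (diagonal planar wave and its rotating match)
# ---------------------------------------------------------------------------

def diagonal_planar_template(
    k: float = PLANAR_K, sigma: float = DEFAULT_SIGMA_RATIO
) -> WaveTemplate:
    """Long-wavelength planar wave from the bottom-left to the top-right."""
    return WaveTemplate(
        name="planar_diag_045", kind="planar", k=k, sigma=sigma, direction_deg=45.0
    )


def matched_rotating_example(
    planar_rho44: float,
    rng: np.random.Generator | int | None = None,
    n_noise_reps: int = 20,
    sigma: float = DEFAULT_SIGMA_RATIO,
    direction_tol_deg: float = 25.0,
    construction_seed: int = 0,
) -> tuple[WaveTemplate, np.ndarray]:
    """Rotating wave with net direction bottom-left -> top-right whose
    rho_c at (4,4) matches a given planar value as closely as the family
    allows.

    Candidate rotation centres on a coarse grid around the array (both
    chiralities, k in [0.1, 0.9]) are screened for a net propagation
    direction within ``direction_tol_deg`` of 45 visual degrees.  The
    candidate whose noise-averaged (4,4) coefficient sits closest to
    ``planar_rho44`` is then chosen; this template selection is part of
    the reference construction and is scored with a dedicated generator
    (``construction_seed``) at high repetition count so the selected wave
    type is reproducible.  The *reported* fingerprint is re-measured with
    the caller's ``rng`` over ``n_noise_reps`` realizations.
    """
    candidates: list[WaveTemplate] = []
    for cx in np.arange(-8.0, 17.1, 1.0):
        for cy in np.arange(-8.0, 17.1, 1.0):
            if -0.5 <= cx <= 9.5 and -0.5 <= cy <= 9.5:
                continue  # off-array centres only: a large wave seen in part
            for chir in ("ccw", "cw"):
                for k in np.linspace(0.1, 0.9, 5):
                    tpl = WaveTemplate(
                        name=f"rot_{cx:+.0f}_{cy:+.0f}_{chir}_{k:.2f}",
                        kind="rotating", k=float(k), sigma=sigma,
                        center=(float(cx), float(cy)), chirality=chir,
                    )
                    d = propagation_direction(noise_free_phase(tpl))
                    if abs((d - 45.0 + 180.0) % 360.0 - 180.0) <= direction_tol_deg:
                        object.__setattr__(tpl, "direction_deg", d)
                        candidates.append(tpl)
    if not candidates:
        raise RuntimeError("no rotating candidate matches the target net direction")
    # cheap screen on the noise-free (4,4) coefficient before averaging
    keep = [
        tpl
        for tpl in candidates
        if abs(circular.fingerprint(noise_free_phase(tpl)).rho_44 - planar_rho44) < 0.15
    ] or candidates
    sel_rng = np.random.default_rng(construction_seed)
    coarse = [
        (abs(template_fingerprint(t, 20, sel_rng)[0] - planar_rho44), i)
        for i, t in enumerate(keep)
    ]
    coarse.sort()
    finalists = [keep[i] for _, i in coarse[:15]]
    best, best_err = None, np.inf
    for tpl in finalists:
        fp_sel = template_fingerprint(tpl, 200, sel_rng)
        # the example wave's curvature weakens the horizontal-axis
        # coefficient (origin (4,1)) relative to the vertical-axis one
        if not (fp_sel[2] < fp_sel[1]):
            continue
        err = abs(fp_sel[0] - planar_rho44)
        if err < best_err:
            best, best_err = tpl, err
    if best is None:
        best = finalists[0]
    fp = template_fingerprint(best, n_noise_reps, np.random.default_rng(rng))
    return best, fp


# ---------------------------------------------------------------------------
# full synthetic sessions
# ---------------------------------------------------------------------------

from .epochs import TrialEpochs  # noqa: E402  (no import cycle: epochs is leafward)
from .session import EVENT_NAMES, LfpSession  # noqa: E402


@dataclass
class SyntheticSessionSpec:
    """Recipe for a multi-trial synthetic session.

    The trial layout mirrors the delayed match-to-sample task: 0.5 s
    pre-fixation baseline, 0.5 s fixation, 0.5 s sample, 2 s delay,
    0.5 s test.  ``schedule`` maps epoch name -> (wave rate in events/s,
    direction bias = probability that a wave travels along the preferred
    rather than the anti-preferred direction).
    """

    n_trials: int = 50
    fs: float = 1000.0
    epochs: TrialEpochs = field(default_factory=TrialEpochs)
    band: str = "beta"
    carrier_hz: float = 20.0
    preferred_direction_deg: float = 45.0
    schedule: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "baseline": (1.5, 0.5),
            "fixation": (1.5, 0.5),
            "sample": (2.0, 0.8),
            "delay": (2.0, 0.8),
            "test": (1.5, 0.5),
        }
    )
    wave_duration: float = 0.2
    amplitude: float = 10.0
    k: float = PLANAR_K
    rotating_fraction: float = 0.0
    rotating_pool: tuple[WaveTemplate, ...] = ()
    noise_white: float = 1.0
    noise_pink: float = 1.0
    seed: int = 0
    spikes: bool = False
    spike_base_rate: float = 2.0
    spike_gain: float = 2.0

    def __post_init__(self):
        for name, (rate, bias) in self.schedule.items():
            if rate < 0 or not (0.0 <= bias <= 1.0):
                raise ValueError(f"bad schedule entry for {name}: {(rate, bias)}")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise along the last axis, unit variance."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    f = np.fft.rfftfreq(n, d=1.0)
    scale = np.where(f > 0, 1.0 / np.sqrt(np.maximum(f, f[1] if len(f) > 1 else 1.0)), 0.0)
    spec = np.fft.rfft(white, axis=-1) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def synthesize_session(
    spec: SyntheticSessionSpec,
) -> tuple[LfpSession, "pd.DataFrame", "pd.DataFrame | None"]:
    """Generate a synthetic session, its ground-truth event log and spikes.

    Returns ``(session, event_log, spikes)``.  The event log has columns
    (trial, t, t_trial, band, kind, direction_deg, k, center_x, center_y,
    wavelength_class); ``t`` is absolute session time and ``t_trial`` is
    trial-relative.  Waves are band-limited carrier bursts at the band's
    centre frequency with the requested spatial phase structure, on a
    pink+white background.  Identical specs (including seed) give
    bit-identical sessions.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    ep = spec.epochs
    trial_len = int(round(ep.duration * spec.fs))
    T = spec.n_trials * trial_len
    n_elec = 64
    w = 2 * np.pi * spec.carrier_hz
    t_axis = np.arange(trial_len) / spec.fs

    volt = np.zeros((T, GRID_N, GRID_N))
    amp_envelope = np.zeros((T, GRID_N, GRID_N))  # for amplitude-linked spikes
    log_rows = []
    windows = ep.windows()
    x, y = grid_coords()

    for trial in range(spec.n_trials):
        t0_trial = trial * trial_len
        onsets: list[tuple[float, WaveTemplate]] = []
        for name, (rate, bias) in spec.schedule.items():
            a, b = windows[name]
            n_ev = rng.poisson(rate * (b - a))
            for t_on in np.sort(rng.uniform(a, b, n_ev)):
                if spec.rotating_pool and rng.random() < spec.rotating_fraction:
                    tpl = spec.rotating_pool[rng.integers(len(spec.rotating_pool))]
                else:
                    toward = rng.random() < bias
                    d = spec.preferred_direction_deg + (0.0 if toward else 180.0)
                    tpl = WaveTemplate(
                        name=f"ev_planar_{d:05.1f}", kind="planar", k=spec.k,
                        w=w, A=spec.amplitude, sigma=0.0, direction_deg=d % 360.0,
                    )
                onsets.append((float(t_on), tpl))
        # thin events closer than half a wave duration (capacity limit)
        kept: list[tuple[float, WaveTemplate]] = []
        for t_on, tpl in sorted(onsets):
            if kept and t_on - kept[-1][0] < spec.wave_duration / 2:
                warnings.warn("wave schedule overlap; event thinned", stacklevel=2)
                continue
            kept.append((t_on, tpl))
        for t_on, tpl in kept:
            i_on = int(round(t_on * spec.fs))
            n_dur = int(round(spec.wave_duration * spec.fs))
            i_end = min(i_on + n_dur, trial_len)
            seg = slice(t0_trial + i_on, t0_trial + i_end)
            tt = t_axis[: i_end - i_on]
            env = np.hanning(2 * n_dur)[: i_end - i_on] if i_end - i_on < n_dur else np.hanning(n_dur)
            phi = tpl.phase_input()
            phi = np.where(np.isnan(phi), 0.0, phi)
            profile = np.ones_like(phi)
            if tpl.kind == "rotating" and tpl.center is not None:
                r = np.hypot(x - tpl.center[0], y - tpl.center[1])
                profile = 1.0 / (1.0 + r / 2.0)  # amplitude peaks near the centre
            phase0 = rng.uniform(0, 2 * np.pi)
            carrier = np.cos(
                tpl.w * tt[:, None, None] + phase0 - tpl.k * phi[None, :, :]
            )
            burst = tpl.A * env[:, None, None] * profile[None, :, :] * carrier
            volt[seg] += burst
            amp_envelope[seg] += tpl.A * env[:, None, None] * profile[None, :, :]
            log_rows.append(
                {
                    "trial": trial,
                    "t": t0_trial / spec.fs + t_on,
                    "t_trial": t_on,
                    "epoch": ep.epoch_of(t_on),
                    "band": spec.band,
                    "kind": tpl.kind,
                    "direction_deg": tpl.direction_deg,
                    "k": tpl.k,
                    "center_x": tpl.center[0] if tpl.center else np.nan,
                    "center_y": tpl.center[1] if tpl.center else np.nan,
                    "wavelength_class": tpl.wavelength_class,
                }
            )

    flat = volt.reshape(T, n_elec).T  # (64, T)
    noise = spec.noise_white * rng.standard_normal(flat.shape)
    noise += spec.noise_pink * _pink_noise(rng, flat.shape)
    flat = flat + noise

    events = []
    for trial in range(spec.n_trials):
        t0 = trial * ep.duration
        for name, offset in zip(
            EVENT_NAMES,
            (ep.baseline, ep.baseline + ep.fixation,
             ep.baseline + ep.fixation + ep.sample,
             ep.baseline + ep.fixation + ep.sample + ep.delay),
        ):
            events.append({"trial": trial, "event": name, "t": t0 + offset})
    session = LfpSession(
        voltage=flat,
        fs=spec.fs,
        events=pd.DataFrame(events),
        array_label=f"synthetic:{spec.band}",
    )
    log = pd.DataFrame(
        log_rows,
        columns=["trial", "t", "t_trial", "epoch", "band", "kind", "direction_deg",
                 "k", "center_x", "center_y", "wavelength_class"],
    )

    spikes = None
    if spec.spikes:
        rate = spec.spike_base_rate + spec.spike_gain * amp_envelope.reshape(T, n_elec)
        p = np.clip(rate / spec.fs, 0, 1)
        hits = rng.random(p.shape) < p
        tt, ee = np.nonzero(hits)
        spikes = pd.DataFrame({"electrode": ee, "t": tt / spec.fs})
    return session, log, spikes
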