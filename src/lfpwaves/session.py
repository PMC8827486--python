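"""Session container: LFP voltage, grid geometry, trial events, band definitions.

A session holds an (n_electrodes, n_samples) voltage matrix sampled at
``fs`` (1 kHz by default), a map from electrode index to 1-based (x, y)
coordinates on the 8x8 lattice (image convention: y = row from the top),
the set of lattice sites with no electrode, and per-trial task event
times.  Sessions round-trip through a single HDF5 file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import InvalidBandError
from .geometry import DEFAULT_PITCH_UM, GRID_N

EVENT_NAMES = ("fixation_on", "sample_on", "sample_off", "test_on")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def validate(self, fs: float) -> None:
        if not (0 < self.lo < self.hi < fs / 2):
            raise InvalidBandError(
                f"band {self.name}: need 0 < {self.lo} < {self.hi} < fs/2={fs/2}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 40.0, 120.0),
)


def get_band(name: str) -> BandDefinition:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}")


@dataclass
class LfpSession:
    """Multi-electrode LFP recording with geometry and trial events.

    ``grid_map`` has shape (n_electrodes, 2) holding 1-based (x, y);
    ``missing`` is a set of (x, y) lattice sites with no electrode;
    ``events`` is a DataFrame with columns (trial, event, t) in seconds.
    """

    voltage: np.ndarray
    fs: float = 1000.0
    grid_map: np.ndarray | None = None
    pitch_um: float = DEFAULT_PITCH_UM
    missing: frozenset = frozenset()
    events: pd.DataFrame | None = None
    array_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=np.float64)
        if self.grid_map is None:
            self.grid_map = default_grid_map(self.voltage.shape[0])
        self.grid_map = np.asarray(self.grid_map, dtype=int)
        self.missing = frozenset(tuple(m) for m in self.missing)
        self._validate()

    def _validate(self) -> None:
        n_elec = self.voltage.shape[0]
        if self.grid_map.shape != (n_elec, 2):
            raise ValueError("grid_map must be (n_electrodes, 2)")
        coords = {tuple(c) for c in self.grid_map}
        if len(coords) != n_elec:
            raise ValueError("grid coordinates must be unique")
        if not all(1 <= x <= GRID_N and 1 <= y <= GRID_N for x, y in coords):
            raise ValueError("grid coordinates must lie in 1..8 x 1..8")
        if coords & self.missing:
            raise ValueError("missing sites overlap electrode sites")
        lattice = {(x, y) for x in range(1, GRID_N + 1) for y in range(1, GRID_N + 1)}
        if coords | self.missing != lattice:
            raise ValueError("every lattice site must be an electrode or missing")
        if self.events is not None and len(self.events):
            order = {name: i for i, name in enumerate(EVENT_NAMES)}
            for trial, g in self.events.groupby("trial"):
                g = g[g["event"].isin(order)]
                t = g.iloc[np.argsort(g["event"].map(order).to_numpy(), kind="stable")]["t"].to_numpy()
                if not np.all(np.diff(t) > 0):
                    raise ValueError(f"event times not strictly increasing in trial {trial}")

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_trials(self) -> int:
        if self.events is None or not len(self.events):
            return 0
        return int(self.events["trial"].nunique())

    def to_grid(self, signal: np.ndarray | None = None) -> np.ndarray:
        """Arrange an (n_electrodes, T) signal onto the (T, 8, 8) lattice.

        Missing sites are NaN.  Defaults to the raw voltage.
        """
        sig = self.voltage if signal is None else np.asarray(signal)
        out = np.full((sig.shape[1], GRID_N, GRID_N), np.nan)
        for e, (x, y) in enumerate(self.grid_map):
            out[:, y - 1, x - 1] = sig[e]
        return out

    def trial_start_times(self, pre_fixation: float = 0.5) -> np.ndarray:
        """Trial start (baseline onset) = fixation_on - pre_fixation, seconds."""
        fx = self.events[self.events["event"] == "fixation_on"]
        return (fx.sort_values("trial")["t"].to_numpy() - pre_fixation)

    # -- I/O ---------------------------------------------------------------

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("lfp", data=self.voltage.astype(np.float32))
            f.create_dataset("grid_map", data=self.grid_map)
            miss = np.array(sorted(self.missing), dtype=int).reshape(-1, 2)
            f.create_dataset("missing", data=miss)
            if self.events is not None and len(self.events):
                ev = self.events
                f.create_dataset("events/trial", data=ev["trial"].to_numpy(int))
                f.create_dataset(
                    "events/event",
                    data=np.array([s.encode() for s in ev["event"]]),
                )
                f.create_dataset("events/t", data=ev["t"].to_numpy(float))
            f.attrs["fs"] = self.fs
            f.attrs["pitch_um"] = self.pitch_um
            f.attrs["array_label"] = self.array_label

    @classmethod
    def from_hdf5(cls, path) -> "LfpSession":
        with h5py.File(path, "r") as f:
            voltage = f["lfp"][...].astype(np.float64)
            grid_map = f["grid_map"][...]
            missing = frozenset(tuple(int(v) for v in row) for row in f["missing"][...])
            events = None
            if "events" in f:
                events = pd.DataFrame(
                    {
                        "trial": f["events/trial"][...],
                        "event": [s.decode() for s in f["events/event"][...]],
                        "t": f["events/t"][...],
                    }
                )
            return cls(
                voltage=voltage,
                fs=float(f.attrs["fs"]),
                grid_map=grid_map,
                pitch_um=float(f.attrs["pitch_um"]),
                missing=missing,
                events=events,
                array_label=str(f.attrs.get("array_label", "")),
            )


def default_grid_map(n_electrodes: int, missing=()) -> np.ndarray:
    """Row-major electrode layout covering all non-missing lattice sites."""
    miss = {tuple(m) for m in missing}
    coords = [
        (x, y)
        for y in range(1, GRID_N + 1)
        for x in range(1, GRID_N + 1)
        if (x, y) not in miss
    ]
    if len(coords) != n_electrodes:
        raise ValueError(
            f"{n_electrodes} electrodes cannot tile {len(coords)} available sites"
        )
    return np.array(coords, dtype=int)


def read_events_csv(path) -> pd.DataFrame:
    """Read an events table; accepts columns (trial, event, t) or (trial, event, name, t)."""
    df = pd.read_csv(path)
    if "name" in df.columns and "event" not in df.columns:
        df = df.rename(columns={"name": "event"})
    return df[["trial", "event", "t"]]
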