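"""End-to-end orchestration: preprocess -> detect -> classify -> speed -> epochs.

Thin plumbing over the library modules: a :class:`RunConfig` names the
inputs, thresholds and seeds; :func:`run_pipeline` executes the stages in
order and writes event tables, statistics and a provenance manifest.
Deterministic stages re-run bit-identically for an identical config.
"""

from __future__ import annotations

import hashlib
import json
import time

import yaml
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import CHANCE_THRESHOLD, classify, fingerprint_series, rotation_map, circ_corr_series
from .epochs import TrialEpochs, direction_bias_timecourse, epoch_wave_counts
from .errors import ConfigurationError
from .kinematics import wave_speed
from .planar import DistanceMapSet, count_waves
from .preprocess import phase_maps
from .session import LfpSession, get_band
from .simulate import ReferenceLibrary


@dataclass
class RunConfig:
    session_path: str
    out_dir: str
    bands: tuple[str, ...] = ("beta",)
    library_path: str | None = None
    threshold: float = CHANCE_THRESHOLD
    rho_origin: tuple[float, float] = (4, 4)
    positive_direction_sign: float = 1.0  # flip to orient the task-enhanced direction
    epochs: TrialEpochs = field(default_factory=TrialEpochs)
    seed: int = 0
    classify_stride_ms: float = 20.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "epochs" in raw:
            raw["epochs"] = TrialEpochs(**raw["epochs"])
        if "bands" in raw:
            raw["bands"] = tuple(raw["bands"])
        if "rho_origin" in raw:
            raw["rho_origin"] = tuple(raw["rho_origin"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d["epochs"] = asdict(self.epochs)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages; returns the artifact directory.

    Writes per-band wave-event tables (CSV), classified instants with
    speeds (CSV), epoch statistics (JSON) and ``manifest.json``.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spath = Path(config.session_path)
    if not spath.exists():
        raise ConfigurationError(f"session file not found: {spath}")
    library = None
    if config.library_path is not None:
        lpath = Path(config.library_path)
        if not lpath.exists():
            raise ConfigurationError(f"library file not found: {lpath}")
        library = ReferenceLibrary.from_json(lpath)

    session = LfpSession.from_hdf5(spath)
    dmaps = DistanceMapSet()
    stages: list[dict] = []
    stats: dict = {}
    for band_name in config.bands:
        band = get_band(band_name)
        t0 = time.time()
        series = phase_maps(session, band)
        stages.append({"stage": f"preprocess[{band_name}]", "seconds": time.time() - t0})

        t0 = time.time()
        events, _ = count_waves(series, dmaps, config.threshold)
        events.insert(0, "band", band_name)
        events.to_csv(out / f"events_{band_name}.csv", index=False)
        stages.append({"stage": f"detect[{band_name}]", "seconds": time.time() - t0})

        t0 = time.time()
        stride = max(1, int(round(config.classify_stride_ms * session.fs / 1000.0)))
        idx = np.arange(0, series.n_samples, stride)
        rows = []
        if library is not None:
            fps = fingerprint_series(series.phase[idx])
            for i, fp in zip(idx, fps):
                c = classify(fp, library, config.threshold)
                row = {
                    "t": i / session.fs,
                    "band": band_name,
                    "kind": c.kind,
                    "direction_deg": c.direction_deg,
                    "wavelength_class": c.wavelength_class,
                    "rho_44": fp[0],
                    "rho_14": fp[1],
                    "rho_41": fp[2],
                    "matched_template": c.matched_template,
                    "euclid_dist": c.euclid_dist,
                }
                if c.kind != "none" and c.wavelength_class == "long":
                    row["speed_cm_s"] = wave_speed(
                        series, i / session.fs, session.pitch_um
                    ).speed_cm_s
                else:
                    row["speed_cm_s"] = np.nan
                rows.append(row)
        classified = pd.DataFrame(rows)
        classified.to_csv(out / f"classified_{band_name}.csv", index=False)
        stages.append({"stage": f"classify+speed[{band_name}]", "seconds": time.time() - t0})

        t0 = time.time()
        band_stats: dict = {}
        if session.n_trials:
            trial_len = int(round(config.epochs.duration * session.fs))
            starts = (session.trial_start_times(config.epochs.baseline) * session.fs).round().astype(int)
            theta = rotation_map(config.rho_origin)
            rho_trials = []
            ev_rows = []
            for tr, s0 in enumerate(starts):
                seg = series.phase[s0 : s0 + trial_len]
                if seg.shape[0] < trial_len:
                    continue
                rho_trials.append(config.positive_direction_sign * circ_corr_series(seg, theta))
                in_trial = events[
                    (events["t_start"] >= s0 / session.fs)
                    & (events["t_start"] < (s0 + trial_len) / session.fs)
                ]
                for _, r in in_trial.iterrows():
                    ev_rows.append({"trial": tr, "t": r["t_start"] - s0 / session.fs})
            rho = np.stack(rho_trials) if rho_trials else np.zeros((0, trial_len))
            ev_df = pd.DataFrame(ev_rows, columns=["trial", "t"])
            counts = epoch_wave_counts(
                ev_df, config.epochs, len(rho_trials), rng=config.seed, n_perm=1000
            )
            bias = direction_bias_timecourse(rho, config.epochs, session.fs)
            band_stats = {
                "wave_counts": counts.to_dict(orient="records"),
                "direction_bias": bias.to_dict(orient="records"),
            }
        stats[band_name] = band_stats
        stages.append({"stage": f"epochs[{band_name}]", "seconds": time.time() - t0})

    (out / "epoch_stats.json").write_text(json.dumps(stats, indent=1, default=float))
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "session": str(spath),
        "library": config.library_path,
        "stages": stages,
        "total_seconds": time.time() - t_start,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
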