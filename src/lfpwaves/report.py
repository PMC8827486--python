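"""Session summary report: wave-count and direction-bias panels.

Produces, for one band of one session, the trial-averaged wave-count
timecourse with baseline-significance marks, the direction-bias
timecourse, and a polar direction histogram — as CSVs plus a single PNG
overview figure.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .circular import circ_corr_series, rotation_map
from .epochs import (
    TrialEpochs,
    direction_bias_timecourse,
    direction_histogram,
    epoch_wave_counts,
)
from .planar import count_waves
from .preprocess import phase_maps
from .session import LfpSession, get_band


def session_report(
    session: LfpSession,
    out_dir: str | Path,
    band_name: str = "beta",
    epochs: TrialEpochs | None = None,
    rho_origin: tuple[float, float] = (4, 4),
    seed: int = 0,
) -> Path:
    """Write the summary CSVs and overview figure; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    epochs = epochs or TrialEpochs()
    band = get_band(band_name)
    series = phase_maps(session, band)
    events, _ = count_waves(series)

    trial_len = epochs.duration
    ev = pd.DataFrame(
        {
            "trial": (events["t_start"] // trial_len).astype(int),
            "t": events["t_start"] % trial_len,
            "azimuth_deg": events["azimuth_deg"],
        }
    )
    n_trials = max(session.n_trials, int(ev["trial"].max()) + 1 if len(ev) else 1)
    counts = epoch_wave_counts(ev, epochs, n_trials, bin_s=0.25, n_perm=1000, rng=seed)
    counts.to_csv(out / f"wave_counts_{band_name}.csv", index=False)

    theta = rotation_map(rho_origin)
    tl = int(round(epochs.duration * session.fs))
    starts = (session.trial_start_times(epochs.baseline) * session.fs).round().astype(int)
    rho = np.stack(
        [series.phase[s : s + tl] for s in starts if s + tl <= series.n_samples]
    )
    rho = np.stack([circ_corr_series(r, theta) for r in rho])
    bias = direction_bias_timecourse(rho, epochs, session.fs)
    bias.to_csv(out / f"direction_bias_{band_name}.csv", index=False)

    edges, hist = direction_histogram(ev["azimuth_deg"].to_numpy())
    pd.DataFrame({"bin_lo_deg": edges[:-1], "bin_hi_deg": edges[1:], "mass": hist}).to_csv(
        out / f"direction_histogram_{band_name}.csv", index=False
    )

    fig = plt.figure(figsize=(11, 3.2))
    ax = fig.add_subplot(1, 3, 1)
    tc = 0.5 * (counts["t0"] + counts["t1"])
    ax.plot(tc, counts["mean_count"], lw=1.5)
    sig = counts["significant"]
    ax.plot(tc[sig], np.full(sig.sum(), -0.02 * counts["mean_count"].max()), ".k", ms=4)
    for edge in np.cumsum([epochs.baseline, epochs.fixation, epochs.sample, epochs.delay]):
        ax.axvline(edge, color="0.8", lw=0.8)
    ax.set_xlabel("time in trial (s)")
    ax.set_ylabel(f"wave components / {0.25:.2f} s")
    ax.set_title(f"{band_name} wave counts")

    ax = fig.add_subplot(1, 3, 2)
    tb = 0.5 * (bias["t0"] + bias["t1"])
    ax.plot(tb, bias["delta_positive"], "r-o", ms=3, label="positive dir")
    ax.plot(tb, bias["delta_negative"], "b-o", ms=3, label="negative dir")
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("time in trial (s)")
    ax.set_ylabel("exceedance - baseline")
    ax.set_title("direction bias")
    ax.legend(fontsize=8)

    ax = fig.add_subplot(1, 3, 3, projection="polar")
    centers = np.deg2rad(0.5 * (edges[:-1] + edges[1:]))
    ax.bar(centers, hist, width=np.deg2rad(np.diff(edges)), alpha=0.7)
    ax.set_title("wave directions")

    fig.tight_layout()
    fig.savefig(out / f"report_{band_name}.png", dpi=120)
    plt.close(fig)
    return out
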