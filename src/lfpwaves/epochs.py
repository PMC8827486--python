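"""Task-epoch aggregation of wave statistics and baseline comparisons.

Trials follow the delayed match-to-sample layout: a 0.5 s pre-fixation
baseline, 0.5 s fixation, 0.5 s sample presentation, 2 s memory delay and
a 0.5 s test window.  All comparisons are against the baseline window,
with two-sided trial-permutation tests at p < 0.01 (10,000 permutations
by default, uncorrected per bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import CHANCE_THRESHOLD
from .geometry import circular_std
from .preprocess import PhaseMapSeries

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class TrialEpochs:
    """Epoch durations (s) and derived windows relative to trial start."""

    baseline: float = 0.5
    fixation: float = 0.5
    sample: float = 0.5
    delay: float = 2.0
    test: float = 0.5

    @property
    def duration(self) -> float:
        return self.baseline + self.fixation + self.sample + self.delay + self.test

    def windows(self) -> dict[str, tuple[float, float]]:
        t = 0.0
        out = {}
        for name in ("baseline", "fixation", "sample", "delay", "test"):
            d = getattr(self, name)
            out[name] = (t, t + d)
            t += d
        return out

    def intervals(self, width: float = 0.5) -> list[tuple[float, float]]:
        """Non-overlapping analysis intervals of ``width`` tiling the trial."""
        edges = np.arange(0.0, self.duration + 1e-9, width)
        return [(float(a), float(b)) for a, b in zip(edges[:-1], edges[1:])]

    def epoch_of(self, t: float) -> str | None:
        for name, (a, b) in self.windows().items():
            if a <= t < b:
                return name
        return None


def _perm_pvalue(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided permutation p-value for a difference of means across trials."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n = len(a)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n].mean() - pooled[n:].mean()) >= obs - 1e-15:
            count += 1
    return (count + 1) / (n_perm + 1)


def epoch_wave_counts(
    events: pd.DataFrame,
    epochs: TrialEpochs,
    n_trials: int,
    bin_s: float = 0.25,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Trial-averaged wave counts per time bin with significance vs baseline.

    ``events`` must carry columns ``trial`` and ``t`` (trial-relative
    seconds).  Each bin's per-trial counts are compared against the
    per-trial baseline count (rate-matched to the bin width) by a
    two-sided trial-permutation test.
    """
    rng = np.random.default_rng(rng)
    edges = np.arange(0.0, epochs.duration + 1e-9, bin_s)
    b0, b1 = epochs.windows()["baseline"]
    per_trial = np.zeros((n_trials, len(edges) - 1))
    base = np.zeros(n_trials)
    for trial, g in events.groupby("trial"):
        i = int(trial)
        per_trial[i], _ = np.histogram(g["t"], bins=edges)
        base[i] = ((g["t"] >= b0) & (g["t"] < b1)).sum() * (bin_s / (b1 - b0))
    rows = []
    for j in range(len(edges) - 1):
        counts = per_trial[:, j]
        if counts.sum() == 0 and base.sum() == 0:
            p = np.nan
        else:
            p = _perm_pvalue(counts, base, n_perm, rng)
        rows.append(
            {
                "t0": edges[j],
                "t1": edges[j + 1],
                "epoch": epochs.epoch_of(float(edges[j])),
                "mean_count": counts.mean(),
                "sem": counts.std(ddof=1) / np.sqrt(max(n_trials, 2)),
                "baseline_mean": base.mean(),
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def direction_histogram(
    directions_deg: np.ndarray, bin_deg: float = 12.0
) -> tuple[np.ndarray, np.ndarray]:
    """Polar histogram of wave azimuths; returns (bin_edges_deg, mass).

    Mass is normalized to sum to 1 (empty input gives zero mass).
    """
    n_bins = int(round(360.0 / bin_deg))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    d = np.asarray(directions_deg, float) % 360.0
    h, _ = np.histogram(d, bins=edges)
    total = h.sum()
    return edges, h / total if total else h.astype(float)


def align_preferred(
    histograms: list[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate each array's histogram so its modal bin sits at 0 degrees,
    then average across arrays.  Preserves secondary lobes (e.g. the
    opposite-direction lobe at 180 degrees)."""
    aligned = []
    edges = None
    for e, h in histograms:
        edges = e
        if h.sum() == 0:
            aligned.append(h)
            continue
        aligned.append(np.roll(h, -int(np.argmax(h))))
    return edges, np.mean(aligned, axis=0)


def rho_histograms(
    rho: np.ndarray,
    epochs: TrialEpochs,
    fs: float,
    bins: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
    epoch_names: tuple[str, ...] = ("sample", "delay", "test"),
) -> dict[str, dict]:
    """Per-epoch rho_c histograms against the baseline overlay.

    ``rho`` is (n_trials, T) of per-instant circular correlations at the
    chosen rotation-map origin, sign-oriented so the task-enhanced
    direction is positive.  Histograms are normalized to unit mass; each
    bin carries a two-sided trial-permutation significance mark vs the
    baseline histogram.  The chance zone is (-0.3, 0.3).
    """
    rng = np.random.default_rng(rng)
    if bins is None:
        bins = np.linspace(-1.0, 1.0, 41)
    rho = np.asarray(rho, float)
    n_trials = rho.shape[0]
    win = epochs.windows()

    def trial_hists(name: str) -> np.ndarray:
        a, b = win[name]
        i0, i1 = int(a * fs), int(b * fs)
        seg = rho[:, i0:i1]
        out = np.zeros((n_trials, len(bins) - 1))
        for i in range(n_trials):
            v = seg[i][np.isfinite(seg[i])]
            h, _ = np.histogram(v, bins=bins)
            out[i] = h / max(h.sum(), 1)
        return out

    base = trial_hists("baseline")
    result = {}
    for name in epoch_names:
        cur = trial_hists(name)
        pvals = np.array(
            [_perm_pvalue(cur[:, j], base[:, j], n_perm, rng) for j in range(cur.shape[1])]
        )
        result[name] = {
            "bins": bins,
            "epoch_hist": cur.mean(axis=0),
            "baseline_hist": base.mean(axis=0),
            "p": pvals,
            "significant": pvals < alpha,
            "chance_zone": (-CHANCE_THRESHOLD, CHANCE_THRESHOLD),
        }
    return result


def direction_bias_timecourse(
    rho: np.ndarray,
    epochs: TrialEpochs,
    fs: float,
    threshold: float = CHANCE_THRESHOLD,
    interval_s: float = 0.5,
) -> pd.DataFrame:
    """Positive/negative exceedance fractions minus baseline per interval.

    For each ``interval_s`` window of the trial, the fraction of instants
    with rho_c > +threshold (and < -threshold), minus the corresponding
    baseline fraction; positive delta_positive with negative
    delta_negative indicates a net directional bias.
    """
    rho = np.asarray(rho, float)
    b0, b1 = epochs.windows()["baseline"]
    base = rho[:, int(b0 * fs) : int(b1 * fs)]
    base_pos = np.nanmean(base > threshold)
    base_neg = np.nanmean(base < -threshold)
    rows = []
    for a, b in epochs.intervals(interval_s):
        seg = rho[:, int(a * fs) : int(b * fs)]
        rows.append(
            {
                "t0": a,
                "t1": b,
                "epoch": epochs.epoch_of(a),
                "delta_positive": np.nanmean(seg > threshold) - base_pos,
                "delta_negative": np.nanmean(seg < -threshold) - base_neg,
            }
        )
    return pd.DataFrame(rows)


def standing_wave_instants(
    series: PhaseMapSeries,
    wave_mask: np.ndarray,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Label non-wave instants as standing vs neither by phase dispersion.

    The circular standard deviation of each phase map is computed; among
    instants the detector did not label as traveling waves, those whose
    phase SD falls below a cutoff (the lower mode of the two-component
    split of the non-wave SD distribution, found by 1-D two-means unless
    given) are standing waves: coherent oscillations with little spatial
    phase structure.  Returns a per-instant frame with columns
    (phase_sd, label) where label is 'traveling', 'standing' or 'neither'.
    """
    sd = circular_std(series.phase.reshape(series.n_samples, -1), axis=1)
    wave_mask = np.asarray(wave_mask, bool)
    non_wave_sd = sd[~wave_mask]
    if cutoff is None:
        cutoff = _two_means_cutoff(non_wave_sd[np.isfinite(non_wave_sd)])
    label = np.where(wave_mask, "traveling", np.where(sd < cutoff, "standing", "neither"))
    return pd.DataFrame({"phase_sd": sd, "label": label})


def _two_means_cutoff(x: np.ndarray) -> float:
    """Boundary between the two modes of a 1-D sample via two-means."""
    if x.size == 0:
        return np.nan
    lo, hi = np.percentile(x, [10, 90])
    c = np.array([lo, hi], dtype=float)
    for _ in range(100):
        d = np.abs(x[:, None] - c[None, :])
        assign = d.argmin(axis=1)
        new = np.array(
            [x[assign == j].mean() if np.any(assign == j) else c[j] for j in (0, 1)]
        )
        if np.allclose(new, c):
            break
        c = new
    return float(c.mean())


def spike_rate_by_wavelength(
    spikes: pd.DataFrame,
    instant_class: pd.DataFrame,
    fs: float,
    n_electrodes: int,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> dict | None:
    """Mean spike rate during short- vs long-wavelength wave instants.

    ``spikes`` has columns (electrode, t); ``instant_class`` has columns
    (t, wavelength_class).  Rates are spikes per electrode per second
    within each instant class; the two classes are compared with a
    two-sided permutation test on instant labels.  Returns None (with a
    warning) when either class is empty or there are no spikes.
    """
    rng = np.random.default_rng(rng)
    if spikes is None or not len(spikes):
        warnings.warn("no spikes; wavelength comparison skipped")
        return None
    cls = instant_class[instant_class["wavelength_class"].isin(["short", "long"])]
    if not len(cls):
        warnings.warn("no classified wave instants; comparison skipped")
        return None
    t_inst = cls["t"].to_numpy()
    labels = cls["wavelength_class"].to_numpy()
    if (labels == "short").sum() == 0 or (labels == "long").sum() == 0:
        warnings.warn("one wavelength class is empty; comparison skipped")
        return None
    # spikes landing within +-0.5 sample of an instant count toward it
    spike_bins = np.round(spikes["t"].to_numpy() * fs).astype(int)
    inst_bins = np.round(t_inst * fs).astype(int)
    counts = np.zeros(len(inst_bins))
    lookup = pd.Series(np.arange(len(inst_bins)), index=inst_bins)
    hits = lookup.reindex(spike_bins).dropna().astype(int)
    np.add.at(counts, hits.to_numpy(), 1)
    rate = counts * fs / n_electrodes  # spikes/s per electrode at each instant
    short, long_ = rate[labels == "short"], rate[labels == "long"]
    p = _perm_pvalue(short, long_, n_perm, rng)
    return {
        "short_rate": float(short.mean()),
        "long_rate": float(long_.mean()),
        "n_short": int(len(short)),
        "n_long": int(len(long_)),
        "p": p,
        "significant": bool(p < alpha),
    }
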