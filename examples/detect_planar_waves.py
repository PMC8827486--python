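"""Quadrant-method detection of directional traveling waves.

Builds a short synthetic session carrying beta-band planar waves along the
45-degree diagonal, extracts band-limited phase maps, and counts wave
events across the 12 quadrant-pair directions.
"""

import warnings

from lfpwaves.planar import count_waves
from lfpwaves.preprocess import phase_maps
from lfpwaves.session import get_band
from lfpwaves.simulate import SyntheticSessionSpec, synthesize_session

spec = SyntheticSessionSpec(n_trials=5, seed=42)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    session, truth, _ = synthesize_session(spec)

series = phase_maps(session, get_band("beta"))
events, _ = count_waves(series)

print(f"session: {session.n_trials} trials, {session.duration:.0f} s, "
      f"{len(truth)} scheduled wave bursts (45 deg preferred)")
print(f"detected {len(events)} wave components across 12 directions")
print("\ncomponents per direction (each positive cycle of a traversal counts once;")
print("co-aligned quadrant pairs fire together for a single wave):")
print(events["direction_label"].value_counts().to_string())
print("\npeak correlation of the strongest event: "
      f"{events['peak_correlation'].max():.2f} (threshold 0.3)")
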