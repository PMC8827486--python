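# Methods

This note records the models, conventions, parameter choices and known
limitations behind `lfpwaves`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Geometry and sign conventions

Grid coordinates are 1-based `(x, y)` with `x` the column (left→right) and
`y` the row stored in image order, so arrays index as `map[y-1, x-1]` and
`y` increases *downward*. This matrix-style frame is the one in which the
canonical rotation-map origins (4,4), (1,4), (4,1) have their documented
axes: the (4,4) map's net direction lies along the bottom-left→top-right
diagonal, (1,4) discriminates top-half vs bottom-half travel, and (4,1)
discriminates lateral travel. User-facing azimuths are *visual* degrees
(0° = rightward, 90° = visually up); conversion handles the flipped y.

Phase is the argument of the Hilbert analytic signal, in (−π, π] with 0 at
the oscillation peak. Under this convention a site that peaked recently
carries small positive phase, so the instantaneous phase *decreases* along
the propagation direction, and in the quadrant method a wave's **source**
quadrant correlates positively with its outward distance map while the
**destination** correlates negatively. The published description of the
same rule has the two signs swapped, which corresponds to the opposite
(equally common, rarely stated) phase-sign convention; our mapping is
fixed by requiring that simulated ground-truth waves are recovered with
the correct source→destination label.

## Filtering and phase maps

* 4th-order Butterworth band-pass, realized as second-order sections for
  numerical stability, applied forward and reverse (`sosfiltfilt`) so
  in-band components undergo no phase shift. Bands: theta 4–8, alpha 8–12,
  beta 12–30, gamma 40–120 Hz.
* Missing electrodes (at most a few per session in practice) are filled
  per sample with the mean of their available 4-neighbours — the simplest
  linear scheme on a lattice, exact for planar gradients. More than half
  the grid missing is refused.
* Morlet power summaries use 7-cycle complex wavelets (a conventional
  trade-off between time and frequency resolution; the source analyses do
  not state their value) with optional per-electrode baseline subtraction.
* Acquisition-chain analog filters are treated as session metadata and
  never re-applied.

## Wave simulation

Waves are movies of the complex field `g(t, φ) = A e^{i(wt − kφ)} + σγ(t)`
on the 8×8 grid, where the input map φ is either the zero-centred
projection of grid coordinates onto a direction unit vector (planar) or
the signed polar angle about a rotation centre, possibly off-grid
(rotating). γ is i.i.d. standard *complex* Gaussian per site and sample
(the noise term's distribution beyond "Gaussian white" is unstated at
source; a circular complex form keeps the noise phase-symmetric). Defaults:

* σ = 0.25·A. Phase-based statistics are amplitude-invariant, so A is
  immaterial; σ sets fingerprint variance and is our declared choice.
* Planar wavenumber k = 0.5 rad/grid-unit → wavelength ≈ 12.6 electrode
  pitches ≈ 1.8× the array span, implementing the "long wavelength
  relative to the array" regime the quadrant method requires.
* Rotating maps use the pure angle with no radial term; the wavelength
  then grows geometrically with distance from the centre, which the test
  suite verifies on rings of increasing radius.

## Reference library

32 planar types span all directions at 360/32 = 11.25° spacing at the
planar k above. 40 rotating types are the product of 5 rotation-centre
placements × 8 wavenumbers evenly spaced in [0.1, 0.9]. Centres sit at
0–2 pitches from the array centre in varied directions: placing centres
further off-array at low k leaves so little phase range across the array
that noise at the default σ swamps the fingerprint, violating the
construction requirement that every type keep at least one coefficient
above the 0.3 chance threshold. With the shipped placements the worst
entry's strongest coefficient is ≈ 0.45 (recomputed by the acceptance
script). Every fingerprint is the mean over 20 noise realizations; the
library serializes to JSON with its seed.

Classification is nearest-neighbour Euclidean distance in the 3-D
fingerprint space, with `kind = none` inside the chance zone
(max |ρ<sub>c</sub>| ≤ 0.3) and exact ties broken toward planar (logged).
Rotating wavelength classes split at k = 0.5 (short ≥ 0.5 > long); planar
library waves are long-wavelength by construction. A wave *event* is
classified by its movie-averaged fingerprint: averaging over the event's
instants suppresses per-sample noise the same way the library's
realization averaging does, so query and reference are shrunk alike.
At σ = 0 every template recovers itself exactly; at σ = 0.25·A kind
recovery over 200 random draws is ≥ 90% (typically 100%).

### The worked-example rotating match

The planar/rotating contrast example needs "the" rotating wave with the
same net direction whose (4,4) coefficient matches the planar wave's.
Matching ρ<sub>c</sub>(4,4) alone is degenerate — mirror-image centres
about the 45° diagonal swap the (1,4)/(4,1) coefficients — so the search
additionally requires what the example is about: the curvature weakens
the *horizontal*-axis coefficient (ρ<sub>41</sub> < ρ<sub>14</sub>).
Candidates (coarse centre grid around the array, both chiralities,
k ∈ [0.1, 0.9], net direction within ±25° of the diagonal) are scored on
noise-averaged fingerprints with a dedicated construction seed at high
repetition count, making the selected template reproducible; the reported
coefficient is then re-measured with the caller's seed. Noise attenuates
strongly curved maps more than planar ones, so the matched rotating
ρ<sub>c</sub>(4,4) (≈ 0.80) sits somewhat below the planar value (≈ 0.95)
— the family's closest approach at the default σ.

## Detection thresholds

The operational threshold is fixed at 0.3 for both statistics. The
shuffle procedure that motivates it — permute phase values uniformly
across the 64 sites, correlate against the fixed templates, take the 99th
percentile of |r| — is implemented and verified (≈ 0.32 for the full-array
Pearson statistic and for ρ<sub>c</sub>); re-deriving the threshold per
run is a validation step, not a calibration. A per-quadrant (16-site)
Pearson null would sit near 0.63, far above 0.3, which is why the
detection gate uses the *full-array* correlation over positive-phase
sites, with the per-quadrant opposite-sign rule assigning the direction;
the conjunctive rule keeps the per-direction false-positive rate at or
below the nominal 1% on shuffled maps.

Windowing: detection runs per millisecond sample; a 20 ms window sliding
by one sample (step size unstated at source) marks a direction active,
and each maximal contiguous active run is one wave event. Because only
positive phase values enter, each positive cycle of a multi-cycle burst
counts as its own traversal, and co-aligned quadrant pairs legitimately
fire together for a single wave — wave *components*, not unique waves.
Both quadrants of a pair must contribute ≥ 6 positive-phase sites (our
choice) or the instant is undetermined.

## Speed

Speed = mean over electrodes of the temporal phase gradient (central
circular difference across ±1 ms) divided by the mean magnitude of the
spatial phase gradient (central circular differences on the grid),
converted to cm/s via the 400 µm pitch — gradients averaged first, then
the ratio, computed only for long-wavelength instants. Circular
differencing (angle of the complex ratio) avoids 2π-wrap artifacts. On
noise-free planar waves the estimate matches f·λ within 2% for
wavelengths ≥ 2× the array width and grows with frequency at fixed
wavelength. Near-zero spatial gradients (synchronous/standing activity)
flag the estimate invalid.

## Task-epoch statistics

Trials follow the 0.5 s baseline / 0.5 s fixation / 0.5 s sample / 2 s
delay / 0.5 s test layout. All significance marks are two-sided
trial-permutation tests at p < 0.01 (10,000 permutations by default,
seeded, uncorrected per bin). Direction histograms default to 12° bins;
per-array histograms are aligned by rotating each modal direction to 0°
before averaging, preserving secondary lobes. Direction-bias timecourses
report, per 0.5 s interval, the fraction of instants with
ρ<sub>c</sub> > +0.3 (and < −0.3) minus the baseline fraction, with the
sign oriented so the task-enhanced direction is positive (a per-array
configuration entry). Standing-wave labelling computes the circular SD of
each phase map and splits the non-wave SD distribution with a 1-D
two-means cutoff (logged per run). Spike-rate comparisons between short-
and long-wavelength instants use the same permutation machinery.

## Synthetic sessions

`synthesize_session` emulates the study structure, not its biophysics:
band-limited carrier bursts (Hann envelope, default 0.2 s) at a band's
centre frequency carry the scheduled spatial phase pattern, with
per-epoch Poisson event rates and a direction-bias parameter (probability
of the preferred vs anti-preferred direction), on pink (1/f) + white
background noise — a conventional LFP stand-in. Rotating bursts carry a
radially decaying amplitude profile (higher near the centre), which is
what makes amplitude-coupled synthetic spikes fire faster during
short-wavelength instants. Ground truth (event log, optional spikes) is
returned alongside, and identical specs are bit-identical.

What passing synthetic tests shows: the estimator chain recovers known
phase structure, calibrated thresholds control false positives, and
injected task modulations are recovered monotonically (Spearman ρ > 0.9
across bias levels 0.5–1.0 at 50 trials, using a shared session seed so
sessions differ only in the direction draws). What it does not show:
robustness to real-data nuisances — non-stationary spectra, volume
conduction, artifacts, electrode drift — which are out of scope here.

## Problem sizes

Default validation sizes were chosen to make every check run comfortably
on a laptop-class single core: 20 noise realizations per fingerprint
(matching the library's construction), 10,000 shuffles for the null,
200 draws for recovery rates, and 50-trial sessions (≈ 200 s of 64-channel
data each) for the end-to-end bias experiment.

## Known limitations

* Rotating library entries share one chirality; opposite-sense rotations
  classify to the nearest available entry and may be reported planar.
* Net direction is ill-defined for rotation exactly centred on the array
  (the tangential field nearly cancels); direction labels for such
  entries are nominal.
* The quadrant method is restricted to wavelengths long relative to the
  array; short-wavelength waves are the classifier's domain.
* Rotating-wave anatomical localization (relating curvature statistics to
  sulcal landmarks) is a subjective, non-algorithmic analysis and is not
  implemented.
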