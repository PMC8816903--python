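# Methods

`tunnelvision` quantifies odor-gated visual attraction of free-flying
mosquitoes from 3D tracking data, and ships a seeded agent-based simulator
that emulates the wind-tunnel assay so the full analysis chain can be
exercised and validated without access to raw tracking recordings.

## The assay and its statistics

A cohort of 50 female mosquitoes flies in a 224 × 61 × 61 cm working section
with laminar flow at 40 cm/s. Two 3 cm visual objects sit on the floor 33 cm
downwind of a CO₂ point source, 18 cm apart: a spectral *test* object and an
evenly reflecting *control*. A trial has three phases — filtered air (pre),
CO₂ release, and post — and multi-camera tracking yields 3D positions at
60 frames/s. Identities are not maintained over long periods, so one animal
contributes many short trajectories; trajectories are treated as the
independent sampling unit.

The analysis chain:

* **Length filter.** Only trajectories with at least 90 frames (1.5 s at
  60 fps) are analyzed.
* **Fictive volumes.** "Investigating" an object means being inside an
  axis-aligned 14 × 14 cm footprint × 4 cm tall box, crosswind-centered on
  the object and shifted slightly downwind. The downwind shift defaults to
  2 cm, which keeps the observed hover point (~3–5 cm downwind of the
  object) inside the box; it is configurable. Box membership is half-open
  ([lo, hi) per axis) so adjacent volumes can tile without double counting.
* **Preference index.** Per trajectory, PI = (t_test − t_control) /
  (t_test + t_control) over in-volume time; +1/−1 means exclusive
  investigation of one object. Trajectories entering neither volume carry no
  information about relative preference and are excluded (only a fraction of
  trajectories ever approach an object).
* **Bootstrap CI.** The cohort mean PI gets a percentile bootstrap CI from
  resampling individual trajectories 500 times at the 95% level. The
  percentile interval is the minimal choice consistent with a plain
  resampling description; BCa would be a drop-in refinement. Percentile
  intervals on n ≈ 200 samples empirically cover ~94–95% at nominal 95%.
* **Relative flight activity.** Trajectory count in each phase divided by
  the count in the previous phase; undefined when the denominator phase has
  no trajectories.
* **Occupancy maps.** The arena projection (top or side view) is tiled with
  0.3 cm² squares (side √0.3 ≈ 0.548 cm); per-cell occurrence counts are
  normalized to percentages summing to 100. The cell spec is read as an
  *area*; a side-length reading is available via `cell_side`. Replicate
  trials are pooled as the unweighted mean of percentage maps, so every
  trial contributes equally regardless of how many records it has.
* **Controls.** A 14 × 14 × 4 cm volume placed uniformly at random in the
  tunnel (rejecting overlap with the object volumes) is scored against the
  object volume; genuine object attraction drives this PI strongly
  negative. A sensitivity analysis rescales the fictive volumes (0.75–1.5×)
  and reports the stability of the mean PI and the capture fraction.
* **Per-trajectory PI is computed within one phase** after clipping tracks
  at phase boundaries (half-open [start, end) intervals, so the phases
  partition the records exactly). Whether boundary-straddling tracks should
  instead be scored whole is ambiguous; clipping is the choice that makes
  phase-level statistics well defined.

## The plume model

Centerline CO₂ concentration is modeled as an exponential decay above
ambient with a Gaussian cross-section:

    C(d, r) = ambient + A·exp(−d/λ)·exp(−r²/(2σ(d)²)),
    σ(d) = σ₀(1 + k·d)

with d the downwind distance from the source and r the radial offset.
A and λ are calibrated in closed form so the centerline passes through the
two measured anchors — 1700 ppm at 20 cm and 1500 ppm at 30 cm over a
400 ppm ambient — giving λ = 10/ln(13/11) ≈ 59.9 cm and
A = 1300·(13/11)² ≈ 1815.7 ppm. σ₀ = 0.375 cm makes the near-source plume
diameter (~4σ) about 1.5 cm; the spread rate k = 0.05 is a nominal
turbulent-widening choice. Upwind of the source the model returns ambient,
and the far field decays to ambient.

## The behavioral simulator

The simulator's job is to produce trajectory tables whose *downstream
statistics* behave like the real assay; it is not a biomechanical model.
Each agent runs a four-state machine (resting, wall-exploring,
plume-tracking, object-investigating) stepped at dt = 1/60 s:

* **Take-off.** Resting agents take off as a Poisson process
  (`base_takeoff_rate`, default 0.003/s) multiplied by `activation_factor`
  (default 2.0) while the agent's CO₂-activation flag is fresh. This is the
  mechanism behind the doubling of flight activity at CO₂ onset. Flight
  bouts end by landing at rate 1/`mean_bout_s` (default 6 s).
* **Flight.** A correlated random walk (per-frame heading memory 0.95,
  speed ~ N(25, 5) cm/s) with specular reflection at the walls.
* **Odor.** A flying agent inside the plume (local concentration above
  500 ppm) surges upwind and refreshes its activation flag. Because the
  plume is a ~1.5 cm filament at 20 cm height, resting animals would almost
  never touch it, yet in the real assay the whole cohort responds within
  minutes — dispersed filaments circulate through the section. We model
  this as a Poisson "filament encounter" process (default 0.3/s per agent)
  active whenever CO₂ is being released; each encounter refreshes the
  activation flag. Activation persists `activation_decay_s` = 300 s after
  the last encounter, inside the observed 5–10 min window of persistent
  sensitization.
* **Vision.** An *activated* agent within 20 cm (horizontal) of an object
  begins investigating with per-second probability
  `investigate_rate × visual_gain × attraction_weight(label)`. It hovers
  with mean-reverting (OU) noise around a point `hover_offset_cm` = 4 cm
  downwind of the object center at 2 cm height (inside the ~3–5 cm observed
  band), dwells ~ Exp(4 s), then makes a brief excursion and may return.
  `co2_sensing=False` (a CO₂-receptor knockout) prevents activation
  entirely; `visual_gain=0` (a long-wavelength opsin double knockout)
  abolishes investigation while leaving odor-driven activation intact. In
  both cases CO₂-phase object residence collapses to the pre-phase
  baseline, which is the simulator's null-genotype contract.
* **Identity loss.** The bout-level tracks are fragmented: at each frame the
  track ends with probability `dropout_prob` (default 0.01, giving
  geometric fragments of mean 100 frames ≈ 1.7 s, comparable to the ~3 s
  average trajectory of real tracking after filtering).

All randomness flows from one `numpy` Generator seeded explicitly; identical
(config, seed) gives byte-identical output files. Genotype/species presets
differ only in attraction weights, visual gain and CO₂ sensing — the level
of description this simulator operates at.

What the simulator does *not* emulate: computational fluid dynamics and
intermittent plume structure, flight aerodynamics, close-range heat and
humidity cues, landing behavior, light-level dependence, and interactions
between individuals. Passing tests therefore demonstrate that the analysis
pipeline recovers known generative parameters from realistically structured
trajectory data — not that the simulator reproduces real mosquito behavior
beyond the summary statistics listed above.

## Desk-scale study conditions

Real trials run 1 h per phase with thousands of trajectories; tests and the
validation suite use compressed phases (tens of seconds to ten minutes) with
the same 50-agent cohorts, chosen so each scored phase still yields
O(10²) trajectories. Where a statistic is compared across conditions
(activity doubling, preference ordering, null genotypes), the check uses
≥ 20 seeded replicates and compares at the precision the replicate spread
supports (a one-sample t-test or an explicit sampling-error band), since
per-replicate trajectory counts are O(10²) rather than O(10³).

Two design choices keep these sweeps well powered and fast:

* `simulate_replicates` runs many independent trials in one vectorized
  pass (all cohorts' agents stacked), amortizing the per-timestep cost of
  the state machine; a batch is reproducible from its own seed.
* For the attraction-weight ordering check, a "replicate experiment" pools
  the scored trajectories of four independent trials per stimulus,
  mirroring the multi-trial-per-stimulus structure of the real assay.
  Single five-to-ten-minute trials leave the replicate mean PI with a
  standard deviation near 0.2 (scored trajectories cluster within
  investigation visits, so the effective sample is visits, not
  trajectories); pooling four trials brings it to ~0.1, which separates
  the 1:1 / 2:1 / 4:1 weight conditions (mean PIs ≈ 0 / 0.33 / 0.63)
  cleanly at 20 replicates.

## Photometry and models

Spectra are piecewise-linear (wavelength nm, value) tables. Band intensity
is a trapezoidal integral over the native grid (plus exact band endpoints),
by default against a flat unit illuminant — when a measured projector
spectrum is available it can be supplied as the illuminant. Weber contrast
is (I_object − I_background)/I_background on band intensities (400–700 nm),
scale-invariant by construction. Peak wavelength is the argmax of
reflectance in 400–700 nm with ties broken toward the longer wavelength.
The spectral feature vector is 13 AUC bins of 25 nm spanning 350–675 nm.
The bundled spectra (Gaussian peaks at the tested dominant wavelengths plus
grays) are synthetic stand-ins shaped like colored-paper reflectance curves,
not measurements.

The all-subsets model fits OLS over the 8 subsets of {contrast,
peak_wavelength, brightness} and ranks by Gaussian AIC
(−2·loglik + 2(k+2), counting intercept, slopes and variance; subset
rankings at fixed n are convention-invariant). Within 2 AIC of the minimum
the tie goes to the smaller model. "Brightness" defaults to band-integrated
reflectance; peak reflectance is available as an alternative, flagged in
reports. The PCA regression centers (optionally scales) the AUC matrix,
regresses the response on leading component scores, and back-projects the
coefficients through the loadings to per-band effects — the sign of the
summed 500–575 nm effect is the headline readout. Group comparisons use
Kruskal–Wallis, pairwise Mann–Whitney U with a Bonferroni-corrected
threshold (default α = 0.01), and an insert-and-absorb compact letter
display; one-sample t-tests check "mean PI ≠ 0". The base tests are scipy's;
the workflow, correction and letter display are this package's.

## Numerical conventions

* Units: cm, seconds, ppm, nm; frame 0 at t = 0, t = frame/frame_rate.
* Coordinates: origin at the upwind end on the floor at the tunnel
  centerline; x downwind, y crosswind, z up.
* All intervals (phases, volume bounds, AUC bins) are half-open.
* CSV output uses shortest round-trip float repr and is read back with
  correctly-rounded parsing, so write∘read is lossless; the HDF container
  stores one float64/int64 dataset per column under `/trajectories`.
* Degenerate inputs fail loudly: empty tables cannot be bootstrapped or
  normalized into occupancy maps; zero-variance samples cannot be t-tested;
  a missing control object is a validation error.

## Known limitations

* The simulator's transition rates are phenomenological; only the outcomes
  they generate (activation doubling, hover offset, persistence window,
  approach fractions) are anchored to measurements.
* Percentile bootstrap CIs undercover slightly (~94% at nominal 95% for
  n = 200); acceptable here, but BCa would tighten it.
* The photometric fixtures cannot reproduce measured stimulus contrasts —
  they reproduce the formulas, not the physical spectra.
* The multilevel (trial-as-random-effect) pseudoreplication check and
  landing/biting quantification are out of scope.
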