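# Methods

This note records the model assumptions, algorithmic definitions, default
parameters, and numerical choices behind `qdtrack`, plus the limits of the
synthetic generator the estimators are validated against.

## Data model

A **trajectory** is a sequence of planar positions (µm) at consecutive
frames with a fixed frame interval `dt` (default 0.1 s, i.e. 10 Hz
imaging). Frame indices are strictly increasing integers; motion analysis
additionally requires them to be gap-free and raises otherwise rather than
silently interpolating. A **cell recording** bundles the trajectories of
one cell with an optional boundary polygon + centre annotation and optional
per-frame punctum-intensity lists. Trajectories of 50 frames or fewer are
discarded before analysis (strict inequality: exactly 50 is dropped).

## Motion profiling

For each trajectory point *i* a centred window of `window_frames` = 20
points (truncated at the trajectory ends, half-open `[i−10, i+10)`) is
analyzed:

- **Local MSD.** `msd(n)` is the mean squared planar displacement over all
  ordered point pairs `(j, j+n)` inside the window, for lags
  `n = 1..n_max` (10). A window with fewer than `n_max + 1` points is
  flagged invalid.
- **Exponent α.** Least-squares line through `(log lag, log msd)`; lags
  with non-positive MSD are excluded and at least 3 positive points are
  required. An optional `offset` (µm²) is subtracted from the MSD before
  fitting: independent Gaussian localization noise of variance σ² per
  coordinate adds a constant `4σ²` to the planar MSD, and for slow
  particles this floor biases the log–log slope downward (for
  D = 0.01 µm²/s, dt = 0.1 s, σ = 20 nm the *ideal* Brownian slope over
  lags 1–10 is 0.88). `AnalysisConfig.loc_noise_var` feeds this correction
  when σ is known (as it is for synthetic data); the default is 0, i.e.
  no correction, since σ is generally unknown for real recordings.
- **Diffusion constant D.** Least-squares slope *s* of MSD versus lag over
  the first `d_fit_points` = 5 lags with a **free intercept** (the
  intercept absorbs the same noise floor), `D = s/4`, clamped at 0 when
  the slope is negative (flagged).
- **Persistence φ.** Mean cosine of the turning angles between consecutive
  *smoothed* displacement vectors `r(j+h) − r(j−h)` with
  `h = persistence_halfwidth` (default 2 frames); `h = 0` recovers raw
  adjacent steps. Smoothing is required for the same reason the paper-style
  velocity estimate is smoothed: with 100-ms steps of order 0.08 µm and
  ~20 nm localization error, the raw turning-angle cosine of genuinely
  directed motion saturates near 0.6–0.8 and straddles any useful
  threshold, while smoothed vectors restore φ ≈ 1 for straight motion.
  φ = 1 for perfectly straight paths, −1 for a perfect zig-zag (at
  `h = 0`), ≈ 0 for an isotropic random walk; zero-length vectors
  contribute no angle and at least 2 angles are required.
- **Directed state.** Point *i* is *directed* iff `α_i ≥ alpha_dir` (1.4)
  and `φ_i ≥ phi_min` (0.7). The printed thresholds in the source study are
  not legible; these defaults make noise-free ballistic motion always pass
  while pure Brownian motion passes at only ≈ 1% of points (and almost
  never survives the segment rules below), and both are configurable.

## Directed segments

Candidate runs are maximal stretches of consecutive directed-flagged
points. A run becomes one or more segments under two rules:

1. **Minimum length**: at least `min_directed_frames` = 5 points.
2. **Displacement rule**: every rolling sub-window of
   `w = round(0.5 s / dt)` frame intervals (5 at 10 Hz) must displace more
   than `min_displacement_um` = 0.267 µm (one pixel). Runs shorter than a
   full sub-window use `w = P−1` intervals with the threshold prorated to
   the same minimum speed, `0.267 µm × (w·dt / 0.5 s)`.

A candidate run that fails the displacement rule somewhere is **split at
the slowest failing sub-window and the parts re-checked recursively**,
keeping the maximal rule-obeying sub-runs, rather than being discarded
wholesale. This matters because the 20-frame window bleeds the directed
flag a few frames past the true end of a directed phase; the sub-window
straddling that slow tail would otherwise veto an entire genuine run. Every
reported segment therefore satisfies both rules by construction.

Segment **velocity** is the mean of smoothed instantaneous speeds — per
point, the central difference `(r(i+h) − r(i−h)) / (2h·dt)` with
`h = velocity_halfwidth` = 2 — taken over *interior* points only, i.e.
points whose full ±h window lies inside the segment. Edge points mix
directed and non-directed displacement; because the diffusive + noise
contribution is an additive absolute term, including them inflates slow
conditions relatively more and biases between-condition velocity ratios
upward (measured: a true 0.70 ratio estimated at ≈ 0.755 with edge points,
≈ 0.744 without). Segments too short or too close to a trajectory end to
have interior estimates fall back to all finite speeds, then to the net
path-length speed. **Run length** is the summed step length over the
segment.

## Motion modes

Whole trajectories are classified by the exponent of their time-averaged
MSD over lags 1–10 (all ordered pairs pooled across the trajectory), using
the same power-law fit (with the `4σ²` offset when configured). The
whole-trajectory fit is nearly unbiased, whereas the mean of per-point
20-frame-window exponents carries a systematic ≈ −0.09 bias (Jensen's
inequality applied to the log of a noisy MSD), which would misplace
trajectories near the class boundaries; this is a deliberate deviation from
averaging local exponents. Boundaries are half-open with boundary values
assigned upward: `[0, 0.4)` constrained, `[0.4, 1.0)` subdiffusive,
`[1.0, ∞)` superdiffusive; trajectories without a valid fit are
*unclassified* and reported separately.

## Two-step statistics

All population statistics weight cells, not samples: step 1 averages within
each cell (and time bin), step 2 takes the unweighted mean ± standard error
across cells. Directed-motion point velocities are binned in 5-minute
intervals by their absolute times; motion-mode proportions in 15-minute
intervals, a trajectory belonging to the bin containing its midpoint.

## Endocytic ratio

For each visible punctum, `a` is its distance from the annotated cell
centre and `b` the distance from the centre to the **first** crossing of
the boundary polygon along the ray through the punctum. The per-frame ratio
is `R = mean(b/a)` (the equation-form definition; `ratio_of_means` is
available as a config switch since the prose form conflicts). Points at the
centre (`a = 0`) are excluded; frames with no usable points are gaps. The
time series is smoothed with a centred, truncated, gap-preserving moving
average over `smooth_points` = 20 frames. R = 1 when all cargo sits on the
boundary and increases as cargo approaches the centre; it is invariant
under rigid motion and uniform scaling of points + geometry.

## Intensity series

Per frame, the mean intensity over all visible puncta, normalized to frame
0 (which must be non-empty with positive mean). Under intensity-conserving
pairwise fusion without blinking, the normalized mean equals
(initial count)/(current count).

## Colocalization

Manders `M1 = Σ red[p] over {p : green[p] > threshold} / Σ red[p]` with a
strictly-greater comparison; the threshold is a number or Otsu's method on
the green channel (the automatic rule used in the source study is
unstated, so it is a required, recorded config item). Zero total red
intensity flags the result invalid. Group statistics are mean ± SD (ddof 1)
over per-image M1 values; empty groups are omitted with a warning. M2 is
provided symmetrically but unused by the pipeline.

## Synthetic generator

Per-frame first-order Markov switching among three motion states, each with
an independently checkable signature:

- **constrained**: a discrete mean-reverting (AR(1)) walk around an anchor
  with stationary SD `confinement_radius/2` and hard radial reflection at
  `confinement_radius`;
- **subdiffusive**: increments drawn from fractional Gaussian noise
  (circulant-embedding synthesis) with Hurst `alpha_sub/2` and one-step
  variance `2·D_free·dt` per coordinate, giving an ensemble MSD of exactly
  `4·D_free·dt·k^alpha_sub` (`alpha_sub = 1` reduces to free diffusion);
- **directed**: constant speed `v_directed` with per-frame Gaussian heading
  jitter `dir_jitter` (0.2 rad) and a small diffusive overlay `D_directed`,
  so directed runs are not trivially straight lines.

Independent Gaussian localization noise (`loc_noise_sigma`, default 20 nm)
is added to every coordinate last. Whole-cell scenes place trajectories
near a star-shaped boundary polygon, superimpose inward drift with radial
reflection at the boundary, and generate per-frame puncta from two-state
telegraph blinking; pairwise fusion (at most one event per frame) adds the
absorbed punctum's base intensity to the survivor, which stops blinking —
total base intensity is conserved. Two-channel image fixtures place
truncated Gaussian red spots inside/outside a green mask with amplitudes
scaled so the red-on-green intensity fraction is exact. All randomness
flows from explicit seeds; identical inputs give bit-identical outputs.

Generator limits: no microscope PSF or camera-noise model, no 3-D motion,
no motion-blur coupling between blinking and localization, fusion partners
are chosen at random rather than by proximity, and blinking on/off rates
are plausibility defaults, not calibrated values.

## Default parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `dt` | 0.1 | s | 10 Hz video rate |
| `pixel_size` | 0.267 | µm | camera pixel at the imaging magnification |
| `window_frames` | 20 | frames | local MSD / persistence window |
| `n_max` | 10 | lags | power-law fit range |
| `d_fit_points` | 5 | lags | initial linear MSD fit for D |
| `alpha_dir` | 1.4 | – | directed-state exponent threshold (chosen; see above) |
| `phi_min` | 0.7 | – | directed-state persistence threshold (chosen) |
| `alpha_constrained` | 0.4 | – | constrained / subdiffusive boundary |
| `alpha_super` | 1.0 | – | subdiffusive / superdiffusive boundary |
| `min_directed_frames` | 5 | frames | minimum segment length |
| `min_displacement_um` | 0.267 | µm | one pixel per 0.5 s |
| `displacement_window_s` | 0.5 | s | rolling displacement window |
| `velocity_halfwidth` | 2 | frames | smoothed central-difference speed |
| `persistence_halfwidth` | 2 | frames | smoothed turning-angle vectors (0 = raw steps) |
| `bin_5min` / `bin_15min` | 300 / 900 | s | statistics bins |
| `smooth_points` | 20 | frames | endocytic-ratio moving average |
| `min_traj_frames` | 50 | frames | selection filter (strict >) |
| `loc_noise_var` | 0 | µm² | known σ² for the MSD noise-floor correction |

Every parameter is echoed into the run manifest and hashed into each CSV
header, so results are always traceable to their exact configuration.

## Validation

`scripts/acceptance.py` (and `tests/test_acceptance.py`, which asserts the
bands) checks, from a single seed: exponent recovery for Brownian /
ballistic / subdiffusive ensembles; median-D recovery with and without
localization noise; recall, velocity accuracy and zero rule violations for
embedded directed runs; the two-condition two-step velocity ratio; mode
accuracy and mixture recovery; endocytic-ratio exact cases, agreement with
an independent per-edge ray-intersection oracle, and monotonicity under
inward drift; Manders agreement with a double-loop pixel oracle and group
means at constructed overlap fractions; and byte-identical CLI reruns.
Derived oracles are implemented independently of the library code paths
they check.

## Known limitations

- Directed phases much shorter than the 20-frame window are diluted below
  the state thresholds and can be missed (the acceptance recall criterion
  uses 30-frame runs; 7–8-frame runs are at the resolution limit).
- With persistence smoothing, pure Brownian motion crosses the point-level
  directed thresholds at ≈ 1% of points; almost all such runs are removed
  by the length and displacement rules, but rare spurious short segments
  can survive in very large Brownian ensembles.
- The α noise-floor correction requires a known localization σ; without
  it, slow-particle exponents are biased low (quantified above).
- Frame gaps are not bridged; trajectories must be resampled or split
  upstream.
- The endocytic ratio assumes a star-shaped-enough boundary around the
  annotated centre that the first ray crossing is the relevant one.
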