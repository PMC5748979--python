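# Methods

This note documents the models, conventions and numerical choices behind
`centrotrack`, in the order data flows through the pipeline.

## Synthetic pair dynamics (`simgen.simulate_pair`)

The separation d(t) of a centrosome pair is modeled in two regimes.

**Search-and-capture.** A discrete-time mean-reverting (Ornstein–Uhlenbeck
type) process reflected at zero:

    d[t+1] = | μ + a (d[t] − μ) + η ε[t] |,   a = exp(−Δt/τ),
    η = σ √(1 − a²),   ε ~ N(0, 1)

so the stationary mean is exactly μ (`mean_separation_search`) and the
stationary SD exactly σ (`sd_search`). The confined "toward and away"
character of the phase is captured by mean reversion; nothing finer (cortex
geometry, microtubule dynamics) is modeled. Defaults: τ = 200 s (a few frame
intervals — slow enough that excursions persist across frames, fast enough
that a 60–90 frame movie samples the stationary law), Δt = 40 s, σ = 2 µm
(wild-type-like; 1 µm for the contractile-knockout-like condition),
μ = 11.5 µm for pairs that do not cluster.

For clustering-competent pairs the search baseline is **8.0 µm**. The
capture band — the separation at which directed motion initiates — is
7–8 µm, and pairs that succeed are precisely those whose search phase dwells
near that band; a baseline at the non-clustering 11.5 µm would almost never
trigger within a movie and would not describe a clustering pair's search
phase. This value is a modeling choice, not a measured constant.

**Motorized phase.** At the first frame t* with d ≤ 7.5 µm
(`onset_separation`) *and* the pair flagged `cluster=True`, d descends
linearly from d[t*] to `final_separation` (1.5 µm) over
⌈900 s / 40 s⌉ = 23 frame intervals, then fluctuates about the plateau with
SD 0.03 µm. Proximity is necessary but not sufficient: sufficiency is
encoded by the `cluster` flag, so non-clustering pairs may approach the band
and still never engage. Anaphase onset is placed 2 frames after completion
for clustering pairs (clustering completes just before anaphase), and near
the end of the movie otherwise; the offset is configurable.

**3D embedding.** Only d(t) is analyzed downstream, so the embedding is
free: the pair is placed symmetrically about a fixed midpoint on an axis
that precesses by small random angles per frame (SD 2° in-plane, 0.5°
axial), which keeps the pair inside the shallow z extent of the rendered
volume while the distance is honored to machine precision.

## Image formation (`simgen.render_stack`)

Each centrosome contributes an axis-aligned anisotropic 3D Gaussian
(σ_xy = 0.11 µm, σ_z = 0.35 µm — typical for a 1.45-NA spinning-disk system
at 488 nm) of amplitude 500 photons on a 10-photon background, sampled at
voxel centers (i + 0.5)·spacing. Default grid: 35 z-slices at 500 nm,
0.13 µm xy pixels (100×/1.45 NA with 2×2 binning; the acquisition pixel size
after binning is not independently verified). Noise is Poisson, optionally
plus Gaussian read noise. Photobleaching, drift, and cell boundaries are not
modeled — a tracker that passes here is validated for geometry and noise,
not for those confounds.

## Localization and linking (`spots`, `linker`)

Coordinates are physical µm with the origin at the corner of voxel (0,0,0);
voxel centers at (i + 0.5)·spacing; indices 0-based.

- **z-selection**: the z-slice maximizing the mean intensity of the
  500 × 500 nm xy window (nearest odd pixel count, minimum 1×1; 3×3 px at
  0.13 µm) around the seed; ties break to the lower slice.
- **Auto-seeding** replaces interactive clicking: local maxima of the max
  projection above median + 5·MAD with a 1 µm minimum separation; a
  "provided" mode replays click CSVs. Max (not mean) projection is used for
  the seeding display/detection surface.
- **Masked detection**: brightest voxel within a sphere of the gate radius
  (physical distances, anisotropic voxels honored), accepted only above
  median + 3·1.4826·MAD + 2% of the frame's dynamic range — the last term
  keeps faint PSF shoulders from counting as detections on clean frames.
  Ties resolve toward the predicted position, then lowest (z, y, x).
- **Subpixel refinement**: least-squares anisotropic 3D Gaussian plus
  constant offset over a 7×7×5-voxel window (scipy `least_squares`, bounded
  trust region); flat or failed windows fall back to an intensity-weighted
  centroid, flagged in the output.
- **Gate radius**: r = 2·Δt·v_avg with v_avg = 0.02 µm/s, i.e. 1.6 µm at
  40 s — twice the mean per-frame displacement.
- **Propagation plan**: every non-anchor frame chains frame-by-frame toward
  its nearest anchor (ties to the earlier anchor).
- **Association** is globally optimal one-to-one assignment
  (`linear_sum_assignment`) under the gate per propagation step, so results
  are independent of detection order; blocks owned by different anchors are
  stitched at their boundary the same way. A missed detection carries the
  track's position forward; gaps of ≤ 2 frames are filled by linear
  interpolation, longer gaps terminate the track (at 0.02 µm/s and 40 s
  frames, longer extrapolation is unreliable). No Kalman prediction and no
  merge/split handling.

## Clustering kinematics (`kinematics`)

**Completion** ("separation stabilized") is operationalized as the earliest
frame t_c from which d stays ≤ 2 µm *and* every 5-frame window inside
[t_c, end) has SD ≤ 0.3 µm. Windows are taken fully inside the stable tail;
a window straddling t_c would mix descent frames into the stability test and
reject obvious step-like completions. Because the final descent step is
usually already below 2 µm, detection lands one or two frames inside the
descent; at thresholds between the plateau and the last descent step the
generator truth is recovered exactly.

**Phase segmentation** fits, over the record up to completion, the two-piece
model *constant plateau → linear descent reaching d(completion)*: with knot
k and N = completion, f(t) = d[N] + m(t − N) for t ≥ k and f(t) = f(k)
before; the knot minimizing total squared error (slope refit per knot,
closed form) wins, and ties go to the earliest knot. Reported quantities:
the motorized onset is the first descending frame b = k + 1; the onset
separation is d[b]; the motorized speed is |m|/Δt; the motorized duration is
(completion − b + 1)·Δt, counting the intervals from the knot through
completion (the generator's 900 s nominal phase spans ⌈900/40⌉ = 23
intervals = 920 s). A non-negative fitted slope marks the pair
unsegmentable, as does a completion earlier than frame 3.

*Known limitation.* Conditioned on triggering, the last search frames tend
to descend into the capture band, and the least-squares knot absorbs that
approach: for pairs with extended search phases the knot is early by several
frames and the per-pair onset separation is overestimated. Ensemble
*medians* remain accurate under the study conditions (over 60 replicate
50-pair ensembles: onset separation 7.6 ± 0.5 µm against the 7.5 µm truth,
motorized duration 918 ± 36 s against 920 s) because most clustering pairs
begin their movie near the capture band. Per-pair segmentations of
long-searching pairs should be treated with caution.

**MSD** uses the time-averaged estimator, MSD(τ) = ⟨(d(t+τ) − d(t))²⟩ over
all start times and pairs, restricted to the search phase by default (the
alternative — ensemble displacement from an aligned origin — is available
via `phase="all"` plus pre-alignment, since which estimator produced the
published curves is not stated).

**Aligned population statistics** align each pair at anaphase onset (an
input annotation; how it was annotated originally is not modeled) or at
completion, then report per-time cross-pair mean, SD (ddof = 1, NaN when
n < 2) and n.

**Histograms** pool search-phase separations (clustered pairs: frames before
their motorized onset; failed pairs: the pre-anaphase span) into right-open
0.5 µm bins, reporting the median and its SEM from a seeded 1,000-resample
bootstrap (the original "medians ± SEM" method is unstated; bootstrap is the
assumption-free choice).

## Tripolar geometry (`geometry`)

The vertex for inter-pole angles is the **centroid** of the three poles (the
original vertex convention is unstated; the centroid is invariant to rigid
motion and uniform scaling and always lies inside the pole triangle, in its
plane, so the three angles partition 360° exactly). The smallest of three
angles summing to 360° is necessarily ≤ 120°, and no angle can reach 180°
(the centroid of non-collinear points cannot lie on a line joining two of
them) — the simulator samples the remaining two angles inside those bounds.
Rose histograms use right-open 10° bins on (0°, 120°], the top edge closing
into the last bin. Clustering efficiency is a binomial fraction with a
Wilson score interval.

## AFM elasticity (`afm`)

Units: piezo z in µm, deflection in nm (or V with an nm/V sensitivity),
spring constant in N/m, force in pN, indentation in nm, modulus in Pa.

- **Sensitivity** from glass curves: Theil–Sen slope of the upper half of
  the deflection range (robust to the contact kink); on glass the deflection
  follows the piezo one-for-one, so the slope converts signal to length.
- **Contact point**: every sampled z is scored as a candidate z0 by the
  combined SSE of a flat force baseline before it and a conical-Sneddon
  quadratic (in the deflection-corrected indentation) after it; the minimum
  wins, refined off-grid by parabolic interpolation of the SSE profile. The
  exact algorithm of the originally cited method is not public; this joint
  piecewise-residual scan is the package's own substitute and is validated
  by the forward round trip (noiseless recovery within one 10 nm sample;
  bias under 20 pN noise well inside two samples). Curves whose best
  piecewise fit explains < 5% more variance than a flat line are rejected as
  contact-free.
- **Indentation**: δ = (z − z0) − d with the pre-contact deflection baseline
  subtracted; F = k·d. Negative-δ samples are dropped. Only approach
  segments are analyzed.
- **Averaging**: per-position curves are linearly resampled onto the common
  overlap of their δ ranges and averaged pointwise.
- **Sneddon fit**: F = (2/π)·E/(1−ν²)·tan(α)·δ², linear in E, restricted to
  δ ≤ 800 nm so the cortex dominates the restoring force. ν = 0.5
  (incompressible cell, standard in AFM cell mechanics) and α = 35° (typical
  conical half-angle for the V-shaped soft-lever class) are defaults, both
  configurable; neither is a measured property of the original probe.
  Per-cell values aggregate the four probed positions (mean, SD, n).
  Viscoelasticity, tilt and virtual-deflection corrections are out of scope.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds (`numpy` Generators); equal
seeds give bit-identical outputs, and run outputs carry the config checksum
in a manifest. The bundled analyses use ensembles of 40–50 pairs of 90–120
frames, rendered stacks of 64×64×21 voxels × 25 frames, 200-replicate
Monte-Carlo checks for the AFM and MSD limits, and 200–500 simulated
tripolar spindles — sizes at which the Monte-Carlo error of every reported
median or ratio is several times smaller than the tolerance it is compared
against.
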