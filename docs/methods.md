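# Methods

This note records the models, parameter choices and numerical decisions
behind `physarum_morph`, and what the phantom-based validation does and
does not establish about real recordings.

## Imaging model and preprocessing

Input is an ordered series of 8-bit greyscale stills (RGB is collapsed
with BT.601 luminance weights); timestamps are index × capture interval,
never file mtimes, so reruns are bit-reproducible. Two capture regimes are
assumed: a 24 h dish-scale series at 1 frame/60 s (growth), and a 1 h
macro series at 1 frame/4 s, i.e. Fs = 0.25 Hz (veins).

Denoising is non-local means (strength 8 on the 0–255 scale, 5 px patch,
21 px search window). The dish ROI is found once, on the first frame, by
a Canny + Hough circle transform with 1 px radius resolution inside the
configured bounds (defaults 1500–1750 px for full-resolution sensors;
geometry-relative parameters scale with the image). The circle with the
highest normalised accumulator vote fixes the centre (near-ties broken by
distance to the frame centre); because a dish rim ring produces two
concentric near-tied circles, the radius is then refined from the radial
histogram of edge pixels around that centre, taking the innermost ring
with ≥ 50 % of the strongest ring's support — the ROI is the *inner*
circle of the dish. Pixels outside the ROI are filled with 255 so the
inverse threshold can never call them foreground.

Scale calibration is a single reference length: pixel_pitch [µm/px] =
1000 × known_mm / known_px.

## Growth and exploration

Segmentation: foreground iff intensity < Gaussian-weighted local mean
(window 71 px, σ = (window−1)/6) − offset 4. Masks are not hole-filled:
veins legitimately enclose background windows, and a large solid blob
whose interior locally matches its own mean is intentionally left to the
threshold's judgement. Areas are foreground counts × (pitch/1000)².

The growth rate uses **raw** areas, (A_t24 − A_t0)/A_t0, with A_t24 the
frame nearest 24 h (within one capture interval); the baseline-subtracted
series A_t − A_t0 exists for plotting only, since the ratio would be
undefined on it. The inoculum disc counts toward both covered and
explored area — no carve-out. Exploration is the running union of
foreground masks; it is monotone by construction and ≥ covered area at
every frame.

Growth inhibition is the signed normalised difference
(Area_c − ⟨Area_c0⟩)/⟨Area_c0⟩, negative under inhibition; the positive
"inhibition magnitude" is its negation, and both conventions are exposed
because published dose–response curves are frequently plotted with the
positive sign. The dose–response fit is an ordinary least-squares
polynomial (default degree 3) over per-replicate points, with per-dose
mean ± σ returned alongside.

## Fractal complexity

Box counting uses grids anchored at the foreground bounding-box corner
(making D translation- and padding-invariant) and box sizes descending in
powers of two within [2, min(H,W)/4]; D is the negative slope of the
log–log least-squares line, and the fit R² is always reported so that
poor scaling regimes are visible rather than silently averaged away.
Single-offset grids are used for determinism. The dimension is computed
on the full segmentation mask (not the skeleton), subsampled to one frame
every 10 min.

## Vein morphometry

The vein-set segmentation uses window 79 (midpoint of the plausible
69–91 range at full resolution; configurable) and offset 2. Thinning is
the standard iterative (Zhang–Suen-equivalent) skeletonization from
scikit-image; sections come from a probabilistic Hough transform on the
skeleton (1 px ρ, 1° θ, 25 votes, 10 px minimum length). Measurement
positions are spaced every 5 skeleton px with a minimum of four per
section, fixed in image coordinates for the whole hour.

Width at a position is measured on the denoised greyscale frame by
marching rays in ±normal direction in 0.25 px steps (bilinear
interpolation) until the intensity exceeds a stop level: the midpoint
between the section's median line intensity and the local background
median. The background probe samples rings at 1–4 × 15 px along the
normals and keeps the brightest median, so a probe that lands inside a
wide vein cannot masquerade as background. The chord is evaluated over a
small angular fan (0, ±0.15, ±0.3 rad) around the nominal normal and the
minimum taken: a Hough line oblique to the vein axis by θ inflates the
normal chord by 1/cos θ, and the perpendicular width is the minimal chord
through the point. The stop level is re-estimated per frame so slow
illumination drift does not bias the rays.

QC cascade, in order, on first-frame widths: (1) mean width strictly over
1 mm → rejected; (2) positions outside Q3+1.5·IQR / Q1−1.5·IQR of the
section's widths dropped, fewer than four survivors → rejected (quartiles
use the standard linear interpolation definition); (3) section median
strictly over 2× the median of active sections' medians → rejected;
(4) |vein − background| median contrast below 10 intensity units →
rejected; (5) among geometrically overlapping sections the one with more
active positions survives (ties: lower id). The cascade is idempotent:
re-running it on its own output changes nothing.

## Contraction spectra

Traces are denoised by a one-sided-FFT gate: PSD bins at or below
Q3 + 1.5·IQR (quartiles over the non-DC bins) are zeroed and the spectrum
inverted; the DC bin is always preserved so the mean width survives.
Welch slicing uses segment length 256 (≈17 min at 0.25 Hz — at least two
cycles of the slowest physiological frequency per slice), 90 % overlap
with stride = ⌊segment × (1 − overlap)⌋ (so a 900-sample hour gives
stride 25 and 26 slices), per-slice mean removal and a Hann window. Each
slice's frequency is the power-weighted mean of i·Fs/N over the seven
bins around the peak (DC excluded, window clipped to [1, N/2]); this
weighting interpolates below the bin width of Fs/N ≈ 0.98 mHz, and slices
are *not* averaged into one PSD first, which keeps the estimator honest
under frequency drift. PSD normalisation is by window power; the
estimator is scale-invariant so the choice cannot affect results.

A trace is flagged *low confidence* when no PSD bin exceeds 3× the IQR
gate: the PSD of pure noise is approximately exponential, whose maximum
routinely clears Q3 + 1.5·IQR itself, so a margin factor is required for
"no periodic component" to be detectable at all; 3× separates the noise
maximum (≈2× the gate in expectation for hour-long traces) from any
physiologically plausible spectral line, which exceeds it by orders of
magnitude. Organism-level averaging excludes sections outside 1.5·IQR of
the per-section frequency distribution (skipped below three sections) and
reports mean ± σ.

## Volume estimation

Diameters (pooled as per-position time-means over the hour — the stable
choice when widths oscillate) are histogrammed into 50 equal intervals
between min and max, half-open with the last closed; if all widths are
identical the distribution degenerates to a single interval at that
value. With interval centres 2r_k and proportions p_k, lengths are
l_k = A·p_k/(2r_k) (A = raw 24 h area, since the physical network
includes the inoculum) and est. vol = Σ π r_k² l_k, all unit-converted to
mm before use. The normalized volume est. vol/A has units of length and
reads as an effective mean network thickness.

The cross-section error forms are exact algebra: ε_S(α) =
(α − sin α)/(2π − (α − sin α)) on [0, 2π) (0 at α=0, 1 at α=π, divergent
toward 2π) and ε_E(x) = x/(2r − x) on [0, 2r) (0 at x=0, 1 at x=r). The
reported worst-case volume interval is [est/(1+ε_max), est]: the circular
assumption can only overestimate relative to these geometries, so the
correction is one-sided.

## Phantoms: what they do and do not show

Phantom generators are deterministic in (spec, seed) and export ground
truth sufficient for every oracle without re-reading pixels. Strokes are
drawn from signed distance fields with a 1 px anti-aliasing ramp
(hard-edge and flat-cap modes exist where exact pixel counts or exact
2r·L projected areas are needed; flat caps are avoided when the skeleton
is analysed, because a rectangle's medial axis grows diagonal corner
spurs that a capsule does not have). Noise is additive Gaussian clipped
to [0, 255].

Validation problem sizes: dish phantoms of 384² px with rim radii
110–150 px (20 random placements), disc series of 25 frames with radii
16–23 px, separated stroke networks of 420² px with widths 100–600 µm at
10 µm/px (≥ 50 sections), and 900-frame 160² px pulsating series. The
growth-oracle disc radii sit below ~25 px deliberately: the adaptive
threshold's 71 px window must see background from the disc centre, and
solid discs much wider than the window would be segmented as rings —
real plasmodia are networks of thin veins, which is the regime the
threshold is designed for.

What passing phantoms does **not** show: robustness to uneven
illumination, condensation, dish reflections, organism fragmentation, or
contraction waveforms far from sinusoidal; phantom veins are straight
strokes, so curvature-induced width bias is untested; and the volume
model's cylindrical-section assumption is checked only in the regime
where it is exact by construction.

## Known limitations

* Sections at vein crossings whose widths vary smoothly (rather than as
  outliers) can survive the consistency filter; the cascade bounds, but
  does not eliminate, junction bias.
* ROI detection assumes a bright interior inside a darker rim; dishes
  imaged with inverted polarity need a manual ROI (`manual_roi`).
* The exploration union is pixel-exact and therefore inherits any
  segmentation error frame by frame; there is no temporal smoothing.
* Statistics helpers are deliberately thin (Shapiro–Wilk, unpaired
  two-tailed t-test, star annotation at p ≤ 0.05/0.01/0.001, no
  multiple-testing correction); study designs needing more belong in a
  dedicated statistics package.
* The molarity helper documents an internal inconsistency in published
  epinephrine dilution labels (34.12 µM corresponds to 1:160 000, not
  1:175 000); it computes from first principles and leaves the
  interpretation to the user.
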