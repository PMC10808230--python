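# Methods

This note documents the model, the quantification pipeline, and the design
choices behind `nanocable`, in the order a reader would meet them: the
agent-based simulator, the pseudo-image renderer, the analyses, the
synthetic-movie generator, and the numerical conventions shared by all of
them.

## The physical picture

During tracheal tube expansion the apical cortex carries sub-diffraction
F-actin condensates ("nanoclusters", minor/major axis modes near 140/210 nm)
that fuse and fission continuously. Fusion along the circumferential axis is
slightly more stable than along other directions, and over many fusion
cycles this small bias self-organizes the cortex into parallel
circumferential actin cables with a regular spacing near 0.5 µm. The model
treats the cortex as a flat periodic 2 D patch: the tube circumference maps
to the image y axis (90°), the tube's long axis to x (0°). Anisotropic
membrane tension enters only as direction-dependent drag on the filaments.

## Agent-based model

**Filaments** are bead–spring chains: 6 beads spaced 0.05 µm, contour
length 0.25 µm (set so that a cluster of a few tens of filaments has the
observed nanocluster size; the connector rest length of 0.035 µm matches the
α-actinin crosslinking span). Forces per bead:

- harmonic stretching between consecutive beads,
  `F = k_stretch (|r_{i+1}-r_i| - d0)`, `k_stretch = 100` (force/length in
  drag-normalized units), `d0 = 0.05 µm`;
- harmonic bending through the discrete Laplacian,
  `E = (k_bend/2) Σ_i |r_{i-1} - 2 r_i + r_{i+1}|²`, `k_bend = 2` — stiff
  enough that 250-nm filaments stay nearly straight (persistence length of
  F-actin is ~10 µm, far above the filament length);
- harmonic connector springs (below).

**Connectors** are transient springs between points on two distinct
filaments. Crosslinkers (α-actinin/Zasp52 analog) are passive; motors
(myosin II minifilament analog) advance both attachment arc-length
coordinates toward the barbed end at `motor_speed = 0.2 µm/s` and detach at
the filament end. Binding: each free connector attempts binding with
probability `1 − exp(−bind_rate·dt)`; a uniformly random bead is drawn and a
partner bead within the capture radius (0.1 µm) on another filament is
chosen uniformly (cKDTree with periodic boxsize; ties broken by the run's
single RNG stream). Unbinding is Poisson with per-kind rates (crosslinkers
0.5 s⁻¹, motors 2 s⁻¹).

**Integration** is Euler–Maruyama with a diagonal drag tensor: displacement
= force·dt/γ componentwise plus noise of per-axis variance
`2·kT·dt/γ_axis`, `kT = 5·10⁻⁴` (units: drag·µm²/s). `γ_x = 1` always;
anisotropic conditions use `γ_y = 40`. dt = 1 ms; a step moving any bead
farther than one bead spacing raises an instability diagnostic rather than
silently corrupting the run. Connector binding/unbinding and filament
turnover are applied every 10 steps with the rates integrated over the
longer interval, which leaves event statistics unchanged and dominates the
cost budget otherwise.

**Turnover** replaces a whole filament (releasing its connectors) by a fresh
straight one at a uniform random position and orientation, at rate
0.05 s⁻¹. This is the effective-diffusion mechanism that arrests coarsening:
the steady-state cluster spacing falls as turnover accelerates (the suite
asserts this trend over 0.005–0.2 s⁻¹). Whether the original system renews
whole filaments or depolymerizes tips is not documented; whole-filament
renewal is the simplest mechanism with the stated effect.

**Condition grid.** Crosslinker levels L/M/H = 60/800/1600; rows toggle
motors (0 or 400) and friction anisotropy (γ_y/γ_x = 1 or 40). With
moderate crosslinkers alone (1-M) the filaments condense into isolated
elliptical nanoclusters (median minor axis ≈ 0.2 µm); adding motors (3-M)
connects them into a labyrinth; adding anisotropic friction (4-M) aligns
the condensation instability with the fast (x) axis, producing parallel
cables running along y with spacing ≈ 0.5 µm. Mechanistically the drag
anisotropy makes density modulations along x grow fastest, so stripes
extended along y are selected — the same continuum logic as an anisotropic
mobility in a phase-separating film. Default duration 90 s reaches the
dynamic steady state at these parameters; the pattern keeps exchanging
material afterwards (and coarsens slowly, which is why longer runs drift
toward slightly larger spacings).

All numeric defaults above are this package's calibration of the
undocumented force-law constants; they are recorded in `params.py` and can
be overridden per run. The claims the package tests are pattern-level
(sizes, spacings, orientations, orderings), not force-level.

## Rendering

Bead positions are histogrammed on a 69 × 69 grid of 0.04325 µm boxes,
counts are multiplied by 20 to match experimental intensity levels, and a
Gaussian blur of σ = 2 px (periodic boundaries) mimics diffraction. The
grid side (2.98425 µm) differs from the 3 µm box by 0.5%; beads wrap into
the grid periodically so intensity mass is conserved exactly. Blur acts on
float intensities (no 8-bit rescaling first).

## Orientation and coherency

The structure tensor is built from Gaussian-derivative gradients (σ = 1 px,
configurable) and averaged over the ROI. The dominant direction is the
eigen-axis of least intensity variation folded to axial [0, 90]°, coherency
is (λ₁−λ₂)/(λ₁+λ₂). A constant ROI yields coherency 0 and an undefined
(NaN) direction; an exactly isotropic tensor likewise. The cable criterion —
direction > 75° and coherency > 0.3 — defines the anchor time point of
circumferential cable formation. Orientation distributions use the
per-pixel tensor smoothed in a σ = 2 px window, weighted by gradient
energy; the median is interpolated within its histogram bin.

## Cluster morphometrics

Binarization follows the reference recipe: rolling-ball background
subtraction (r = 50 px), local Otsu threshold in a disk of radius 5 px on
the 8-bit rescaled image, 3×3 median despeckle. The threshold comparison is
inclusive (`>=`) with zero excluded, so a perfectly flat bright plateau —
whose local window is single-valued — counts as foreground while a flat
dark background does not; on continuous-valued images this is
indistinguishable from a strict comparison. Components of at least
0.01 µm² are described by their moment-equivalent ellipse (axes = 4√λ of
the pixel covariance, the Analyze-Particles convention), circularity
4πA/P² capped at 1, solidity from the convex hull; solidity < 0.7 is
excluded, edge-touching components are kept. Axial angles of cluster major
axes are doubled to the full circle for circular means/medians and halved
back; an antipodal (zero-resultant) doubled sample leaves the mean flagged
undefined.

Skeleton analysis prunes terminal branches (endpoint-to-junction paths;
junction-free components are kept whole, so a simple bar is not erased) and
reports the mean over ROIs of the longest connected skeleton, with diagonal
steps weighted √2.

## Fusion stability

Masks are segmented by watershed on the (lightly smoothed) distance
transform; smoothing the seed landscape (σ = 1 px, minimum seed distance
3 px) prevents pixelation plateaus from splitting one constriction into
parallel lines. Watershed lines interior to the mask with ≥ 5 px are
candidate fusion sites; a site is newly formed iff its pixels carried no
mask signal one frame earlier. Duration counts consecutive frames from
birth (≤ 11) in which ≥ 80% of the boundary pixels stay on; events whose
horizon extends past the movie end are right-censored and flagged. Events
are binned 0–30/30–60/60–90° by the *fusion direction* — perpendicular to
the boundary line's principal axis — so that two clusters merging along the
circumferential axis land in the 60–90° bin, matching how the field names
fusion directions.

## Motion anisotropy

Clusters of 0.01–0.1 µm² and circularity 0.5–1.0 at frame t are matched at
t+1 to a component with 0.5–2× the area and ≥ 1 px overlap; ambiguities
resolve by largest overlap, then closest size, else the step is skipped.
The anisotropy statistic is mean|Δy| / mean|Δx| (NaN for an all-static
movie), with a two-sided t test comparing |Δx| and |Δy| per condition.

## PIV

Frames are enlarged 10× (bilinear), giving 91-px interrogation windows of
0.394 µm at the native 0.04325 µm pitch. Each window of consecutive
enlarged frames is matched by cross-correlation; the correlation is
zero-padded (linear, not circular) and each lag is divided by its overlap
area, which removes the loss-of-pairs taper that otherwise biases broad
correlation peaks toward zero. The peak search is confined to the validity
radius and refined to sub-pixel precision by parabolic interpolation.
Vectors longer than 0.1 × window are invalid (so the default settings
measure speeds up to ≈ 123 nm/s), as are featureless windows. The ×4
temporal subdivision is applied to the *velocity fields* by linear
interpolation between frame pairs: interpolating the images first and
correlating blended sub-frames is ill-posed, because consecutive blends
share identical content whose self-match locks the correlation peak at
zero lag. Velocities are reported in nm/s. Known limitation: when the
feature correlation length approaches the window size (very smooth,
blob-like textures) the measured speed is biased low by roughly 10–15%;
sharp-edged binarizable textures, the intended regime, do not suffer this.

## Structure factor

S(q) = |Σ_j exp(−i q·r_j)|²/N on the reciprocal lattice of the periodic
box (the mathematically identical single-sum form of the double sum over
pairs), summed over lattice vectors per |q| annulus (bin width δq = 2π/L,
bins centered on lattice multiples so Bragg peaks sit on bin centers) and
averaged over the last snapshots of a run (default 10–40; the acceptance
pipeline pools S(q) curves across seeds before fitting, which is much more
stable than fitting per seed at this box size, where only ~6 cables fit).
The interval is 2π/μ from a bounded least-squares fit of
A/(√(2π)σ)·exp(−(q−μ)²/2σ²) over the peak ± 3 bins. A fit is refused
(aperiodic) when the best interior bin is not a strict local maximum or
does not exceed 1.5× the median of the searched range. The image-based
route (`image_interval`) uses the Hann-windowed, 4×-zero-padded power
spectrum with the same Gaussian fit.

## Statistics

Two-sided two-sample KS (scipy), Watson's two-sample U² with mid-rank tie
handling (implemented here; p by seeded permutation, default, or by the
asymptotic series), and Kruskal–Wallis followed by pairwise two-sided
Wilcoxon rank-sum tests with Bonferroni multiplication capped at 1. Axial
angles are always doubled before circular testing. The suite calibrates all
three tests' type-I error at α = 0.05 over 10⁴ null replicates (±1.5
points).

## Synthetic-movie generator

The generator emulates what the analyses assume about the real movies:
anti-aliased elliptical clusters with lognormal sizes (modes 0.14/0.21 µm,
spread σ = 0.18), axial von-Mises orientations, periodic Gaussian-profile
cables (interval 0.45 µm), band-pass-noise labyrinths, lattice random
walks (isotropic, or biased with an exact planted |Δy|/|Δx|), scripted
fusion/fission events (disk pairs that overlap into a necked peanut for a
planned 1–11 frames), a light Gaussian PSF (σ = 0.8 px, countering the
erosion of small ellipses by thresholding and despeckling), and optional
Poisson/Gaussian noise (off by default so oracle tests see the clean
construction). Ground truth is emitted as tables next to the frames.

What it does *not* emulate: Airyscan PSF structure and deconvolution
artifacts, photobleaching, z-projection effects, intensity heterogeneity
within clusters, and cluster shape change during motion. Passing recovery
tests therefore demonstrates that the analysis chain is correct on data
with the assumed statistical structure, not that the biological estimates
from real movies are unbiased.

The staged series mimics the developmental program: isotropic clusters →
aligned but disconnected clusters (aspect ≈ 1.5, κ = 8) → connected
cables at a scripted frame. By construction the dominant direction rises
above 75° during the aligned phase while coherency stays below 0.3 until
the cables appear, reproducing the orientation-before-connectivity
ordering; the cable-criterion detector returns the scripted transition
frame.

## Known limitations

- **Motor-driven connectivity is not reproduced.** In this calibration the
  motors behave as active fluidizers: the isotropic motor condition (3-M)
  shows more, smaller components than the motor-free one (1-M) instead of
  a connected labyrinth, and within the anisotropic row the motors refine
  the pattern to the observed ~0.5 µm interval rather than coarsening it.
  Variants that do make motors connective — end-dwelling at the barbed end
  (`motor_end_dwell`) and a myosin-minifilament-scale reach
  (`motor_rest_length`, `motor_capture_radius`) — raise the 4-M coherency
  substantially but coarsen the cable spacing toward 1 µm, so the defaults
  keep the short-reach, end-detaching motors that reproduce the spacing,
  the cluster geometry, the cable criterion, and the emergence ordering.
  The switches are exposed for exploring the trade-off.
- **Anisotropy alone is too effective here.** Condition 2-M (anisotropic
  friction, no motors) already reaches coherency ≈ 0.36–0.39, partially
  satisfying the cable criterion that should single out 4-M; its pattern
  is, however, coarser and less regular than the 4-M cables.
- **PIV underestimates speeds on very smooth textures** (feature
  correlation length approaching the window), by roughly 10–15%; see the
  PIV section.
- The moment-ellipse angle of a near-round cluster is dominated by
  covariance noise and, after axial folding, piles up at 45°; orientation
  statistics are therefore meaningful only for appreciably elongated
  clusters (the analyses use medians, which are robust to this).

## Problem sizes and tolerances

Simulation-based checks run 400 filaments (2400 beads) in a 3 µm box for
90 simulated seconds (60 s for the turnover-trend scan), 2–3 seeds per
condition — a scale chosen so a full steady state forms in about a minute
of wall time per run. Cluster-size checks use the median over pooled
records with a ±25% band around 200 nm; the cable interval uses a ±20%
band around 0.5 µm with S(q) pooled across seeds; recovery tests state
their tolerances inline (one 30-nm histogram bin for size modes, ±0.02 µm
for the planted cable interval, ±10% for planted motion ratios, ±15–25%
for PIV speeds). Degenerate inputs (empty states, empty masks, flat
images, all-static movies) return defined sentinels (empty lists, NaN with
flags) or raise typed errors, as documented per function.
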