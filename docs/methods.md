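# Methods

This note documents the models behind `hdnirs`, the defaults and why
they were chosen, and what the synthetic experiments can and cannot say
about real recordings.

## Probe geometry

Both arrays live in a planar head-surface patch (millimetres, origin at
the layout centroid). No atlas registration is attempted: the package
compares array *designs*, not anatomy, and a plane preserves everything
the comparison needs (channel separations, overlap, field of view,
mirror symmetry).

* **Sparse** — a 3×11 grid at 30 mm pitch with alternating
  source/detector roles (corners are sources): 17 sources, 16 detectors
  and exactly 52 channels at 30 mm. Eight extra detectors sit 8 mm
  outward of the sources in columns 2/4/6/8 of the top and bottom rows,
  adding eight short-separation (SS) channels for 60 in total. The grid
  shape is the only 17-source/16-detector 30 mm arrangement consistent
  with 52 channels; which sources carry SS detectors is a design choice
  (mirror-symmetric, spread along the array).
* **HD** — a five-row triangular lattice with pitch 33/√3 ≈ 19.05 mm,
  so first nearest neighbours are 19.05 mm apart and second nearest
  exactly 33 mm. Sources occupy even columns of rows 0/4 and odd
  columns of row 2 (the centre site of row 4 is demoted to a detector),
  giving 25 sources and 58 detectors whose enumeration yields 108
  19 mm and 91 33 mm channels — within a few percent of the
  reference hexagonal design (112/94), whose exact counts depend on
  boundary trimming that is not fully specified. Eight SS detectors
  hang 8 mm below the outer bottom-row sources. The field of view
  matches the sparse grid's bounding box to within 10% on each axis.

Channels are enumerated by scanning all source-detector pairs against
distance bins (centre ± 2 mm): {8, 30} mm for sparse, {8, 19, 33} mm
for HD, ordered by (source id, detector id).

## Forward model

The photon-transport step is an analytic diffusion approximation: the
semi-infinite-medium Green's function with an extrapolated boundary
(index-matched, `z_b = 2D`), pencil beams replaced by isotropic point
sources one transport mean free path deep. Channel-to-vertex
sensitivity uses the Rytov (adjoint) form

    A[ch, v] = G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d) · dV / D,

which is reciprocal in source/detector exchange, non-negative, and
decays monotonically with vertex depth. Optical properties (1/mm):
μa = 0.018, μs′ = 1.1 at 760 nm; μa = 0.019, μs′ = 1.0 at 850 nm —
typical adult-head effective values.

The head collapses to two congruent lateral grids (default 5 mm
sampling) below the optode plane:

| surface | depth | compartment thickness |
|---|---|---|
| scalp | 3 mm | 10 mm |
| brain | 15 mm | 4 mm |

Each vertex represents a voxel of lateral cell area × compartment
thickness. The thicknesses matter: the superficial scalp+skull
compartment is physically much thicker than the cortical gray-matter
sheet, and this weighting is what lets the spatially variant
regularization (below) attribute a uniform superficial signal to the
scalp surface at the standard α_spatial = 0.001. The brain/scalp
separation also requires the superficial sensitivity peak under the
optodes to be resolved — coarser lateral sampling than the default 5 mm
degrades it (the peak sets λ_spatial through a maximum).

Multispectral stacking multiplies each wavelength's sensitivity block
by the natural-log extinction coefficients (1/(mm·µM), from the
standard compiled haemoglobin tabulation at 760/850 nm), so the forward
map goes directly from (ΔHbO, ΔHbR) in µM to ΔOD.

## Image reconstruction

Spatially variant rescaling over columns (vertices × chromophores):
`L_vv = sqrt((AᵀA)_vv + α_sp · max diag(AᵀA))`, `Â = A L⁻¹` — note the
vertex-wise Gram diagonal and the square root, which make the rescaling
dimensionally consistent with `A L⁻¹`. Tikhonov inversion in channel
space, `x = L⁻¹ Âᵀ (ÂÂᵀ + λI)⁻¹ y` with
`λ = α_meas · max diag(ÂÂᵀ)`; both α default to 0.001. The
channel-space system is solved through one Cholesky factorization (no
explicit inverse), reused across measurement vectors — per-block
reconstructions cost one triangular solve each. The "brain only"
variant restricts `A` to cortical columns and applies plain Tikhonov.

A reconstruction of this family is a smoothed minimum-weighted-norm
estimate: it recovers *location* well but spreads amplitude, so a
reconstructed peak underestimates the injected vertex amplitude by
design. Amplitude-recovery checks therefore compare the pipeline
against a forward-model oracle in channel space (see Validation), while
localization is assessed in image space.

The display mask keeps vertices whose normalized channel-summed
sensitivity strictly exceeds 0.01 (applied to the linear normalized
value, after inversion, for display only).

## Synthetic recordings

The generator defines the study conditions:

* **Paradigm** — 20 s initial rest, then 18 blocks of 18 s (9 congruent,
  9 incongruent, seeded random order) with inter-stimulus rest jittered
  uniformly in 10–15 s; sampling 24.4 Hz (sparse) / 17.5 Hz (HD).
* **Activation** — two 12 mm-radius cortical patches at (±90, 0) mm
  (a dorsolateral-prefrontal analogue), jittered ±12 mm per subject in
  the full experiment to emulate inter-subject anatomical variability;
  peak HbO 1.0 µM (incongruent) / 0.5 µM (congruent), HbR = −0.25·HbO.
  The temporal profile is a canonical double-gamma impulse response
  (peak ≈ 6 s, undershoot ≈ 16 s) convolved with the block boxcar and
  peak-normalized, so the stated amplitude is the peak excursion.
* **Superficial physiology** — a seeded sum of five sinusoids at
  0.02–0.12 Hz (≈0.05 µM RMS) shared by every scalp vertex (HbR at
  −0.3× HbO), the component that short-separation regression exists to
  remove.
* **Nuisance** — per-channel cardiac pulsation at 1.1 Hz (0.021 OD,
  above the 0.5 Hz low-pass so the filter is exercised), smooth random
  cubic drift (0.012 OD RMS), and white noise (0.003 OD at 30 mm)
  scaled by `sqrt(G(30 mm)/G(L))`, a shot-noise-like law that makes
  photon-rich short channels quiet and 33 mm channels the noisiest —
  consistent with 19 mm channels showing higher raw SNR than 33 mm
  ones. These defaults give raw channel SNR (mean/SD) around 45–50,
  in the 40–60 range typical of good adult-forehead recordings.
* **Artifacts** — six spike events (0.05–0.15 OD, 0.2 s decay) and two
  baseline-shift events (±0.03–0.08 OD) at seeded times, each hitting a
  random 15% of channels; an optional dead-channel fraction produces
  sub-threshold intensities for the pruning stage.

Intensity is `I = i0·exp(−ΔOD_total)` with `i0 = 0.02`. Every
stochastic element derives from explicit seeds; identical seeds
reproduce recordings bit for bit, and the superficial signal is defined
in continuous time so both arrays (different sampling rates) see the
same subject.

What the generator does *not* emulate: curved multi-layer anatomy and
CSF light piping, Mayer waves and respiration with realistic spectra,
subject-specific optode coupling, serially correlated sensor noise, and
cap-placement error. Passing tests therefore demonstrate that the
analysis machinery behaves correctly under the assumed signal model —
not that either array will achieve these exact numbers on real heads.

## Preprocessing

Fixed order: prune → OD → SplineSG → low-pass → Beer-Lambert.

* **Pruning** — drop a channel if, at either wavelength, mean raw
  intensity < 0.001 or mean/SD < 5 (strict inequalities; a constant
  channel counts as infinite SNR).
* **OD** — natural log relative to the channel mean.
* **SplineSG** — per trace: spikes are samples whose residual from a
  2 s Savitzky-Golay baseline exceeds 6× its robust (MAD) SD; baseline
  shifts are flagged where the baseline's change across 1 s exceeds 6×
  the robust SD of that change series (self-normalizing, so smooth
  physiological oscillation is not flagged). Shift segments are
  corrected by subtracting a smoothing spline (p = 0.99, csaps
  convention, λ = (1−p)/p on the sample grid) and re-anchoring the
  segment and everything after it to levels estimated from 3 s windows
  of a smoothed copy (keeping cardiac out of the anchors). Spike
  samples are replaced by the value of a 10 s, order-3 Savitzky-Golay
  fit. Clean channels pass through unchanged. Detection also produces a
  global motion time mask used later for block rejection.
* **Low-pass** — order-3 Butterworth at 0.5 Hz, zero-phase
  (forward-backward), giving ≥ 40 dB at the 1.1 Hz cardiac line.
* **Beer-Lambert** — per channel 2×2 solve with the extinction matrix,
  path = separation × partial-pathlength factor (default 1,
  configurable).

## GLM

One OLS fit per channel and chromophore. Design columns: per condition,
26 Gaussians (SD 1 s, 1 s step) whose centres span −2…23 s inclusive
around each retained block onset; Legendre drift polynomials of order
0–3; the SS channel whose HbO trace best correlates with the long
channel (ties to the lowest index); one Heaviside column per detected
motion event (absorbing residual baseline steps — including those a
correction leaves *inside* the SS regressor, which would otherwise
contaminate every channel regressed against it); and nuisance copies of
the condition basis for motion-rejected blocks, so their responses
cannot leak into the retained-condition estimates. Blocks whose
−2…23 s window overlaps the motion mask are rejected before
estimation, mirroring the practice of discarding artifact-contaminated
blocks ahead of the GLM; subjects left with fewer than five blocks in
either condition are excluded.

Numerically the fit shares one Cholesky factorization of the common
design Gram matrix across channels and adds the per-channel SS column
through a bordered-system (Schur complement) solve; a near-zero Schur
complement falls back to the SS-free solution, and rank deficiency
raises an error naming the collinear columns. The HRF estimate is the
basis expansion on the −2…23 s grid at the recording's sampling rate.

## Statistics

Block delta: mean concentration over [onset+7, onset+18) minus
[onset−2, onset) (start-inclusive, end-exclusive at the sample level).
Per-site t = mean/SE across blocks (sample SD, n−1); degenerate SE = 0
yields a flagged signed infinity. Group critical value is the
two-tailed Student quantile (2.12 for 17 subjects at α = 0.05).

ROI definitions: mirror-symmetric lateral channel bands
(55 ≤ |x| ≤ 125 mm of the channel midpoint, long channels only), and a
shared cortical vertex set derived from the HD array: vertices whose
sensitivity summed over the ROI channels (normalized over the brain
surface) strictly exceeds 0.01, then those strictly above the stage-1
mean. Restricting candidates to the brain surface is essential — over
the stacked brain+scalp vertex set the summed map is scalp-dominated,
and a scalp "ROI" would measure exactly the superficial leakage the
reconstruction is designed to reject.

Array comparison selects, per subject/hemisphere/condition, the maximal
HbO t (minimal for HbR) over ROI channels, and the mean delta of the 25
extreme-t ROI vertices in image space, then applies a paired two-tailed
Student's t-test between arrays (pairs with a missing member dropped).

The cluster permutation test thresholds the observed group t map at the
two-tailed critical value, joins supra-threshold channels by spatial
adjacency (distance ≤ radius, default 33 mm; singletons allowed),
scores clusters by the sum of |t|, and builds the null by seeded
subject-level sign flips (default 5000 permutations), recording the
maximum cluster mass per permutation;
`p = (1 + #{null ≥ observed}) / (1 + n_perm)`. The sign-flip sum and
the flip-invariant sum of squares make the null t maps a single matrix
product per permutation. With radius 0 the test reduces to a
per-channel max-statistic permutation test. Null simulations (20
channels, 15 subjects, 200 permutations) put the family-wise rejection
rate near the nominal 5%, slightly conservative due to the discreteness
of 200 permutations.

## Validation strategy and problem sizes

* Closed-form pieces (Green's function, rescaling, inversion) are
  checked against independent dense evaluations to 1e-10 relative.
* Amplitude recovery uses an independent oracle: the ground truth
  pushed through the forward model and exact Beer-Lambert inversion to
  a true channel concentration time course, windowed exactly like the
  pipeline. Noiselessly the two agree to ~0.1%; the tolerance tested is
  10%. Peak localization of the reconstructed noiseless HD image is
  required within 10 mm (typical error ≈ 8 mm at 5 mm sampling, set by
  grid quantization and the depth-weighting bias of the inversion).
* The paired-array direction (HD image deltas larger, HD localization
  at least as good) is measured over 20 seeded subjects at default
  noise on an 8 mm head grid — the coarser grid keeps the ensemble
  inside a few minutes while leaving the comparison direction
  untouched; brain/scalp-separation checks use the default 5 mm grid
  they require.
* GLM recovery at default noise is evaluated at the strongest ROI
  channel; across seeds the relative L2 error is 0.06–0.13 against a
  <0.15 requirement, a floor set by white noise over nine blocks that
  is consistent with the ~1 µM across-block standard errors seen in
  comparable real recordings.

## Known limitations

* The planar two-surface head cannot reproduce absolute partial
  pathlengths of a layered curved head; channel-space concentrations
  carry the usual partial-volume scaling (ppf = 1) and are only
  comparable within the model.
* Selected channel-space deltas can favour the sparse grid: max-t
  selection on the HD array often picks quiet 19 mm channels whose
  concentration amplitude is smaller — the same selection trade-off the
  real comparison reports — while image space consistently favours HD.
* The brain/scalp separation of the reconstruction depends on the
  resolved superficial sensitivity peak; head grids coarser than the
  default 5 mm under-resolve it and shift the depth balance.
* The cluster statistic (sum of |t|, sign-flip null) is one standard
  choice among several; mass definition, adjacency radius and singleton
  handling are configurable.
* SNIRF output covers the subset of the format the pipeline needs (one
  data block, measurement list, probe positions, stim blocks), not the
  full specification.
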