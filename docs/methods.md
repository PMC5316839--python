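# Methods

This note documents the models behind each analysis stage, the parameters
that matter, what the synthetic generators emulate, and the numerical
choices made where the design was genuinely open.

## Conventions

Images are row-major `(row, col)` float arrays with a physical pixel size
in nanometres; physical x runs along columns and y up (so a displacement
`(drow, dcol)` has direction `atan2(-drow, dcol)`).  Orientations are
axial: degrees in `[-90, 90)`, counterclockwise from the image x-axis.  The
radial-reference convention subtracts the axial bearing of each pixel from
the pattern centre before binning, wrapping back into `[-90, 90)`.

## Orientation analysis

Local orientation comes from the structure tensor: the outer product of the
intensity gradient, smoothed with a Gaussian window (`window_sigma`,
default 2 px).  The minor eigenvector points along the fibres; coherence
`(l1 - l2)/(l1 + l2)` in [0, 1] measures anisotropy and gates which pixels
enter the histograms (default `coherence_min = 0.2`; a relative floor of
1e-6 on the tensor trace suppresses floating-point residue in flat regions,
which is tiny but can be perfectly anisotropic).  Gradients use
nearest-edge padding — constant padding would fabricate strong edges along
the image border.  Histograms use 90 bins of 2 degrees, enough to separate
the vortex twin peaks; probabilities are per-pixel with equal weight.
Peaks are local maxima with circular wrap-around, prominence >= 0.01 of
probability mass, parabolically refined to sub-bin precision.  The mode is
reported as a probability-weighted axial mean over +-2 bins, which removes
the half-bin quantization when the true mode falls on a bin edge.

The vortex signature is evaluated in the radial convention; star, aster and
random signatures in the absolute convention.  This reconstruction — spiral
fibres crossing the local radial direction at +-45 degrees, both
chiralities equally weighted — is the only geometry we found consistent
with symmetric +-45-degree peaks, and it is a reconstruction, not a
published rule.

## Pattern morphometrics and classification

*Diameter delta.*  360 radial rays are cast from the centre (0.5-px steps,
bilinear sampling).  A ray's coarse arm tip is the first radius where the
intensity stays below background + 2 noise s.d. (median/MAD estimates) for
5 consecutive samples; the tip is then refined to the radius where the
profile crosses half its shaft level, which is unbiased for a step edge
under symmetric PSF blur.  Arm directions are angular peaks of the
tip-radius function (peaks within 10 degrees merged).  Each arm contributes
an end-to-end span: its tip radius plus the opposing tip radius when an arm
exists within 15 degrees of the opposite bearing, and twice its tip radius
otherwise (no opposing arm, as in odd-armed stars).  Delta is the mean span
times the pixel size.  Recovery bias is under 5% for spans of 1-8 um at
default noise.

*Vortex diameter.*  Twice the radius of the maximum of the angularly
averaged radial profile, parabolically refined.  The ring test requires an
interior annular maximum with (i) contrast at least 35% of the image
dynamic range, (ii) a central dip below 75% of the ring amplitude,
(iii) decay beyond 2.2 ring radii, and (iv) rotational symmetry — at least
60% of bearings occupied at the ring radius.  Criteria (i)-(iv) are our
operationalization of "ring-like with high rotational symmetry"; a single
fibre crossing near the centre of a random network fails (iv), a dense
network fails (i) and (iii).

*Classification.*  (1) ring topology => vortex; (2) otherwise the pattern
must be centre-dominated (smoothed central intensity >= 2 s.d. above the
image mean) and isolated (most rays reach background before the image
edge), with at least 3 radiating arms => star if delta >= 3 um else aster
(the field's size rule); the orientation-signature peak count (<= 6 for
stars) only modulates a confidence score; (3) anything else => random, with
low confidence when the signature is not flat.  A single fibre (two
opposing directions) is deliberately not an asterisk.

## Mesh pore sizes

The image is normalized to its maximum and thresholded at 0.002 — an
intentionally low cut that keeps everything above true zero, appropriate
for high-contrast (SEM-like) meshes on a near-black background.  The
inverted mask's connected components (4-connected pores against
8-connected fibres, the standard complementary pairing) are each replaced
by the ellipse with the same second central moments; the pore size xi is
twice the mean semi-axis, read as a diameter.  Border-touching components
are excluded because their extent is censored by the field of view.
Exponential mean and rate come from the closed-form MLE (the sample mean);
at least 10 pores are required.

The mesh generator renders an isotropic Poisson line process whose
intensity is the expected number of fibre crossings per micrometre of
transect, so the mean free chord — and with it the mean pore size — scales
as 1/intensity; halving the fibre density doubles the mean pore diameter.
The two-condition comparison uses intensities 0.6 and 1.2 crossings/um on
a 40 x 40 um field at 20-nm pixels with 20-nm fibres, sizes at which the
border-censoring and fibre-width biases are both small; smaller fields or
sparser meshes bias the ratio below 2 through censoring of large pores.

## Track statistics

sigma is the per-track median Euclidean distance to a fixed per-pattern
centre ("median" following the Results usage; the Methods word "medium" is
read as a typographical variant); tau is last minus first observation
time.  The dwell-model fit compares a right-censored exponential (censored
at the movie length, detected as dwell within one frame interval of it;
MLE mean = total observed time / number of uncensored tracks) against an
uncensored Gaussian, selecting by AIC.  A sample in which every track
survives the whole movie is degenerate — on-off kinetics are unresolvable —
and is reported as Gaussian with mean equal to the movie length.

The generator's mobile regime draws positions i.i.d. uniform in a disk of
radius R about the centre (median distance R/sqrt(2); R = 495 nm
reproduces a 350-nm median) and exponential dwells truncated at the movie;
the immobilized regime pins every track to the centre for the full movie,
making the sigma = 0 contract exact (optional jitter is available but off
by default).  Defaults: 598 tracks, 300-s movie, 5-s frames, 20-s mean
dwell.  A minimal greedy nearest-neighbour frame linker exists only to
build fixtures from rendered movies; CSV track tables are the primary
input.

## FRAP

Intensities are divided by the per-pixel mean of the (>= 2) pre-bleach
frames; with a reference region, each frame is further divided by the
reference's frame-wise mean, correcting slow observational photobleaching
(a 1000-s decay is corrected to within 1%).  Normalization is idempotent.
The kymograph is the lnROI profile per frame; the recovery fraction per
pixel is (I(t) - I_postbleach) / (I_prebleach - I_postbleach) (pixels
bleached by less than 5% are excluded as uninformative).  Iso-kymograph
contours are extracted at 9 levels, 0.1-0.9.

Contours are closed curves around the unrecovered region, so before
fitting, points hugging the bleach-region edges (within 1.5 px) or the
first post-bleach column are discarded and the remainder split into
contiguous runs, then split again at the bleach midpoint — two converging
fronts otherwise merge into one Lambda-shaped branch with a meaningless
joint slope.  Each branch's position-versus-time regression slope gives a
velocity (x pixel size / frame interval).  Branches spanning positions at
essentially constant time are iso-time contours, the signature of
homogeneous (polarity-free) recovery; when they dominate, or when no
branch drifts faster than 0.15 px/frame, the result is "homogeneous" with
v = 0.  Opposite-signed slopes on the two sides of the bleach midpoint
mean recovery from both ends (two velocities); same-signed slopes mean one
front.  Monomer rate = v / 2.7 nm.  Velocity recovery is within 10% over
10-100 nm/s at default noise; the two-branch rule is a stand-in for a
visual judgement of directionality.

Temporal projections colour each pixel by the frame of its maximum
intensity (blue early to red late, amplitude-weighted) and paint pixels
bright in >= 80% of frames white (immobile structures).

## AFM

Force curves are piezo position z and cantilever deflection delta, both in
nm; with the spring constant k in N/m, force in nN is k * delta.  The
contact point minimizes, over every candidate breakpoint (coarse grid of
every 4th sample, then refined to every sample), the residual of a
constant baseline before plus a two-term power-law branch
a * d^1.5 + b * d^2 after — the two Hertz exponents, which also absorb the
softening of the branch by the cantilever's own deflection.  A curve whose
total rise stays below 3.5 baseline s.d. raises a no-contact error.
Indentation past contact is d = (z - z0) - (delta - delta0), with delta0
interpolated at the contact point so a rigid z-offset changes nothing.

The modulus is a linear least-squares fit of F against d^m inside the
100-500 nm depth window (m = 1.5 sphere, 2 pyramid), with Poisson ratio
0.5 (incompressible; not stated in the source protocols).  Both tip models
are provided because bead-tipped probes and pyramid contact models both
appear in practice; the CLI default is pyramid, and the pyramid face
half-angle is a required user parameter — it is probe-specific and no
default would be defensible.  Fitting a curve with the wrong tip model
leaves an order-of-magnitude larger RMSE, which is the intended
model-mismatch flag.  Noiseless generated curves refit E exactly (relative
error < 1e-6); with 1-nm deflection noise the median of 100 fits is within
5% of truth and 95% of contact points are within 20 nm.

## Synthetic generators

All generators share a `GeneratorConfig` (field size, pixel size, PSF
sigma, background, noise, seed); identical configuration gives
bit-identical output.  Rendering draws anti-aliased unit strokes, blurs by
the PSF, normalizes to peak 1, adds constant background and Gaussian
noise, and clips at zero — a minimal forward model of fluorescence
imaging.

Two rendering profiles are used:

* the **instrument profile** (default: 29-nm pixels, 38-nm PSF sigma
  ~ 90-nm FWHM, 5% background, 3% noise) emulates a high-NA TIRF-SIM
  recording and is used for everything that analyses "recorded" images;
* the **simulation profile** (`simulation_config`: 4-nm pixels, 6-nm PSF,
  low noise) renders the same scale-free pattern geometry finely enough to
  resolve individual fibres, the synthetic analogue of plotting simulated
  geometry directly.  The vortex orientation signature is evaluated on this
  profile: inside a 500-nm vortex the spiralling fibre texture lies below
  the optical resolution of the instrument raster, where the ring's own
  edges (tangential, +-90 degrees) dominate the tensor.  Mesh images use a
  20-nm, zero-background profile emulating SEM contrast.

Vortices are logarithmic-spiral arcs (constant +-45-degree pitch to the
local radial direction, equal chirality counts, 80 arcs) crossing a
150-nm-thick annulus of the given diameter.  Stars default to 5 bundled
arms (150-nm bundles), asters to 12 single-fibre arms (40 nm), both with a
compact bright core; arm angles are evenly spaced with +-8-degree jitter
unless given.  In the diameter-recovery sweep, asters below 2 um carry 8
arms — a dozen arms on a 1-um pattern would sit closer together than the
PSF can separate, which is a resolution limit, not an estimator defect.
Random networks draw uniformly positioned and oriented 1-um segments at a
given density per um^2.

What the generators do *not* emulate: filament curvature and buckling,
intensity variation along fibres, pattern crowding and overlap,
camera-specific (Poisson/EMCCD) noise, drift, or the coarsening dynamics
that create the patterns.  Passing tests therefore demonstrate that the
estimators recover known geometry under idealized optics — they do not
validate segmentation on real, cluttered micrographs.

## Problem sizes

The test suite and the acceptance script run on deliberately modest sizes
chosen as the smallest at which the statistical claims are stable: a
40-scene classification benchmark (10 per class), 3 seeds per span in the
diameter sweep, 598-track populations, two 2000^2-px meshes per condition,
100-curve AFM Monte Carlo sets, and 5 seeds per FRAP velocity.
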