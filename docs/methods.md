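# Methods

`rgscal` simulates the calibration of a wall-mounted infrared
respiratory-gating camera against a nine-point plate, and quantifies what
calibration quality means clinically: the residual baseline drift a
miscalibration leaves in a DIBH gating trace while the couch travels
through the scanner bore.

## Model

The tracking system reports metric 3D marker positions, so the map between
the physical (couch) frame and the camera-view frame is modelled as a 4×4
homogeneous **affine** calibration matrix `A` with bottom row `[0,0,0,1]`
(12 free parameters):

    X' = A X,

`X` the 4×n homogeneous world coordinates of observed markers and `X'`
their camera-view coordinates. No perspective division is modelled: the
camera system triangulates positions internally and exposes 3D
coordinates, so a projective (DLT) model would add parameters the data
cannot constrain. The textbook shorthand `A = X' X⁻¹` is realised as the
least-squares solution (`X` is 4×n, not square): `CalibrationModel.fit()`
minimises `Σ‖x'ᵢ − A xᵢ‖²` by a single `lstsq` solve over the shared
design block, and tests pin it to an independent normal-equations solve at
1e−9.

A fit needs ≥ 4 non-coplanar world points. The nine plate points alone are
coplanar (the plate is levelled, all z = 0); what rescues the geometry is
the marker block itself, whose four markers span ~35 mm vertically. A
block-centers-only session is therefore rank-deficient: the model raises a
degeneracy error unless a flagged minimum-norm solution is explicitly
requested.

### "Eigenvalues" of the calibration

Calibration quality is conventionally summarised by the SVD spectrum of
`A`'s 3×3 linear part: an undistorted (rigid) calibration has all singular
values equal to 1. Eigenvalues of a non-symmetric affine matrix may be
complex, so singular values are the implemented reading. Each singular
value is assigned to the world axis its right singular vector is most
parallel to; because the matrix is near-identity, its singular vectors mix
strongly under noise, so the assignment is solved globally (maximising
total alignment via `linear_sum_assignment`) rather than greedily per
axis — a greedy pass leaves the later axes with whatever contaminated
vectors remain. Exact ties break deterministically with a warning.
`CalibrationResults.axis_gains()` (`‖A e_axis‖`) is provided as a
coupling-free per-axis diagnostic.

## Scene and noise generator

The synthetic scene stands in for the room: a rigid ground-truth camera
pose (default: 35° tilt about the lateral axis, 2 m standoff — a plausible
wall mount; the pose is configurable, and all drift statistics below are
pose-independent for rigid poses), the 3×3 plate (rows 150 mm apart
longitudinally, columns 100 mm laterally, point #1 on the isocenter), and
a four-marker block whose default tetrahedron (~50 mm extent, 35 mm tall)
is an invented but realistic stand-in for the unpublished vendor geometry.

Placement noise magnitudes come from the packaged positioning-uncertainty
table (measured SDs, camera-view frame, adopted as world-frame SDs since
the pose is near-rigid):

| mode              | lateral | longitudinal | vertical | yaw SD |
|-------------------|--------:|-------------:|---------:|-------:|
| manual (row +15)  | 1.41 mm | 1.73 mm      | 0.20 mm  | 1°     |
| manual (row −15)  | 1.57 mm | 1.65 mm      | 0.24 mm  | 1°     |
| manual with laser | 0.41 mm | 0.41 mm      | 0.20 mm  | 0      |
| couch move        | 0.00 mm | 0.25 mm      | 0.05 mm  | 0      |

Manual rows are per-point where measured (#3's row for the +150 mm row,
#7's row for the −150 mm row). The 1° yaw SD for free-hand placement is a
documented default (orientation error matters but no figure is published);
laser and couch modes suppress it. Gaussian draws model an operator
misplacing the whole rigid block (one draw per placement, shared by its
four markers).

The **single-block** strategy uses laser precision on the center row and
free-hand (manual) placement on the six off-row points; the
**three-block** strategy replaces free-hand placement with couch moves.
The calibration software pairs *nominal* world coordinates with the
*observed* camera coordinates of the noisy placement — that mismatch is
the entire error mechanism; camera-side observation noise exists but is
off by default.

The Monte Carlo sweep mode (`uniform_sweep`) instead perturbs every marker
coordinate independently, uniform on [−u, +u] per axis (the convention of
perturbing the entries of `X` directly for a stated "± u mm"
uncertainty). The distinction matters: a block-level draw is shared by the
four markers of a block and therefore cancels out of the within-block
vertical regressor, hiding exactly the short-lever-arm vertical
sensitivity the sweep is meant to expose. Both pictures are switchable per
`NoiseModel(per_marker=...)`.

What the generator does **not** emulate: lens/stereo physics, infrared
reflectance, plate levelling error, couch sag, operator bias (all draws
are zero-mean), or whatever proprietary pose-filtering the vendor applies
on top of raw marker positions. Passing tests therefore validate the error
*propagation* — placement noise → matrix error → drift — not the absolute
drift magnitudes of any particular room.

## Eigenvalue sweep

For each half-width u ∈ {1…5} mm (2000 repetitions each in the shipped
study size): simulate a nine-point session with per-marker uniform noise,
fit, record axis-assigned singular values. Per-axis dispersion grows with
u, and the geometry orders it: the plate spans ±150 mm in Y and ±100 mm in
X, but the only vertical spread is the block's ~35 mm height, so
SD(σ_y) < SD(σ_x) ≪ SD(σ_z).

The clinical "0.5 mm tolerance for the eigenvalue" is dimensionally
ambiguous (singular values are unitless). `tolerance_threshold` interprets
it as a positional error |σ−1|·L over a per-axis reference lever arm L
(plate half-extent for X/Y: 100/150 mm; block half-height for Z), takes a
configurable per-repetition summary (mean by default, max over axes), and
returns the largest swept u within tolerance. The interpretation is a
documented choice, configurable via the lever arms. Degenerate repetitions
are excluded rather than retried, keeping draw streams seed-stable; box
plots use Tukey 1.5×IQR whiskers.

## Drift pipeline

The reported world position of a marker at true position p is
`A_hat⁻¹ A_true p`, so over a scan translating the marker by L
longitudinally the reported vertical coordinate changes by

    drift = [A_hat⁻¹ A_true − I]_{zy} · L,

signed, exactly linear in L, and zero iff the composition has no y→z
coupling. Drifts are reported in cm per 400 mm (the typical breast DIBH
scan length). The waveform simulator (free-breathing sinusoid — default
4 s period, 1 cm peak-to-peak — two cycles, then a breath hold at maximum
inhale while the couch moves the marker from −L/2 to +L/2 at 20 mm/s,
25 Hz sampling) exists for realism and CSV export; tests require its
scan-phase amplitude change to equal the closed form to 1e−9.

`drift_experiment` pairs repetitions across strategies by a shared
per-repetition seed: session → fit → closed-form drift, summarised as
mean, sample SD, mean |drift| and the fraction meeting the 0.2 cm
recommendation.

A structural note on magnitudes: for a rigid camera pose the least-squares
error matrix is the world-frame regression of placement errors onto
nominal coordinates (the rotation cancels in the norm), so the y→z
coupling is driven solely by the *vertical* placement SD — which the
levelled plate keeps at ~0.2 mm. The simulated single-block drifts
therefore sit near 0.02 cm SD, an order of magnitude below drifts measured
on real hardware; real-room drift evidently receives contributions (block
tilt, vendor algorithm internals) outside this noise model. The
simulation's comparative claim — three-block ≪ single-block — is the
robust output; absolute drift magnitudes are not.

## Procedure planner

Calibration procedures are ordered action lists (laser alignments, couch
moves, free-hand repositions, captures) checked by a validator: every
point captured exactly once, every capture's exposed block at the point's
nominal world position given the cumulative couch offset, laser alignments
only with their targets on the laser plane, couch back at reference at the
end. Bookkeeping conventions (documented in the module; they are the only
reading consistent with the procedures' published effort tallies): initial
block placement is not an action; one transverse-laser alignment covers
all the center-row points it lists; a couch move of any distance counts
once; an alignment flagged `at_reference` includes re-referencing the
couch. The reordered variant's final return to reference before
verification is left implicit, as in its published tally.

Resulting counts (laser alignments, couch moves, repositions):
stock single-block (1, 0, 8); three-block (1, 4, 0); single-block variant
(7, 12, 6); column-reordered variant (3, 6, 2).

## Table statistics

`report` reproduces the derived rows of the two packaged measured tables:
column summaries with the **sample** SD (n−1 — the only convention that
reproduces the printed single-block summary, whose population SD would
round to 0.11 rather than 0.12), a pooled-variance Student t-test (as
named in the source of the tables; Welch offered as an option, with
explicit degenerate-variance contracts), criterion counts on |drift|
(drifts are signed), quadrature propagation √(sd₁²+sd₂²) for the
point-difference row (which reproduces all three printed cells at printed
precision, supporting quadrature as the construction), binomial pair
counts, and standard-normal tail fractions.

## Numerical choices

* Units: mm internally everywhere; cm only at reporting layers, with
  unit-suffixed CSV column names.
* Rank threshold for degeneracy: design-matrix singular values below
  1e−8 × σ_max.
* Transform inverses clean the bottom row of affine inverses against
  round-off; inversion of a singular (minimum-norm) estimate raises.
* Isocenter verification is strict: every axis offset must be < 5 mm;
  exactly 5 mm fails.
* All randomness flows through `numpy.random.Generator`; every
  experiment is bit-reproducible under a fixed seed, and sub-seeds are
  drawn below 2³¹.
* Plate column/side sign conventions (which side is #5 vs #9, which row
  is +y) are documented conventions; every downstream statistic is
  symmetric under mirroring, and a test relabels the columns to prove it.

## Known limitations

* Absolute drift and eigenvalue-dispersion magnitudes depend on the
  assumed camera pose and block geometry; only orderings and directions
  are asserted.
* The affine model cannot represent lens distortion or stereo bias; the
  "±3 mm for 0.5 mm tolerance" style of threshold answer depends on the
  documented lever-arm interpretation.
* The planner's effort counts follow the published bookkeeping; an
  alternative bookkeeping (counting laser-guided slides as repositions,
  or alignment re-referencing as couch moves) would change totals.
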