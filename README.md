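# rgscal

Simulation toolkit for the calibration quality of **wall-mounted
respiratory-gating cameras** used at CT simulation (RGSC-style infrared
marker-block tracking).

With a couch- or gantry-mounted camera the patient and camera move
together; with a wall mount they do not, so couch travel during a DIBH or
4D CT acquisition shows up in the gating trace as **baseline drift**
unless the world→camera calibration removes it. Calibration is performed
against a nine-point plate (3 rows × 3 columns; 150 mm row, 100 mm column
spacing) by placing a four-marker reflector block at each point — and how
accurately the block is *placed* decides how good the calibration is. The
package is aimed at medical physicists evaluating calibration procedures:
it compares the stock single-block procedure (free-hand placement on six
of the nine points) against a three-block procedure in which every
placement is laser- or couch-guided.

## Model

The tracking system relates physical-world and camera-view coordinates by
a 4×4 homogeneous calibration matrix,

```
X' = A X
```

estimated as an affine least-squares fit (`A = X' X⁺`) over the marker
correspondences of a calibration session. Three results derive from it:

* **singular values** of A's linear part per world axis (1 = no
  distortion), and their Monte Carlo dispersion under ±1…±5 mm placement
  uncertainty;
* **residual baseline drift**: the vertical signal
  `[A_hat⁻¹ A_true − I]_zy · L` that L = 40 cm of couch travel leaves in a
  simulated DIBH trace, in cm;
* **procedure effort**: validated action lists for four calibration
  procedures with tallies of laser alignments, couch moves and free-hand
  repositions.

It also reproduces the derived statistics (summaries, pooled Student
t-test, 0.2 cm criterion counts, quadrature-propagated point-difference
SDs, normal-tail and pair-count arguments) of the two small measured
tables packaged under `src/rgscal/data/`.

## Worked example

```python
from rgscal import generate_session, fit_calibration, TrueTransform

session = generate_session("single_block", rng=7)   # 9 placements x 4 markers
result = fit_calibration(session)
print(result.summary())
```

```
Camera calibration fit (affine, least squares)
==============================================
observations:        36
strategy:            single_block
residual RMS:        1.2078 mm
singular values:     X 0.990629  Y 1.004883  Z 0.999988
calibration matrix A (world -> camera view):
[[   0.994223    0.011013   -0.003506   -0.85144 ]
 [   0.000544    0.820207   -0.573902   -0.337618]
 [   0.000991    0.574192    0.818962 1999.591231]
 [   0.          0.          0.          1.      ]]
```

The ground truth here is a rigid 35°-tilt wall-mount pose, so ideal
singular values are all 1; free-hand placement noise has pulled X to 0.991
(a ~1% lateral scale distortion). The fit still passes the clinical 0.5 cm
isocenter verification —

```python
ver = result.verify_isocenter(TrueTransform.default())
print([round(o, 4) for o in ver.offset_mm], ver.passed)
# [0.8512, 0.5096, 0.1408] True
```

— which is precisely the weakness the comparison targets: verification at
the isocenter cannot see a scale/shear error that grows with couch
travel. The drift this calibration leaves over a 40 cm scan:

```python
print(result.residual_drift(TrueTransform.default()))  # 0.0043 cm
```

Compare procedures over 200 paired repetitions:

```python
from rgscal.drift import drift_experiment
for name, s in drift_experiment(200, seed=0).items():
    print(name, s.mean_abs_cm, s.sd_cm)
# single_block 0.0189 0.0238
# three_block  0.0057 0.0070
```

Couch-guided placement cuts the residual drift by ~3× in this simulation
(absolute magnitudes are scene-dependent; see `docs/methods.md`). Effort
counts for the encoded procedures:

```
$ rgscal plan
                      strategy  laser_alignments  couch_movements  block_repositions
           varian_single_block                 1                0                  8
                   three_block                 1                4                  0
          single_block_variant                 7               12                  6
single_block_variant_reordered                 3                6                  2
```

Other CLI subcommands: `simulate-session`, `fit`, `eigen-sweep`,
`drift-compare`, `report-tables`, and `run-all` (full bundle with a run
manifest; deterministic per seed).

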