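# Methods

`emtdig` models the measurement chain of an electromagnetic-tracking (EMT)
head digitizer — the device used before a MEG/EEG acquisition to record the
anatomical fiducials, HPI coils, EEG electrodes and scalp points that tie
the head, device and MRI coordinate frames together — and quantifies how
tracking noise, electromagnetic interference, head motion and
transmitter–receiver distance degrade digitization, and how digitization
error propagates into equivalent-current-dipole localization error on a
spherical phantom. All lengths are millimeters, times seconds, rates Hz;
all frames are right-handed.

## Coordinate frames and registration

The head frame is built from the three cardinal landmarks in the
Neuromag/MEGIN style: +x runs from the left toward the right preauricular
point (LPA → RPA), the origin is the foot of the perpendicular dropped from
the nasion onto the LPA–RPA segment, +y points from the origin to the
nasion, and z = x × y. This is the only convention supported; it makes the
transformed LPA/RPA lie on the x-axis and the nasion on the +y-axis, which
the pipeline asserts after every session. No fiducial symmetrization is
applied.

Rigid alignment is the Kabsch/Umeyama least-squares fit: centroids removed,
rotation from the SVD of the cross-covariance, with the standard
determinant guard (the smallest-singular-value axis is flipped if the
optimal orthogonal matrix is a reflection), then the translation from the
centroids. It requires at least three non-collinear correspondences and
reports the post-alignment RMSD. ICP iterates nearest-neighbour matching
(`scipy.spatial.cKDTree`; exact ties resolve deterministically to a single
neighbour) and the Kabsch update until the RMSD improves by less than `tol`
(default 1e-9 mm) or `max_iter` (50); the accepted RMSD sequence is
non-increasing and the best transform seen is returned.

## The synthetic tracking generator

No raw tracking data are distributed with the study this machinery is
designed for, so the generator emulates the relevant physics rather than
replaying recordings. It produces, for a rigid test fixture, the two
streams a real session yields: the stylus-tip receiver and a head-bound
6-DOF reference receiver, sampled on a common clock.

**Fixtures.** Four deterministic ground-truth objects:

| name | points | geometry |
|---|---|---|
| `test_frame_9` | 9 | 16-cm square plate: 4 mid-side points (3 used as cardinals + back) and 5 top-face points; physical points are excavated 2 mm deep, so outward normals are carried for depth compensation |
| `phantom_5` | 5 | sphere of radius 87.5 mm: 3 fiducials (doubling as HPI coils) + 2 further HPI markers |
| `head35` | 35 | sphere of radius 520/2π ≈ 82.76 mm (52-cm head circumference): 3 fiducials + 32 marked scalp points |
| `eegcap32` | 35 | sphere of radius 610/2π ≈ 97.08 mm (61-cm circumference): 3 fiducials + 32 EEG electrode sites |

The 32 free points use a golden-spiral placement on the upper cap —
deterministic, roughly equidistributed, and documented here as a stand-in:
the physical objects' exact point coordinates are not published. Sphere
fixtures put the cardinals on the equator so the fixture frame coincides
with its own head frame, which makes ground truth trivial to express.

**Noise.** Per-axis Gaussian noise with a distance power law,
σ(d) = σ₀·(d/d₀)^γ, evaluated at each sample's true distance from the
transmitter. Defaults: d₀ = 150 mm, γ = 3 (tracking precision degrades
roughly with the inverse field strength, and the field of a compact
transmitter falls off dipolarly), σ₀ = 0.05 / 0.08 / 0.03 mm for the
`fastrak_tx2` / `fastrak_tx1` / `aurora` profiles. The σ₀ values are free
calibration constants chosen only to reproduce the qualitative ordering of
the three systems' native fluctuation (aurora < tx2 < tx1); absolute
fluctuation levels of the physical systems are not published as numbers, so
these are configuration values, not claims. With γ = 3 the model is
deliberately pessimistic at long range: beyond ~300 mm the per-axis noise
exceeds what a 1-mm clustering radius can absorb, so long-distance
experiments must either widen the radius or accept cluster loss — the real
systems are better behaved near the edge of their measurement volume.

**Interference.** A magnetic object is modelled as a quasi-static bias
(not extra variance): magnitude `strength / |src − transmitter|^decay`
(default decay 3 — the object couples to the transmitter field and
re-radiates), directed from the object toward the receiver. This is the
simplest model that reproduces the qualitative observations: interference
falls off steeply with the object's distance from the transmitter and
displaces, rather than scatters, the digitized points.

**Motion.** An optional rigid trajectory moves the fixture during
digitization; the default "moving" condition is a sinusoidal ±5° rotation
plus ±10 mm translation at 0.2 Hz. The reference receiver (100 mm
posterior to the fixture centroid, rigid with it) follows the same
trajectory and carries its orientation quaternion, as a 6-DOF receiver
does.

**Error index.** The `aurora` profile emits a per-sample quality score in
[0, 1] (0 = ideal) emulated as `clip(σ(d)/σ_max + |bias|/1 mm, 0, 1)` with
σ_max = 1 mm. The real device's score is proprietary; this emulation only
preserves its monotonicity in distance and interference, which is what the
filtering logic needs.

What the generator does **not** emulate: operator hand tremor and stylus
orientation, skin/foam compliance, transmitter field physics (Biot–Savart
of the coils), receiver-specific noise anisotropy, and sample dropout.
Passing tests therefore demonstrate the correctness of the pipeline's
geometry, clustering, statistics and error propagation under controlled
conditions — not the absolute accuracy of any physical digitizer.

## Digitization pipeline

1. **Movement compensation** re-expresses each stylus sample through the
   simultaneous reference pose, `q = R_ref(t)ᵀ (p_stylus − p_ref(t))`; a
   position-only reference degrades gracefully to translation
   compensation. Timestamps must agree to 1 µs.
2. **Error-index filtering** (optional, before clustering, so discarded
   samples cannot form clusters) keeps samples with index ≤ threshold.
3. **Cluster detection** finds stylus dwells as time-contiguous runs: a
   sample joins the current run if its distance to the running centroid is
   ≤ radius (strict ≤; default 1 mm), otherwise the run closes and is kept
   if it has ≥ min_count samples (default 100). Sequential run detection —
   rather than density clustering over all samples — keeps label
   assignment by dwell order well-defined; a pairwise membership rule
   (distance to every member ≤ radius) is available as an option. With the
   defaults, a 3-s dwell at 40 Hz yields ≈120-sample clusters. The cluster
   spread is bounded by the radius with respect to the running centroid at
   admission time; the final centroid can shift marginally.
4. **Averaging and labelling**: each cluster's centroid becomes one
   digitized point; labels are assigned in dwell order, the first three
   being nasion/LPA/RPA.
5. **Depth compensation** (optional): a blunt stylus tip resting on an
   excavated point sits `depth` mm outside the true point along the
   outward normal; the correction subtracts `depth·normal` (default 2 mm
   for the test frame).
6. **Head-frame assembly**: the head transform is built from the three
   cardinal centroids and applied to every point.

min_count does not scale with sampling rate (100 at both 40 and 60 Hz);
at 60 Hz a 3-s dwell simply yields ~180-sample clusters.

## Error metrics

* Mean position tracking fluctuation of a nominally fixed receiver:
  `mPTF = (1/n) Σ_{k=1}^{n−1} |p_{k+1} − p_k|`. Note the 1/n prefactor over
  n−1 consecutive differences — the implemented definition is (n−1)/n times
  the conventional mean step length. For iid isotropic Gaussian noise of
  per-axis σ the expected value is (n−1)/n · 4σ/√π.
* Digitization error: per-label Euclidean distance between digitized and
  true positions in the head frame; the mean error is the arithmetic mean
  over all matched points.
* Summaries: quartiles are Tukey hinges (medians of the median-inclusive
  halves — exact on small samples, no interpolation ambiguity);
  IQR = Q3 − Q1. The default outlier rule is the literal multiple-of-Q3
  convention: outlier if value > 1.5·Q3, extreme if value > 3.0·Q3; the
  conventional Tukey fences (Q3 + 1.5·IQR, Q3 + 3·IQR) are available via
  `fence="tukey"`. The two conventions differ whenever Q3 ≷ 3·IQR; users
  comparing against box-plot fences should select explicitly.
* Welch's unequal-variance two-tailed t-test (via `scipy.stats`), returning
  the statistic, Welch–Satterthwaite degrees of freedom and p-value.

## Dipole forward model and error propagation

The forward model is the closed-form field of a current dipole in a
homogeneous, spherically symmetric conductor (Sarvas), sampled by point
magnetometers projected on their orientations. The default array is a
helmet-like golden-spiral cap of 102 radial point magnetometers at 120 mm
around a 90-mm conductor sphere; the phantom source set is 8 tangential
dipoles of 1000 nAm at 50 mm radius. A real 306-channel
gradiometer/magnetometer array is deliberately not modelled: the object of
study is the propagation of co-registration error, which is
array-independent to first order.

Dipole fitting is variable projection: at a candidate location the moment
is solved linearly (the lead field has rank 2 — the radial direction is
silent — handled by least squares, with a small ridge in the vectorized
grid scan); the location minimizing the residual over a 5-mm grid inside
the conductor seeds a Levenberg–Marquardt refinement of the projected
residual (finite-difference Jacobian, tolerances 1e-15). LM was chosen over
a simplex search because noiseless self-generated data must be recovered to
well below 1e-6 mm for the error-propagation identities to hold exactly;
the grid lead fields are cached per array, making repeated fits cheap.
Degenerate inputs: all-zero measurements and arrays with fewer than 6
sensors are rejected; a dipole at the conductor center or with a purely
radial moment produces an exactly zero field (and is therefore unfittable).

Co-registration error propagation mirrors the phantom experiment in which
recorded digitizations replace the true one: the device frame is taken to
coincide with the true head frame (only the relative transform error
matters, so this costs no generality); each session's device-to-head
transform is estimated from its ≥4 HPI markers (the phantom's fiducials
double as HPI coils) by the Kabsch fit; fields are generated under the true
transform; dipoles are fitted in the device frame and mapped to the head
frame with the perturbed transform. A pure rigid offset of the digitization
therefore reappears, exactly, as the localization error of every dipole.

## Problem sizes and numerical choices

Default sessions are one 3-s dwell per fixture point at the profile's
native rate (40 Hz Aurora-like, 60 Hz Fastrak-like: 120 Hz multiplexed
over two receivers), i.e. 4 200 samples for the 35-point head model — the
desk-scale regime the pipeline targets. Monte-Carlo suites in the tests
use 6–25 seeds and 4–8 dipoles, sizes at which every monotonicity and
recovery property is already unambiguous. Rotation-grid cross-checks of
the Kabsch fit use a 5° Euler grid. Stream/session files are fixed-point
text (6 decimals) so round-trips are lossless at 1e-6 mm and runs are
byte-reproducible from their logged seed and config.

## Known limitations

* The noise calibration constants (σ₀ per profile) and the cubic growth
  exponent are qualitative; absolute fluctuation and error magnitudes
  produced by the simulator are not predictions of any physical system.
* The interference model is a static bias field; eddy-current dynamics,
  orientation-dependent coupling and line-frequency pickup are out of
  scope.
* Cluster detection assumes sequential dwells; revisiting a point later in
  the session produces a second cluster, and label assignment is strictly
  by dwell order.
* The spherical conductor and point-magnetometer array idealize the MEG
  side; absolute localization errors are meaningful relative to each
  other, not as hardware predictions.
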