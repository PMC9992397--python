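# emtdig

Simulation and evaluation toolkit for **electromagnetic head digitization**
in MEG/EEG.

Before a MEG or EEG acquisition, an electromagnetic tracking (EMT)
digitizer — a transmitter generating an AC field plus tracked receivers —
records the 3-D positions of the anatomical fiducials (nasion, left/right
preauricular points), HPI coils, EEG electrodes and scalp points. These
points define the head coordinate frame and, through the HPI coils, the
device-to-head transform on which source localization depends. `emtdig` is
for instrumentation and methods researchers who want to study that
measurement chain quantitatively: it simulates realistic stylus/reference
tracking streams over rigid test fixtures, digitizes them the way a
switchless clustering digitizer does, computes the field's standard error
metrics, and propagates digitization error into equivalent-current-dipole
localization error on a spherical phantom.

## What's inside

* **`geometry`** — Neuromag/MEGIN-style head frame from fiducials
  (+x LPA→RPA, origin at the perpendicular foot from nasion, +y toward
  nasion, z = x×y), Kabsch rigid registration with reflection guard, ICP.
* **`emt_sim`** — synthetic tracking streams over four deterministic test
  fixtures (9-point test frame, 5-point spherical phantom, 35-point head
  model, 32-electrode cap) with distance-dependent Gaussian noise
  σ(d) = σ₀·(d/d₀)^γ, interference bias, rigid head motion, and an
  Aurora-style per-sample error index in [0, 1]. System profiles:
  `fastrak_tx2`, `fastrak_tx1` (60 Hz), `aurora` (40 Hz).
* **`digitize`** — movement compensation against the head-bound reference
  receiver, error-index filtering, dwell-cluster detection (100 points
  within 1 mm by default; a 3-s dwell at 40 Hz gives ≈120-sample clusters),
  blunt-tip depth compensation, head-frame session assembly.
* **`metrics`** — mean position tracking fluctuation
  `mPTF = (1/n) Σ_{k=1}^{n−1} |p_{k+1} − p_k|`, per-point digitization error
  `‖p_est − p_act‖` and its mean, Tukey-hinge quartiles with
  outlier (>1.5·Q3) / extreme (>3.0·Q3) fractions, Welch's t-test.
* **`dipole`** — Sarvas spherical-conductor forward model, grid-seeded
  equivalent-current-dipole fitting, and propagation of a perturbed
  digitization into per-dipole localization error via HPI-based
  device-to-head transforms.
* **`io` / `config` / `cli`** — plain-text stream and session formats,
  validated `key = value` experiment configs, and an `emtdig` command.

## Worked example

Digitize the 35-point head model with the Aurora-like profile, fixture
150 mm and 200 mm from the transmitter, still head:

```sh
emtdig experiment --fixture head35 --profile aurora \
    --distance-mm 150 --distance-mm 200 --seed 1 --out demo
```

The log reports one line per distance:

```
distance 150 mm (seed 1): mean error 0.0204 mm over 35 points
distance 200 mm (seed 2): mean error 0.0198 mm over 35 points
```

and `demo/stats.csv` holds the per-point errors and the summary block,
e.g. for 150 mm:

```
150.0 summary  mean              0.020435
150.0 summary  q1                0.015959
150.0 summary  q2                0.020658
150.0 summary  q3                0.026446
150.0 summary  iqr               0.010486
150.0 summary  outlier_fraction  0.028571
150.0 summary  extreme_fraction  0.000000
150.0 summary  n                 35.000000
```

Reading: each of the 35 dwells was recovered as a ≈120-sample cluster, the
cluster centroids land ~0.02 mm from ground truth (averaging the 0.03–0.11 mm
per-sample noise over ~120 samples), the interquartile range is ~0.01 mm,
and one point of 35 (2.9%) exceeds the 1.5·Q3 outlier fence. Head-frame
sessions are written as `kind label x y z` text files (`demo/*.dig`), and
`demo/run.log` records the seed and full configuration, so every run is
reproducible byte-for-byte.

The same pipeline is available as a library:

```python
import emtdig as e

fx = e.make_fixture("head35")
stylus, reference = e.simulate_session_streams(
    fx, e.default_config("aurora", seed=1), fixture_offset=150.0
)
session = e.run_session(stylus, reference, list(zip(fx.labels, fx.kinds)))
print(e.mean_digitization_error(session, e.fixture_head_truth(fx)))
```

To study co-registration impact, perturb a phantom digitization and
propagate it through dipole fitting:

```python
array = e.SensorArray.spherical_cap()          # 102 radial magnetometers
dipoles = e.default_phantom_dipoles()          # 8 tangential, 1000 nAm
errors = e.propagate_coreg_error(true_session, perturbed_session, array, dipoles)
```

A digitization shifted rigidly by 2 mm yields exactly 2 mm of localization
error for every dipole; noisy HPI digitization yields errors growing
monotonically with the noise level.

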