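"""Synthetic electromagnetic-tracking (EMT) streams over rigid test fixtures.

Emulates the data an EMT digitizer produces while a stylus dwells on each
point of a rigid test object: continuous receiver position streams at a
fixed sampling rate, Gaussian tracking noise whose magnitude grows with
transmitter-receiver distance, additive bias from nearby electromagnetic
interference sources, optional rigid motion of the fixture, and a
per-sample quality score ("error index") in [0, 1] for profiles that
provide one.

Everything is deterministic given the configuration seed.  All lengths are
millimeters, times are seconds, rates are Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import RigidTransform

__all__ = [
    "FixturePoint",
    "Fixture",
    "TransmitterModel",
    "NoiseModel",
    "InterferenceSource",
    "TrackingStream",
    "SimConfig",
    "SYSTEM_PROFILES",
    "make_fixture",
    "fixture_head_truth",
    "noise_sigma",
    "interference_bias",
    "sinusoidal_motion",
    "simulate_session_streams",
]

POINT_KINDS = ("cardinal", "hpi", "eeg", "extra")

#: Sphere radius (mm) of the marked-point head model: 52 cm circumference.
HEAD35_RADIUS = 520.0 / (2.0 * np.pi)
#: Sphere radius (mm) of the EEG-cap head model: 61 cm circumference.
EEGCAP_RADIUS = 610.0 / (2.0 * np.pi)
#: Shell radius (mm) used for the 5-point spherical phantom stand-in.
PHANTOM_RADIUS = 87.5
#: Side length (mm) of the square top plate of the 9-point test frame.
TEST_FRAME_SIDE = 160.0


@dataclass(frozen=True)
class FixturePoint:
    label: str
    kind: str
    position: np.ndarray  # true position, fixture frame (mm)
    normal: np.ndarray  # outward unit surface normal

    def __post_init__(self):
        if self.kind not in POINT_KINDS:
            raise ValueError(f"unknown point kind {self.kind!r}")
        p = np.asarray(self.position, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError(f"normal of {self.label!r} is not unit length")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class Fixture:
    """Named ground-truth point set with outward surface normals."""

    name: str
    points: tuple[FixturePoint, ...]

    def __post_init__(self):
        labels = [p.label for p in self.points]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in fixture {self.name!r}")
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    @property
    def kinds(self) -> list[str]:
        return [p.kind for p in self.points]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    @property
    def normals(self) -> np.ndarray:
        return np.array([p.normal for p in self.points])

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


@dataclass(frozen=True)
class TransmitterModel:
    """Field-generator placement and usable measurement volume."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    field_scale: float = 1.0
    falloff_exponent: float = 3.0  # dipolar far-field falloff
    usable_range: float = 660.0  # mm

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.falloff_exponent <= 0:
            raise ValueError("falloff_exponent must be positive")
        if self.usable_range <= 0:
            raise ValueError("usable_range must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Distance-dependent tracking fluctuation: sigma(d) = sigma0*(d/d0)^g."""

    sigma0: float = 0.05  # mm at the reference distance
    d0: float = 150.0  # mm
    growth_exponent: float = 3.0

    def __post_init__(self):
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


@dataclass(frozen=True)
class InterferenceSource:
    """A magnetic object distorting the transmitter field.

    The induced digitization bias scales with the object's coupling strength
    and falls off with its distance to the transmitter (the object re-radiates
    the transmitter's field); the bias points from the object toward the
    receiver.
    """

    position: np.ndarray
    strength: float  # mm * mm^decay_exponent
    decay_exponent: float = 3.0

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )
        if self.strength < 0:
            raise ValueError("strength must be non-negative")


@dataclass
class TrackingStream:
    """Time-ordered receiver position samples at a constant rate.

    ``orientations`` (unit quaternions, scalar-last, shape (n, 4)) are
    carried for 6-DOF receivers such as the head-bound reference receiver;
    ``error_index`` is present for system profiles that report a per-sample
    quality score in [0, 1] (0 = ideal).
    """

    t: np.ndarray
    positions: np.ndarray
    rate: float
    receiver_id: str = "stylus"
    error_index: np.ndarray | None = None
    orientations: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float).reshape(-1)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.t.shape[0] != self.positions.shape[0]:
            raise ValueError("t and positions lengths differ")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.error_index is not None:
            self.error_index = np.asarray(self.error_index, dtype=float).reshape(-1)
            if self.error_index.shape[0] != self.t.shape[0]:
                raise ValueError("error_index length mismatch")
            if self.error_index.size and (
                self.error_index.min() < 0 or self.error_index.max() > 1
            ):
                raise ValueError("error_index values must lie in [0, 1]")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 4)
            if self.orientations.shape[0] != self.t.shape[0]:
                raise ValueError("orientations length mismatch")

    def __len__(self) -> int:
        return self.t.shape[0]

    def subset(self, mask) -> "TrackingStream":
        mask = np.asarray(mask)
        return TrackingStream(
            self.t[mask],
            self.positions[mask],
            rate=self.rate,
            receiver_id=self.receiver_id,
            error_index=None if self.error_index is None else self.error_index[mask],
            orientations=None if self.orientations is None else self.orientations[mask],
        )


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation settings for one system profile."""

    seed: int = 0
    rate: float = 40.0  # Hz
    dwell_time: float = 3.0  # s per fixture point
    system_profile: str = "aurora"
    transit_time: float = 0.0  # s of stylus travel between points
    sigma_max: float = 1.0  # mm; error-index normalization scale

    def __post_init__(self):
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be positive")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.system_profile not in SYSTEM_PROFILES:
            raise ValueError(f"unknown system_profile {self.system_profile!r}")


#: Per-system defaults.  Rates follow the vendor specifications (the Fastrak
#: multiplexes 120 Hz over two receivers; the Aurora samples each receiver at
#: 40 Hz).  sigma0 values are free calibration constants ordered to match the
#: observed ranking of native fluctuation (aurora < tx2 < tx1); they are
#: configuration values, not measurements.
SYSTEM_PROFILES: dict[str, dict] = {
    "fastrak_tx2": {
        "rate": 60.0,
        "noise": NoiseModel(sigma0=0.05, d0=150.0, growth_exponent=3.0),
        "transmitter": TransmitterModel(usable_range=1500.0),
        "has_error_index": False,
    },
    "fastrak_tx1": {
        "rate": 60.0,
        "noise": NoiseModel(sigma0=0.08, d0=150.0, growth_exponent=3.0),
        "transmitter": TransmitterModel(usable_range=500.0),
        "has_error_index": False,
    },
    "aurora": {
        "rate": 40.0,
        "noise": NoiseModel(sigma0=0.03, d0=150.0, growth_exponent=3.0),
        "transmitter": TransmitterModel(usable_range=660.0),
        "has_error_index": True,
    },
}


def default_config(profile: str, seed: int = 0, **overrides) -> SimConfig:
    """SimConfig with the profile's native sampling rate."""
    spec = SYSTEM_PROFILES[profile]
    kw = dict(seed=seed, rate=spec["rate"], system_profile=profile)
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# fixtures

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def _spiral_cap(n: int, radius: float, z_lo: float = 0.05, z_hi: float = 0.95):
    """n points on the upper cap of a sphere via the golden-spiral rule.

    z/radius is spaced uniformly in [z_lo, z_hi]; azimuth advances by the
    golden angle.  Deterministic and roughly equidistributed.
    """
    i = np.arange(n)
    z = z_lo + (z_hi - z_lo) * (i + 0.5) / n
    theta = _GOLDEN_ANGLE * i
    rho = np.sqrt(1.0 - z**2)
    pts = radius * np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts


def _sphere_fixture(name: str, radius: float, n_free: int, free_kind: str,
                    free_prefix: str) -> Fixture:
    pts: list[FixturePoint] = []
    # cardinals on the equator; fixture frame coincides with the head frame
    for label, pos in (
        ("nasion", (0.0, radius, 0.0)),
        ("lpa", (-radius, 0.0, 0.0)),
        ("rpa", (radius, 0.0, 0.0)),
    ):
        p = np.array(pos)
        pts.append(FixturePoint(label, "cardinal", p, p / np.linalg.norm(p)))
    for j, p in enumerate(_spiral_cap(n_free, radius), start=1):
        pts.append(
            FixturePoint(f"{free_prefix}{j:03d}", free_kind, p, p / np.linalg.norm(p))
        )
    return Fixture(name, tuple(pts))


def make_fixture(name: str) -> Fixture:
    """Deterministic ground-truth geometry for the four test objects.

    * ``test_frame_9`` — square 16-cm top plate with four mid-side points
      (used as nasion/LPA/RPA plus a back point) and five top-face points;
      the physical points are excavated 2 mm deep, so normals matter for
      blunt-stylus depth compensation.
    * ``phantom_5`` — spherical phantom offering five digitizable marker
      locations (three fiducials that double as HPI coils, two extra HPI).
    * ``head35`` — head model of 52 cm circumference with 3 fiducials and
      32 marked scalp points.
    * ``eegcap32`` — head model of 61 cm circumference wearing a 32-channel
      EEG cap, plus 3 fiducials.
    """
    if name == "test_frame_9":
        h = TEST_FRAME_SIDE / 2.0
        pts = [
            FixturePoint("nasion", "cardinal", np.array([0.0, h, 0.0]),
                         np.array([0.0, 1.0, 0.0])),
            FixturePoint("lpa", "cardinal", np.array([-h, 0.0, 0.0]),
                         np.array([-1.0, 0.0, 0.0])),
            FixturePoint("rpa", "cardinal", np.array([h, 0.0, 0.0]),
                         np.array([1.0, 0.0, 0.0])),
            FixturePoint("back", "extra", np.array([0.0, -h, 0.0]),
                         np.array([0.0, -1.0, 0.0])),
            FixturePoint("top_c", "extra", np.array([0.0, 0.0, 0.0]),
                         np.array([0.0, 0.0, 1.0])),
        ]
        for label, (x, y) in (
            ("top_fl", (-h / 2, h / 2)),
            ("top_fr", (h / 2, h / 2)),
            ("top_bl", (-h / 2, -h / 2)),
            ("top_br", (h / 2, -h / 2)),
        ):
            pts.append(
                FixturePoint(label, "extra", np.array([x, y, 0.0]),
                             np.array([0.0, 0.0, 1.0]))
            )
        return Fixture(name, tuple(pts))
    if name == "phantom_5":
        r = PHANTOM_RADIUS
        pts = []
        for label, pos in (
            ("nasion", (0.0, r, 0.0)),
            ("lpa", (-r, 0.0, 0.0)),
            ("rpa", (r, 0.0, 0.0)),
        ):
            p = np.array(pos)
            pts.append(FixturePoint(label, "cardinal", p, p / r))
        c = r / np.sqrt(2.0)
        for label, pos in (("hpi4", (0.0, c, c)), ("hpi5", (0.0, -c, c))):
            p = np.array(pos)
            pts.append(FixturePoint(label, "hpi", p, p / r))
        return Fixture(name, tuple(pts))
    if name == "head35":
        return _sphere_fixture(name, HEAD35_RADIUS, 32, "extra", "scalp")
    if name == "eegcap32":
        return _sphere_fixture(name, EEGCAP_RADIUS, 32, "eeg", "EEG")
    raise ValueError(
        f"unknown fixture {name!r}; expected one of "
        "test_frame_9, phantom_5, head35, eegcap32"
    )


def fixture_head_truth(fixture: Fixture) -> dict[str, np.ndarray]:
    """Ground-truth point positions re-expressed in the fixture's own head
    frame (the frame built from its three cardinal points)."""
    from .geometry import FiducialSet, head_frame_from_fiducials

    by_label = {p.label: p.position for p in fixture.points}
    T = head_frame_from_fiducials(
        FiducialSet(by_label["nasion"], by_label["lpa"], by_label["rpa"])
    )
    return {p.label: T.apply(p.position) for p in fixture.points}


# ---------------------------------------------------------------------------
# noise and interference

def noise_sigma(d: float, model: NoiseModel) -> float:
    """Per-axis tracking-noise standard deviation at distance ``d`` (mm)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be positive")
    out = model.sigma0 * (d / model.d0) ** model.growth_exponent
    return float(out) if out.ndim == 0 else out


def interference_bias(
    src: InterferenceSource, receiver_pos, transmitter_pos
) -> np.ndarray:
    """Quasi-static bias displacement (mm) induced by a magnetic object.

    Magnitude ``strength / |src - transmitter|^decay`` (the object couples to
    the transmitter field and re-radiates), directed from the object toward
    the receiver.
    """
    rec = np.asarray(receiver_pos, dtype=float).reshape(3)
    tx = np.asarray(transmitter_pos, dtype=float).reshape(3)
    d_tx = float(np.linalg.norm(src.position - tx))
    d_rec = float(np.linalg.norm(rec - src.position))
    if d_tx < 1e-9 or d_rec < 1e-9:
        raise ValueError("interference source coincides with transmitter or receiver")
    if src.strength == 0.0:
        return np.zeros(3)
    direction = (rec - src.position) / d_rec
    return (src.strength / d_tx**src.decay_exponent) * direction


# ---------------------------------------------------------------------------
# motion and session simulation

def sinusoidal_motion(
    angle_deg: float = 5.0,
    shift_mm: float = 10.0,
    freq_hz: float = 0.2,
    axis=(0.0, 0.0, 1.0),
) -> Callable[[float], RigidTransform]:
    """Default "moving head" trajectory: +/-angle rotation and +/-shift
    translation, both sinusoidal at ``freq_hz``."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)

    def trajectory(t: float) -> RigidTransform:
        phase = np.sin(2.0 * np.pi * freq_hz * t)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * phase * ax).as_matrix()
        trans = np.array([shift_mm * phase, 0.0, 0.0])
        return RigidTransform(R, trans)

    return trajectory


#: Reference receiver sits 100 mm behind the fixture centroid, rigid with it.
REFERENCE_OFFSET = np.array([0.0, -100.0, 0.0])


def simulate_session_streams(
    fixture: Fixture,
    cfg: SimConfig,
    transmitter: TransmitterModel | None = None,
    noise: NoiseModel | None = None,
    interference: Sequence[InterferenceSource] = (),
    motion: Callable[[float], RigidTransform] | None = None,
    fixture_offset: float = 150.0,
) -> tuple[TrackingStream, TrackingStream]:
    """Simulate one full digitization session over ``fixture``.

    The transmitter sits at its model position (origin by default); the
    fixture is placed with its centroid ``fixture_offset`` mm along +y from
    the transmitter.  The stylus dwells ``cfg.dwell_time`` s on each fixture
    point in order (optionally travelling for ``cfg.transit_time`` s between
    points); a 6-DOF reference receiver rides rigidly with the fixture.  Both
    receivers are sampled on a common clock at ``cfg.rate`` Hz with per-axis
    Gaussian noise of amplitude ``noise_sigma`` at the receiver's distance
    from the transmitter plus any interference bias.  Aurora-profile streams
    carry an emulated error index
    ``clip(sigma(d)/sigma_max + |bias|/1mm, 0, 1)``.

    Returns ``(stylus_stream, reference_stream)`` in the global (transmitter)
    frame; bit-identical for identical inputs and seed.
    """
    if len(fixture.points) == 0:
        raise ValueError("fixture has no points")
    profile = SYSTEM_PROFILES[cfg.system_profile]
    transmitter = transmitter if transmitter is not None else profile["transmitter"]
    noise = noise if noise is not None else profile["noise"]
    has_ei = profile["has_error_index"]
    rng = np.random.default_rng(cfg.seed)

    place = RigidTransform(
        np.eye(3),
        transmitter.position
        + np.array([0.0, fixture_offset, 0.0])
        - fixture.centroid(),
    )
    local_pts = fixture.positions  # fixture frame
    ref_local = fixture.centroid() + REFERENCE_OFFSET

    n_dwell = int(round(cfg.dwell_time * cfg.rate))
    n_transit = int(round(cfg.transit_time * cfg.rate))
    dt = 1.0 / cfg.rate

    # build the stylus-tip trajectory in the fixture frame
    tip_local: list[np.ndarray] = []
    for i, p in enumerate(local_pts):
        if i > 0 and n_transit > 0:
            prev = local_pts[i - 1]
            # straight-line travel, lifted 20 mm off the surface mid-way
            frac = (np.arange(n_transit) + 1.0) / (n_transit + 1.0)
            lift = 20.0 * np.sin(np.pi * frac)[:, None] * fixture.normals[i][None, :]
            tip_local.extend(prev + frac[:, None] * (p - prev) + lift)
        tip_local.extend([p] * n_dwell)
    tip_local = np.asarray(tip_local)
    n = tip_local.shape[0]
    t = np.arange(n) * dt

    if motion is None:
        stylus_true = place.apply(tip_local)
        ref_true = np.tile(place.apply(ref_local), (n, 1))
        ref_quat = np.tile(
            Rotation.from_matrix(place.rotation).as_quat(), (n, 1)
        )
    else:
        stylus_true = np.empty((n, 3))
        ref_true = np.empty((n, 3))
        ref_quat = np.empty((n, 4))
        for k in range(n):
            world = place.compose(motion(t[k]))
            stylus_true[k] = world.apply(tip_local[k])
            ref_true[k] = world.apply(ref_local)
            ref_quat[k] = Rotation.from_matrix(world.rotation).as_quat()

    def corrupt(true_pos: np.ndarray):
        d = np.linalg.norm(true_pos - transmitter.position, axis=1)
        sig = noise.sigma0 * (d / noise.d0) ** noise.growth_exponent
        out = true_pos + rng.standard_normal(true_pos.shape) * sig[:, None]
        bias_mag = np.zeros(len(true_pos))
        for srcobj in interference:
            biases = np.array(
                [interference_bias(srcobj, p, transmitter.position) for p in true_pos]
            )
            out = out + biases
            bias_mag += np.linalg.norm(biases, axis=1)
        ei = None
        if has_ei:
            ei = np.clip(sig / cfg.sigma_max + bias_mag / 1.0, 0.0, 1.0)
        return out, ei

    stylus_pos, stylus_ei = corrupt(stylus_true)
    ref_pos, ref_ei = corrupt(ref_true)

    stylus = TrackingStream(
        t, stylus_pos, rate=cfg.rate, receiver_id="stylus", error_index=stylus_ei
    )
    reference = TrackingStream(
        t,
        ref_pos,
        rate=cfg.rate,
        receiver_id="reference",
        error_index=ref_ei,
        orientations=ref_quat,
    )
    return stylus, reference
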