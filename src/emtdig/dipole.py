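"""Spherical-conductor MEG forward model and equivalent-current-dipole fits.

The forward model is the closed-form magnetic field of a current dipole in
a homogeneous spherically symmetric conductor (the Sarvas formula), sampled
by point magnetometers.  Dipole fitting solves the moment linearly at each
candidate location and searches the location nonlinearly, starting from the
best point of a coarse grid inside the conductor.

This is the machinery needed to propagate a digitization/co-registration
error into a source-localization error on a phantom: generate fields under
the true device-to-head transform, fit dipoles, and map the fits back with
the (mis-)estimated transform.

Positions are millimeters; dipole moments are nAm; fields are tesla.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .digitize import DigitizationSession
from .geometry import fit_rigid

__all__ = [
    "SensorArray",
    "CurrentDipole",
    "FitResult",
    "sarvas_field",
    "forward",
    "fit_dipole",
    "propagate_coreg_error",
    "default_phantom_dipoles",
]

_MU0_4PI = 1e-7  # T*m/A
_MM = 1e-3
_NAM = 1e-9

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class SensorArray:
    """Point magnetometers around a spherical conductor (device frame)."""

    positions: np.ndarray  # (m, 3) mm
    orientations: np.ndarray  # (m, 3) unit vectors
    sphere_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    conductor_radius: float = 90.0  # mm

    def __post_init__(self):
        p = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        o = np.asarray(self.orientations, dtype=float).reshape(-1, 3)
        c = np.asarray(self.sphere_center, dtype=float).reshape(3)
        if p.shape != o.shape:
            raise ValueError("positions and orientations shapes differ")
        norms = np.linalg.norm(o, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("sensor orientations must be unit vectors")
        if np.any(np.linalg.norm(p - c, axis=1) <= self.conductor_radius):
            raise ValueError("all sensors must lie outside the conductor sphere")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "orientations", o)
        object.__setattr__(self, "sphere_center", c)

    def __len__(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def spherical_cap(
        cls,
        n_sensors: int = 102,
        array_radius: float = 120.0,
        conductor_radius: float = 90.0,
        sphere_center=(0.0, 0.0, 0.0),
    ) -> "SensorArray":
        """Helmet-like cap of radial point magnetometers (golden spiral)."""
        i = np.arange(n_sensors)
        z = 0.15 + (0.975 - 0.15) * (i + 0.5) / n_sensors
        theta = _GOLDEN_ANGLE * i
        rho = np.sqrt(1.0 - z**2)
        o = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
        c = np.asarray(sphere_center, dtype=float)
        return cls(c + array_radius * o, o, c, conductor_radius)


@dataclass(frozen=True)
class CurrentDipole:
    """Point current dipole: location (mm) and moment (nAm)."""

    location: np.ndarray
    moment: np.ndarray
    frame: str = "device"

    def __post_init__(self):
        object.__setattr__(
            self, "location", np.asarray(self.location, dtype=float).reshape(3)
        )
        object.__setattr__(
            self, "moment", np.asarray(self.moment, dtype=float).reshape(3)
        )


@dataclass(frozen=True)
class FitResult:
    dipole: CurrentDipole
    residual_norm: float  # residual as a fraction of the data norm
    converged: bool
    localization_error: float | None = None  # mm vs supplied truth


def _sarvas_leadfield(dip_pos: np.ndarray, array: SensorArray) -> np.ndarray:
    """Lead field L with B(sensor j) = L[..., j, :] @ Q  (Q in nAm, B in T).

    Vectorized over an arbitrary leading shape of dipole positions (mm).
    """
    c = array.sphere_center
    r = (array.positions - c) * _MM  # (m, 3) meters, conductor-centered
    o = array.orientations  # (m, 3)
    r0 = (np.atleast_2d(dip_pos) - c) * _MM  # (N, 3)
    lead_shape = r0.shape[:-1]

    a_vec = r[None, :, :] - r0[:, None, :]  # (N, m, 3)
    a = np.linalg.norm(a_vec, axis=-1)  # (N, m)
    rn = np.linalg.norm(r, axis=-1)[None, :]  # (1, m)
    ar = np.einsum("nmk,mk->nm", a_vec, r)  # a_vec . r
    r0r = np.einsum("nk,mk->nm", r0, r)  # r0 . r

    F = a * (rn * a + rn**2 - r0r)  # (N, m)
    # grad F = (a^2/r + ar/a + 2a + 2r) r - (a + 2r + ar/a) r0
    ar_a = ar / a
    gF = (
        (a**2 / rn + ar_a + 2.0 * a + 2.0 * rn)[..., None] * r[None, :, :]
        - (a + 2.0 * rn + ar_a)[..., None] * r0[:, None, :]
    )  # (N, m, 3)
    gF_o = np.einsum("nmk,mk->nm", gF, o)

    r0_x_o = np.cross(np.broadcast_to(r0[:, None, :], gF.shape), o[None, :, :])
    r0_x_r = np.cross(np.broadcast_to(r0[:, None, :], gF.shape), r[None, :, :])
    L = (_MU0_4PI * _NAM / F[..., None] ** 2) * (
        F[..., None] * r0_x_o - gF_o[..., None] * r0_x_r
    )
    return L.reshape(lead_shape + (len(array), 3))


def sarvas_field(
    dipole: CurrentDipole, sensor_pos, sensor_orientation, sphere_center=(0, 0, 0)
) -> float:
    """Field (T) of one dipole at one point magnetometer.

    Exactly zero for a dipole at the conductor center and for a purely
    radial dipole moment (the spherical conductor is silent to both).
    """
    sensor_pos = np.asarray(sensor_pos, dtype=float).reshape(3)
    if np.allclose(sensor_pos, dipole.location):
        raise ValueError("sensor coincides with the dipole location")
    o = np.asarray(sensor_orientation, dtype=float).reshape(3)
    arr = SensorArray(
        sensor_pos[None, :],
        (o / np.linalg.norm(o))[None, :],
        np.asarray(sphere_center, dtype=float),
        conductor_radius=min(
            float(np.linalg.norm(sensor_pos - np.asarray(sphere_center, float))) * 0.999,
            90.0,
        ),
    )
    L = _sarvas_leadfield(dipole.location[None, :], arr)[0, 0]
    return float(L @ dipole.moment)


def forward(dipoles, array: SensorArray) -> np.ndarray:
    """Superposed field (T) of one or more dipoles at every sensor."""
    if isinstance(dipoles, CurrentDipole):
        dipoles = [dipoles]
    b = np.zeros(len(array))
    for d in dipoles:
        if (
            np.linalg.norm(d.location - array.sphere_center)
            >= array.conductor_radius
        ):
            raise ValueError(
                f"dipole at {d.location} lies outside the conductor sphere"
            )
        L = _sarvas_leadfield(d.location[None, :], array)[0]
        b += L @ d.moment
    return b


def _grid_cache(array: SensorArray, spacing: float):
    key = f"_grid_{spacing:g}"
    cached = getattr(array, key, None)
    if cached is not None:
        return cached
    R = array.conductor_radius - 5.0
    ax = np.arange(-R, R + spacing / 2, spacing)
    G = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    G = G[np.linalg.norm(G, axis=1) <= R] + array.sphere_center
    L = _sarvas_leadfield(G, array)  # (N, m, 3)
    object.__setattr__(array, key, (G, L))
    return G, L


def _solve_moment(L: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Least-squares moment for a (m, 3) lead field (rank-2: radial silent)."""
    return np.linalg.lstsq(L, b, rcond=None)[0]


def fit_dipole(
    measurements,
    array: SensorArray,
    truth: CurrentDipole | None = None,
    grid_spacing: float = 5.0,
) -> FitResult:
    """Single equivalent-current-dipole fit.

    The moment is solved linearly at each candidate location; the location
    minimizing the residual over a ``grid_spacing`` grid inside the conductor
    seeds a Levenberg-Marquardt refinement of the projected residual.
    """
    b = np.asarray(measurements, dtype=float).reshape(-1)
    if b.shape[0] != len(array):
        raise ValueError("measurement count does not match sensor count")
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0 or len(array) < 6:
        raise ValueError("need >= 6 sensors with nonzero signal to fit a dipole")

    G, L = _grid_cache(array, grid_spacing)
    # batched ridge-regularized normal equations; ridge breaks the radial
    # null direction of the rank-2 lead field
    Gram = np.einsum("nmi,nmj->nij", L, L)
    tr = np.trace(Gram, axis1=1, axis2=2)
    ridge = 1e-9 * tr + 1e-12 * max(float(tr.max()), 1e-300)
    Gram = Gram + ridge[:, None, None] * np.eye(3)
    rhs = np.einsum("nmi,m->ni", L, b)
    Q = np.linalg.solve(Gram, rhs[..., None])[..., 0]
    resid2 = np.sum((np.einsum("nmi,ni->nm", L, Q) - b) ** 2, axis=1)
    x0 = G[int(np.argmin(resid2))]

    def residual(loc):
        with np.errstate(all="ignore"):
            Lx = _sarvas_leadfield(loc[None, :], array)[0]
            q = _solve_moment(Lx, b)
            r = Lx @ q - b
        return np.where(np.isfinite(r), r, 1e3 * bnorm)

    sol = least_squares(
        residual, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        max_nfev=2000,
    )
    loc = sol.x
    Lx = _sarvas_leadfield(loc[None, :], array)[0]
    q = _solve_moment(Lx, b)
    res_frac = float(np.linalg.norm(Lx @ q - b) / bnorm)
    err = None
    if truth is not None:
        err = float(np.linalg.norm(loc - truth.location))
    return FitResult(
        CurrentDipole(loc, q, frame="device"),
        residual_norm=res_frac,
        converged=bool(sol.success),
        localization_error=err,
    )


def default_phantom_dipoles(
    n: int = 8, radius: float = 50.0, amplitude: float = 1000.0
) -> list[CurrentDipole]:
    """Tangential dipoles at ``radius`` mm, ``amplitude`` nAm, evenly spread
    in azimuth at 35 degrees elevation (phantom-style layout)."""
    out = []
    elev = np.deg2rad(35.0)
    for k in range(n):
        az = 2.0 * np.pi * k / n
        loc = radius * np.array(
            [np.cos(elev) * np.cos(az), np.cos(elev) * np.sin(az), np.sin(elev)]
        )
        tang = np.array([-np.sin(az), np.cos(az), 0.0])  # azimuthal => tangential
        out.append(CurrentDipole(loc, amplitude * tang, frame="head"))
    return out


def _hpi_positions(session: DigitizationSession) -> dict[str, np.ndarray]:
    return {
        p.label: p.position
        for p in session.points
        if p.kind in ("hpi", "cardinal")
    }


def propagate_coreg_error(
    true_session: DigitizationSession,
    perturbed_session: DigitizationSession,
    array: SensorArray,
    dipoles: list[CurrentDipole],
    grid_spacing: float = 5.0,
) -> list[float]:
    """Localization error (mm) per dipole caused by replacing the digitization.

    The phantom's true head frame is taken to coincide with the device frame
    (this costs no generality: only the relative transform error matters).
    The device-to-head transform of each session is estimated from its
    HPI-marker positions (cardinal markers double as HPI coils); fields are
    generated under the true transform, dipoles are fitted in the device
    frame, and the fits are mapped to the head frame with the perturbed
    transform.  The per-dipole error is the distance to the true head-frame
    location.
    """
    hpi_true = _hpi_positions(true_session)
    hpi_pert = _hpi_positions(perturbed_session)
    common = [lab for lab in hpi_true if lab in hpi_pert]
    if len(common) < 4:
        raise ValueError(
            f"need >= 4 common HPI markers, found {len(common)}: {sorted(common)}"
        )
    # device-frame HPI positions: device frame == true head frame
    dev = np.array([hpi_true[lab] for lab in common])
    pert = np.array([hpi_pert[lab] for lab in common])
    T_pert, _ = fit_rigid(dev, pert)  # estimated device -> head

    errors = []
    for d in dipoles:
        b = forward(CurrentDipole(d.location, d.moment, frame="device"), array)
        fit = fit_dipole(b, array, grid_spacing=grid_spacing)
        fitted_head = T_pert.apply(fit.dipole.location)
        errors.append(float(np.linalg.norm(fitted_head - d.location)))
    return errors
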