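"""Synthetic rotation data: dipole physics, trajectories, recordings, cohorts.

The monitored object is a nacre nucleus carrying a small cylindrical
neodymium magnet, implanted in a pearl oyster inside the sensor dome.  Three
qualitatively different rotation regimes are emulated, matching the patterns
associated with the three final pearl-shape classes:

``Round``
    random tumbling -- a great-circle walk whose heading diffuses quickly,
    so the moment direction wanders over the whole sphere;
``Atypical``
    near-axial rotation -- steady rotation about a slowly drifting axis,
    tracing a (noisy) circle;
``Other``
    no rotation -- the moment direction only wobbles slowly around a fixed
    direction (no mineral deposition, no net rotation).

The cohort-level rotation speed is drawn from the measured distribution
0.69 +/- 0.13 deg/min for rotating pearls; speed carries *no* class signal
(the study conditions found no significant speed difference between shape
classes), only the rotation *pattern* separates classes.

Field values are in arbitrary units (the unit dipole prefactor); sensor
noise is specified relative to the RMS of the noiseless signal.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import DOME_RADIUS_M, DomeGeometry, build_dome, position_weights

__all__ = [
    "CLASSES",
    "CLASS_PROBS",
    "SPEED_MEAN_DEG_MIN",
    "SPEED_SD_DEG_MIN",
    "OrientationTrajectory",
    "SensorRecording",
    "PearlRecord",
    "default_magnet_position",
    "dipole_field",
    "simulate_trajectory",
    "simulate_clock_scene",
    "simulate_recording",
    "simulate_cohort",
    "inject_rejection_event",
]

#: Fixed class order used throughout (labels, probability vectors, metrics).
CLASSES: tuple[str, str, str] = ("Round", "Atypical", "Other")

#: Observed cohort class mix: (semi-)round 27.6%, baroque/drop/button/circled
#: 21.3%, no or very irregular deposit 51.1%.
CLASS_PROBS: tuple[float, float, float] = (0.276, 0.213, 0.511)

#: Mean and SD of the rotation speed of rotating pearls, deg/min.
SPEED_MEAN_DEG_MIN: float = 0.69
SPEED_SD_DEG_MIN: float = 0.13

#: Default heading-diffusion / wobble scales per class.  Round pearls tumble
#: with a fast-diffusing rotation axis, Atypical pearls keep a nearly fixed
#: axis, Other pearls only wobble slowly around a fixed direction.
ROUND_JITTER_DEG_SQRT_H: float = 30.0
ATYPICAL_JITTER_DEG_SQRT_H: float = 2.0
OTHER_WOBBLE_SD_DEG: float = 0.5
#: Slowest/fastest wobble period for non-rotating pearls (hours).
OTHER_WOBBLE_PERIODS_H: tuple[float, float] = (2.0, 12.0)


@dataclass
class OrientationTrajectory:
    """Timestamped unit-vector series of the magnet moment direction.

    Attributes
    ----------
    t : ndarray, shape (n,)
        Seconds since the start of the acquisition, strictly increasing.
    u : ndarray, shape (n, 3)
        Unit moment-direction vectors.
    magnet_position : ndarray, shape (3,)
        Magnet location in dome-centred coordinates (m).
    valid : ndarray of bool, shape (n,) or None
        Optional reliability mask (set by the reconstruction stage).
    """

    t: np.ndarray
    u: np.ndarray
    magnet_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.magnet_position = np.asarray(self.magnet_position, dtype=float)
        if self.t.ndim != 1 or self.u.shape != (self.t.size, 3):
            raise ValueError("t must be (n,) and u (n, 3)")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        """Sampling interval in seconds (assumes uniform sampling)."""
        if self.t.size < 2:
            raise ValueError("need at least two timestamps")
        return float(self.t[1] - self.t[0])

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.t.size, dtype=bool)
        return self.valid

    def to_csv(self) -> str:
        df = pd.DataFrame({"t": self.t, "x": self.u[:, 0], "y": self.u[:, 1], "z": self.u[:, 2]})
        return df.to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str, magnet_position: np.ndarray | None = None) -> "OrientationTrajectory":
        df = pd.read_csv(io.StringIO(text))
        pos = np.zeros(3) if magnet_position is None else magnet_position
        return cls(t=df["t"].to_numpy(), u=df[["x", "y", "z"]].to_numpy(), magnet_position=pos)


@dataclass
class SensorRecording:
    """Timestamped multi-channel scalar magnetometer series.

    ``values[i, j]`` is the field projection read by sensor ``j`` at time
    ``t[i]``, in arbitrary field units.
    """

    t: np.ndarray
    values: np.ndarray
    geometry: DomeGeometry

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.t.size, self.geometry.n_sensors):
            raise ValueError("values must be (n_times, n_sensors)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensor values must be finite")

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self) -> str:
        cols = {f"s{j + 1:02d}": self.values[:, j] for j in range(self.values.shape[1])}
        return pd.DataFrame({"t": self.t, **cols}).to_csv(index=False)

    @classmethod
    def from_csv(cls, text: str, geometry: DomeGeometry) -> "SensorRecording":
        df = pd.read_csv(io.StringIO(text))
        chan = [c for c in df.columns if c.startswith("s")]
        return cls(t=df["t"].to_numpy(), values=df[chan].to_numpy(), geometry=geometry)


@dataclass
class PearlRecord:
    """One simulated pearl: identity, label, trajectory and metadata.

    ``culture_days`` is the full graft-to-harvest cultivation time;
    ``acq_offset_days`` is the number of days between grafting and the start
    of the rotation acquisition (acquisitions cover the end of cultivation).
    """

    pearl_id: str
    true_class: str
    trajectory: OrientationTrajectory
    culture_days: int
    acq_offset_days: int
    harvest_date_group: str
    speed_deg_min: float

    def __post_init__(self) -> None:
        if self.true_class not in CLASSES:
            raise ValueError(f"unknown class {self.true_class!r}")
        if not (self.culture_days >= self.acq_offset_days >= 0):
            raise ValueError("need culture_days >= acq_offset_days >= 0")

    def metadata(self) -> dict:
        return {
            "pearl_id": self.pearl_id,
            "true_class": self.true_class,
            "culture_days": self.culture_days,
            "acq_offset_days": self.acq_offset_days,
            "harvest_date_group": self.harvest_date_group,
            "speed_deg_min": self.speed_deg_min,
        }


def cohort_manifest(cohort: Sequence[PearlRecord]) -> str:
    """JSON manifest of per-pearl metadata (no trajectory payload)."""
    return json.dumps([r.metadata() for r in cohort], indent=2)


def default_magnet_position(geom: DomeGeometry | None = None, ring_position: int = 2) -> np.ndarray:
    """Magnet location on the dome axis at the height of a sensor ring.

    The oyster rests on a base placing the nucleus at the height of the
    second sensor ring (the ring with the best calibration accuracy), on the
    vertical axis of the dome.
    """
    geom = geom or build_dome()
    if not 1 <= ring_position <= len(geom.rings):
        raise ValueError("ring_position out of range")
    elev = np.radians(geom.rings[ring_position - 1])
    return np.array([0.0, 0.0, geom.radius * np.sin(elev)])


def dipole_field(moment: np.ndarray, at: np.ndarray) -> np.ndarray:
    """Magnetic dipole field with unit prefactor, ``B ~ (3(m.r^)r^ - m)/|r|^3``.

    Parameters
    ----------
    moment : (3,) array
        Dipole moment vector (not necessarily unit; B is linear in it).
    at : (..., 3) array
        Displacement(s) from the dipole to the field point(s), metres.

    Returns
    -------
    (..., 3) array of field vectors in arbitrary units.
    """
    m = np.asarray(moment, dtype=float)
    r = np.asarray(at, dtype=float)
    rn = np.linalg.norm(r, axis=-1, keepdims=True)
    if np.any(rn == 0):
        raise ValueError("field point coincides with the dipole")
    r_hat = r / rn
    mdotr = np.sum(m * r_hat, axis=-1, keepdims=True)
    return (3.0 * mdotr * r_hat - m) / rn**3


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


def _tangent_walk(
    n_steps: int,
    dt: float,
    speed_deg_min: float,
    heading_jitter_deg_sqrt_h: float,
    u0: np.ndarray,
    w0: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Great-circle walk with diffusing heading.

    Each step advances the unit vector by exactly ``speed * dt`` of arc along
    the current heading ``w`` (a tangent unit vector), then the heading is
    rotated in the tangent plane by a Gaussian angle of standard deviation
    ``jitter * sqrt(dt)``.  With zero jitter this is uniform rotation about
    the fixed axis ``u x w``; large jitter gives random tumbling.
    """
    alpha = math.radians(speed_deg_min) * dt / 60.0
    eta_sd = math.radians(heading_jitter_deg_sqrt_h) * math.sqrt(dt / 3600.0)
    ca, sa = math.cos(alpha), math.sin(alpha)
    u = np.empty((n_steps, 3))
    ux, uy, uz = u0
    wx, wy, wz = w0
    u[0] = u0
    if eta_sd > 0:
        etas = rng.normal(0.0, eta_sd, size=n_steps)
    else:
        etas = np.zeros(n_steps)
    for i in range(1, n_steps):
        # great-circle step and parallel transport of the heading
        nux = ca * ux + sa * wx
        nuy = ca * uy + sa * wy
        nuz = ca * uz + sa * wz
        twx = -sa * ux + ca * wx
        twy = -sa * uy + ca * wy
        twz = -sa * uz + ca * wz
        # rotate heading about the new position by eta (stays tangent)
        e = etas[i]
        if e != 0.0:
            ce, se = math.cos(e), math.sin(e)
            cx = nuy * twz - nuz * twy
            cy = nuz * twx - nux * twz
            cz = nux * twy - nuy * twx
            wx = ce * twx + se * cx
            wy = ce * twy + se * cy
            wz = ce * twz + se * cz
        else:
            wx, wy, wz = twx, twy, twz
        # renormalise occasionally to kill drift
        if i % 1024 == 0:
            nn = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
            nux, nuy, nuz = nux / nn, nuy / nn, nuz / nn
            dp = wx * nux + wy * nuy + wz * nuz
            wx, wy, wz = wx - dp * nux, wy - dp * nuy, wz - dp * nuz
            wn = math.sqrt(wx * wx + wy * wy + wz * wz)
            wx, wy, wz = wx / wn, wy / wn, wz / wn
        ux, uy, uz = nux, nuy, nuz
        u[i] = (ux, uy, uz)
    return u


def _wobble_series(
    n_steps: int,
    dt: float,
    wobble_sd_deg: float,
    u0: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Slow band-limited wobble around a fixed direction.

    Each tangent-plane component is a sum of three sinusoids with random
    periods (log-uniform over hours-long timescales) and phases, scaled so
    the total angular standard deviation equals ``wobble_sd_deg``.  Sinusoids
    keep the apparent angular speed small at any sampling rate, unlike white
    or diffusive noise.
    """
    e1 = _any_perpendicular(u0)
    e2 = np.cross(u0, e1)
    t = np.arange(n_steps) * dt
    sd_rad = math.radians(wobble_sd_deg)
    amp = sd_rad / math.sqrt(3.0)  # 3 sinusoids/component, var = 3 A^2/2 per comp
    lo, hi = OTHER_WOBBLE_PERIODS_H
    offsets = []
    for _ in range(2):
        comp = np.zeros(n_steps)
        for _ in range(3):
            period_s = 3600.0 * math.exp(rng.uniform(math.log(lo), math.log(hi)))
            phase = rng.uniform(0.0, 2.0 * math.pi)
            comp += amp * np.sin(2.0 * math.pi * t / period_s + phase)
        offsets.append(comp)
    a, b = offsets
    u = u0[None, :] + a[:, None] * e1[None, :] + b[:, None] * e2[None, :]
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def simulate_trajectory(
    shape_class: str,
    duration_s: float,
    rate_hz: float = 1.0,
    speed_deg_min: float = SPEED_MEAN_DEG_MIN,
    axis: np.ndarray | None = None,
    jitter: float | None = None,
    seed: int | np.random.Generator | None = None,
    u0: np.ndarray | None = None,
    magnet_position: np.ndarray | None = None,
) -> OrientationTrajectory:
    """Simulate a class-conditional moment-direction trajectory.

    Parameters
    ----------
    shape_class : {"Round", "Atypical", "Other"}
        Rotation regime (see module docstring).
    duration_s, rate_hz : float
        Length of the acquisition and sampling rate (1 Hz by default).
    speed_deg_min : float
        Mean angular speed; the per-step angular increments of Round and
        Atypical trajectories average exactly to this value.  Ignored for
        Other (no rotation).
    axis : (3,) array, optional
        Rotation axis for Atypical trajectories (random if omitted); the
        initial direction is perpendicular to it.
    jitter : float, optional
        Heading diffusion in deg/sqrt(hour) for Round/Atypical, or wobble SD
        in degrees for Other.  Class-specific defaults if omitted.
    seed : int or Generator, optional
        Randomness source; fixed seed gives bit-identical output.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if speed_deg_min < 0:
        raise ValueError("speed must be non-negative")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) * dt
    pos = default_magnet_position() if magnet_position is None else np.asarray(magnet_position, float)

    if shape_class == "Other":
        start = _unit(rng.normal(size=3)) if u0 is None else _unit(np.asarray(u0, float))
        wob = OTHER_WOBBLE_SD_DEG if jitter is None else jitter
        if wob == 0:
            u = np.tile(start, (n, 1))
        else:
            u = _wobble_series(n, dt, wob, start, rng)
    elif shape_class == "Round":
        start = _unit(rng.normal(size=3)) if u0 is None else _unit(np.asarray(u0, float))
        w0 = _unit(np.cross(_unit(rng.normal(size=3)), start))
        jit = ROUND_JITTER_DEG_SQRT_H if jitter is None else jitter
        u = _tangent_walk(n, dt, speed_deg_min, jit, start, w0, rng)
    elif shape_class == "Atypical":
        ax = _unit(rng.normal(size=3)) if axis is None else _unit(np.asarray(axis, float))
        if u0 is None:
            start = _any_perpendicular(ax)
        else:
            start = _unit(np.asarray(u0, float))
        w0 = _unit(np.cross(ax, start))
        jit = ATYPICAL_JITTER_DEG_SQRT_H if jitter is None else jitter
        u = _tangent_walk(n, dt, speed_deg_min, jit, start, w0, rng)
    else:
        raise ValueError(f"unknown class {shape_class!r}")
    return OrientationTrajectory(t=t, u=u, magnet_position=pos)


#: Clock rig speed: one revolution per hour.
CLOCK_SPEED_DEG_MIN: float = 6.0


def simulate_clock_scene(
    magnet_mode: str,
    ring_position: int = 2,
    duration_s: float = 3600.0,
    rate_hz: float = 1.0,
    geometry: DomeGeometry | None = None,
) -> tuple[OrientationTrajectory, float]:
    """Deterministic calibration scene: clock-driven magnet, 1 rev/hour.

    The magnet hangs from a rod rotating about the vertical axis at exactly
    one revolution per hour, positioned on the dome axis at the centre
    height of the chosen sensor ring.  ``magnet_mode`` sets the angle of the
    magnet moment to the rotation axis: ``"parallel"`` (0 deg, rotation
    unobservable), ``"diagonal"`` (45 deg cone) or ``"perpendicular"``
    (90 deg, equatorial sweep).

    Returns the trajectory and the true angular speed (6 deg/min).
    """
    modes = {"parallel": 0.0, "diagonal": 45.0, "perpendicular": 90.0}
    if magnet_mode not in modes:
        raise ValueError(f"magnet_mode must be one of {sorted(modes)}")
    geom = geometry or build_dome()
    pos = default_magnet_position(geom, ring_position)
    dt = 1.0 / rate_hz
    n = int(round(duration_s * rate_hz)) + 1
    t = np.arange(n) * dt
    omega = 2.0 * np.pi / 3600.0  # rad/s
    tilt = np.radians(modes[magnet_mode])
    u = np.stack(
        [
            np.sin(tilt) * np.cos(omega * t),
            np.sin(tilt) * np.sin(omega * t),
            np.full(n, np.cos(tilt)),
        ],
        axis=1,
    )
    traj = OrientationTrajectory(t=t, u=u, magnet_position=pos)
    return traj, CLOCK_SPEED_DEG_MIN


def projection_matrix(geom: DomeGeometry, magnet_position: np.ndarray) -> np.ndarray:
    """(n_sensors, 3) matrix G with ``values = u @ G.T`` for a unit dipole.

    Row i is ``(3 r^ (r^ . a_i) - a_i) / |r_i|^3`` with ``r_i`` the
    displacement from the magnet to sensor i and ``a_i`` its axis.
    """
    r = geom.positions - magnet_position[None, :]
    rn = np.linalg.norm(r, axis=1, keepdims=True)
    r_hat = r / rn
    a = geom.axes
    rdota = np.sum(r_hat * a, axis=1, keepdims=True)
    return (3.0 * rdota * r_hat - a) / rn**3


def simulate_recording(
    traj: OrientationTrajectory,
    geom: DomeGeometry,
    noise_sd: float | None = None,
    offset_sd: float | None = None,
    noise_frac: float = 0.05,
    offset_frac: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> SensorRecording:
    """Forward-model the dome channels for a moment-direction trajectory.

    ``value_i(t) = B(u_t, p_i - magnet_position) . axis_i + offset_i + eps``.
    Per-channel offsets are drawn once; noise is iid Gaussian.  When
    ``noise_sd``/``offset_sd`` are omitted they are set to ``noise_frac`` /
    ``offset_frac`` times the RMS of the noiseless signal (the physical
    sensors carry offset-compensation circuits, hence zero offset fraction
    by default).
    """
    rng = np.random.default_rng(seed)
    G = projection_matrix(geom, traj.magnet_position)
    clean = traj.u @ G.T
    rms = float(np.sqrt(np.mean(clean**2)))
    nsd = noise_frac * rms if noise_sd is None else noise_sd
    osd = offset_frac * rms if offset_sd is None else offset_sd
    values = clean
    if osd > 0:
        values = values + rng.normal(0.0, osd, size=(1, geom.n_sensors))
    if nsd > 0:
        values = values + rng.normal(0.0, nsd, size=clean.shape)
    return SensorRecording(t=traj.t.copy(), values=np.array(values, copy=True), geometry=geom)


def simulate_cohort(
    n_pearls: int,
    class_probs: Sequence[float] = CLASS_PROBS,
    speed_mean: float = SPEED_MEAN_DEG_MIN,
    speed_sd: float = SPEED_SD_DEG_MIN,
    culture_day_range: tuple[int, int] = (365, 545),
    seed: int | np.random.Generator | None = None,
    sample_interval_s: float = 60.0,
    acquisition_weeks: tuple[int, int] = (3, 6),
    acquisition_s: float | None = None,
    n_harvest_groups: int = 3,
) -> list[PearlRecord]:
    """Generate a labelled cohort of simulated pearls.

    Per pearl: the class is multinomial with ``class_probs``; the rotation
    speed is Normal(``speed_mean``, ``speed_sd``) truncated to positive
    (identical across classes -- speed carries no class information), except
    ``Other`` pearls which do not rotate; cultivation time is uniform over
    ``culture_day_range`` (12-18 months by default); the acquisition covers
    the last ``acquisition_weeks`` (uniform int) of cultivation, sampled
    every ``sample_interval_s`` seconds; ``harvest_date_group`` labels
    cultivation-time terciles.

    ``acquisition_s`` overrides the per-pearl acquisition duration with a
    fixed value (used for short calibration-style cohorts).
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.size != len(CLASSES) or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_probs must be 3 non-negative values summing to 1")
    if n_pearls < 0:
        raise ValueError("n_pearls must be non-negative")
    rng = np.random.default_rng(seed)
    lo_d, hi_d = culture_day_range
    tn = stats.truncnorm((0.0 - speed_mean) / speed_sd, np.inf, loc=speed_mean, scale=speed_sd)

    records: list[PearlRecord] = []
    culture_days_all = []
    for i in range(n_pearls):
        cls = CLASSES[rng.choice(len(CLASSES), p=probs)]
        speed = 0.0 if cls == "Other" else float(tn.rvs(random_state=rng))
        culture_days = int(rng.integers(lo_d, hi_d + 1))
        if acquisition_s is not None:
            dur = float(acquisition_s)
        else:
            weeks = int(rng.integers(acquisition_weeks[0], acquisition_weeks[1] + 1))
            dur = weeks * 7 * 86400.0
        acq_days = int(math.ceil(dur / 86400.0))
        acq_offset = max(0, culture_days - acq_days)
        child_seed = int(rng.integers(2**31))
        traj = simulate_trajectory(
            cls,
            duration_s=dur,
            rate_hz=1.0 / sample_interval_s,
            speed_deg_min=speed,
            seed=child_seed,
        )
        culture_days_all.append(culture_days)
        records.append(
            PearlRecord(
                pearl_id=f"P{i + 1:03d}",
                true_class=cls,
                trajectory=traj,
                culture_days=culture_days,
                acq_offset_days=acq_offset,
                harvest_date_group="g0",
                speed_deg_min=speed,
            )
        )
    if records:
        qs = np.quantile(culture_days_all, np.linspace(0, 1, n_harvest_groups + 1)[1:-1])
        for r in records:
            r.harvest_date_group = f"g{int(np.searchsorted(qs, r.culture_days, side='right'))}"
    return records


def inject_rejection_event(
    traj: OrientationTrajectory,
    onset_s: float,
    peak_speed: float = 4.8,
    ramp_s: float = 600.0,
) -> OrientationTrajectory:
    """Superimpose a sudden rotation acceleration (pre-rejection signature).

    The trajectory is unchanged before ``onset_s``; afterwards the angular
    speed ramps linearly from the current instantaneous speed to
    ``peak_speed`` (deg/min) over ``ramp_s`` seconds and then holds, rotating
    about a fixed axis.  Deterministic (no randomness).
    """
    if not (traj.t[0] <= onset_s <= traj.t[-1]):
        raise ValueError("onset outside trajectory")
    i0 = int(np.searchsorted(traj.t, onset_s))
    if i0 >= len(traj) - 1:
        return replace(traj, t=traj.t.copy(), u=traj.u.copy())
    dt = traj.dt
    u = traj.u.copy()
    # heading at onset: last motion direction, or an arbitrary tangent if static
    prev = u[i0] - u[max(i0 - 1, 0)]
    prev -= np.dot(prev, u[i0]) * u[i0]
    if np.linalg.norm(prev) > 1e-12:
        w = prev / np.linalg.norm(prev)
        v0 = math.degrees(np.linalg.norm(u[i0] - u[i0 - 1])) * 60.0 / dt if i0 > 0 else 0.0
    else:
        w = _any_perpendicular(u[i0])
        v0 = 0.0
    cur = u[i0]
    for i in range(i0 + 1, len(traj)):
        elapsed = traj.t[i] - onset_s
        frac = min(1.0, elapsed / ramp_s) if ramp_s > 0 else 1.0
        speed = v0 + (peak_speed - v0) * frac
        alpha = math.radians(speed) * dt / 60.0
        ca, sa = math.cos(alpha), math.sin(alpha)
        new_u = ca * cur + sa * w
        w = -sa * cur + ca * w
        cur = new_u
        u[i] = cur
    return replace(traj, t=traj.t.copy(), u=u)
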