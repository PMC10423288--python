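"""Signal path from raw dome channels to rotation kinematics.

Stages: Gaussian-weighted moving-average noise filtering, orientation
reconstruction by the position-weighted channel sum, sphere/equator
projections, angular-speed estimation and the calibration accuracy metric,
plus the legacy binned velocity/acceleration feature vector.

The reconstruction estimator is deliberately the simple weighted sum used by
the acquisition software: ``v_t = sum_i value_i(t) * p_hat_i`` normalised to
the unit sphere.  With partial (hemisphere) sensor coverage it is biased --
the bias is bounded (a few degrees for the 25-sensor dome with the magnet at
the second-ring height) and vanishes as coverage approaches a dense full
sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import DomeGeometry, position_weights
from .simulate import OrientationTrajectory, SensorRecording

__all__ = [
    "AzimuthTrajectory",
    "SpeedEstimate",
    "gaussian_kernel",
    "gaussian_smooth",
    "reconstruct_orientation",
    "project_equator",
    "angular_speed",
    "azimuth_speed",
    "calibration_accuracy",
    "observability_score",
    "binned_kinematics",
]


@dataclass
class AzimuthTrajectory:
    """Equator projection of a moment-direction trajectory.

    ``phi`` is the azimuth in degrees wrapped to [0, 360); ``valid`` is
    False where the direction is too close to a pole for the azimuth to be
    meaningful.
    """

    t: np.ndarray
    phi: np.ndarray
    valid: np.ndarray


@dataclass
class SpeedEstimate:
    """Angular-speed summary of a trajectory.

    ``per_step`` holds the per-interval speeds in deg/min; ``hours_per_rev``
    is the equivalent revolution time ``360 / (mean * 60)``.
    """

    per_step: np.ndarray
    mean: float
    sd: float
    hours_per_rev: float
    lag: int = 1

    def to_dict(self) -> dict:
        return {
            "mean_deg_min": self.mean,
            "sd_deg_min": self.sd,
            "hours_per_rev": self.hours_per_rev,
            "lag": self.lag,
        }


def gaussian_kernel(window: int, sd: float | None = None) -> np.ndarray:
    """Gaussian weights over a ``window``-sample span, normalised to sum 1.

    The kernel SD defaults to ``window / 5`` samples, a standard choice for
    Gaussian-weighted moving averages.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if sd is None:
        sd = window / 5.0
    j = np.arange(window) - (window - 1) / 2.0
    w = np.exp(-0.5 * (j / sd) ** 2) if window > 1 else np.ones(1)
    return w / w.sum()


def gaussian_smooth(rec: SensorRecording, window: int = 60, sd: float | None = None) -> SensorRecording:
    """Per-channel Gaussian-weighted moving average.

    Output length equals input length; at the edges the truncated window is
    renormalised so constant signals pass through unchanged.  ``window=1``
    is the identity.
    """
    if len(rec) == 0:
        raise ValueError("empty recording")
    if window > len(rec):
        raise ValueError("window longer than the recording")
    w = gaussian_kernel(window, sd)
    if window == 1:
        return SensorRecording(t=rec.t.copy(), values=rec.values.copy(), geometry=rec.geometry)
    num = ndimage.convolve1d(rec.values, w, axis=0, mode="constant", cval=0.0)
    den = ndimage.convolve1d(np.ones(len(rec)), w, mode="constant", cval=0.0)
    return SensorRecording(t=rec.t.copy(), values=num / den[:, None], geometry=rec.geometry)


def reconstruct_orientation(
    rec: SensorRecording,
    geom: DomeGeometry | None = None,
    norm_floor_frac: float = 0.01,
) -> OrientationTrajectory:
    """Estimate the moment direction from the channel values.

    The raw estimate is the position-weighted sum ``v_t = sum_i value_i(t)
    p_hat_i``; the returned directions are ``v_t / |v_t|``.  Frames whose
    raw norm falls below ``norm_floor_frac`` times the series median norm
    are flagged invalid (the direction is undefined there) rather than
    interpolated; their direction is carried over from the nearest valid
    frame where possible.
    """
    geom = geom or rec.geometry
    if rec.values.shape[1] != geom.n_sensors:
        raise ValueError("channel count does not match geometry")
    v = rec.values @ position_weights(geom)
    norms = np.linalg.norm(v, axis=1)
    med = np.median(norms)
    floor = norm_floor_frac * med if med > 0 else 0.0
    valid = norms > max(floor, 0.0)
    u = np.zeros_like(v)
    np.divide(v, norms[:, None], out=u, where=norms[:, None] > 0)
    if not valid.all():
        # fill flagged frames with the nearest valid direction (display only;
        # downstream estimators honour the mask)
        idx = np.arange(len(valid))
        good = idx[valid]
        if good.size:
            nearest = good[np.clip(np.searchsorted(good, idx), 0, good.size - 1)]
            u[~valid] = u[nearest[~valid]]
        else:
            u[:] = np.array([0.0, 0.0, 1.0])
    return OrientationTrajectory(t=rec.t.copy(), u=u, magnet_position=np.zeros(3), valid=valid)


def raw_weighted_sum(rec: SensorRecording, geom: DomeGeometry | None = None) -> np.ndarray:
    """Unnormalised position-weighted channel sum (n, 3)."""
    geom = geom or rec.geometry
    return rec.values @ position_weights(geom)


def project_equator(traj: OrientationTrajectory, pole_cut: float = 0.95) -> AzimuthTrajectory:
    """Project a direction trajectory onto the equator (azimuth angle).

    ``phi = atan2(y, x)`` in degrees wrapped to [0, 360).  Samples with
    ``|z| > pole_cut`` are marked invalid: near the poles the azimuth is
    ill-conditioned.
    """
    phi = np.degrees(np.arctan2(traj.u[:, 1], traj.u[:, 0])) % 360.0
    valid = (np.abs(traj.u[:, 2]) <= pole_cut) & traj.valid_mask
    return AzimuthTrajectory(t=traj.t.copy(), phi=phi, valid=valid)


def angular_speed(traj: OrientationTrajectory, lag: int = 1) -> SpeedEstimate:
    """Angular speed from great-circle steps between samples ``lag`` apart.

    The step angle is ``arccos(clamp(u_t . u_{t+lag}))`` converted to
    deg/min.  ``lag=1`` is the plain per-step estimator; a larger lag (a few
    minutes of data) suppresses the positive bias that measurement noise
    induces at slow rotation speeds.  Flagged-invalid samples are excluded.
    """
    if len(traj) < lag + 1:
        raise ValueError("trajectory too short for the requested lag")
    dt = traj.dt
    dots = np.clip(np.sum(traj.u[:-lag] * traj.u[lag:], axis=1), -1.0, 1.0)
    theta = np.degrees(np.arccos(dots))
    ok = traj.valid_mask[:-lag] & traj.valid_mask[lag:]
    per_step = theta[ok] * 60.0 / (dt * lag)
    if per_step.size == 0:
        raise ValueError("no valid sample pairs")
    mean = float(per_step.mean())
    sd = float(per_step.std(ddof=1)) if per_step.size > 1 else 0.0
    hpr = 360.0 / (mean * 60.0) if mean > 0 else math.inf
    return SpeedEstimate(per_step=per_step, mean=mean, sd=sd, hours_per_rev=hpr, lag=lag)


def azimuth_speed(az: AzimuthTrajectory) -> float:
    """Mean azimuthal rate (deg/min) over consecutive valid samples.

    Wrapped differences are mapped to (-180, 180]; the mean absolute rate is
    returned.  This is the estimator applied to the clock-calibration
    scenes, where the motion is purely azimuthal.
    """
    ok = az.valid[:-1] & az.valid[1:]
    if not np.any(ok):
        raise ValueError("no valid consecutive azimuth pairs")
    dphi = np.diff(az.phi)[ok]
    dphi = (dphi + 180.0) % 360.0 - 180.0
    dt = float(az.t[1] - az.t[0])
    return float(np.mean(np.abs(dphi)) * 60.0 / dt)


def calibration_accuracy(estimated, true_speed: float) -> float:
    """Percent accuracy of speed estimates against a known rotation speed.

    ``accuracy = 100 * max(0, 1 - |mean_est - true| / true)``, averaged over
    the provided estimates when a sequence is given (the calibration rig is
    scored by averaging over the three magnet orientations).  Accepts
    floats, :class:`SpeedEstimate` objects, or a sequence of either.
    """
    if true_speed <= 0:
        raise ValueError("true_speed must be positive")

    def one(e) -> float:
        mean = e.mean if isinstance(e, SpeedEstimate) else float(e)
        return 100.0 * max(0.0, 1.0 - abs(mean - true_speed) / true_speed)

    if isinstance(estimated, (list, tuple)):
        if not estimated:
            raise ValueError("no estimates given")
        return float(np.mean([one(e) for e in estimated]))
    return one(estimated)


def observability_score(traj: OrientationTrajectory, noise_floor_deg: float = 0.05) -> float:
    """Fraction of steps whose angular change exceeds a noise floor.

    Rotation about the magnet's own axis is invisible to the sensors, and a
    non-rotating pearl produces the same near-static signal; this score
    makes that ambiguity explicit instead of hiding it.  Values near 0 mean
    the trajectory is observationally static.
    """
    dots = np.clip(np.sum(traj.u[:-1] * traj.u[1:], axis=1), -1.0, 1.0)
    theta = np.degrees(np.arccos(dots))
    ok = traj.valid_mask[:-1] & traj.valid_mask[1:]
    if not np.any(ok):
        return 0.0
    return float(np.mean(theta[ok] > noise_floor_deg))


def binned_kinematics(traj: OrientationTrajectory, bins_per_day: int = 100) -> np.ndarray:
    """Binned velocity/acceleration feature vector (legacy tabular features).

    The per-step angular velocity (deg/min) and its first difference per
    minute (deg/min^2) are averaged inside uniform time bins, ``bins_per_day``
    per day of data, and concatenated: a 1-day trajectory yields
    ``2 * bins_per_day`` features.
    """
    if len(traj) < 3:
        raise ValueError("trajectory too short")
    if bins_per_day < 1:
        raise ValueError("bins_per_day must be >= 1")
    dt = traj.dt
    span_s = traj.t[-1] - traj.t[0]
    n_bins = max(1, int(round(span_s / 86400.0 * bins_per_day)))
    dots = np.clip(np.sum(traj.u[:-1] * traj.u[1:], axis=1), -1.0, 1.0)
    vel = np.degrees(np.arccos(dots)) * 60.0 / dt  # deg/min at step midpoints
    t_vel = traj.t[:-1] + dt / 2.0
    acc = np.diff(vel) / (dt / 60.0)  # deg/min^2
    t_acc = traj.t[1:-1]
    edges = np.linspace(traj.t[0], traj.t[-1], n_bins + 1)

    def bin_means(x, tx):
        which = np.clip(np.searchsorted(edges, tx, side="right") - 1, 0, n_bins - 1)
        sums = np.bincount(which, weights=x, minlength=n_bins)
        counts = np.bincount(which, minlength=n_bins)
        out = np.zeros(n_bins)
        np.divide(sums, counts, out=out, where=counts > 0)
        return out

    return np.concatenate([bin_means(vel, t_vel), bin_means(acc, t_acc)])
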