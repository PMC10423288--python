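"""Hemispherical sensor dome geometry.

A cultured-pearl oyster sits inside a 4.2 L half-sphere dome instrumented
with 25 single-axis magnetoresistive sensors.  Twenty-four sensors are glued
on three elevation rings (6, 30 and 60 degrees above the base plane, eight
per ring) and one sensor sits at the zenith (90 degrees).  Each sensor reads
the component of the local magnetic field along its measurement axis, taken
here as the outward radial direction of the dome.

Coordinates are right-handed with the base plane at ``z = 0`` and the zenith
on ``+z``.  Lengths are in metres, angles in degrees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Sensor",
    "DomeGeometry",
    "DOME_RADIUS_M",
    "hemisphere_radius_from_volume",
    "build_dome",
    "build_sphere_grid",
    "position_weights",
]


def hemisphere_radius_from_volume(volume_liters: float = 4.2) -> float:
    """Radius (m) of a half-sphere of the given volume.

    Solves ``(2/3) * pi * r**3 = V``.  The default 4.2 L dome gives
    ``r ~= 0.126 m``.
    """
    if volume_liters <= 0:
        raise ValueError("volume must be positive")
    v_m3 = volume_liters * 1e-3
    return float((3.0 * v_m3 / (2.0 * np.pi)) ** (1.0 / 3.0))


#: Default dome radius derived from the 4.2 L enclosure volume.
DOME_RADIUS_M: float = hemisphere_radius_from_volume(4.2)


@dataclass(frozen=True)
class Sensor:
    """One single-axis magnetic sensor on the dome surface.

    Attributes
    ----------
    index : int
        1-based sensor number (1..25 for the default dome).
    position : ndarray, shape (3,)
        Sensor location in metres, dome-centred coordinates.
    axis : ndarray, shape (3,)
        Unit measurement direction; the channel reads ``B . axis``.
    ring : float
        Elevation angle of the sensor's ring in degrees above the base plane.
    """

    index: int
    position: np.ndarray
    axis: np.ndarray
    ring: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float))
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-12:
            raise ValueError(f"sensor {self.index}: axis must be a unit vector")
        if self.position[2] < -1e-12:
            raise ValueError(f"sensor {self.index}: position below base plane")


@dataclass(frozen=True)
class DomeGeometry:
    """Positions and measurement axes of the sensors in one dome."""

    radius: float
    sensors: tuple[Sensor, ...]
    rings: tuple[float, ...]

    @property
    def n_sensors(self) -> int:
        return len(self.sensors)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of sensor positions in metres."""
        return np.array([s.position for s in self.sensors])

    @property
    def axes(self) -> np.ndarray:
        """(n, 3) array of unit measurement axes."""
        return np.array([s.axis for s in self.sensors])

    def to_json(self) -> str:
        payload = {
            "radius": self.radius,
            "rings": list(self.rings),
            "sensors": [
                {
                    "index": s.index,
                    "position": s.position.tolist(),
                    "axis": s.axis.tolist(),
                    "ring": s.ring,
                }
                for s in self.sensors
            ],
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DomeGeometry":
        payload = json.loads(text)
        sensors = tuple(
            Sensor(
                index=d["index"],
                position=np.asarray(d["position"], dtype=float),
                axis=np.asarray(d["axis"], dtype=float),
                ring=float(d["ring"]),
            )
            for d in payload["sensors"]
        )
        return cls(
            radius=float(payload["radius"]),
            sensors=sensors,
            rings=tuple(float(r) for r in payload["rings"]),
        )


def build_dome(
    radius: float = DOME_RADIUS_M,
    per_ring: Sequence[int] = (8, 8, 8),
    ring_angles: Sequence[float] = (6.0, 30.0, 60.0),
    zenith: bool = True,
) -> DomeGeometry:
    """Construct a hemispherical dome with sensors on elevation rings.

    Sensors are placed at equal azimuthal spacing within each ring with the
    azimuth origin on ``+x``, ordered ring-major (lowest ring first) and
    azimuth-minor, with the optional zenith sensor last.  The measurement
    axis of every sensor is the outward radial direction, so a positive
    reading means the field points away from the dome centre.

    Parameters
    ----------
    radius : float
        Dome radius in metres.  Default: radius of a 4.2 L half-sphere.
    per_ring : sequence of int
        Number of sensors on each ring.  The default (8, 8, 8) plus the
        zenith sensor gives the standard 25-sensor dome.
    ring_angles : sequence of float
        Elevation angle of each ring, degrees in [0, 90), strictly
        increasing.
    zenith : bool
        Whether to add one sensor at the pole (90 degrees).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if len(per_ring) != len(ring_angles):
        raise ValueError("per_ring and ring_angles must have the same length")
    angles = [float(a) for a in ring_angles]
    if any(b <= a for a, b in zip(angles, angles[1:])):
        raise ValueError("ring_angles must be strictly increasing")
    if any(a < 0 or a > 90 for a in angles):
        raise ValueError("ring angles must lie in [0, 90]")

    sensors: list[Sensor] = []
    idx = 1
    for n, elev in zip(per_ring, angles):
        if n <= 0:
            raise ValueError("per_ring entries must be positive")
        el = np.radians(elev)
        for k in range(n):
            az = 2.0 * np.pi * k / n
            p_hat = np.array(
                [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
            )
            sensors.append(Sensor(index=idx, position=radius * p_hat, axis=p_hat, ring=elev))
            idx += 1
    rings = tuple(angles)
    if zenith:
        sensors.append(
            Sensor(index=idx, position=np.array([0.0, 0.0, radius]), axis=np.array([0.0, 0.0, 1.0]), ring=90.0)
        )
        rings = rings + (90.0,)
    return DomeGeometry(radius=radius, sensors=tuple(sensors), rings=rings)


def build_sphere_grid(n_sensors: int, radius: float = DOME_RADIUS_M) -> DomeGeometry:
    """Dense quasi-uniform full-sphere grid of radial sensors.

    Uses a Fibonacci lattice.  This is not a physical device: it serves as
    the asymptotic reference for the position-weighted-sum orientation
    estimator, whose bias vanishes as sensor coverage approaches the full
    sphere.  Points below the base plane have ``z < 0``, so the hemisphere
    invariant of the physical dome does not apply here.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors for a sphere grid")
    i = np.arange(n_sensors) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n_sensors)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    p_hat = np.stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)],
        axis=1,
    )
    built = []
    for k in range(n_sensors):
        # Bypass the dataclass hemisphere check (z >= 0): full-sphere grid.
        s = Sensor.__new__(Sensor)
        object.__setattr__(s, "index", k + 1)
        object.__setattr__(s, "position", radius * p_hat[k])
        object.__setattr__(s, "axis", p_hat[k])
        object.__setattr__(s, "ring", float(np.degrees(np.pi / 2 - polar[k])))
        built.append(s)
    return DomeGeometry(radius=radius, sensors=tuple(built), rings=())


def position_weights(geom: DomeGeometry) -> np.ndarray:
    """Per-sensor unit position vectors ``p_i / |p_i|``, shape (n, 3).

    These are the weights of the orientation estimator: the moment-direction
    estimate at each timestamp is the readings-weighted sum of these vectors.
    """
    p = geom.positions
    return p / np.linalg.norm(p, axis=1, keepdims=True)
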