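"""Render orientation trajectories as images and assemble image datasets.

Each dataset sample is one 224 x 224 RGB image showing a segment of the
moment-direction trajectory scattered on the unit sphere, viewed
orthographically from the barycenter of the points (the direction that
maximises visible rotation data), with points coloured by time order.
Additional views rotated in 60-degree increments about the camera axis are
available, but only the first view enters the datasets.

Dataset variants mirror the evaluation protocol: ``full`` keeps every
weekly segment of every pearl, ``week`` the last weekly segment (one sample
per pearl), ``month`` the last up-to-four weekly segments, and ``day`` the
last week split into daily segments.

Rendering uses a small deterministic software rasterizer (latest-point-wins
per pixel), so identical segments give bit-identical images on any
platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .simulate import CLASSES, OrientationTrajectory, PearlRecord

__all__ = [
    "RenderSpec",
    "PearlSample",
    "ImageDataset",
    "DATASET_VARIANTS",
    "segment_trajectory",
    "barycenter_viewpoint",
    "rotate_about_axis",
    "render_views",
    "render_segment",
    "assemble_dataset",
]

DATASET_VARIANTS = ("day", "week", "month", "full")

SECONDS_PER_DAY = 86_400.0
SECONDS_PER_WEEK = 604_800.0


@dataclass(frozen=True)
class RenderSpec:
    """Rendering style, frozen by default so images are reproducible."""

    size: int = 224
    n_views: int = 6
    view_step: float = 60.0
    point_radius: int = 2
    colormap: str = "viridis"
    wireframe: bool = True
    background: tuple[int, int, int] = (0, 0, 0)
    margin: float = 1.15  # half-extent of the canvas in sphere radii

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("size must be positive")
        if self.n_views * self.view_step > 360.0 + 1e-9:
            raise ValueError("n_views * view_step must not exceed 360 degrees")


@dataclass
class PearlSample:
    """One rendered segment plus the two metadata scalars and the label."""

    image: np.ndarray
    culture_days: int
    acq_offset_days: int
    pearl_id: str
    label: str
    period: tuple[float, float]  # (start_day, end_day) relative to graft

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be (H, W, 3)")


@dataclass
class ImageDataset:
    samples: list[PearlSample]
    variant: str

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def pearl_ids(self) -> list[str]:
        return sorted({s.pearl_id for s in self.samples})

    def labels_by_pearl(self) -> dict[str, str]:
        return {s.pearl_id: s.label for s in self.samples}

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "pearl_id": s.pearl_id,
                "label": s.label,
                "variant": self.variant,
                "period_start_day": s.period[0],
                "period_end_day": s.period[1],
                "culture_days": s.culture_days,
                "acq_offset_days": s.acq_offset_days,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)


def segment_trajectory(traj: OrientationTrajectory, granularity: str = "week") -> list[OrientationTrajectory]:
    """Cut a trajectory into contiguous day or week segments.

    Segments are non-overlapping and aligned to the trajectory start; a
    trailing partial segment is kept only if it covers at least half the
    nominal span.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    spans = {"day": SECONDS_PER_DAY, "week": SECONDS_PER_WEEK}
    if granularity not in spans:
        raise ValueError("granularity must be 'day' or 'week'")
    span = spans[granularity]
    t0 = traj.t[0]
    total = traj.t[-1] - t0
    segments = []
    n_full = int(total // span)
    for k in range(n_full + 1):
        lo, hi = t0 + k * span, t0 + (k + 1) * span
        sel = (traj.t >= lo) & (traj.t < hi)
        if not np.any(sel):
            continue
        covered = traj.t[sel][-1] - traj.t[sel][0]
        if k == n_full and covered < 0.5 * span:
            continue  # drop short trailing remainder
        seg = OrientationTrajectory(
            t=traj.t[sel].copy(),
            u=traj.u[sel].copy(),
            magnet_position=traj.magnet_position.copy(),
            valid=None if traj.valid is None else traj.valid[sel].copy(),
        )
        segments.append(seg)
    return segments


def barycenter_viewpoint(segment: OrientationTrajectory) -> np.ndarray:
    """Camera direction maximising visible rotation data.

    Normalised mean of the segment's (valid) unit vectors.  When the mean is
    degenerate (antipodally balanced cloud), falls back to the principal
    axis of the point scatter.
    """
    pts = segment.u[segment.valid_mask]
    if pts.size == 0:
        raise ValueError("no valid points in segment")
    mean = pts.mean(axis=0)
    n = np.linalg.norm(mean)
    if n >= 1e-6:
        return mean / n
    # Antipodally balanced cloud: view along the normal of the best-fit
    # plane (the smallest-variance axis of the scatter), which shows e.g. a
    # great-circle trajectory face-on.
    _, vecs = np.linalg.eigh(pts.T @ pts)
    axis = vecs[:, 0]
    return axis if axis[2] >= 0 else -axis


def _camera_basis(cam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(up, cam)) > 0.999:
        up = np.array([1.0, 0.0, 0.0])
    right = np.cross(up, cam)
    right /= np.linalg.norm(right)
    upv = np.cross(cam, right)
    return right, upv


def rotate_about_axis(points: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of row vectors about ``axis`` (right-handed)."""
    a = math.radians(angle_deg)
    k = axis / np.linalg.norm(axis)
    ca, sa = math.cos(a), math.sin(a)
    return points * ca + np.cross(np.broadcast_to(k, points.shape), points) * sa + np.outer(points @ k, k) * (1.0 - ca)


def _rasterize(
    xy: np.ndarray,
    order: np.ndarray,
    spec: RenderSpec,
) -> np.ndarray:
    """Latest-point-wins scatter rasterizer with a time colormap."""
    size = spec.size
    img = np.empty((size, size, 3), dtype=np.uint8)
    img[:] = np.array(spec.background, dtype=np.uint8)
    yy, xx = np.mgrid[0:size, 0:size]
    if spec.wireframe:
        cx = (size - 1) / 2.0
        scale = size / (2.0 * spec.margin)
        rad = np.hypot(xx - cx, yy - cx)
        ring = np.abs(rad - scale) < 0.75
        img[ring] = 70  # dim grey sphere outline
    if xy.shape[0] == 0:
        return img
    scale = size / (2.0 * spec.margin)
    px = np.round((xy[:, 0] + spec.margin) * scale).astype(int)
    py = np.round((spec.margin - xy[:, 1]) * scale).astype(int)
    rank = np.empty(len(order), dtype=float)
    rank[:] = order / max(1, len(order) - 1)
    # time buffer: each pixel keeps the rank of the latest point covering it
    tbuf = np.full((size, size), -1.0)
    r = spec.point_radius
    offsets = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1) if dy * dy + dx * dx <= r * r]
    for dy, dx in offsets:
        qx = px + dx
        qy = py + dy
        ok = (qx >= 0) & (qx < size) & (qy >= 0) & (qy < size)
        np.maximum.at(tbuf, (qy[ok], qx[ok]), rank[ok])
    hit = tbuf >= 0.0
    cmap = colormaps[spec.colormap]
    colors = (np.asarray(cmap(tbuf[hit]))[:, :3] * 255).astype(np.uint8)
    img[hit] = colors
    return img


def render_views(
    segment: OrientationTrajectory,
    spec: RenderSpec = RenderSpec(),
    camera: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Render the segment from the barycenter viewpoint and rotated views.

    View ``k`` shows the point cloud rotated by ``k * view_step`` degrees
    about the camera axis, so successive views differ by an in-plane
    rotation of the scene.  Points are drawn in time order (later points
    painted over earlier ones) with a perceptually uniform time colormap on
    a dark background.
    """
    pts = segment.u[segment.valid_mask]
    if camera is None:
        if pts.shape[0] == 0:
            camera = np.array([0.0, 0.0, 1.0])
        else:
            camera = barycenter_viewpoint(segment)
    right, upv = _camera_basis(camera)
    order = np.arange(pts.shape[0])
    images = []
    for k in range(spec.n_views):
        q = pts if k == 0 else rotate_about_axis(pts, camera, k * spec.view_step)
        xy = np.stack([q @ right, q @ upv], axis=1) if q.shape[0] else np.empty((0, 2))
        images.append(_rasterize(xy, order, spec))
    return images


def render_segment(segment: OrientationTrajectory, spec: RenderSpec = RenderSpec()) -> np.ndarray:
    """First (barycenter) view only -- the image that enters the datasets."""
    from dataclasses import replace as _dc_replace

    return render_views(segment, _dc_replace(spec, n_views=1))[0]


def assemble_dataset(
    cohort: Sequence[PearlRecord],
    variant: str,
    spec: RenderSpec = RenderSpec(),
    trajectories: dict[str, OrientationTrajectory] | None = None,
) -> ImageDataset:
    """Build the image dataset for one evaluation variant.

    ``trajectories`` optionally maps pearl_id to a reconstructed trajectory
    (the realistic path: render what the sensors saw); by default the
    records' own trajectories are rendered.  Per-sample metadata carries the
    pearl's total cultivation time and the graft-to-segment-start offset.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if variant not in DATASET_VARIANTS:
        raise ValueError(f"variant must be one of {DATASET_VARIANTS}")
    samples: list[PearlSample] = []
    for rec in cohort:
        traj = (trajectories or {}).get(rec.pearl_id, rec.trajectory)
        weeks = segment_trajectory(traj, "week")
        if not weeks:
            continue
        if variant == "full":
            chosen = weeks
        elif variant == "week":
            chosen = weeks[-1:]
        elif variant == "month":
            chosen = weeks[-4:]
        else:  # day: last week split per day
            chosen = segment_trajectory(weeks[-1], "day")
        for seg in chosen:
            start_day = rec.acq_offset_days + seg.t[0] / SECONDS_PER_DAY
            end_day = rec.acq_offset_days + seg.t[-1] / SECONDS_PER_DAY
            samples.append(
                PearlSample(
                    image=render_segment(seg, spec),
                    culture_days=rec.culture_days,
                    acq_offset_days=int(start_day),
                    pearl_id=rec.pearl_id,
                    label=rec.true_class,
                    period=(start_day, end_day),
                )
            )
    return ImageDataset(samples=samples, variant=variant)
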