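"""Interlaced-microbeam transection geometry.

A transection is built from one thin quasi-laminar microbeam delivered
through several ports rotated in the horizontal plane, with a small vertical
step between ports.  Stacking n beams of width w with step s gives a slab of
thickness w + (n - 1) s along the step axis (200 um for the default 4 ports
of 50 um beams and 50 um steps).  In the horizontal plane, each port sweeps a
strip whose width equals the beam height; the interlaced target is the
intersection of those strips — a regular octagon for four ports at 45 deg
spacing, whose across-flats width equals the strip width (the printed 2 mm
"diameter"); the across-vertices diameter, width / cos(pi/8), is also
reported.  Entrance and target doses are carried as plan metadata only; no
radiation transport is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely import affinity
from shapely.geometry import Polygon, box


class RasterSizeError(ValueError):
    pass


@dataclass(frozen=True)
class Port:
    angle_deg: float
    beam_width_um: float = 50.0
    beam_height_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.beam_width_um <= 0:
            raise ValueError("beam_width_um must be positive")
        if self.beam_height_mm <= 0:
            raise ValueError("beam_height_mm must be positive")


@dataclass(frozen=True)
class TransectionPlan:
    """Irradiation plan: ports, vertical step, and transection positions (mm)."""

    ports: tuple[Port, ...] = (
        Port(0.0), Port(45.0), Port(90.0), Port(-45.0),
    )
    step_um: float = 50.0
    ap_coords_mm: tuple[float, ...] = (2.0, 0.0, -2.0, -4.0)
    ml_mm: float = -4.5
    entrance_dose_Gy: float = 800.0   # informational only
    target_dose_Gy: float = 820.0     # informational only

    def __post_init__(self) -> None:
        if len(self.ports) < 1:
            raise ValueError("plan needs at least one port")
        if self.step_um < 0:
            raise ValueError("step_um must be non-negative")


@dataclass(frozen=True)
class FootprintResult:
    """Computed interlaced-target geometry."""

    thickness_um: float
    footprint_polygon: np.ndarray        # (n, 2) vertices, mm
    min_caliper_width_mm: float
    max_diameter_mm: float               # across-vertices
    area_mm2: float

    @property
    def n_vertices(self) -> int:
        return self.footprint_polygon.shape[0]


def interlaced_thickness(n_ports: int, beam_width_um: float, step_um: float) -> float:
    """Stacked extent along the step axis: width + (n_ports - 1) * step.

    Warns when step > width (the stacked slabs leave gaps)."""
    if n_ports < 1:
        raise ValueError("n_ports must be >= 1")
    if beam_width_um <= 0:
        raise ValueError("beam_width_um must be positive")
    if step_um < 0:
        raise ValueError("step_um must be non-negative")
    if step_um > beam_width_um:
        warnings.warn(
            f"step ({step_um} um) exceeds beam width ({beam_width_um} um): "
            "stacked slabs are not contiguous", stacklevel=2,
        )
    return beam_width_um + (n_ports - 1) * step_um


def _strip(angle_deg: float, width: float, length: float) -> Polygon:
    rect = box(-length / 2.0, -width / 2.0, length / 2.0, width / 2.0)
    return affinity.rotate(rect, angle_deg, origin=(0.0, 0.0))


def _min_caliper_width(vertices: np.ndarray) -> float:
    """Rotating calipers: min over edge directions of the extent along the
    edge normal (convex polygon)."""
    n = vertices.shape[0]
    best = np.inf
    for i in range(n):
        e = vertices[(i + 1) % n] - vertices[i]
        norm = np.hypot(*e)
        if norm == 0:
            continue
        normal = np.array([-e[1], e[0]]) / norm
        proj = vertices @ normal
        best = min(best, proj.max() - proj.min())
    return float(best)


def intersection_footprint(
    angles_deg: Sequence[float], strip_width_mm: float,
) -> FootprintResult:
    """In-plane intersection of equal-width strips through a common axis.

    Returns the convex intersection polygon with its minimum caliper width
    (across-flats) and maximum vertex-to-vertex diameter.
    """
    angles = sorted({float(a) % 180.0 for a in angles_deg})
    if len(angles) < 2:
        raise ValueError("need >= 2 distinct strip directions (one strip is unbounded)")
    if strip_width_mm <= 0:
        raise ValueError("strip_width_mm must be positive")
    length = 10.0 * strip_width_mm
    poly = _strip(angles[0], strip_width_mm, length)
    for a in angles[1:]:
        poly = poly.intersection(_strip(a, strip_width_mm, length))
    verts = np.asarray(poly.exterior.coords)[:-1]
    # enforce counter-clockwise order (scalar 2D cross product)
    e1, e2 = verts[1] - verts[0], verts[2] - verts[1]
    if e1[0] * e2[1] - e1[1] * e2[0] < 0:
        verts = verts[::-1]
    d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(-1)
    return FootprintResult(
        thickness_um=float("nan"),
        footprint_polygon=verts,
        min_caliper_width_mm=_min_caliper_width(verts),
        max_diameter_mm=float(np.sqrt(d2.max())),
        area_mm2=float(poly.area),
    )


def compute_footprint(plan: TransectionPlan) -> FootprintResult:
    """Full plan geometry: stacked thickness plus in-plane footprint."""
    widths = {p.beam_width_um for p in plan.ports}
    heights = {p.beam_height_mm for p in plan.ports}
    if len(widths) != 1 or len(heights) != 1:
        raise ValueError("compute_footprint requires uniform beam width/height across ports")
    thickness = interlaced_thickness(len(plan.ports), widths.pop(), plan.step_um)
    fp = intersection_footprint([p.angle_deg for p in plan.ports], heights.pop())
    return FootprintResult(
        thickness_um=thickness,
        footprint_polygon=fp.footprint_polygon,
        min_caliper_width_mm=fp.min_caliper_width_mm,
        max_diameter_mm=fp.max_diameter_mm,
        area_mm2=fp.area_mm2,
    )


def render_doseprint(
    plan: TransectionPlan, pixel_um: float, max_pixels: int = 50_000_000,
) -> tuple[np.ndarray, float]:
    """Side-view raster of beam-pass counts (film view: beam height x step axis).

    Each port contributes one slab of its beam width, offset by the port index
    times the step.  Pixels count traversing beams; the interlaced target is
    the contiguous count>=1 band.  Returns (counts, pixel_um).
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    if not plan.ports:
        raise ValueError("plan has no ports")
    height_um = max(p.beam_height_mm for p in plan.ports) * 1000.0
    extent_y = max(
        i * plan.step_um + p.beam_width_um for i, p in enumerate(plan.ports)
    )
    nx = int(np.ceil(height_um / pixel_um))
    ny = int(np.ceil(extent_y / pixel_um)) + 2
    if nx * ny > max_pixels:
        raise RasterSizeError(f"raster {nx} x {ny} exceeds cap of {max_pixels} pixels")
    counts = np.zeros((ny, nx), dtype=np.int32)
    y = (np.arange(ny) + 0.5) * pixel_um
    for i, p in enumerate(plan.ports):
        lo = i * plan.step_um
        hi = lo + p.beam_width_um
        rows = (y >= lo) & (y < hi)
        nxi = int(np.ceil(p.beam_height_mm * 1000.0 / pixel_um))
        counts[rows, :nxi] += 1
    return counts, pixel_um


def footprint_raster(
    angles_deg: Sequence[float], strip_width_mm: float, pixel_mm: float,
    max_pixels: int = 50_000_000,
) -> tuple[np.ndarray, float]:
    """In-plane raster of strip-pass counts; the interlaced footprint is the
    set of pixels crossed by every strip (count == number of directions)."""
    angles = sorted({float(a) % 180.0 for a in angles_deg})
    if pixel_mm <= 0:
        raise ValueError("pixel_mm must be positive")
    half = 0.75 * strip_width_mm
    n = int(np.ceil(2 * half / pixel_mm))
    if n * n > max_pixels:
        raise RasterSizeError(f"raster {n} x {n} exceeds cap of {max_pixels} pixels")
    c = (np.arange(n) + 0.5) * pixel_mm - half
    xx, yy = np.meshgrid(c, c)
    counts = np.zeros((n, n), dtype=np.int32)
    for a in angles:
        th = np.deg2rad(a)
        across = -xx * np.sin(th) + yy * np.cos(th)
        counts += (np.abs(across) <= strip_width_mm / 2.0).astype(np.int32)
    return counts, pixel_mm
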