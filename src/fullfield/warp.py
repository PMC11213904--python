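"""Calibration-driven warping of rectangular images onto the curved screen.

The projector cannot illuminate the cylindrical screen head-on, so a
rectangular source canvas (1024 x 768) must be warped into the curved,
keystoned region of the raster that actually lands on the display
surface.  The goal of the warp is the "wallpaper" rule: equal source
pixels must cover equal arc length on the physical surface, so that the
original 4:3 aspect ratio is preserved on the display and off-screen
pixels are exactly black.

Calibration measures projector-pixel coordinates of a handful of points
along the top and bottom screen edges (at known arc-length fractions:
corners, midpoints, ...).  :func:`fit_calibration` recovers the physical
projection model from those points by nonlinear least squares on
reprojection error, and :func:`build_warp_map` ray-traces the fitted
model through every output pixel.  Circular arcs fitted through each
edge's points are kept on the model for validation (degenerate or
crossing calibrations) and for active-region reporting — a purely 2D
arc-interpolation warp is a 10-30 px approximation under the reference
pose, so the mapping itself is model-based.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from fullfield import geometry as geo
from fullfield.geometry import (
    ProjectionGeometry,
    ProjectorPose,
    ScreenGeometry,
)

__all__ = [
    "CalibrationError",
    "CalibrationPoints",
    "Arc",
    "WarpModel",
    "WarpMap",
    "fit_circle",
    "fit_calibration",
    "build_warp_map",
    "warp_image",
    "unwarp_image",
]


class CalibrationError(ValueError):
    """Degenerate or inconsistent calibration measurements."""


@dataclass(frozen=True)
class CalibrationPoints:
    """Measured projector-pixel coordinates along the screen outline.

    Each edge needs at least three points, ordered left to right and
    evenly spaced in surface arc length (endpoints included) — the
    measurement protocol clicks the screen corners and edge midpoints.
    ``top_edge`` is the edge on which the source image's top row lands.
    """

    top_edge: np.ndarray
    bottom_edge: np.ndarray

    def __post_init__(self):
        for name in ("top_edge", "bottom_edge"):
            pts = np.asarray(getattr(self, name), dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
                raise CalibrationError(f"{name} needs >= 3 (x, y) points")
            if len(np.unique(pts, axis=0)) != len(pts):
                raise CalibrationError(f"{name} contains duplicate points")
            object.__setattr__(self, name, pts)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(
                {"top_edge": self.top_edge.tolist(),
                 "bottom_edge": self.bottom_edge.tolist()},
                f, indent=1,
            )

    @classmethod
    def load(cls, path) -> "CalibrationPoints":
        with open(path) as f:
            d = json.load(f)
        return cls(np.array(d["top_edge"]), np.array(d["bottom_edge"]))


@dataclass(frozen=True)
class Arc:
    """Circular arc in projector-pixel space: circle plus angular span."""

    center: np.ndarray
    radius: float
    theta0: float
    theta1: float

    def point(self, u):
        """Arc point at normalized position u in [0, 1] (equal-angle)."""
        th = self.theta0 + np.asarray(u) * (self.theta1 - self.theta0)
        return np.stack(
            [self.center[0] + self.radius * np.cos(th),
             self.center[1] + self.radius * np.sin(th)], axis=-1
        )

    @property
    def width_px(self) -> float:
        pts = self.point(np.linspace(0, 1, 101))
        return float(pts[:, 0].max() - pts[:, 0].min())


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle through >= 3 points.

    Returns (center, radius, rms_residual).  Exact interpolation for three
    non-collinear points; algebraic (Kasa) least squares followed by a
    geometric Gauss-Newton refinement otherwise.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, res, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or not np.isfinite(sol).all():
        raise CalibrationError("collinear calibration points: degenerate arc")
    cx, cy = sol[0] / 2, sol[1] / 2
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0:
        raise CalibrationError("collinear calibration points: degenerate arc")
    r = math.sqrt(r2)
    if r > 1e7 * (np.ptp(x) + np.ptp(y) + 1e-12):
        raise CalibrationError("collinear calibration points: degenerate arc")
    if len(pts) > 3:

        def resid(p):
            return np.hypot(x - p[0], y - p[1]) - p[2]

        fit = least_squares(resid, [cx, cy, r], method="lm")
        cx, cy, r = fit.x
    rms = float(np.sqrt(np.mean((np.hypot(x - cx, y - cy) - r) ** 2)))
    return np.array([cx, cy]), float(r), rms


def _fit_arc(points: np.ndarray) -> tuple[Arc, float]:
    center, radius, rms = fit_circle(points)
    th = np.unwrap(np.arctan2(points[:, 1] - center[1], points[:, 0] - center[0]))
    return Arc(center, radius, float(th[0]), float(th[-1])), rms


@dataclass(frozen=True)
class WarpModel:
    """Calibrated mapping between source canvas and on-screen region."""

    pose: ProjectorPose
    screen: ScreenGeometry
    native_resolution_px: tuple[int, int]
    source_size_px: tuple[int, int]
    top_arc: Arc
    bottom_arc: Arc
    fit_rms_px: float
    calibration: CalibrationPoints | None = field(default=None, repr=False)

    @property
    def projection(self) -> ProjectionGeometry:
        return ProjectionGeometry(
            native_resolution_px=self.native_resolution_px, pose=self.pose
        )

    @property
    def active_region_px(self) -> tuple[float, float]:
        """Bounding (width, height) of on-screen pixels in the raster."""
        return geo.active_region_px(self.projection, self.screen)


@dataclass(frozen=True)
class WarpMap:
    """Per-output-pixel continuous source coordinates plus on-screen mask."""

    source_x: np.ndarray
    source_y: np.ndarray
    mask: np.ndarray
    model: WarpModel


def _reproject(pose_vec, screen, native, cal: CalibrationPoints) -> np.ndarray:
    pose = ProjectorPose(*pose_vec)
    proj = ProjectionGeometry(native_resolution_px=native, pose=pose)
    w2, h2 = screen.surface_width_cm / 2, screen.surface_height_cm / 2
    out = []
    for pts, h in ((cal.top_edge, -h2), (cal.bottom_edge, h2)):
        ss = np.linspace(-w2, w2, len(pts))
        pred = geo.surface_to_pixel(ss, np.full(len(pts), h), proj, screen)
        out.append((pred - pts).ravel())
    return np.concatenate(out)


def fit_calibration(
    points: CalibrationPoints,
    screen: ScreenGeometry | None = None,
    native_resolution_px: tuple[int, int] = (1024, 768),
    source_size_px: tuple[int, int] = (1024, 768),
) -> WarpModel:
    """Recover the projection model from measured screen-outline points.

    The four pose parameters (incidence angle, two frustum half-angles,
    vertical aim offset) are estimated by Levenberg-Marquardt on the
    reprojection error of the measured points, starting from the
    reference installation.  Calibration points are also fitted with
    circular arcs per edge, which validates the measurement (collinear
    points, crossing arcs) and provides the active-region summary.
    """
    screen = screen or ScreenGeometry()
    top_arc, _ = _fit_arc(points.top_edge)
    bottom_arc, _ = _fit_arc(points.bottom_edge)
    _check_arcs(top_arc, bottom_arc)

    ref = ProjectorPose()
    x0 = [ref.incidence_deg, ref.hfov_deg, ref.vfov_deg, ref.aim_shift_tan]
    fit = least_squares(
        _reproject, x0, args=(screen, tuple(native_resolution_px), points),
        method="lm",
    )
    pose = ProjectorPose(*fit.x)
    rms = float(np.sqrt(np.mean(fit.fun**2)))
    return WarpModel(
        pose=pose,
        screen=screen,
        native_resolution_px=tuple(native_resolution_px),
        source_size_px=tuple(source_size_px),
        top_arc=top_arc,
        bottom_arc=bottom_arc,
        fit_rms_px=rms,
        calibration=points,
    )


def _check_arcs(top: Arc, bottom: Arc) -> None:
    uu = np.linspace(0, 1, 101)
    pt, pb = top.point(uu), bottom.point(uu)
    # matched-u points must keep a consistent vertical ordering (no crossing)
    dy = pb[:, 1] - pt[:, 1]
    if not (np.all(dy > 0) or np.all(dy < 0)):
        raise CalibrationError("top and bottom arcs cross: invalid calibration")
    if top.width_px <= bottom.width_px:
        # the projector-near edge images wider; the reverse means swapped edges
        raise CalibrationError(
            "top arc narrower than bottom: edges swapped or invalid calibration"
        )


def build_warp_map(model: WarpModel) -> WarpMap:
    """Ray-trace the fitted model through every output pixel.

    On-screen output pixels get continuous source coordinates following
    the wallpaper rule — source x proportional to surface arc length,
    source y proportional to surface height — so equal arc-length steps on
    the display surface receive equal source-pixel widths and the source
    aspect ratio is preserved on the surface.  Off-screen pixels are
    masked (rendered black by :func:`warp_image`).
    """
    W, H = model.native_resolution_px
    sw, sh = model.source_size_px
    xs, ys = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    pix = np.column_stack([xs.ravel(), ys.ravel()])
    s, h, on = geo.trace_projector_ray(pix, model.projection, model.screen)
    scr = model.screen
    u = s / scr.surface_width_cm + 0.5
    v = h / scr.surface_height_cm + 0.5
    src_x = np.where(on, u * (sw - 1), np.nan).reshape(H, W)
    src_y = np.where(on, v * (sh - 1), np.nan).reshape(H, W)
    return WarpMap(src_x, src_y, on.reshape(H, W), model)


def _as_float_image(img: np.ndarray, expect_size: tuple[int, int] | None) -> np.ndarray:
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3, 4):
        raise ValueError(f"expected gray/RGB/RGBA image, got shape {arr.shape}")
    if expect_size is not None:
        w, h = expect_size
        if arr.shape[0] != h or arr.shape[1] != w:
            raise ValueError(
                f"image is {arr.shape[1]}x{arr.shape[0]}, expected {w}x{h}"
            )
    return arr.astype(float)


def warp_image(img: np.ndarray, warp_map: WarpMap, interpolation: str = "bilinear"):
    """Resample a source image into the on-screen region of the raster.

    Off-screen pixels are exactly black (0).  ``interpolation`` is
    ``"bilinear"`` (default) or ``"nearest"`` — nearest avoids gray halos
    on binary masks and checkerboards.
    """
    arr = _as_float_image(img, warp_map.model.source_size_px)
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    H, W = warp_map.mask.shape
    out = np.zeros((H, W, arr.shape[2]))
    m = warp_map.mask
    coords = np.array([warp_map.source_y[m], warp_map.source_x[m]])
    for c in range(arr.shape[2]):
        out[:, :, c][m] = ndimage.map_coordinates(
            arr[:, :, c], coords, order=order, mode="nearest"
        )
    out = np.clip(out, 0, 255)
    if np.asarray(img).ndim == 2:
        out = out[:, :, 0]
    if np.asarray(img).dtype == np.uint8:
        return np.round(out).astype(np.uint8)
    return out


def unwarp_image(warped_img: np.ndarray, warp_map: WarpMap,
                 interpolation: str = "bilinear"):
    """Approximate inverse of :func:`warp_image` onto the source canvas.

    Each source pixel is mapped forward through the fitted model to its
    raster position and sampled there.  Source pixels whose raster
    position falls outside the lit region are flagged in the returned
    mask, not extrapolated.
    """
    model = warp_map.model
    arr = _as_float_image(warped_img, model.native_resolution_px)
    sw, sh = model.source_size_px
    scr = model.screen
    gx, gy = np.meshgrid(np.arange(sw, dtype=float), np.arange(sh, dtype=float))
    s = (gx.ravel() / (sw - 1) - 0.5) * scr.surface_width_cm
    h = (gy.ravel() / (sh - 1) - 0.5) * scr.surface_height_cm
    pix = geo.surface_to_pixel(s, h, model.projection, model.screen)
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    out = np.zeros((sh, sw, arr.shape[2]))
    coords = np.array([pix[:, 1], pix[:, 0]])
    W, H = model.native_resolution_px
    inside = (
        (pix[:, 0] >= 0) & (pix[:, 0] <= W - 1)
        & (pix[:, 1] >= 0) & (pix[:, 1] <= H - 1)
    )
    # flag source pixels whose sampling neighbourhood touches unlit raster
    lit = ndimage.map_coordinates(
        warp_map.mask.astype(float), coords, order=1, mode="constant"
    )
    inside &= lit > 0.999
    for c in range(arr.shape[2]):
        vals = ndimage.map_coordinates(arr[:, :, c], coords, order=order, mode="nearest")
        out[:, :, c] = np.where(inside, vals, 0.0).reshape(sh, sw)
    out = np.clip(out, 0, 255)
    mask = inside.reshape(sh, sw)
    if np.asarray(warped_img).ndim == 2:
        out = out[:, :, 0]
    return out, mask
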