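"""Optical geometry of the eye / curved-screen / projector system.

The display is a section of a cylinder (a "bore screen") positioned around
the observer's head inside an MRI scanner.  The projector cannot face the
screen head-on: its rays travel nearly parallel to the bore axis and strike
the screen at a grazing angle, which is why only a fraction of the native
raster lands on the display surface.  This module provides

* closed-form conversions between physical units, visual angles and canvas
  pixels for that geometry, and
* a forward ray tracer from projector pixels to cylinder-surface
  coordinates, which serves as the optical ground truth for the
  calibration-driven warp in :mod:`fullfield.warp`.

Conventions: angles cross API boundaries in degrees and are handled in
radians internally; physical coordinates are centimetres.  The world frame
has its origin at the screen-surface centre, ``x`` to the observer's right,
``y`` from the observer's eye toward the screen centre and ``z`` along the
bore away from the projector.  Surface coordinates ``(s, h)`` are
arc length along the cylinder circumference and height along the (tilted)
surface, both zero at the screen centre.  Visual angles are monocular, from
a single cyclopean eye point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "CM_PER_INCH",
    "ScreenGeometry",
    "ViewingGeometry",
    "ProjectorPose",
    "ProjectionGeometry",
    "SurfaceCoord",
    "CanvasSpec",
    "arc_length",
    "horizontal_fov_from_vertical",
    "cylinder_angular_width",
    "cylinder_angular_height",
    "pixels_per_degree",
    "eccentricity_to_radius_px",
    "radius_px_to_eccentricity",
    "trace_projector_ray",
    "screen_outline_pixels",
    "geometry_report",
    "load_geometry",
]

CM_PER_INCH = 2.54


class GeometryError(ValueError):
    """Raised for physically impossible geometry arguments."""


class OutOfFieldError(GeometryError):
    """Raised when an eccentricity falls beyond the screen edge."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenGeometry:
    """The physical cylindrical screen.

    Defaults describe an 11-inch-radius cylinder section subtending a 120
    degree chord angle, tilted 10 degrees relative to the bore axis, with a
    display surface of 58.5 cm (arc) x 44 cm (linear height).
    """

    radius_cm: float = 11.0 * CM_PER_INCH
    chord_angle_deg: float = 120.0
    tilt_deg: float = 10.0
    surface_width_cm: float | None = None
    surface_height_cm: float = 44.0

    def __post_init__(self):
        if self.radius_cm <= 0:
            raise GeometryError("radius_cm must be positive")
        if not 0 < self.chord_angle_deg < 360:
            raise GeometryError("chord_angle_deg must lie in (0, 360)")
        arc = arc_length(self.radius_cm, self.chord_angle_deg)
        if self.surface_width_cm is None:
            object.__setattr__(self, "surface_width_cm", arc)
        elif abs(self.surface_width_cm - arc) > 0.01 * arc:
            raise GeometryError(
                f"surface_width_cm={self.surface_width_cm:.2f} inconsistent with "
                f"radius x chord arc length {arc:.2f} (>1%)"
            )

    @property
    def half_chord_rad(self) -> float:
        return math.radians(self.chord_angle_deg) / 2


@dataclass(frozen=True)
class ViewingGeometry:
    """Cyclopean eye position on the mid-sagittal plane.

    ``eye_to_screen_cm`` is measured from the eye to the screen centre
    along the cylinder radius; head size and cushioning put it between
    13.5 and 16.5 cm, nominally 15 cm.
    """

    eye_to_screen_cm: float = 15.0

    def __post_init__(self):
        if self.eye_to_screen_cm <= 0:
            raise GeometryError("eye_to_screen_cm must be positive")

    def eye_offset_cm(self, screen: ScreenGeometry) -> float:
        """Distance of the eye from the cylinder axis."""
        if self.eye_to_screen_cm >= screen.radius_cm:
            raise GeometryError("eye must sit inside the cylinder")
        return screen.radius_cm - self.eye_to_screen_cm


@dataclass(frozen=True)
class ProjectorPose:
    """Virtual pinhole equivalent of the projector + mirror periscope.

    The mirror pair makes the projector appear to originate from a virtual
    point behind and below the bore.  We model that point on the bore axis,
    far enough back that the principal ray strikes the (untilted) bore wall
    at ``incidence_deg`` degrees, aimed at the screen-surface centre.  The
    frustum half-angles are free parameters of the physical installation.
    """

    # Defaults are the reference installation: incidence just over 18 deg,
    # frustum solved so the traced on-screen region spans 828 x 284 px of
    # the native 1024 x 768 raster.
    incidence_deg: float = 18.2
    hfov_deg: float = 50.4888096
    vfov_deg: float = 53.2146171
    aim_shift_tan: float = -0.0368620452  # vertical aim offset, tangent units

    def throw_cm(self, screen: ScreenGeometry) -> float:
        """Axial distance from the virtual source to the screen centre plane."""
        return screen.radius_cm / math.tan(math.radians(self.incidence_deg))


@dataclass(frozen=True)
class ProjectionGeometry:
    """Projector raster and its relation to the screen."""

    native_resolution_px: tuple[int, int] = (1024, 768)
    pose: ProjectorPose = field(default_factory=ProjectorPose)

    @property
    def incidence_deg(self) -> float:
        return self.pose.incidence_deg

    def effective_incidence_deg(self, screen: ScreenGeometry) -> float:
        """Grazing angle onto the tilted screen (incidence + tilt)."""
        return self.pose.incidence_deg + screen.tilt_deg


@dataclass(frozen=True)
class SurfaceCoord:
    """Point on the display surface: arc length ``s`` and height ``h``, cm."""

    s_cm: float
    h_cm: float


@dataclass(frozen=True)
class CanvasSpec:
    """A rectangular pixel canvas (the pre-warp stimulus canvas)."""

    width_px: int = 1024
    height_px: int = 768

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)


# ---------------------------------------------------------------------------
# closed-form operations
# ---------------------------------------------------------------------------


def arc_length(radius_cm: float, chord_angle_deg: float) -> float:
    """Arc length of a cylinder section: radius times angle in radians."""
    if radius_cm <= 0:
        raise GeometryError("radius must be positive")
    if not 0 <= chord_angle_deg <= 360:
        raise GeometryError("chord angle must lie in [0, 360] degrees")
    return radius_cm * math.radians(chord_angle_deg)


def horizontal_fov_from_vertical(vfov_deg: float, aspect: float) -> float:
    """Horizontal FOV of a perspective camera from its vertical FOV.

    For a pinhole camera, tan(h/2) = aspect * tan(v/2); a 105 degree
    vertical FOV at 4:3 gives a 120.2 degree horizontal FOV.
    """
    if not 0 < vfov_deg < 180:
        raise GeometryError("vfov must lie in (0, 180) degrees")
    if aspect <= 0:
        raise GeometryError("aspect must be positive")
    return math.degrees(2 * math.atan(aspect * math.tan(math.radians(vfov_deg) / 2)))


def cylinder_angular_width(screen: ScreenGeometry, view: ViewingGeometry) -> float:
    """Horizontal visual angle of the screen, in degrees.

    The eye sits on the mid-sagittal plane ``eye_offset`` from the cylinder
    axis, facing the screen centre.  Each lateral screen edge lies at
    cylinder angle +/- chord/2; the subtended angle is

        2 * atan2(r sin(chord/2), r cos(chord/2) - eye_offset)

    which exceeds 180 degrees once the eye passes the chord plane.
    """
    half = screen.half_chord_rad
    e = view.eye_offset_cm(screen)
    r = screen.radius_cm
    return math.degrees(2 * math.atan2(r * math.sin(half), r * math.cos(half) - e))


def cylinder_angular_height(screen: ScreenGeometry, view: ViewingGeometry) -> float:
    """Vertical visual angle of the screen, in degrees (approximate).

    The vertical section of the cylindrical surface is a straight segment
    of length ``surface_height_cm``, tilted by ``tilt_deg`` about the
    screen centre.  The eye is placed on the radius through the screen
    centre; head position relative to the tilt pivot is idealised, so this
    is an envelope figure rather than an exact per-subject value.
    """
    d = view.eye_to_screen_cm
    half_h = screen.surface_height_cm / 2
    tau = math.radians(screen.tilt_deg)
    rise = half_h * math.cos(tau)
    shift = half_h * math.sin(tau)
    if d <= shift:
        raise GeometryError("eye lies beyond the tilted screen edge")
    up = math.atan(rise / (d - shift))
    down = math.atan(rise / (d + shift))
    return math.degrees(up + down)


def pixels_per_degree(pixels: float, degrees: float) -> float:
    """Pixel density across an angular extent (simple ratio)."""
    if degrees <= 0:
        raise GeometryError("degrees must be positive")
    return pixels / degrees


def eccentricity_to_radius_px(
    ecc_deg: float | np.ndarray,
    view: ViewingGeometry | None = None,
    canvas: CanvasSpec | None = None,
    screen: ScreenGeometry | None = None,
) -> float | np.ndarray:
    """Map eccentricity (deg) to a radius on the source canvas (px).

    The source canvas is pasted onto the cylinder like wallpaper, so equal
    canvas pixels cover equal surface arc length.  Eccentricity is mapped
    proportionally to arc length (the equidistant mapping), normalised so
    the canvas half-width lands at the screen's half angular width for the
    given viewing distance.  The mapping is linear, hence trivially
    invertible; see :func:`radius_px_to_eccentricity`.
    """
    screen = screen or ScreenGeometry()
    view = view or ViewingGeometry()
    canvas = canvas or CanvasSpec()
    half_width_deg = cylinder_angular_width(screen, view) / 2
    ecc = np.asarray(ecc_deg, dtype=float)
    if np.any(ecc < 0) or np.any(ecc > half_width_deg + 1e-9):
        raise OutOfFieldError(
            f"eccentricity outside [0, {half_width_deg:.2f}] degrees"
        )
    out = ecc / half_width_deg * (canvas.width_px / 2.0)
    return float(out) if np.isscalar(ecc_deg) else out


def radius_px_to_eccentricity(
    radius_px: float | np.ndarray,
    view: ViewingGeometry | None = None,
    canvas: CanvasSpec | None = None,
    screen: ScreenGeometry | None = None,
) -> float | np.ndarray:
    """Inverse of :func:`eccentricity_to_radius_px` on its range."""
    screen = screen or ScreenGeometry()
    view = view or ViewingGeometry()
    canvas = canvas or CanvasSpec()
    half_width_deg = cylinder_angular_width(screen, view) / 2
    r = np.asarray(radius_px, dtype=float)
    out = r / (canvas.width_px / 2.0) * half_width_deg
    return float(out) if np.isscalar(radius_px) else out


# ---------------------------------------------------------------------------
# ray tracing
# ---------------------------------------------------------------------------


def _frames(screen: ScreenGeometry, pose: ProjectorPose):
    """World-frame vectors: tilted cylinder axis and projector camera basis."""
    tau = math.radians(screen.tilt_deg)
    r = screen.radius_cm
    # tilted cylinder: axis direction and a point on the axis
    axis_dir = np.array([0.0, -math.sin(tau), math.cos(tau)])
    axis_pt = np.array([0.0, -r * math.cos(tau), -r * math.sin(tau)])
    y_t = np.array([0.0, math.cos(tau), math.sin(tau)])  # radial dir at centre
    # virtual projector on the untilted bore axis, aimed at the screen centre
    z0 = pose.throw_cm(screen)
    position = np.array([0.0, -r, -z0])
    w = -position / np.linalg.norm(position)  # principal axis
    u = np.array([1.0, 0.0, 0.0])
    v = np.cross(w, u)
    return axis_dir, axis_pt, y_t, position, u, v, w


def _pixel_dirs(px: np.ndarray, py: np.ndarray, proj: ProjectionGeometry):
    W, H = proj.native_resolution_px
    pose = proj.pose
    th = math.tan(math.radians(pose.hfov_deg) / 2)
    tv = math.tan(math.radians(pose.vfov_deg) / 2)
    un = (2 * (px + 0.5) / W - 1) * th
    vn = (1 - 2 * (py + 0.5) / H) * tv + pose.aim_shift_tan
    return un, vn


def trace_projector_ray(
    pixel_xy,
    proj: ProjectionGeometry | None = None,
    screen: ScreenGeometry | None = None,
):
    """Trace projector pixel(s) to the tilted cylindrical screen.

    Parameters
    ----------
    pixel_xy : (2,) or (n, 2) array-like
        Projector pixel coordinates (x right, y down, origin at the
        top-left pixel corner grid; pixel centres at integer + 0.5 are
        handled internally).
    proj, screen : optional
        Default to the reference installation.

    Returns
    -------
    s_cm, h_cm, on_screen : arrays (scalars for a single pixel)
        Surface coordinates of the intersection and an on-screen flag.
        Rays that miss the display surface (or the cylinder entirely) are
        flagged off-screen; their coordinates are NaN.
    """
    proj = proj or ProjectionGeometry()
    screen = screen or ScreenGeometry()
    pix = np.atleast_2d(np.asarray(pixel_xy, dtype=float))
    single = np.asarray(pixel_xy).ndim == 1

    axis_dir, axis_pt, y_t, P, u, v, w = _frames(screen, proj.pose)
    un, vn = _pixel_dirs(pix[:, 0], pix[:, 1], proj)
    dirs = (w[None, :] + un[:, None] * u[None, :] + vn[:, None] * v[None, :])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    m0 = P - axis_pt
    d_ax = dirs @ axis_dir
    d_perp = dirs - d_ax[:, None] * axis_dir[None, :]
    m_ax = m0 @ axis_dir
    m_perp = m0 - m_ax * axis_dir

    a = np.einsum("ij,ij->i", d_perp, d_perp)
    b = 2 * d_perp @ m_perp
    c = m_perp @ m_perp - screen.radius_cm**2
    disc = b * b - 4 * a * c

    n = pix.shape[0]
    s_out = np.full(n, np.nan)
    h_out = np.full(n, np.nan)
    on = np.zeros(n, dtype=bool)

    ok = (disc > 0) & (a > 1e-12)
    if np.any(ok):
        sq = np.sqrt(disc[ok])
        t1 = (-b[ok] - sq) / (2 * a[ok])
        t2 = (-b[ok] + sq) / (2 * a[ok])
        x_t = np.array([1.0, 0.0, 0.0])
        half = screen.half_chord_rad
        half_h = screen.surface_height_cm / 2
        idx = np.flatnonzero(ok)
        for t in (t1, t2):  # nearer intersection wins if it is on-screen
            valid = t > 1e-9
            p = P[None, :] + t[:, None] * dirs[idx]
            rel = p - axis_pt[None, :]
            h = rel @ axis_dir
            phi = np.arctan2(rel @ x_t, rel @ y_t)
            hit = valid & (np.abs(phi) <= half) & (np.abs(h) <= half_h) & ~on[idx]
            tgt = idx[hit]
            s_out[tgt] = screen.radius_cm * phi[hit]
            h_out[tgt] = h[hit]
            on[tgt] = True

    if single:
        return float(s_out[0]), float(h_out[0]), bool(on[0])
    return s_out, h_out, on


def surface_to_pixel(
    s_cm,
    h_cm,
    proj: ProjectionGeometry | None = None,
    screen: ScreenGeometry | None = None,
) -> np.ndarray:
    """Project surface coordinates into projector pixel coordinates.

    Exact inverse of :func:`trace_projector_ray` for on-screen points; used
    to synthesise calibration measurements and as the warp oracle.
    """
    proj = proj or ProjectionGeometry()
    screen = screen or ScreenGeometry()
    axis_dir, axis_pt, y_t, P, u, v, w = _frames(screen, proj.pose)
    s = np.atleast_1d(np.asarray(s_cm, dtype=float))
    h = np.atleast_1d(np.asarray(h_cm, dtype=float))
    phi = s / screen.radius_cm
    x_t = np.array([1.0, 0.0, 0.0])
    radial = np.sin(phi)[:, None] * x_t[None, :] + np.cos(phi)[:, None] * y_t[None, :]
    p = axis_pt[None, :] + screen.radius_cm * radial + h[:, None] * axis_dir[None, :]
    rel = p - P[None, :]
    depth = rel @ w
    un = (rel @ u) / depth
    vn = (rel @ v) / depth
    W, H = proj.native_resolution_px
    pose = proj.pose
    th = math.tan(math.radians(pose.hfov_deg) / 2)
    tv = math.tan(math.radians(pose.vfov_deg) / 2)
    px = (un / th + 1) / 2 * W - 0.5
    py = (1 - (vn - pose.aim_shift_tan) / tv) / 2 * H - 0.5
    return np.column_stack([px, py])


def screen_outline_pixels(
    proj: ProjectionGeometry | None = None,
    screen: ScreenGeometry | None = None,
    n: int = 201,
) -> dict[str, np.ndarray]:
    """Projector-pixel coordinates of the four screen edges.

    Edges are named from the projected source image's point of view:
    ``top`` is the screen edge on which the source image's top row lands
    (the edge nearer the projector, which images wider), ``bottom`` the
    opposite edge; ``left``/``right`` are the lateral edges.
    """
    proj = proj or ProjectionGeometry()
    screen = screen or ScreenGeometry()
    w2 = screen.surface_width_cm / 2
    h2 = screen.surface_height_cm / 2
    ss = np.linspace(-w2, w2, n)
    hh = np.linspace(-h2, h2, n)
    return {
        "top": surface_to_pixel(ss, np.full(n, -h2), proj, screen),
        "bottom": surface_to_pixel(ss, np.full(n, h2), proj, screen),
        "left": surface_to_pixel(np.full(n, -w2), hh, proj, screen),
        "right": surface_to_pixel(np.full(n, w2), hh, proj, screen),
    }


def active_region_px(
    proj: ProjectionGeometry | None = None,
    screen: ScreenGeometry | None = None,
) -> tuple[float, float]:
    """Bounding extent (width, height) of on-screen projector pixels."""
    outline = screen_outline_pixels(proj, screen)
    pts = np.vstack(list(outline.values()))
    w = pts[:, 0].max() - pts[:, 0].min()
    h = pts[:, 1].max() - pts[:, 1].min()
    return float(w), float(h)


# ---------------------------------------------------------------------------
# reporting / configuration I/O
# ---------------------------------------------------------------------------


def geometry_report(
    screen: ScreenGeometry | None = None,
    proj: ProjectionGeometry | None = None,
    distances_cm: tuple[float, ...] = (13.5, 15.0, 16.5),
) -> dict:
    """Summary of angular extents and pixel densities of the installation."""
    screen = screen or ScreenGeometry()
    proj = proj or ProjectionGeometry()
    aw, ah = active_region_px(proj, screen)
    rows = []
    for d in distances_cm:
        view = ViewingGeometry(eye_to_screen_cm=d)
        width = cylinder_angular_width(screen, view)
        height = cylinder_angular_height(screen, view)
        rows.append(
            {
                "eye_to_screen_cm": d,
                "angular_width_deg": round(width, 1),
                "angular_height_deg": round(height, 1),
                "px_per_deg_width": round(pixels_per_degree(aw, width), 1),
                "px_per_deg_height": round(pixels_per_degree(ah, height), 1),
            }
        )
    return {
        "arc_length_cm": round(arc_length(screen.radius_cm, screen.chord_angle_deg), 1),
        "surface_cm": (screen.surface_width_cm, screen.surface_height_cm),
        "active_region_px": (round(aw), round(ah)),
        "effective_incidence_deg": round(proj.effective_incidence_deg(screen), 1),
        "by_distance": rows,
    }


def load_geometry(path) -> tuple[ScreenGeometry, ViewingGeometry, ProjectionGeometry]:
    """Read screen/viewing/projection geometry from a YAML or JSON file."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    screen = ScreenGeometry(**cfg.get("screen", {}))
    view = ViewingGeometry(**cfg.get("viewing", {}))
    pcfg = dict(cfg.get("projection", {}))
    pose = ProjectorPose(**pcfg.pop("pose", {}))
    if "native_resolution_px" in pcfg:
        pcfg["native_resolution_px"] = tuple(pcfg["native_resolution_px"])
    proj = ProjectionGeometry(pose=pose, **pcfg)
    return screen, view, proj
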