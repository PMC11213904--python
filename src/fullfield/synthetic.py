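"""Synthetic fixtures: stimuli, calibrations and simulated BOLD.

Everything the pipeline consumes can be generated here, seed-
deterministically and without any downloads: procedural scene / face /
object imagery (schematic drawings standing in for copyrighted
photographs), ground-truth optical calibrations sampled from the ray
tracer, and simulated voxel time series with condition-specific percent-
signal-change amplitudes, polynomial drift, AR(1) noise and planted
eccentricity tuning.

The BOLD generative model mirrors the GLM's assumptions:

    y = baseline * (1 + sum_c beta_c x_c(t) / 100) + drift(t) + e(t),
    e(t) = phi * e(t-1) + N(0, sigma^2)

with x_c the HRF-convolved, peak-normalised boxcar of condition c, so a
planted beta_c is the condition's amplitude in percent signal change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from fullfield import geometry as geo
from fullfield.analysis import BOLDSeries, DesignMatrix, _convolved_regressor
from fullfield.geometry import ProjectionGeometry, ProjectorPose, ScreenGeometry
from fullfield.warp import CalibrationPoints

__all__ = [
    "SimSpec",
    "synth_bold",
    "synth_retinotopic_population",
    "synth_calibration",
    "synth_images",
    "CANVAS_SIZE",
]

CANVAS_SIZE = (1024, 768)


@dataclass(frozen=True)
class SimSpec:
    """Simulated-population description.

    ``amplitudes`` is voxel x condition in percent signal change; noise
    is AR(1) with innovation ``sigma`` and coefficient ``phi``; drift is
    a random Legendre polynomial of order ``drift_order`` (coefficients
    scaled by ``drift_scale`` baseline units).
    """

    amplitudes: np.ndarray
    condition_labels: tuple[str, ...]
    sigma: float = 1.0
    phi: float = 0.3
    drift_order: int = 2
    drift_scale: float = 0.5
    baseline: float = 100.0
    seed: int = 0
    preferred: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        amp = np.asarray(self.amplitudes, dtype=float)
        if not np.isfinite(amp).all():
            raise ValueError("amplitudes must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1 for a stationary AR(1)")
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_voxels(self) -> int:
        return self.amplitudes.shape[0]


def synth_bold(
    spec: SimSpec,
    events: pd.DataFrame,
    tr_s: float = 2.0,
    n_scans: int | None = None,
    rest_labels: tuple[str, ...] = ("rest", "fixation"),
) -> tuple[BOLDSeries, DesignMatrix]:
    """Simulate voxel x time BOLD for a run's events table.

    Returns the series together with the design matrix used to build it
    (condition columns in sorted label order, matching
    :func:`fullfield.analysis.build_design_matrix`).
    """
    ev = events[~events["trial_type"].isin(rest_labels)]
    conditions = sorted(ev["trial_type"].unique())
    if list(conditions) != sorted(spec.condition_labels):
        raise ValueError("events conditions do not match the SimSpec labels")
    if n_scans is None:
        end = (ev["onset"] + ev["duration"]).max()
        n_scans = int(np.ceil(end / tr_s)) + 3
    cols = [
        _convolved_regressor(
            ev.loc[ev["trial_type"] == c, "onset"].values,
            ev.loc[ev["trial_type"] == c, "duration"].values,
            tr_s,
            n_scans,
        )
        for c in conditions
    ]
    X = np.column_stack(cols)
    # amplitudes arrive in spec.condition_labels order; align to sorted
    order = [list(spec.condition_labels).index(c) for c in conditions]
    amp = spec.amplitudes[:, order]

    rng = np.random.default_rng(spec.seed)
    nv = spec.n_voxels
    signal = spec.baseline * (1.0 + amp @ X.T / 100.0)

    t = np.linspace(-1, 1, n_scans)
    drift = np.zeros((nv, n_scans))
    for k in range(1, spec.drift_order + 1):
        coef = rng.normal(0.0, spec.drift_scale, size=nv)
        drift += coef[:, None] * np.polynomial.legendre.Legendre.basis(k)(t)[None, :]

    noise = np.zeros((nv, n_scans))
    if spec.sigma > 0:
        innov = rng.normal(0.0, spec.sigma, size=(nv, n_scans))
        noise[:, 0] = innov[:, 0] / np.sqrt(1 - spec.phi**2)
        for i in range(1, n_scans):
            noise[:, i] = spec.phi * noise[:, i - 1] + innov[:, i]

    data = signal + drift + noise
    design = DesignMatrix(
        X=np.column_stack([X, np.ones(n_scans)]),
        labels=conditions + ["intercept"],
        condition_labels=conditions,
    )
    return BOLDSeries(data, tr_s=tr_s), design


def synth_retinotopic_population(
    n_voxels: int,
    bands: tuple[str, ...] = (
        "ecc1_center", "ecc2", "ecc3", "ecc4", "ecc5_farperiphery",
    ),
    margin: float = 1.0,
    base_amplitude: float = 1.0,
    sigma: float = 1.0,
    phi: float = 0.3,
    seed: int = 0,
    proportions: np.ndarray | None = None,
) -> SimSpec:
    """Population with one planted preferred eccentricity band per voxel.

    Each voxel responds ``base_amplitude`` PSC to every band and
    ``base_amplitude + margin`` to its preferred band; preferred-band
    labels are stored as ground truth on ``spec.preferred``.
    """
    rng = np.random.default_rng(seed)
    k = len(bands)
    if proportions is None:
        proportions = np.full(k, 1 / k)
    proportions = np.asarray(proportions, dtype=float)
    preferred = rng.choice(k, size=n_voxels, p=proportions / proportions.sum())
    amp = np.full((n_voxels, k), base_amplitude)
    amp[np.arange(n_voxels), preferred] += margin
    return SimSpec(
        amplitudes=amp,
        condition_labels=tuple(bands),
        sigma=sigma,
        phi=phi,
        seed=int(rng.integers(2**31 - 1)),
        preferred=preferred,
    )


def synth_calibration(
    proj: ProjectionGeometry | None = None,
    screen: ScreenGeometry | None = None,
    noise_px: float = 0.0,
    rng: np.random.Generator | None = None,
    n_per_edge: int = 3,
) -> CalibrationPoints:
    """Sample screen-outline calibration points from the ray-traced truth.

    Points lie at evenly spaced arc-length fractions along the top and
    bottom screen edges (endpoints included), plus isotropic Gaussian
    pixel noise of ``noise_px``.  Raises if the pose leaves any sampled
    point outside the raster (no screen intersection to measure).
    """
    proj = proj or ProjectionGeometry()
    screen = screen or ScreenGeometry()
    rng = rng or np.random.default_rng(0)
    w2, h2 = screen.surface_width_cm / 2, screen.surface_height_cm / 2
    ss = np.linspace(-w2, w2, n_per_edge)
    top = geo.surface_to_pixel(ss, np.full(n_per_edge, -h2), proj, screen)
    bottom = geo.surface_to_pixel(ss, np.full(n_per_edge, h2), proj, screen)
    W, H = proj.native_resolution_px
    pts = np.vstack([top, bottom])
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > W - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > H - 1):
        raise ValueError("pose throws screen edges outside the raster")
    if noise_px > 0:
        top = top + rng.normal(0, noise_px, top.shape)
        bottom = bottom + rng.normal(0, noise_px, bottom.shape)
    return CalibrationPoints(top_edge=top, bottom_edge=bottom)


def random_pose(rng: np.random.Generator) -> ProjectorPose:
    """Plausible installation jitter around the reference pose."""
    ref = ProjectorPose()
    return ProjectorPose(
        incidence_deg=ref.incidence_deg + rng.uniform(-1.0, 1.0),
        hfov_deg=ref.hfov_deg + rng.uniform(-2.0, 2.0),
        vfov_deg=ref.vfov_deg + rng.uniform(-2.0, 2.0),
        aim_shift_tan=ref.aim_shift_tan + rng.uniform(-0.01, 0.01),
    )


# ---------------------------------------------------------------------------
# procedural imagery
# ---------------------------------------------------------------------------


def _pink_noise(rng, shape, slope=1.5):
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spec = np.fft.fft2(rng.standard_normal(shape)) / f**slope
    out = np.real(np.fft.ifft2(spec))
    out -= out.min()
    return out / max(out.max(), 1e-12)


def _draw_scene(rng, size):
    """Gradient 'room' with a horizon, walls and box furniture."""
    w, h = size
    img = Image.new("L", size)
    d = ImageDraw.Draw(img)
    horizon = int(h * rng.uniform(0.45, 0.6))
    for y in range(h):
        if y < horizon:
            v = 200 - int(80 * y / max(horizon, 1))
        else:
            v = 70 + int(100 * (y - horizon) / max(h - horizon, 1))
        d.line([(0, y), (w, y)], fill=v)
    # side walls (perspective trapezoids)
    lw = int(w * rng.uniform(0.12, 0.25))
    d.polygon([(0, 0), (lw, int(horizon * 0.5)), (lw, h), (0, h)],
              fill=int(rng.integers(60, 120)))
    d.polygon([(w, 0), (w - lw, int(horizon * 0.5)), (w - lw, h), (w, h)],
              fill=int(rng.integers(60, 120)))
    for _ in range(int(rng.integers(4, 9))):  # furniture boxes
        bw, bh = int(rng.integers(w // 12, w // 4)), int(rng.integers(h // 10, h // 3))
        x0 = int(rng.integers(lw, w - lw - bw))
        y0 = int(rng.integers(horizon - bh // 2, h - bh))
        d.rectangle([x0, y0, x0 + bw, y0 + bh], fill=int(rng.integers(30, 220)),
                    outline=20)
    arr = np.asarray(img, dtype=float)
    arr = 0.85 * arr + 0.15 * 255 * _pink_noise(rng, (size[1], size[0]))
    return arr


def _draw_face(rng, size, male: bool):
    """Schematic face; 'male' variants get short hair and a wider jaw."""
    w, h = size
    img = Image.new("L", size, color=230)
    d = ImageDraw.Draw(img)
    cx, cy = w / 2, h / 2
    fw = w * rng.uniform(0.55, 0.7) * (1.08 if male else 1.0)
    fh = h * rng.uniform(0.7, 0.85)
    skin = int(rng.integers(150, 210))
    d.ellipse([cx - fw / 2, cy - fh / 2, cx + fw / 2, cy + fh / 2], fill=skin,
              outline=60, width=2)
    if male:
        d.rectangle([cx - fw / 2, cy - fh / 2, cx + fw / 2, cy - fh * 0.3],
                    fill=int(rng.integers(30, 90)))
    else:
        d.ellipse([cx - fw * 0.62, cy - fh * 0.55, cx + fw * 0.62, cy - fh * 0.05],
                  outline=int(rng.integers(30, 90)), width=int(max(2, w * 0.04)))
    ey = cy - fh * 0.1
    ex = fw * rng.uniform(0.16, 0.22)
    er = w * rng.uniform(0.03, 0.05)
    for sx in (-1, 1):
        d.ellipse([cx + sx * ex - er, ey - er, cx + sx * ex + er, ey + er], fill=30)
    d.line([(cx, cy - fh * 0.02), (cx, cy + fh * 0.12)], fill=70,
           width=int(max(1, w * 0.02)))
    mw = fw * rng.uniform(0.2, 0.35)
    d.arc([cx - mw, cy + fh * 0.12, cx + mw, cy + fh * 0.3], 20, 160, fill=50,
          width=int(max(2, w * 0.02)))
    return np.asarray(img, dtype=float)


def _draw_object(rng, size):
    """Small inanimate object: random polygon / ellipse compound."""
    w, h = size
    img = Image.new("L", size, color=230)
    d = ImageDraw.Draw(img)
    kind = rng.integers(3)
    fill = int(rng.integers(40, 200))
    if kind == 0:  # mug-like
        d.rectangle([w * 0.3, h * 0.3, w * 0.7, h * 0.8], fill=fill, outline=30)
        d.ellipse([w * 0.62, h * 0.4, w * 0.85, h * 0.65], outline=30, width=4)
    elif kind == 1:  # polygon blob
        n = int(rng.integers(5, 9))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        rad = rng.uniform(0.2, 0.45, n)
        pts = [(w / 2 + np.cos(a) * r * w, h / 2 + np.sin(a) * r * h)
               for a, r in zip(ang, rad)]
        d.polygon(pts, fill=fill, outline=30)
    else:  # stacked shapes
        d.ellipse([w * 0.25, h * 0.45, w * 0.75, h * 0.85], fill=fill, outline=30)
        d.rectangle([w * 0.4, h * 0.15, w * 0.6, h * 0.5],
                    fill=int(rng.integers(40, 200)), outline=30)
    return np.asarray(img, dtype=float)


def synth_images(
    kind: str,
    n: int,
    seed: int = 0,
    size: tuple[int, int] | None = None,
) -> list[np.ndarray]:
    """Procedural stimulus pool: ``scene``, ``face`` or ``object``.

    Scenes render at the full canvas; faces/objects default to 256 x 256
    patches (they get resized on placement).  Face pools alternate
    male/female variants, so a pool of 58 is half male.  Deterministic
    per (kind, n, seed).
    """
    if kind not in ("scene", "face", "object"):
        raise ValueError("kind must be scene|face|object")
    size = size or (CANVAS_SIZE if kind == "scene" else (256, 256))
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        if kind == "scene":
            out.append(_draw_scene(rng, size))
        elif kind == "face":
            out.append(_draw_face(rng, size, male=i % 2 == 0))
        else:
            out.append(_draw_object(rng, size))
    return out
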