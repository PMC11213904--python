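"""Stimulus generators on the canonical 1024 x 768 pre-warp canvas.

Every condition class used with the wide-field display is built here:
flickering polar-checkerboard eccentricity rings for retinotopic mapping,
phase-scrambled counterparts of scene images, rescaled-and-padded
"postcard" versions, central artificial scotomas, eccentricity-scaled
face/object item arrays, and luminance-histogram equating across a
stimulus set.  All generators are pure functions of their spec and seed;
identical seeds reproduce byte-identical images.

Eccentricity-to-pixel conversion follows the equidistant wallpaper
mapping of :func:`fullfield.geometry.eccentricity_to_radius_px` at the
nominal 15 cm viewing distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from fullfield.geometry import (
    CanvasSpec,
    OutOfFieldError,
    ViewingGeometry,
    eccentricity_to_radius_px,
)

__all__ = [
    "RingSpec",
    "ScotomaSpec",
    "PostcardSpec",
    "ArrayLayoutSpec",
    "RETINOTOPY_BANDS_DEG",
    "SCOTOMA_DIAMETERS_DEG",
    "SCOTOMA_DIAMETERS_MAIN_TEXT_DEG",
    "make_ring_checkerboard",
    "phase_scramble",
    "make_postcard",
    "apply_scotoma",
    "layout_item_array",
    "match_luminance",
    "build_scotoma_set",
    "LayoutError",
]

#: The five eccentricity bands (inner, outer radius in visual degrees):
#: a centre disc of 1.8 deg radius, then 2.0-5.6, 6.3-16.5, 18.5-50.3,
#: and everything beyond 55.3 deg.
RETINOTOPY_BANDS_DEG: tuple[tuple[float, float], ...] = (
    (0.0, 1.8),
    (2.0, 5.6),
    (6.3, 16.5),
    (18.5, 50.3),
    (55.3, None),
)

#: Central scotoma diameters (deg).  The protocol tables give
#: {0, 29, 58, 88, 140}; running text rounds two of them to {30, 138}.
SCOTOMA_DIAMETERS_DEG: tuple[float, ...] = (0.0, 29.0, 58.0, 88.0, 140.0)
SCOTOMA_DIAMETERS_MAIN_TEXT_DEG: tuple[float, ...] = (0.0, 30.0, 58.0, 88.0, 138.0)

FLICKER_STATES = ("black-white", "white-black", "random-color")


class LayoutError(RuntimeError):
    """Non-overlapping item placement could not be satisfied."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """One eccentricity-band checkerboard condition.

    ``outer_deg`` of ``None`` means "to the edge of the canvas" (the
    far-periphery band).  ``flicker_hz`` is the state alternation rate.
    """

    inner_deg: float
    outer_deg: float | None
    flicker_state: str = "black-white"
    flicker_hz: float = 4.0

    def __post_init__(self):
        if self.outer_deg is not None and self.inner_deg >= self.outer_deg:
            raise ValueError("inner_deg must be < outer_deg")
        if self.flicker_state not in FLICKER_STATES:
            raise ValueError(f"flicker_state must be one of {FLICKER_STATES}")


@dataclass(frozen=True)
class ScotomaSpec:
    """Central mask of ``diameter_deg`` visual degrees, filled with ``fill``."""

    diameter_deg: float
    fill: float = 128.0

    def __post_init__(self):
        if self.diameter_deg < 0:
            raise ValueError("diameter_deg must be >= 0")


@dataclass(frozen=True)
class PostcardSpec:
    """Rescale a whole canvas image and centre it with padding.

    The default 205 x 154 target is the "postcard" size (44 deg wide);
    the 171 x 129 bounding-box variant is used for faces/objects.
    """

    target_size_px: tuple[int, int] = (205, 154)
    pad_value: float = 128.0
    canvas: CanvasSpec = field(default_factory=CanvasSpec)

    def __post_init__(self):
        tw, th = self.target_size_px
        if tw > self.canvas.width_px or th > self.canvas.height_px:
            raise ValueError("target larger than canvas")


@dataclass(frozen=True)
class ArrayLayoutSpec:
    """Item-array layout: per-ring counts, item diameters and ring radii.

    Item size grows with eccentricity to counter cortical magnification:
    3 items of 113 px on the inner ring, 6 of 178 px on the middle ring
    and 4 of 295 px at the canvas corners.  ``jitter_px`` is the maximum
    absolute x/y jitter applied per item; ``corner_outer_ring`` pins the
    outer items to the four corners instead of a circle.
    """

    counts: tuple[int, ...] = (3, 6, 4)
    diameters_px: tuple[int, ...] = (113, 178, 295)
    ring_radii_px: tuple[float, ...] = (100.0, 275.0)
    corner_inset_px: float = 130.0
    jitter_px: float = 8.0
    corner_outer_ring: bool = True
    canvas: CanvasSpec = field(default_factory=CanvasSpec)
    max_retries: int = 200

    def __post_init__(self):
        if len(self.counts) != len(self.diameters_px):
            raise ValueError("counts and diameters_px must align")
        if any(np.diff(self.diameters_px) <= 0):
            raise ValueError("diameters must strictly increase with eccentricity")

    @property
    def total_items(self) -> int:
        return int(sum(self.counts))


# ---------------------------------------------------------------------------
# canvas helpers
# ---------------------------------------------------------------------------


def _radius_grid(canvas: CanvasSpec) -> np.ndarray:
    cx, cy = canvas.center
    x = np.arange(canvas.width_px) - cx + 0.5
    y = np.arange(canvas.height_px) - cy + 0.5
    return np.hypot(x[None, :], y[:, None])


def _theta_grid(canvas: CanvasSpec) -> np.ndarray:
    cx, cy = canvas.center
    x = np.arange(canvas.width_px) - cx + 0.5
    y = np.arange(canvas.height_px) - cy + 0.5
    return np.arctan2(y[:, None], x[None, :])


def _band_radii_px(spec: RingSpec, view: ViewingGeometry, canvas: CanvasSpec):
    r_in = eccentricity_to_radius_px(spec.inner_deg, view, canvas)
    if spec.outer_deg is None:
        r_out = math.hypot(canvas.width_px, canvas.height_px) / 2
    else:
        r_out = eccentricity_to_radius_px(spec.outer_deg, view, canvas)
    return r_in, r_out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def make_ring_checkerboard(
    spec: RingSpec,
    view: ViewingGeometry | None = None,
    canvas: CanvasSpec | None = None,
    phase: int = 0,
    orientation_band: str | None = None,
    n_angular: int = 24,
    n_radial_per_octave: int = 2,
    background: float = 128.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Polar checkerboard confined to an eccentricity band.

    Checks subdivide the band log-radially (constant number of angular
    sectors, radial edges in geometric progression) so check size scales
    with eccentricity.  ``phase`` flips check parity: even/odd phases
    realise the black-white and white-black flicker states; the
    ``random-color`` state colours each check from ``rng``.  Passing
    ``orientation_band`` = ``"horizontal"``/``"vertical"`` restricts the
    pattern to a meridian wedge (for meridian-mapping conditions).

    Returns a float image; grayscale (H, W) for black/white states, RGB
    (H, W, 3) for the random-colour state.
    """
    view = view or ViewingGeometry()
    canvas = canvas or CanvasSpec()
    try:
        r_in, r_out = _band_radii_px(spec, view, canvas)
    except OutOfFieldError as err:
        raise OutOfFieldError(f"ring band outside the screen: {err}") from err
    rr = _radius_grid(canvas)
    tt = _theta_grid(canvas)
    band = (rr >= r_in) & (rr < r_out)
    if orientation_band is not None:
        half = math.radians(20.0)
        if orientation_band == "horizontal":
            band &= (np.abs(tt) < half) | (np.abs(np.abs(tt) - math.pi) < half)
        elif orientation_band == "vertical":
            band &= np.abs(np.abs(tt) - math.pi / 2) < half
        else:
            raise ValueError("orientation_band must be 'horizontal' or 'vertical'")

    r0 = max(r_in, 4.0)  # innermost radial edge; centre disc is one check
    k = np.zeros_like(rr, dtype=int)
    inside = rr >= r0
    ratio = 2.0 ** (1.0 / n_radial_per_octave)
    k[inside] = 1 + np.floor(np.log(rr[inside] / r0) / np.log(ratio)).astype(int)
    ang = np.floor((tt + math.pi) / (2 * math.pi) * n_angular).astype(int)
    parity = (k + ang + phase) % 2

    state = spec.flicker_state
    if state == "random-color":
        rng = rng or np.random.default_rng(0)
        h, w = parity.shape
        img = np.full((h, w, 3), background, dtype=float)
        # colour per (radial, angular) check cell
        cell = k * n_angular + ang
        ncell = int(cell.max()) + 1
        lut = rng.integers(0, 256, size=(ncell, 3)).astype(float)
        img[band] = lut[cell[band]]
        return img
    img = np.full(parity.shape, background, dtype=float)
    black_first = state == "black-white"
    vals = (0.0, 255.0) if black_first else (255.0, 0.0)
    img[band] = np.where(parity[band] == 0, vals[0], vals[1])
    return img


def flicker_frames(
    spec: RingSpec,
    frame_rate_hz: float,
    duration_s: float,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> list[np.ndarray]:
    """Frame sequence cycling contrast states at ``spec.flicker_hz``."""
    rng = rng or np.random.default_rng(0)
    n = int(round(frame_rate_hz * duration_s))
    frames = []
    cycle = ("black-white", "white-black", "random-color")
    for i in range(n):
        state = cycle[int(i * spec.flicker_hz / frame_rate_hz) % len(cycle)]
        s = RingSpec(spec.inner_deg, spec.outer_deg, state, spec.flicker_hz)
        frames.append(make_ring_checkerboard(s, rng=rng, **kwargs))
    return frames


def phase_scramble(
    img: np.ndarray,
    rng: np.random.Generator,
    magnitude: float = 1.0,
    share_channels: bool = True,
) -> np.ndarray:
    """Randomise the phase spectrum while preserving the amplitude spectrum.

    Random phase offsets (scaled by ``magnitude``) are added to the
    original phase spectrum and the image is rebuilt by inverse FFT.  The
    offsets are conjugate-symmetric — they are the phases of a real white
    noise field — so the output is real, and the DC term is untouched so
    mean luminance is preserved exactly.  By default a single offset
    field is shared across colour channels, preserving inter-channel
    phase structure; set ``share_channels=False`` to scramble channels
    independently.

    Returns a float image (values may leave [0, 255]; quantise on save).
    """
    arr = np.asarray(img, dtype=float)
    gray = arr.ndim == 2
    if gray:
        arr = arr[:, :, None]
    h, w, nc = arr.shape

    def noise_field():
        ph = np.angle(np.fft.fft2(rng.standard_normal((h, w))))
        ph[0, 0] = 0.0  # DC untouched -> mean preserved
        return ph * magnitude

    shared = noise_field() if share_channels else None
    out = np.empty_like(arr)
    for c in range(nc):
        noise = shared if share_channels else noise_field()
        F = np.fft.fft2(arr[:, :, c])
        out[:, :, c] = np.real(np.fft.ifft2(np.abs(F) * np.exp(1j * (np.angle(F) + noise))))
    return out[:, :, 0] if gray else out


def make_postcard(img: np.ndarray, spec: PostcardSpec | None = None) -> np.ndarray:
    """Rescale a whole image to postcard size and centre it with padding.

    The entire source is rescaled (never cropped) with bicubic
    resampling, positioned at the canvas centre, and the surround filled
    with ``pad_value``.  Output is always canvas-sized (1024 x 768 by
    default).
    """
    spec = spec or PostcardSpec()
    arr = np.asarray(img)
    tw, th = spec.target_size_px
    pil = Image.fromarray(np.clip(arr, 0, 255).astype(np.uint8))
    small = np.asarray(pil.resize((tw, th), Image.BICUBIC), dtype=float)
    cw, ch = spec.canvas.width_px, spec.canvas.height_px
    shape = (ch, cw) + ((arr.shape[2],) if arr.ndim == 3 else ())
    out = np.full(shape, spec.pad_value, dtype=float)
    y0 = (ch - th) // 2
    x0 = (cw - tw) // 2
    out[y0:y0 + th, x0:x0 + tw] = small
    return out


def apply_scotoma(
    img: np.ndarray,
    spec: ScotomaSpec,
    view: ViewingGeometry | None = None,
) -> np.ndarray:
    """Replace the central disc of ``diameter_deg`` with the fill value.

    Diameter 0 is the identity (the no-mask condition).  The mask edge is
    hard (no feathering).
    """
    arr = np.asarray(img, dtype=float)
    if spec.diameter_deg == 0:
        return arr.copy()
    h, w = arr.shape[:2]
    canvas = CanvasSpec(width_px=w, height_px=h)
    r_px = eccentricity_to_radius_px(spec.diameter_deg / 2, view, canvas)
    rr = _radius_grid(canvas)
    out = arr.copy()
    out[rr <= r_px] = spec.fill
    return out


def scotoma_mask_area_px(
    diameter_deg: float,
    view: ViewingGeometry | None = None,
    canvas: CanvasSpec | None = None,
) -> float:
    """Analytic pixel area of the scotoma disc (for audits)."""
    canvas = canvas or CanvasSpec()
    r = eccentricity_to_radius_px(diameter_deg / 2, view, canvas)
    return math.pi * r * r


def layout_item_array(
    items: list[np.ndarray],
    spec: ArrayLayoutSpec | None = None,
    rng: np.random.Generator | None = None,
    background: float = 128.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Place items on eccentricity rings, larger toward the periphery.

    Items are drawn without replacement from the pool, resized per ring,
    spaced equally in angle with random rotation of each ring and
    per-item jitter; the outermost ring is pinned to the four canvas
    corners (items may crop at the canvas edge, as corners lie outside
    the inscribed circle).  Placement is rejection-sampled until no two
    item discs overlap; an unsatisfiable layout raises :class:`LayoutError`
    reporting the attempt count.

    Returns the composed canvas and a placement table
    (ring, x, y, diameter_px, item_index).
    """
    spec = spec or ArrayLayoutSpec()
    rng = rng or np.random.default_rng(0)
    n_total = spec.total_items
    if len(items) < n_total:
        raise ValueError(f"item pool has {len(items)} < {n_total} items")
    order = rng.choice(len(items), size=n_total, replace=False)
    cw, ch = spec.canvas.width_px, spec.canvas.height_px
    cx, cy = spec.canvas.center

    for attempt in range(spec.max_retries):
        centers, diams, rings = [], [], []
        for ring, (count, diam) in enumerate(zip(spec.counts, spec.diameters_px)):
            outer = spec.corner_outer_ring and ring == len(spec.counts) - 1
            if outer:
                inset = spec.corner_inset_px
                base = [
                    (inset, inset), (cw - inset, inset),
                    (cw - inset, ch - inset), (inset, ch - inset),
                ][:count]
            else:
                radius = spec.ring_radii_px[ring]
                ang = np.arange(count) * 2 * math.pi / count
                base = [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in ang]
            for bx, by in base:
                jx, jy = (0.0, 0.0)
                if spec.jitter_px > 0:
                    jx, jy = rng.uniform(-spec.jitter_px, spec.jitter_px, 2)
                centers.append((bx + jx, by + jy))
                diams.append(diam)
                rings.append(ring)
        # pairwise non-overlap of item discs
        pts = np.array(centers)
        rr = np.array(diams) / 2.0
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
        need = rr[:, None] + rr[None, :]
        iu = np.triu_indices(n_total, k=1)
        if np.all(d[iu] >= need[iu]):
            break
    else:
        raise LayoutError(
            f"no non-overlapping layout after {spec.max_retries} attempts "
            f"(jitter={spec.jitter_px}px)"
        )

    canvas_img = np.full((ch, cw), background, dtype=float)
    table = []
    for (x, y), diam, ring, idx in zip(centers, diams, rings, order):
        patch = np.asarray(items[idx], dtype=float)
        if patch.ndim == 3:
            patch = patch.mean(axis=2)
        pil = Image.fromarray(np.clip(patch, 0, 255).astype(np.uint8))
        res = np.asarray(pil.resize((diam, diam), Image.BICUBIC), dtype=float)
        yy, xx = np.mgrid[0:diam, 0:diam]
        disc = np.hypot(xx - (diam - 1) / 2, yy - (diam - 1) / 2) <= diam / 2
        x0, y0 = int(round(x - diam / 2)), int(round(y - diam / 2))
        sx0, sy0 = max(0, -x0), max(0, -y0)
        sx1 = diam - max(0, x0 + diam - cw)
        sy1 = diam - max(0, y0 + diam - ch)
        tgt = canvas_img[max(0, y0):y0 + sy1, max(0, x0):x0 + sx1]
        sub_disc = disc[sy0:sy1, sx0:sx1]
        tgt[sub_disc] = res[sy0:sy1, sx0:sx1][sub_disc]
        table.append(
            {"ring": ring, "x": x, "y": y, "diameter_px": diam, "item_index": int(idx)}
        )
    return canvas_img, pd.DataFrame(table)


def match_luminance(imgs: list[np.ndarray]) -> list[np.ndarray]:
    """Equate luminance histograms across a stimulus set.

    Each image's sorted pixel values are replaced by the average sorted
    distribution of the whole set (exact histogram specification by rank,
    the plain histogram-equating step of luminance-matching toolboxes).
    Per-image pixel rank order is preserved; ties are broken stably.
    Images must share a common size.  A single image is returned
    unchanged.
    """
    if len(imgs) == 0:
        raise ValueError("need at least one image")
    arrays = [np.asarray(im, dtype=float) for im in imgs]
    if len(arrays) == 1:
        import warnings

        warnings.warn("match_luminance of a single image is the identity")
        return [arrays[0].copy()]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all images must share a common shape")
    flat = [a.ravel() for a in arrays]
    target = np.mean([np.sort(f) for f in flat], axis=0)
    out = []
    for f in flat:
        ranks = np.argsort(np.argsort(f, kind="stable"), kind="stable")
        out.append(target[ranks].reshape(shape))
    return out


def build_scotoma_set(
    content_images: dict[str, list[np.ndarray]],
    diameters_deg: tuple[float, ...] = SCOTOMA_DIAMETERS_DEG,
    out_dir: str | Path | None = None,
    view: ViewingGeometry | None = None,
    fill: float = 128.0,
) -> pd.DataFrame:
    """Cross content types with scotoma levels into a full stimulus set.

    ``content_images`` maps a content label (e.g. scenes, scrambled,
    faces, objects) to its base images.  Every base image is crossed with
    every scotoma diameter; with 4 content types x 20 base images x 5
    levels this emits exactly 400 stimuli.  If ``out_dir`` is given each
    stimulus is written as PNG and the manifest gains a filename column.

    Returns the manifest table (content, base_index, scotoma_deg, filename).
    """
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for content, images in content_images.items():
        for bi, img in enumerate(images):
            for diam in diameters_deg:
                stim = apply_scotoma(img, ScotomaSpec(diam, fill=fill), view)
                fname = f"{content}_{bi:02d}_scot{int(round(diam)):03d}.png"
                if out_dir is not None:
                    Image.fromarray(
                        np.clip(stim, 0, 255).astype(np.uint8)
                    ).save(out_dir / fname)
                rows.append(
                    {"content": content, "base_index": bi,
                     "scotoma_deg": diam, "filename": fname}
                )
    return pd.DataFrame(rows)
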