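"""Stimulus synthesis for a motion-cued shape recognition task.

Three families of stimuli are generated here:

* **Shape pairs** — each pair consists of a sharp-edged "spikey" polygon and
  its smoothed "blob" counterpart.  Both derive from the same control points,
  obtained as the boundary of the Boolean union of several overlapping random
  polygons, so the two members of a pair share size, position, and gross
  layout and differ only in edge character.
* **Blurred images** — shape rasters degraded by convolution with an
  isotropic 2D Gaussian.  Clarity ``c`` and kernel width are linked by
  ``SD = 100 * (1 - c)`` pixels; the clarity-0 stimulus is a blurred circle
  that carries no diagnostic shape information at all.
* **Motion trajectories** — three closed periodic paths (circular,
  triangular, figure-eight/"bimodal") plus a static condition.  The moving
  paths last 1,500 ms by default, complete two 750 ms cycles, share a start
  and end location, and are amplitude-calibrated to have identical mean
  speeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from skimage.draw import disk as _draw_disk
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "ShapePair",
    "StimulusImage",
    "Trajectory",
    "TRAJECTORY_KINDS",
    "MOVING_KINDS",
    "ShapeGenerationError",
    "generate_shape_pair",
    "generate_shape_set",
    "rasterize",
    "apply_blur",
    "make_zero_clarity",
    "make_trajectory",
    "clarity_to_blur_sd",
    "blur_sd_to_clarity",
    "outline_perimeter",
    "fundamental_period_ms",
]

TRAJECTORY_KINDS = ("circular", "triangular", "bimodal", "static")
MOVING_KINDS = ("circular", "triangular", "bimodal")

#: Default raster edge, chosen so that Gaussian kernels up to SD = 100 px
#: (clarity 0) remain representable for a 3 degree stimulus.
DEFAULT_IMAGE_PX = 256

#: Stimulus size on screen, degrees of visual angle.
DEFAULT_SIZE_DEG = 3.0


class ShapeGenerationError(RuntimeError):
    """Raised when random polygons repeatedly fail to union into one region."""


# ---------------------------------------------------------------------------
# clarity <-> blur mapping
# ---------------------------------------------------------------------------

def clarity_to_blur_sd(clarity: float) -> float:
    """Gaussian SD (pixels) for a clarity level in (0, 1]."""
    if not 0.0 < clarity <= 1.0:
        raise ValueError(f"clarity must be in (0, 1], got {clarity}")
    return 100.0 * (1.0 - clarity)


def blur_sd_to_clarity(blur_sd: float) -> float:
    """Inverse of :func:`clarity_to_blur_sd`."""
    if not 0.0 <= blur_sd < 100.0:
        raise ValueError(f"blur_sd must be in [0, 100), got {blur_sd}")
    return 1.0 - blur_sd / 100.0


# ---------------------------------------------------------------------------
# shape pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ShapePair:
    """A matched blob/spikey pair sharing one control-point set.

    Coordinates are in normalized image units: the shape is centred on the
    origin and fits inside the square [-0.5, 0.5]^2.
    """

    pair_id: int
    control_points: np.ndarray  # (n, 2), open ring
    spikey_outline: np.ndarray  # (n + 1, 2), closed
    blob_outline: np.ndarray    # (m + 1, 2), closed
    n_source_polygons: int

    def outline(self, member: str) -> np.ndarray:
        if member == "blob":
            return self.blob_outline
        if member == "spikey":
            return self.spikey_outline
        raise ValueError(f"unknown pair member {member!r}")


def _random_star_polygon(rng: np.random.Generator) -> Polygon:
    """One simple star-shaped polygon on a jittered ring about a random center."""
    n_vert = int(rng.integers(5, 10))
    center = rng.uniform(-0.15, 0.15, size=2)
    radius = rng.uniform(0.18, 0.32)
    # jittered regular angles keep edges well conditioned
    base = np.linspace(0.0, 2.0 * np.pi, n_vert, endpoint=False) + rng.uniform(
        -0.3, 0.3, size=n_vert
    )
    radii = radius * (1.0 + rng.uniform(-0.45, 0.45, size=n_vert))
    pts = center + np.c_[radii * np.cos(base), radii * np.sin(base)]
    return Polygon(pts)


def _chaikin(points: np.ndarray, iterations: int) -> np.ndarray:
    """Chaikin corner cutting on a closed polygon (open-ring representation).

    Each pass replaces every vertex with two points at 1/4 and 3/4 of the
    adjacent edges; by the triangle inequality the boundary never lengthens,
    and the limit curve is a smooth quadratic B-spline.
    """
    pts = np.asarray(points, dtype=float)
    for _ in range(iterations):
        nxt = np.roll(pts, -1, axis=0)
        a = 0.75 * pts + 0.25 * nxt
        b = 0.25 * pts + 0.75 * nxt
        out = np.empty((2 * len(pts), 2))
        out[0::2] = a
        out[1::2] = b
        pts = out
    return pts


def _close(ring: np.ndarray) -> np.ndarray:
    return np.vstack([ring, ring[:1]])


def outline_perimeter(outline: np.ndarray) -> float:
    """Perimeter of a closed outline (first point equal to last)."""
    d = np.diff(outline, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def generate_shape_pair(
    seed: int,
    n_polygons: int = 4,
    smoothing: float = 3.0,
    max_retries: int = 50,
    pair_id: int = 0,
) -> ShapePair:
    """Generate one blob/spikey pair from overlapping random polygons.

    Parameters
    ----------
    seed
        Seeds the generator; identical seeds give identical pairs.
    n_polygons
        Number of overlapping source polygons to union (>= 2).
    smoothing
        Number of Chaikin corner-cutting passes used for the blob (> 0;
        rounded to the nearest integer, minimum 1).
    max_retries
        Internal resampling budget when the union is degenerate (polygons
        not overlapping into a single simple region).
    """
    if n_polygons < 2:
        raise ValueError("n_polygons must be >= 2 (a union of overlaps)")
    if smoothing <= 0:
        raise ValueError("smoothing must be > 0")
    iterations = max(1, int(round(smoothing)))
    rng = np.random.default_rng(seed)

    for _ in range(max_retries):
        polys = [_random_star_polygon(rng) for _ in range(n_polygons)]
        if not all(p.is_valid for p in polys):
            continue
        union = unary_union(polys)
        if union.geom_type != "Polygon" or union.interiors:
            continue
        union = orient(union, sign=1.0)  # CCW
        cp = np.asarray(union.exterior.coords)[:-1]
        # normalize: centroid at origin, max extent 0.8
        cp = cp - np.asarray(union.centroid.coords)[0]
        extent = np.abs(cp).max()
        cp = cp * (0.4 / extent)
        blob = _chaikin(cp, iterations)
        spikey_poly = Polygon(cp)
        blob_poly = Polygon(blob)
        if not (
            spikey_poly.is_valid
            and blob_poly.is_valid
            and blob_poly.area > 0
            and spikey_poly.area > 0
        ):
            continue
        return ShapePair(
            pair_id=pair_id,
            control_points=cp,
            spikey_outline=_close(cp),
            blob_outline=_close(blob),
            n_source_polygons=n_polygons,
        )
    raise ShapeGenerationError(
        f"no simple connected union after {max_retries} resamples (seed={seed})"
    )


def generate_shape_set(
    n_pairs: int = 50, seed: int = 0, n_polygons: int = 4, smoothing: float = 3.0
) -> list[ShapePair]:
    """Generate the task's shape set (default 50 pairs = 100 shapes)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=n_pairs)
    return [
        generate_shape_pair(
            int(s), n_polygons=n_polygons, smoothing=smoothing, pair_id=i
        )
        for i, s in enumerate(pair_seeds)
    ]


# ---------------------------------------------------------------------------
# rasters and blur
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusImage:
    """A grayscale stimulus raster (intensity in [0, 1], background 0)."""

    pixels: np.ndarray
    clarity: float
    blur_sd: float
    source: str  # "blob", "spikey", "shape", or "circle"
    size_deg: float = DEFAULT_SIZE_DEG


def rasterize(
    outline: np.ndarray,
    image_px: int = DEFAULT_IMAGE_PX,
    source: str = "shape",
) -> StimulusImage:
    """Fill a closed outline (normalized units) into a centred raster."""
    if image_px <= 0:
        raise ValueError("image_px must be positive")
    outline = np.asarray(outline, dtype=float)
    if not np.allclose(outline[0], outline[-1]):
        raise ValueError("shape outline is not closed")
    cols = (outline[:, 0] + 0.5) * (image_px - 1)
    rows = (0.5 - outline[:, 1]) * (image_px - 1)
    img = np.zeros((image_px, image_px), dtype=float)
    rr, cc = _draw_polygon(rows, cols, shape=img.shape)
    img[rr, cc] = 1.0
    return StimulusImage(
        pixels=img, clarity=1.0, blur_sd=0.0, source=source
    )


def _gaussian_blur(pixels: np.ndarray, sd: float) -> np.ndarray:
    if sd == 0.0:
        return pixels.copy()
    # reflect padding keeps local mass; stimuli are centred with margins so
    # the boundary rule is invisible at default sizes
    return gaussian_filter(pixels, sigma=sd, mode="reflect", truncate=4.0)


def apply_blur(image: StimulusImage, clarity: float) -> StimulusImage:
    """Blur a shape raster down to ``clarity`` (SD = 100*(1-clarity) px)."""
    sd = clarity_to_blur_sd(clarity)  # validates (0, 1]
    return replace(
        image,
        pixels=_gaussian_blur(image.pixels, sd),
        clarity=clarity,
        blur_sd=sd,
    )


def make_zero_clarity(
    blur_sd: float,
    image_px: int = DEFAULT_IMAGE_PX,
    radius_frac: float = 0.3,
) -> StimulusImage:
    """The clarity-0 stimulus: a blurred circle with no shape information.

    ``blur_sd`` must be strictly positive — an unblurred circle would itself
    carry (wrong) shape information, contradicting the design.
    """
    if blur_sd <= 0:
        raise ValueError("blur_sd must be > 0 for the zero-clarity stimulus")
    if image_px <= 0:
        raise ValueError("image_px must be positive")
    img = np.zeros((image_px, image_px), dtype=float)
    center = ((image_px - 1) / 2.0, (image_px - 1) / 2.0)
    rr, cc = _draw_disk(center, radius_frac * image_px, shape=img.shape)
    img[rr, cc] = 1.0
    return StimulusImage(
        pixels=_gaussian_blur(img, blur_sd),
        clarity=0.0,
        blur_sd=float(blur_sd),
        source="circle",
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Sampled 2D position/velocity time series for one motion condition.

    Positions are defined as the cumulative trapezoidal integral of the
    analytic velocity samples from the start position, so the
    position/velocity consistency is exact by construction.
    """

    kind: str
    duration_ms: float
    period_ms: float
    n_cycles: int
    t_ms: np.ndarray
    positions: np.ndarray   # (n, 2) deg
    velocities: np.ndarray  # (n, 2) deg/s
    sample_rate_hz: float

    @property
    def mean_speed_deg_s(self) -> float:
        v = self.velocities
        return float(np.hypot(v[:, 0], v[:, 1]).mean())


#: Common start (and end) location of the moving trajectories, degrees.
DEFAULT_START_DEG = (-1.0, -1.0)
#: Screen location of the static condition (no printed coordinates exist;
#: configurable).
DEFAULT_STATIC_POS_DEG = (1.0, -1.0)

# unit figure-eight (sin t, sin 2t / 2): arc length per period, computed once
_theta = np.linspace(0.0, 2.0 * np.pi, 20001)
_EIGHT_UNIT_LENGTH = float(
    np.trapezoid(np.hypot(np.cos(_theta), np.cos(2.0 * _theta)), _theta)
)
del _theta


def _circular_velocity(t_s: np.ndarray, radius: float, period_s: float):
    omega = 2.0 * np.pi / period_s
    phi = omega * t_s + 1.25 * np.pi  # start at the circle's lower-left point
    return radius * omega * np.c_[-np.sin(phi), np.cos(phi)]


def _triangular_velocity(t_s: np.ndarray, radius: float, period_s: float):
    # equilateral triangle with perimeter 2*pi*radius, so mean speed matches
    # the circle's exactly; corners traversed at constant speed
    side = 2.0 * np.pi * radius / 3.0
    speed = 3.0 * side / period_s
    verts = np.array([[0.0, 0.0], [side, 0.0], [0.5 * side, side * 0.5 * np.sqrt(3.0)]])
    dirs = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)

    phase = (t_s % period_s) / period_s * 3.0
    eps = 1e-9
    seg_lo = np.floor(phase - eps).astype(int) % 3
    seg_hi = np.floor(phase + eps).astype(int) % 3
    # exactly at a corner sample the two segments differ: record the average
    # of the incoming and outgoing velocities, which makes the trapezoidal
    # closure error cancel pairwise at each corner
    return 0.5 * speed * (dirs[seg_lo] + dirs[seg_hi])


def _bimodal_velocity(t_s: np.ndarray, radius: float, period_s: float):
    omega = 2.0 * np.pi / period_s
    amp = 2.0 * np.pi * radius / _EIGHT_UNIT_LENGTH
    phi = omega * t_s + np.pi
    return amp * omega * np.c_[np.cos(phi), np.cos(2.0 * phi)]


_VELOCITY_FN = {
    "circular": _circular_velocity,
    "triangular": _triangular_velocity,
    "bimodal": _bimodal_velocity,
}


def make_trajectory(
    kind: str,
    duration_ms: float = 1500.0,
    n_cycles: int = 2,
    amplitude_deg: float = 1.25,
    sample_rate_hz: float = 1000.0,
    start_deg: tuple[float, float] = DEFAULT_START_DEG,
    static_pos_deg: tuple[float, float] = DEFAULT_STATIC_POS_DEG,
) -> Trajectory:
    """Build one motion condition's position/velocity time series.

    ``amplitude_deg`` is the circular trajectory's radius; the triangular
    and figure-eight paths are scaled so that all three moving kinds have
    identical path length per cycle, hence identical mean speed.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    if kind not in TRAJECTORY_KINDS:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    n = int(round(duration_ms / 1000.0 * sample_rate_hz)) + 1
    t_s = np.arange(n) / sample_rate_hz
    t_ms = t_s * 1000.0
    period_ms = duration_ms / max(n_cycles, 1)

    if kind == "static":
        pos = np.tile(np.asarray(static_pos_deg, dtype=float), (n, 1))
        vel = np.zeros((n, 2))
        return Trajectory(kind, duration_ms, period_ms, n_cycles, t_ms, pos, vel,
                          sample_rate_hz)

    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1 for moving trajectories")
    vel = _VELOCITY_FN[kind](t_s, amplitude_deg, period_ms / 1000.0)
    pos = np.asarray(start_deg, dtype=float) + np.c_[
        cumulative_trapezoid(vel[:, 0], t_s, initial=0.0),
        cumulative_trapezoid(vel[:, 1], t_s, initial=0.0),
    ]
    return Trajectory(kind, duration_ms, period_ms, n_cycles, t_ms, pos, vel,
                      sample_rate_hz)


def fundamental_period_ms(traj: Trajectory) -> float:
    """Fundamental period of x(t) estimated by autocorrelation.

    Returns the smallest positive lag at which the circular autocorrelation
    of the demeaned horizontal position has a local maximum exceeding half
    the zero-lag value.  The circular form suits these closed, periodic
    paths: the sampled signal spans an integer number of cycles.
    """
    x = traj.positions[:, 0]
    if np.allclose(x[0], x[-1]):
        x = x[:-1]  # drop the duplicated closure sample
    x = x - x.mean()
    n = len(x)
    spec = np.fft.rfft(x)
    ac = np.fft.irfft(np.abs(spec) ** 2, n=n)
    if ac[0] <= 0:
        raise ValueError("degenerate (constant) trajectory has no period")
    lags_all = np.arange(1, n // 2 + 1)
    prev = ac[(lags_all - 1) % n]
    nxt = ac[(lags_all + 1) % n]
    is_peak = (ac[lags_all] >= prev) & (ac[lags_all] >= nxt)
    strong = ac[lags_all] > 0.5 * ac[0]
    lags = lags_all[is_peak & strong]
    if len(lags) == 0:
        raise ValueError("no autocorrelation peak found")
    return float(lags[0] / traj.sample_rate_hz * 1000.0)
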