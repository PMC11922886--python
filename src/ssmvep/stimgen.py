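"""Newton's-rings stimulus synthesis with equal-luminance color modulation.

A stimulus target is a disc of ``n_rings`` concentric annular bands (the
"rings") on a contrasting background.  Three paradigms are rendered:

* ``bimodal`` — rings expand/contract sinusoidally while ring and
  background colors sweep black→red and white→green;
* ``single_motion`` — the same motion with fixed black rings on white;
* ``single_color`` — the color sweep with no motion.

Geometry follows the area-ratio parameterisation: the ratio of total ring
band area to background area inside the stimulus disc equals ``C``.  Outer
radii form the arithmetic sequence ``r_i = (2i-1) r_max / (2n)``; each ring
band occupies the fraction ``C/(1+C)`` of its annular cell, so the global
band/background ratio is exactly ``C`` in the continuum.

Color modulation is isoluminant by construction: the background color of
every frame is solved so the disc-mean perceived luminance is constant over
the cycle, keeping luminance flicker out of the chromatic stimulation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

__all__ = [
    "RingGeometry",
    "ColorState",
    "StimulusConfig",
    "FrameSequence",
    "GamutError",
    "LayoutError",
    "REC709_COEFFS",
    "DEFAULT_C1",
    "BRIGHTNESS_LEVELS",
    "compute_outer_radii",
    "compute_inner_radii",
    "ring_geometry",
    "perceived_luminance",
    "match_luminance",
    "solve_luminance_on_hue",
    "color_waveform",
    "render_mask",
    "measure_area_ratio",
    "render_cycle",
    "compose_layout",
]

#: Rec. 709 luma coefficients for R, G, B.
REC709_COEFFS = np.array([0.2126, 0.7152, 0.0722])

#: Device constant scaling perceived luminance (display dependent).
DEFAULT_C1 = 0.7

#: Default peak channel values for the three brightness levels.  The study
#: names the levels but not their RGB values; these are package defaults.
BRIGHTNESS_LEVELS = {"low": 85.0, "medium": 170.0, "high": 255.0}

PARADIGMS = ("bimodal", "single_motion", "single_color")


class GamutError(ValueError):
    """Requested luminance is unreachable on the target hue.

    Attributes
    ----------
    max_achievable : float
        Largest perceived luminance the pure hue can produce.
    """

    def __init__(self, msg: str, max_achievable: float):
        super().__init__(msg)
        self.max_achievable = max_achievable


class LayoutError(ValueError):
    """Target bounding boxes overlap in a multi-target layout."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def compute_outer_radii(n_rings: int, r_max: float) -> np.ndarray:
    """Outer radii of the ring bands, ``r_i = (2i-1) r_max / (2n)``.

    The sequence is arithmetic with step ``r_max/n``; the outermost ring's
    outer radius ``(2n-1) r_max / (2n)`` stays inside ``r_max``.
    """
    if n_rings < 1 or int(n_rings) != n_rings:
        raise ValueError(f"n_rings must be a positive integer, got {n_rings}")
    if r_max <= 0:
        raise ValueError(f"r_max must be positive, got {r_max}")
    i = np.arange(1, int(n_rings) + 1, dtype=float)
    return (2.0 * i - 1.0) * r_max / (2.0 * n_rings)


def compute_inner_radii(outer_radii: np.ndarray, area_ratio_C: float) -> np.ndarray:
    """Inner radii making the band/background area ratio equal ``C``.

    Each annular cell spans ``[r_{i-1}, r_i]`` (with ``r_0 = 0``); the band
    ``[inner_i, r_i]`` fills the fraction ``C/(1+C)`` of the cell's area:

        inner_i**2 = r_i**2 - C/(1+C) * (r_i**2 - r_{i-1}**2)

    Summing band areas over cells gives band/(disc - band) = C exactly for
    the disc bounded by the outermost outer radius.
    """
    outer = np.asarray(outer_radii, dtype=float)
    if area_ratio_C <= 0:
        raise ValueError(f"area_ratio_C must be positive, got {area_ratio_C}")
    if outer.ndim != 1 or outer.size == 0 or np.any(outer <= 0) or np.any(np.diff(outer) <= 0):
        raise ValueError("outer_radii must be a strictly increasing positive sequence")
    prev = np.concatenate([[0.0], outer[:-1]])
    frac = area_ratio_C / (1.0 + area_ratio_C)
    inner_sq = outer**2 - frac * (outer**2 - prev**2)
    return np.sqrt(inner_sq)


@dataclass(frozen=True)
class RingGeometry:
    """Concentric ring-band geometry of one stimulus disc."""

    n_rings: int
    r_max: float
    outer_radii: np.ndarray
    inner_radii: np.ndarray
    area_ratio_C: float

    @property
    def disc_radius(self) -> float:
        """Radius of the stimulus disc (outermost band's outer edge)."""
        return float(self.outer_radii[-1])

    @property
    def band_widths(self) -> np.ndarray:
        return self.outer_radii - self.inner_radii


def ring_geometry(n_rings: int, r_max: float, area_ratio_C: float) -> RingGeometry:
    """Build the full ring geometry for given ring count and area ratio."""
    outer = compute_outer_radii(n_rings, r_max)
    inner = compute_inner_radii(outer, area_ratio_C)
    return RingGeometry(n_rings=int(n_rings), r_max=float(r_max),
                        outer_radii=outer, inner_radii=inner,
                        area_ratio_C=float(area_ratio_C))


# ---------------------------------------------------------------------------
# colorimetry
# ---------------------------------------------------------------------------

def perceived_luminance(rgb, C1: float = DEFAULT_C1) -> float:
    """Perceived luminance ``L = C1 (0.2126 R + 0.7152 G + 0.0722 B)``.

    ``C1`` is a device constant (0.7 for the AR display the paradigm was
    designed around); channels are in [0, 255].
    """
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError(f"rgb channels must lie in [0, 255], got {rgb!r}")
    return float(C1 * (rgb @ REC709_COEFFS)) if rgb.ndim == 1 else C1 * (rgb @ REC709_COEFFS)


@dataclass(frozen=True)
class ColorState:
    """An RGB triple together with its perceived luminance."""

    rgb: tuple
    perceived_luminance: float
    C1: float = DEFAULT_C1

    def __post_init__(self):
        recomputed = perceived_luminance(self.rgb, self.C1)
        if recomputed != self.perceived_luminance:
            raise ValueError(
                f"stored luminance {self.perceived_luminance} inconsistent with "
                f"rgb {self.rgb} (recomputed {recomputed})")


_HUE_AXES = {
    "red": np.array([1.0, 0.0, 0.0]),
    "green": np.array([0.0, 1.0, 0.0]),
    "blue": np.array([0.0, 0.0, 1.0]),
    "gray": np.array([1.0, 1.0, 1.0]),
}


def match_luminance(reference_rgb, target_hue: str, C1: float = DEFAULT_C1) -> ColorState:
    """Color on a pure hue axis with the reference's perceived luminance.

    The hue axis is scaled so ``L(axis * s) == L(reference)``; if even the
    saturated hue (channel value 255) cannot reach the reference luminance a
    :class:`GamutError` is raised carrying the maximum achievable value.
    """
    axis = _HUE_AXES.get(target_hue)
    if axis is None:
        raise ValueError(f"unknown hue {target_hue!r}; choose from {sorted(_HUE_AXES)}")
    L_ref = perceived_luminance(reference_rgb, C1)
    L_axis_max = perceived_luminance(axis * 255.0, C1)
    if L_ref > L_axis_max * (1 + 1e-12):
        raise GamutError(
            f"luminance {L_ref:.3f} unreachable on {target_hue} "
            f"(max {L_axis_max:.3f})", max_achievable=L_axis_max)
    scale = 0.0 if L_axis_max == 0 else L_ref / L_axis_max
    rgb = tuple(float(v) for v in axis * 255.0 * scale)
    return ColorState(rgb=rgb, perceived_luminance=perceived_luminance(rgb, C1), C1=C1)


def solve_luminance_on_hue(target_luminance: float, hue: str,
                           C1: float = DEFAULT_C1) -> np.ndarray:
    """RGB on (or near) a hue axis achieving an exact perceived luminance.

    Unlike :func:`match_luminance` this never fails inside the display's
    luminance range: when the saturated pure hue is still too dark, the
    color is desaturated toward white (all channels raised equally) until
    the luminance is met.  Used by the renderer, where the background's
    luminance is dictated by the isoluminance constraint.
    """
    axis = _HUE_AXES.get(hue)
    if axis is None:
        raise ValueError(f"unknown hue {hue!r}")
    if target_luminance < 0:
        raise ValueError("luminance must be non-negative")
    L_pure = perceived_luminance(axis * 255.0, C1)
    if target_luminance <= L_pure:
        return axis * 255.0 * (target_luminance / L_pure if L_pure else 0.0)
    # desaturate: rgb = axis*255 + x*(1 - axis), solve for x
    rest = 1.0 - axis
    denom = C1 * float(rest @ REC709_COEFFS)
    if denom == 0:
        raise GamutError(f"luminance {target_luminance:.3f} exceeds display white",
                         max_achievable=L_pure)
    x = (target_luminance - L_pure) / denom
    if x > 255.0 * (1 + 1e-12):
        raise GamutError(
            f"luminance {target_luminance:.3f} exceeds display white",
            max_achievable=perceived_luminance([255, 255, 255], C1))
    return np.clip(axis * 255.0 + min(x, 255.0) * rest, 0.0, 255.0)


def color_waveform(t, frequency_hz: float, R_max: float):
    """Sinusoidal channel trajectory ``R(t) = (R_max/2) (1 - cos(2π f t))``.

    The raised-cosine starts at 0, peaks at ``R_max`` mid-cycle and returns
    to 0 — a smooth color sweep with no luminance step.  The ½ scaling keeps
    the peak at ``R_max`` (the raw ``1 - cos`` ranges over [0, 2]).
    """
    if not (0 < R_max <= 255):
        raise ValueError(f"R_max must be in (0, 255], got {R_max}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = 0.5 * R_max * (1.0 - np.cos(2.0 * np.pi * frequency_hz * t))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusConfig:
    """Full parameterisation of one stimulus target."""

    paradigm: str = "bimodal"
    frequency_hz: float = 3.0
    brightness_level: str = "medium"
    area_ratio_C: float = 0.6
    n_rings: int = 6
    canvas_px: int = 256
    frame_rate_hz: float = 60.0
    r_max: float | None = None          # defaults to canvas_px / 2
    target_offsets_px: tuple = (240, 360)  # (vertical, horizontal)
    C1: float = DEFAULT_C1
    supersample: int = 4

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"paradigm must be one of {PARADIGMS}, got {self.paradigm!r}")
        if self.frequency_hz <= 0:
            raise ValueError("frequency_hz must be positive")
        if self.frame_rate_hz < 2.0 * self.frequency_hz:
            raise ValueError(
                f"frame_rate_hz={self.frame_rate_hz} undersamples "
                f"frequency_hz={self.frequency_hz} (need >= 2f)")
        if self.brightness_level not in BRIGHTNESS_LEVELS:
            raise ValueError(f"brightness_level must be one of {sorted(BRIGHTNESS_LEVELS)}")
        if self.area_ratio_C <= 0:
            raise ValueError("area_ratio_C must be positive")
        if self.effective_r_max > self.canvas_px / 2:
            raise ValueError(
                f"canvas {self.canvas_px}px too small for r_max={self.effective_r_max}")

    @property
    def effective_r_max(self) -> float:
        return self.canvas_px / 2.0 if self.r_max is None else self.r_max

    @property
    def geometry(self) -> RingGeometry:
        return ring_geometry(self.n_rings, self.effective_r_max, self.area_ratio_C)

    @property
    def peak_channel(self) -> float:
        return BRIGHTNESS_LEVELS[self.brightness_level]


@dataclass
class FrameSequence:
    """Time-ordered RGB frames covering an integer number of cycles."""

    frames: np.ndarray              # (n_frames, H, W, 3) float32 in [0, 255]
    timestamps: np.ndarray          # seconds
    mean_luminance_per_frame: np.ndarray
    frame_rate_hz: float
    n_periods: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def luminance_ripple(self) -> float:
        """(max - min) / mean of the per-frame mean luminance."""
        lum = self.mean_luminance_per_frame
        return float((lum.max() - lum.min()) / lum.mean())


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _radius_grid(canvas_px: int, supersample: int = 1) -> np.ndarray:
    """Distances from canvas center, sampled at pixel (or subpixel) centers."""
    n = canvas_px * supersample
    coords = (np.arange(n) + 0.5) / supersample - canvas_px / 2.0
    xx, yy = np.meshgrid(coords, coords)
    return np.hypot(xx, yy)


def _band_mask(radius: np.ndarray, inner: np.ndarray, outer: np.ndarray) -> np.ndarray:
    mask = np.zeros(radius.shape, dtype=bool)
    for ri, ro in zip(inner, outer):
        mask |= (radius >= ri) & (radius < ro)
    return mask


def render_mask(geometry: RingGeometry, canvas_px: int,
                displacement: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Binary band mask and disc mask at 1× resolution (no anti-aliasing).

    ``displacement`` shifts every band boundary radially (the motion model);
    boundaries are clamped at zero.  Returns ``(band_mask, disc_mask)``.
    """
    radius = _radius_grid(canvas_px)
    inner = np.clip(geometry.inner_radii + displacement, 0.0, None)
    outer = np.clip(geometry.outer_radii + displacement, 0.0, None)
    band = _band_mask(radius, inner, outer)
    disc = radius < geometry.disc_radius
    return band & disc, disc


def measure_area_ratio(geometry: RingGeometry, canvas_px: int = 512) -> float:
    """Pixel-counted band/background area ratio inside the stimulus disc.

    Independent check of the geometry construction: counts band pixels
    against non-band disc pixels on the binary mask.
    """
    band, disc = render_mask(geometry, canvas_px)
    n_band = int(band.sum())
    n_bg = int(disc.sum()) - n_band
    if n_bg == 0:
        raise ValueError("degenerate mask: no background pixels")
    return n_band / n_bg


def _coverage(radius_ss: np.ndarray, inner, outer, disc_radius: float,
              supersample: int, canvas_px: int):
    """Anti-aliased band coverage and disc coverage in [0, 1] per pixel."""
    band = _band_mask(radius_ss, inner, outer) & (radius_ss < disc_radius)
    disc = radius_ss < disc_radius
    s = supersample
    band_cov = band.reshape(canvas_px, s, canvas_px, s).mean(axis=(1, 3))
    disc_cov = disc.reshape(canvas_px, s, canvas_px, s).mean(axis=(1, 3))
    return band_cov, disc_cov


def _n_frames_for_periods(frame_rate_hz: float, frequency_hz: float) -> tuple[int, int]:
    """Smallest frame count spanning an integer number of stimulation periods."""
    ratio = Fraction(frame_rate_hz / frequency_hz).limit_denominator(1000)
    return ratio.numerator, ratio.denominator  # (n_frames, n_periods)


def render_cycle(config: StimulusConfig, min_periods: int = 1) -> FrameSequence:
    """Render one (or the minimal integer number of) stimulation cycles.

    Ring bands carry the "ring" color, the rest of the disc the
    "background" color.  For color-modulated paradigms the ring color sweeps
    black→red with the raised-cosine waveform while the background sweeps
    white→green; the background luminance is re-solved every frame from the
    realized band fraction so the disc-mean luminance is constant even while
    the rings move.  Pixels outside the stimulus disc are neutral gray and
    excluded from the luminance bookkeeping.
    """
    geom = config.geometry
    n_frames, n_periods = _n_frames_for_periods(config.frame_rate_hz, config.frequency_hz)
    reps = max(1, math.ceil(min_periods / n_periods))
    n_frames, n_periods = n_frames * reps, n_periods * reps
    t = np.arange(n_frames) / config.frame_rate_hz

    moving = config.paradigm in ("bimodal", "single_motion")
    colored = config.paradigm in ("bimodal", "single_color")

    # motion: sinusoidal radial boundary displacement, amplitude = half the
    # mean band width; phase 0..pi expands, pi..2pi contracts.
    amp = 0.5 * float(geom.band_widths.mean()) if moving else 0.0
    displacement = amp * np.sin(2.0 * np.pi * config.frequency_hz * t)

    peak = config.peak_channel
    white = np.array([peak, peak, peak])
    L_white = perceived_luminance(white, config.C1)

    # color sweep weight in [0, 1] (raised cosine)
    w = color_waveform(t, config.frequency_hz, 255.0) / 255.0 if colored else np.zeros(n_frames)
    red_peak = np.array([peak, 0.0, 0.0])

    radius_ss = _radius_grid(config.canvas_px, config.supersample)
    frames = np.empty((n_frames, config.canvas_px, config.canvas_px, 3), dtype=np.float32)
    mean_lum = np.empty(n_frames)

    # anchor the isoluminance target at the *rendered* zero-displacement
    # band fraction so discretization cannot push the solved background
    # past display white
    cov0 = _coverage(radius_ss, geom.inner_radii, geom.outer_radii,
                     geom.disc_radius, config.supersample, config.canvas_px)
    band_frac0 = cov0[0].sum() / cov0[1].sum()
    L_mean0 = (1.0 - band_frac0) * L_white

    for k in range(n_frames):
        inner = np.clip(geom.inner_radii + displacement[k], 0.0, None)
        outer = np.clip(geom.outer_radii + displacement[k], 0.0, None)
        band_cov, disc_cov = _coverage(radius_ss, inner, outer, geom.disc_radius,
                                       config.supersample, config.canvas_px)
        band_frac = band_cov.sum() / disc_cov.sum()

        ring_rgb = w[k] * red_peak  # black -> red sweep
        L_ring = perceived_luminance(ring_rgb, config.C1)
        if colored:
            # hold the disc-mean luminance at its t=0 value: solve the
            # background luminance from the current band fraction
            L_bg = (L_mean0 - band_frac * L_ring) / (1.0 - band_frac)
            # background sweeps white -> green: hue interpolates, luminance exact
            if w[k] == 0.0:
                bg_rgb = solve_luminance_on_hue(L_bg, "gray", config.C1)
            else:
                green = solve_luminance_on_hue(L_bg, "green", config.C1)
                gray = solve_luminance_on_hue(L_bg, "gray", config.C1)
                bg_rgb = w[k] * green + (1.0 - w[k]) * gray
                # the gray/green mix is luminance-exact because both
                # endpoints carry L_bg and luminance is linear in RGB
        else:
            bg_rgb = white

        frame = np.empty((config.canvas_px, config.canvas_px, 3), dtype=np.float32)
        for c in range(3):
            inside = band_cov * ring_rgb[c] + (disc_cov - band_cov) * bg_rgb[c]
            frame[:, :, c] = inside + (1.0 - disc_cov) * 128.0
        frames[k] = frame

        mean_lum[k] = band_frac * L_ring + (1.0 - band_frac) * perceived_luminance(
            np.clip(bg_rgb, 0, 255), config.C1)

    return FrameSequence(frames=frames, timestamps=t, mean_luminance_per_frame=mean_lum,
                         frame_rate_hz=config.frame_rate_hz, n_periods=n_periods)


# ---------------------------------------------------------------------------
# multi-target layout
# ---------------------------------------------------------------------------

def compose_layout(configs, canvas_px: tuple[int, int],
                   offsets=None, duration_s: float | None = None) -> FrameSequence:
    """Compose four targets into one frame stream.

    Targets sit at (row, col) offsets from the canvas center; the default
    layout puts the 4 / 4.5 Hz targets 240 px above/below center and the
    3 / 3.5 Hz targets 360 px left/right of center.  Each target's rendered
    cycle is tiled cyclically over the composed duration, which must span an
    integer number of every target's periods.
    """
    configs = list(configs)
    if offsets is None:
        if len(configs) != 4:
            raise ValueError("default layout requires exactly 4 configs")
        v, h = configs[0].target_offsets_px
        offsets = [(-v, 0), (v, 0), (0, -h), (0, h)]
    if len(offsets) != len(configs):
        raise ValueError("one offset per config required")
    freqs = [c.frequency_hz for c in configs]
    if len(set(freqs)) != len(freqs):
        raise ValueError("target frequencies must be distinct" if len(configs) > 1
                         else "duplicate frequency")

    H, W = canvas_px
    fps = configs[0].frame_rate_hz
    if any(c.frame_rate_hz != fps for c in configs):
        raise ValueError("all targets must share one frame rate")

    # bounding boxes + overlap check
    boxes = []
    for cfg, (dy, dx) in zip(configs, offsets):
        half = cfg.canvas_px / 2.0
        cy, cx = H / 2.0 + dy, W / 2.0 + dx
        if cy - half < 0 or cx - half < 0 or cy + half > H or cx + half > W:
            raise LayoutError(f"target at offset ({dy},{dx}) exceeds the canvas")
        boxes.append((cy - half, cy + half, cx - half, cx + half))
    for a in range(len(boxes)):
        for b in range(a + 1, len(boxes)):
            ya0, ya1, xa0, xa1 = boxes[a]
            yb0, yb1, xb0, xb1 = boxes[b]
            if ya0 < yb1 and yb0 < ya1 and xa0 < xb1 and xb0 < xa1:
                raise LayoutError(f"targets {a} and {b} overlap")

    cycles = [render_cycle(cfg) for cfg in configs]
    if duration_s is None:
        # minimal duration that is an integer number of frames and of
        # every target's rendered super-period
        n_total = int(np.lcm.reduce([c.n_frames for c in cycles]))
    else:
        n_total = int(round(duration_s * fps))
        for c in cycles:
            if n_total % c.n_frames:
                raise ValueError("duration must span whole cycles of every target")

    frames = np.full((n_total, H, W, 3), 128.0, dtype=np.float32)
    for cfg, (dy, dx), cyc in zip(configs, offsets, cycles):
        half = cfg.canvas_px // 2
        y0 = int(round(H / 2.0 + dy)) - half
        x0 = int(round(W / 2.0 + dx)) - half
        idx = np.arange(n_total) % cyc.n_frames
        frames[:, y0:y0 + cfg.canvas_px, x0:x0 + cfg.canvas_px, :] = cyc.frames[idx]

    mean_lum = np.array([
        np.mean([c.mean_luminance_per_frame[k % c.n_frames] for c in cycles])
        for k in range(n_total)])
    return FrameSequence(frames=frames, timestamps=np.arange(n_total) / fps,
                         mean_luminance_per_frame=mean_lum, frame_rate_hz=fps,
                         n_periods=1)
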