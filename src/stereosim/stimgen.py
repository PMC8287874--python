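"""Random-dot stereogram (RDS) stimulus synthesis.

Three stimulus classes are supported: an upright surface (e.g. a face-like
depth map), its picture-plane inversion, and a depth-power-matched random
surface obtained by Fourier phase scrambling.  A depth map is rendered as a
disparity-defined RDS in which task difficulty is controlled by the
signal-to-noise ratio (SNR): the fraction of target dots that carry the
surface's disparity versus dots assigned a random disparity.

Coordinate conventions: origin at the stimulus center, x rightward,
y upward, in degrees of visual angle.  Grids are row-major with row 0 at
the top.  Disparity is in arcmin, positive = crossed ("near").  The
disparity of a dot is applied as a symmetric +/- d/2 horizontal shift of
its two half-images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "DepthMap",
    "StimulusSpec",
    "StereoPair",
    "make_oval_mask",
    "invert_depth_map",
    "phase_randomize",
    "render_rds",
    "render_feature_pair",
    "export_stimulus",
    "load_depth_map",
]

ARCMIN_PER_DEG = 60.0
ARCSEC_PER_ARCMIN = 60.0


@dataclass
class DepthMap:
    """A 2D grid of relative depth with an oval validity mask.

    ``values`` are unitless relative depths; rendering scales them linearly
    so that the global absolute maximum maps to the spec's maximum
    disparity.  ``mask`` marks the oval target region.
    """

    values: np.ndarray
    mask: np.ndarray
    pixels_per_degree: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("depth values must be a 2D grid")
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("depth values must be finite")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def height_deg(self) -> float:
        return self.shape[0] / self.pixels_per_degree

    def width_deg(self) -> float:
        return self.shape[1] / self.pixels_per_degree


@dataclass(frozen=True)
class StimulusSpec:
    """Geometry and dot statistics of one RDS stimulus.

    Defaults follow the psychophysics setup: an 8.68 deg square stimulus
    with a 6.45 x 4.55 deg oval target, 20 dots/deg^2 of 0.05 deg dots,
    and a maximum target disparity of 5.3 arcmin (5.4 in the in-bore
    variant).
    """

    stim_size_deg: float = 8.68
    target_height_deg: float = 6.45
    target_width_deg: float = 4.55
    max_disparity_arcmin: float = 5.3
    dot_density_per_deg2: float = 20.0
    dot_size_deg: float = 0.05
    snr: float = 1.0
    depth_sign: str = "near"
    background_grid_square_deg: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "stim_size_deg",
            "target_height_deg",
            "target_width_deg",
            "max_disparity_arcmin",
            "dot_density_per_deg2",
            "dot_size_deg",
            "background_grid_square_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.snr <= 1.0:
            raise ValueError("snr must lie in [0, 1]")
        if self.depth_sign not in ("near", "far"):
            raise ValueError("depth_sign must be 'near' or 'far'")

    @property
    def n_dots(self) -> int:
        return int(round(self.dot_density_per_deg2 * self.stim_size_deg**2))


@dataclass
class StereoPair:
    """One rendered RDS trial stimulus.

    ``dots`` holds one row per dot with columns ``x_deg, y_deg,
    disparity_arcmin, polarity, role`` (role in signal/noise/surround);
    ``left_image``/``right_image`` are grayscale rasters in [0, 1].
    """

    dots: pd.DataFrame
    left_image: np.ndarray
    right_image: np.ndarray
    spec: StimulusSpec
    seed: int | None = None
    pixels_per_degree: float = 20.0


def make_oval_mask(shape: tuple[int, int]) -> np.ndarray:
    """Boolean ellipse inscribed in a rectangular grid."""
    rows, cols = shape
    r = (np.arange(rows) + 0.5) / rows * 2.0 - 1.0
    c = (np.arange(cols) + 0.5) / cols * 2.0 - 1.0
    return (r[:, None] ** 2 + c[None, :] ** 2) <= 1.0


def invert_depth_map(depth: DepthMap) -> DepthMap:
    """Rotate a depth map 180 degrees in the picture plane.

    Both the depth values and the mask are rotated; depth amplitudes are
    unchanged, so the depth histogram is preserved exactly.
    """
    return DepthMap(
        values=np.rot90(depth.values, 2).copy(),
        mask=np.rot90(depth.mask, 2).copy(),
        pixels_per_degree=depth.pixels_per_degree,
    )


def phase_randomize(depth: DepthMap, seed: int | np.random.Generator | None = None) -> DepthMap:
    """Scramble Fourier phases while preserving the amplitude spectrum.

    The oval mask is applied to the input before the transform.  Random
    phases are taken from the spectrum of a white-noise real image, which
    is Hermitian-symmetric by construction (DC and Nyquist phases are 0 or
    pi), so the inverse transform is exactly real and the 2D amplitude
    spectrum is conserved to machine precision.  The result removes all
    structural coherence but keeps the depth power of the original.
    """
    if not np.all(np.isfinite(depth.values)):
        raise ValueError("depth values must be finite")
    rng = np.random.default_rng(seed)
    masked = np.where(depth.mask, depth.values, 0.0)
    spectrum = np.fft.fft2(masked)
    amplitude = np.abs(spectrum)
    random_phase = np.angle(np.fft.fft2(rng.standard_normal(masked.shape)))
    scrambled = np.fft.ifft2(amplitude * np.exp(1j * random_phase)).real
    return DepthMap(values=scrambled, mask=depth.mask.copy(),
                    pixels_per_degree=depth.pixels_per_degree)


def _depth_at(depth: DepthMap, x: np.ndarray, y: np.ndarray,
              target_w: float, target_h: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-pixel depth lookup for dot positions inside the target.

    Returns (values, in_target) where in_target marks dots that fall on a
    masked (valid) pixel of the oval target region.
    """
    rows, cols = depth.shape
    col = np.floor((x + target_w / 2.0) / target_w * cols).astype(int)
    row = np.floor((target_h / 2.0 - y) / target_h * rows).astype(int)
    inside = (col >= 0) & (col < cols) & (row >= 0) & (row < rows)
    col_c = np.clip(col, 0, cols - 1)
    row_c = np.clip(row, 0, rows - 1)
    in_target = inside & depth.mask[row_c, col_c]
    return depth.values[row_c, col_c], in_target


def _rasterize(x: np.ndarray, y: np.ndarray, polarity: np.ndarray,
               spec: StimulusSpec, ppd: float) -> np.ndarray:
    """Paint dots as filled squares on a mid-gray raster."""
    size_px = max(2, int(round(spec.stim_size_deg * ppd)))
    img = np.full((size_px, size_px), 0.5)
    half = spec.stim_size_deg / 2.0
    r_dot = max(1, int(round(spec.dot_size_deg * ppd / 2.0)))
    px = np.round((x + half) / spec.stim_size_deg * (size_px - 1)).astype(int)
    py = np.round((half - y) / spec.stim_size_deg * (size_px - 1)).astype(int)
    shade = np.where(polarity == "white", 1.0, 0.0)
    for cx, cy, s in zip(px, py, shade):
        img[max(0, cy - r_dot): cy + r_dot + 1,
            max(0, cx - r_dot): cx + r_dot + 1] = s
    return img


def render_rds(depth: DepthMap, spec: StimulusSpec,
               seed: int | np.random.Generator | None = None,
               pixels_per_degree: float = 20.0,
               rasterize: bool = True) -> StereoPair:
    """Render a depth map as a signal-in-noise random-dot stereogram.

    Dots are placed uniformly at the spec's density over the stimulus
    square.  Inside the oval target, exactly floor(snr * n_target) dots
    (chosen without replacement) are signal dots carrying the depth map's
    local disparity, linearly scaled so the global |max| equals
    ``spec.max_disparity_arcmin`` and signed by ``spec.depth_sign``
    (near = crossed = positive).  The remaining target dots are noise dots
    with disparities drawn uniformly from +/- max disparity.  Surround
    dots lie in the fixation plane (zero disparity).  Half-images shift
    each dot horizontally by +/- d/2 and wrap at the stimulus edge.
    """
    if spec.target_height_deg > spec.stim_size_deg or spec.target_width_deg > spec.stim_size_deg:
        raise ValueError("target exceeds stimulus extent")
    rng = np.random.default_rng(seed)
    n = spec.n_dots
    half = spec.stim_size_deg / 2.0
    x = rng.uniform(-half, half, n)
    y = rng.uniform(-half, half, n)
    polarity = np.where(rng.random(n) < 0.5, "black", "white")

    peak = np.max(np.abs(np.where(depth.mask, depth.values, 0.0)))
    if peak == 0:
        raise ValueError("depth map is blank (max |depth| = 0)")
    scale = spec.max_disparity_arcmin / peak
    sign = 1.0 if spec.depth_sign == "near" else -1.0

    local_depth, in_target = _depth_at(
        depth, x, y, spec.target_width_deg, spec.target_height_deg)

    disparity = np.zeros(n)
    role = np.full(n, "surround", dtype=object)
    target_idx = np.flatnonzero(in_target)
    n_target = target_idx.size
    n_signal = int(math.floor(spec.snr * n_target))
    signal_idx = rng.choice(target_idx, size=n_signal, replace=False)
    noise_idx = np.setdiff1d(target_idx, signal_idx)
    role[signal_idx] = "signal"
    role[noise_idx] = "noise"
    disparity[signal_idx] = sign * scale * local_depth[signal_idx]
    disparity[noise_idx] = rng.uniform(
        -spec.max_disparity_arcmin, spec.max_disparity_arcmin, noise_idx.size)

    dots = pd.DataFrame({
        "x_deg": x, "y_deg": y, "disparity_arcmin": disparity,
        "polarity": polarity, "role": role,
    })

    shift = disparity / ARCMIN_PER_DEG / 2.0  # deg per half-image
    # crossed (positive) disparity: left half-image shifted right, right left
    x_left = (x + shift + half) % spec.stim_size_deg - half
    x_right = (x - shift + half) % spec.stim_size_deg - half
    if rasterize:
        left = _rasterize(x_left, y, polarity, spec, pixels_per_degree)
        right = _rasterize(x_right, y, polarity, spec, pixels_per_degree)
    else:
        left = np.empty((0, 0))
        right = np.empty((0, 0))
    return StereoPair(dots=dots, left_image=left, right_image=right,
                      spec=spec, seed=None if isinstance(seed, np.random.Generator) else seed,
                      pixels_per_degree=pixels_per_degree)


def render_feature_pair(
    depth: DepthMap,
    spec: StimulusSpec,
    target_offset_arcsec: float,
    reference_disparity_arcmin: float = 7.8,
    seed: int | np.random.Generator | None = None,
    offset_range_arcsec: float = 150.0,
    **render_kwargs,
) -> tuple[StereoPair, StereoPair]:
    """Render the reference/target pair for the fine depth-feature task.

    Both stimuli are noise-free (SNR = 1) and carry crossed disparity.
    The reference surface peaks at 7.8 arcmin; the target peaks at the
    reference plus an offset expressed in arcsec (task range 0-150).
    """
    if not 0.0 <= target_offset_arcsec <= offset_range_arcsec:
        raise ValueError(
            f"offset {target_offset_arcsec} arcsec outside "
            f"[0, {offset_range_arcsec}]")
    rng = np.random.default_rng(seed)
    ref_spec = replace(spec, snr=1.0, depth_sign="near",
                       max_disparity_arcmin=reference_disparity_arcmin)
    tgt_peak = reference_disparity_arcmin + target_offset_arcsec / ARCSEC_PER_ARCMIN
    tgt_spec = replace(spec, snr=1.0, depth_sign="near",
                       max_disparity_arcmin=tgt_peak)
    reference = render_rds(depth, ref_spec, rng, **render_kwargs)
    target = render_rds(depth, tgt_spec, rng, **render_kwargs)
    return reference, target


def export_stimulus(pair: StereoPair, path_prefix: str,
                    formats: tuple[str, ...] = ("side_by_side", "anaglyph"),
                    dots_csv: bool = True) -> list[str]:
    """Write a rendered pair to disk.

    Produces ``<prefix>_sbs.png`` (left|right side by side) and/or
    ``<prefix>_anaglyph.png`` (red = left eye, cyan = right eye), plus the
    dot list as CSV.  Returns the written paths.
    """
    import imageio.v3 as iio

    if pair.left_image.size == 0:
        raise ValueError("pair was rendered without rasters")
    written: list[str] = []
    left8 = (pair.left_image * 255).astype(np.uint8)
    right8 = (pair.right_image * 255).astype(np.uint8)
    if "side_by_side" in formats:
        p = f"{path_prefix}_sbs.png"
        iio.imwrite(p, np.hstack([left8, right8]))
        written.append(p)
    if "anaglyph" in formats:
        p = f"{path_prefix}_anaglyph.png"
        iio.imwrite(p, np.stack([left8, right8, right8], axis=-1))
        written.append(p)
    if dots_csv:
        p = f"{path_prefix}_dots.csv"
        pair.dots.to_csv(p, index=False)
        written.append(p)
    return written


def load_depth_map(path: str, pixels_per_degree: float,
                   mask: np.ndarray | None = None) -> DepthMap:
    """Read a grayscale depth map from PNG (8/16-bit) or whitespace text.

    Intensity codes depth; values are centered so mid-gray maps to zero.
    If no mask is given, the inscribed oval is used.
    """
    if path.endswith((".png", ".tif", ".tiff")):
        import imageio.v3 as iio

        raw = np.asarray(iio.imread(path), dtype=float)
        if raw.ndim == 3:
            raw = raw.mean(axis=-1)
        raw = raw / raw.max() - 0.5 if raw.max() > 0 else raw
    else:
        raw = np.loadtxt(path, dtype=float)
    if mask is None:
        mask = make_oval_mask(raw.shape)
    return DepthMap(values=raw, mask=mask, pixels_per_degree=pixels_per_degree)
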