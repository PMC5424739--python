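"""Pupil and glint segmentation in NIR eye images.

The detector runs in three stages. A rough pupil estimate is found by
histogram thresholding of dark pixels, morphological cleaning, and a
circular Hough transform (CHT). A bright-spot pass inside the eye ROI
locates the corneal glint the same way. Both rough circles then seed a
region-based level-set refinement (a Chan--Vese energy restricted to an
adaptive mask around each seed), and the geometric centers are the
centroids of the refined regions.

Coordinates are 0-based pixels, x to the right, y down; centers may be
fractional. Arrays are indexed ``[y, x]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion, opening
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import DegenerateHistogramError, NoCircleError, SegmentationCollapseError

__all__ = [
    "EyeFrame",
    "CircleEstimate",
    "RegionBoundary",
    "Detection",
    "SegmentationConfig",
    "binarize_dark_regions",
    "clean_binary",
    "detect_circle_cht",
    "refine_boundary_chan_vese",
    "detect_pupil_and_glint",
]


@dataclass(frozen=True)
class EyeFrame:
    """One grayscale NIR eye image.

    Parameters
    ----------
    pixels : ndarray
        2-D 8-bit intensity array.
    frame_index : int
        Non-negative frame number within the session.
    eye_side : {"left", "right"}
    """

    pixels: np.ndarray
    frame_index: int = 0
    eye_side: str = "left"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError("eye frame must be 2-D and at least 64x64")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if self.eye_side not in ("left", "right"):
            raise ValueError("eye_side must be 'left' or 'right'")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class CircleEstimate:
    """Rough circle from the Hough accumulator: center (x, y), radius, vote score."""

    center: tuple[float, float]
    radius: float
    score: float


@dataclass
class RegionBoundary:
    """A single-component segmented region with its traced boundary."""

    mask: np.ndarray
    contour: np.ndarray
    area: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "RegionBoundary":
        mask = np.asarray(mask, dtype=bool)
        contours = measure.find_contours(mask.astype(float), 0.5)
        if contours:
            longest = max(contours, key=len)
            contour = longest[:, ::-1]  # (row, col) -> (x, y)
        else:
            contour = np.empty((0, 2))
        return cls(mask=mask, contour=contour, area=int(mask.sum()))

    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(xs.mean()), float(ys.mean())


@dataclass
class Detection:
    """Per-frame pupil + glint result. ``valid`` requires both structures."""

    pupil: RegionBoundary | None
    glint: RegionBoundary | None
    pupil_center: tuple[float, float] | None
    glint_center: tuple[float, float] | None
    valid: bool

    @property
    def pupil_area(self) -> int | None:
        return None if self.pupil is None else self.pupil.area


@dataclass
class SegmentationConfig:
    """Tunable parameters of the detector (defaults suit ~160x120 eye crops)."""

    binarize_threshold: float | str = "auto"
    open_radius: int = 2
    median_size: int = 3
    pupil_radius_range: tuple[int, int] = (10, 40)
    glint_radius_range: tuple[int, int] = (2, 10)
    glint_rel_threshold: float = 0.9
    glint_min_intensity: float = 180.0  # glints are near-saturated specular spots
    eye_roi_scale: float = 3.0
    mask_pupil_scale: float = 1.5
    mask_glint_scale: float = 2.0
    mu: float = 0.25
    lambda_in: float = 1.0
    lambda_out: float = 1.0
    max_iter: int = 200
    vote_floor: float = 8.0


def binarize_dark_regions(frame: EyeFrame, threshold: float | str = "auto") -> np.ndarray:
    """Mask pixels darker than ``threshold``.

    ``"auto"`` picks Otsu's inter-class-variance threshold from the
    intensity histogram (the threshold level itself belongs to the dark
    class, as Otsu places it on the lower class edge); a flat histogram
    raises :class:`DegenerateHistogramError`.
    """
    px = frame.pixels
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        if px.max() == px.min():
            raise DegenerateHistogramError("degenerate histogram: uniform image")
        return px <= threshold_otsu(px)
    return px < threshold


def clean_binary(mask: np.ndarray, open_radius: int = 2, median_size: int = 3) -> np.ndarray:
    """Remove speckle noise: opening, median filter, keep the largest component."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    out = mask
    if open_radius > 0:
        out = opening(out, disk(open_radius))
    if median_size > 1:
        out = ndimage.median_filter(out.astype(np.uint8), size=median_size).astype(bool)
    if not out.any():
        return out
    labels, n = ndimage.label(out)
    if n > 1:
        sizes = ndimage.sum_labels(out, labels, index=np.arange(1, n + 1))
        out = labels == (1 + int(np.argmax(sizes)))
    return out


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """8-connected outer boundary of a binary mask (for Hough voting)."""
    mask = np.asarray(mask, dtype=bool)
    return mask & ~erosion(mask, disk(1))


def detect_circle_cht(
    mask_or_edges: np.ndarray,
    radius_range: tuple[int, int],
    vote_floor: float = 8.0,
) -> CircleEstimate:
    """Highest-vote circle over ``radius_range`` by the circular Hough transform.

    Votes are raw accumulator counts (not perimeter-normalized), so larger
    well-supported circles beat small ones, matching an exhaustive
    accumulator count. Raises :class:`NoCircleError` if no candidate
    reaches ``vote_floor`` votes.
    """
    rmin, rmax = radius_range
    if rmin < 2 or rmax <= rmin:
        raise ValueError("need rmin >= 2 and rmax > rmin")
    edges = np.asarray(mask_or_edges, dtype=bool)
    if not edges.any():
        raise NoCircleError("no circle found: empty input")
    radii = np.arange(rmin, rmax + 1)
    accum = hough_circle(edges, radii, normalize=False)
    votes, cxs, cys, rads = hough_circle_peaks(accum, radii, total_num_peaks=1)
    if len(votes) == 0 or votes[0] < vote_floor:
        raise NoCircleError("no circle found: accumulator below vote floor")
    return CircleEstimate(center=(float(cxs[0]), float(cys[0])), radius=float(rads[0]), score=float(votes[0]))


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def _region_energy(
    u: np.ndarray, region: np.ndarray, domain: np.ndarray, mu: float, lin: float, lout: float
) -> tuple[float, float, float]:
    """Chan--Vese energy of ``region`` within ``domain`` with optimal constants.

    Energy = mu * perimeter + lin * sum_in (u - cin)^2 + lout * sum_out (u - cout)^2,
    perimeter counted as 4-neighbor label-change edges inside the domain.
    """
    inside = region & domain
    outside = domain & ~region
    cin = float(u[inside].mean()) if inside.any() else 0.0
    cout = float(u[outside].mean()) if outside.any() else 0.0
    per = int(np.sum(region[:, 1:] != region[:, :-1])) + int(np.sum(region[1:, :] != region[:-1, :]))
    e = mu * per + lin * float(((u[inside] - cin) ** 2).sum()) + lout * float(((u[outside] - cout) ** 2).sum())
    return e, cin, cout


def refine_boundary_chan_vese(
    frame: EyeFrame,
    seed: CircleEstimate,
    mask_margin: float = 1.5,
    mu: float = 0.25,
    lambda_in: float = 1.0,
    lambda_out: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-3,
    record_energy: list[float] | None = None,
) -> RegionBoundary:
    """Refine a seed circle into an accurate region boundary.

    Minimizes the piecewise-constant Mumford--Shah (Chan--Vese) energy
    restricted to an adaptive mask -- a disk around the seed, scaled by
    ``mask_margin`` so the mask tracks the rough pupil/glint size and
    location. The curve is initialized on the seed circle and evolved by
    alternating minimization: region constants are the current region
    means, and a candidate region update (the data-optimal relabeling,
    optionally median-smoothed for the length term) is accepted only if
    it lowers the energy, so the energy is non-increasing by
    construction. Intensities are normalized to [0, 1]; ``mu`` weighs
    the discrete perimeter on that scale.

    Pass ``record_energy`` to collect the per-iteration energy values.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    u = frame.pixels.astype(float) / 255.0
    domain = _disk_mask(u.shape, seed.center, mask_margin * seed.radius)
    if not domain.any():
        raise SegmentationCollapseError("adaptive mask lies outside the frame")
    region = _disk_mask(u.shape, seed.center, seed.radius) & domain
    if not region.any() or not (domain & ~region).any():
        raise SegmentationCollapseError("seed circle does not split the adaptive mask")

    n_domain = int(domain.sum())
    energy, cin, cout = _region_energy(u, region, domain, mu, lambda_in, lambda_out)
    if record_energy is not None:
        record_energy.append(energy)
    for _ in range(max_iter):
        # Data-optimal relabeling given the current means.
        cand = (lambda_in * (u - cin) ** 2 <= lambda_out * (u - cout) ** 2) & domain
        # Length-term candidate: majority-smoothed version of the relabeling.
        smooth = ndimage.median_filter(cand.astype(np.uint8), size=3).astype(bool) & domain
        best, best_e = region, energy
        for trial in (cand, smooth):
            if not trial.any() or not (domain & ~trial).any():
                continue
            e, _, _ = _region_energy(u, trial, domain, mu, lambda_in, lambda_out)
            if e < best_e:
                best, best_e = trial, e
        changed = int(np.sum(best ^ region))
        region, energy = best, best_e
        _, cin, cout = _region_energy(u, region, domain, mu, lambda_in, lambda_out)
        if record_energy is not None:
            record_energy.append(energy)
        if changed <= tol * n_domain:
            break

    if not region.any() or not (domain & ~region).any():
        raise SegmentationCollapseError("segmentation collapsed")
    labels, n = ndimage.label(region)
    if n > 1:
        sizes = ndimage.sum_labels(region, labels, index=np.arange(1, n + 1))
        region = labels == (1 + int(np.argmax(sizes)))
    return RegionBoundary.from_mask(region)


def _clip_roi(shape: tuple[int, int], center: tuple[float, float], half: float) -> tuple[slice, slice]:
    x0 = max(0, int(np.floor(center[0] - half)))
    x1 = min(shape[1], int(np.ceil(center[0] + half)) + 1)
    y0 = max(0, int(np.floor(center[1] - half)))
    y1 = min(shape[0], int(np.ceil(center[1] + half)) + 1)
    return slice(y0, y1), slice(x0, x1)


def detect_pupil_and_glint(frame: EyeFrame, config: SegmentationConfig | None = None) -> Detection:
    """Full per-frame detector: rough circles, refinement, geometric centers.

    Returns a :class:`Detection` with ``valid=False`` (instead of raising)
    when the pupil or the glint cannot be found, so downstream feature
    extraction can skip the frame. Glint pixels overlapping the pupil are
    excluded from the pupil region before the area count and centroid.
    """
    cfg = config or SegmentationConfig()

    # Rough pupil: dark threshold -> clean -> CHT on the mask boundary.
    try:
        dark = binarize_dark_regions(frame, cfg.binarize_threshold)
    except DegenerateHistogramError:
        return Detection(None, None, None, None, False)
    dark = clean_binary(dark, cfg.open_radius, cfg.median_size)
    if not dark.any():
        return Detection(None, None, None, None, False)
    try:
        pupil_seed = detect_circle_cht(boundary_pixels(dark), cfg.pupil_radius_range, cfg.vote_floor)
    except NoCircleError:
        return Detection(None, None, None, None, False)

    # Eye ROI around the rough pupil; bright-spot glint pass inside it.
    roi = _clip_roi(frame.pixels.shape, pupil_seed.center, cfg.eye_roi_scale * pupil_seed.radius)
    roi_px = frame.pixels[roi]
    bright = np.zeros_like(frame.pixels, dtype=bool)
    bright[roi] = roi_px >= max(cfg.glint_rel_threshold * roi_px.max(), cfg.glint_min_intensity)
    bright = clean_binary(bright, open_radius=1, median_size=1)
    glint_seed = None
    if bright.any():
        try:
            glint_seed = detect_circle_cht(boundary_pixels(bright), cfg.glint_radius_range, cfg.vote_floor)
        except NoCircleError:
            glint_seed = None

    # Level-set refinement of both structures with their adaptive masks.
    try:
        pupil = refine_boundary_chan_vese(
            frame, pupil_seed, cfg.mask_pupil_scale, cfg.mu, cfg.lambda_in, cfg.lambda_out, cfg.max_iter
        )
    except SegmentationCollapseError:
        return Detection(None, None, None, None, False)
    glint = None
    if glint_seed is not None:
        try:
            glint = refine_boundary_chan_vese(
                frame, glint_seed, cfg.mask_glint_scale, cfg.mu, cfg.lambda_in, cfg.lambda_out, cfg.max_iter
            )
        except SegmentationCollapseError:
            glint = None

    if glint is not None and (pupil.mask & glint.mask).any():
        pupil = RegionBoundary.from_mask(pupil.mask & ~glint.mask)

    pupil_center = pupil.centroid()
    if glint is None:
        return Detection(pupil, None, pupil_center, None, False)
    return Detection(pupil, glint, pupil_center, glint.centroid(), True)
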