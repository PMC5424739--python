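"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the three signal families the method consumes:

* NIR eye frames -- a mid-gray iris, a dark (optionally chord-clipped,
  hence non-elliptical) pupil disk, a small bright corneal glint, and
  additive Gaussian sensor noise clipped to [0, 255];
* per-frame pupil-size series and monitor-space gaze traces organized
  into balanced selection (TP) and non-selection (TN) events -- TP
  events pair a template-shaped pupil constriction (20% dip over the
  10-frame window) with a sub-threshold gaze jitter landing on a
  textured monitor patch; TN events either wander (saccadic gaze), or
  fixate with a flat pupil on a blank monitor region;
* monitor images of controllable texture density (band-limited patches
  on a flat background, with patch centers recorded).

Everything is driven by ``numpy.random.default_rng`` with an explicit
integer seed, so a fixed seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .pupil_feature import WINDOW_SIZE, default_template_bank
from .segmentation import EyeFrame

__all__ = [
    "EyeSceneTruth",
    "SyntheticSession",
    "gen_eye_frame",
    "gen_monitor_image",
    "gen_session",
]


@dataclass(frozen=True)
class EyeSceneTruth:
    """Scene parameters of one rendered eye frame (the rendering ground truth)."""

    pupil_center: tuple[float, float]
    pupil_radius: float
    pupil_intensity: float
    glint_center: tuple[float, float]
    glint_radius: float
    glint_intensity: float
    iris_level: float
    noise_sigma: float
    chord_offset: float | None  # pupil-radius fractions; None = full disk
    seed: int

    def pupil_mask(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = self.pupil_center
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= self.pupil_radius**2
        if self.chord_offset is not None:
            # flat chord cut on the +x side, at chord_offset * radius from center
            mask &= xx - cx <= self.chord_offset * self.pupil_radius
        return mask

    def glint_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.glint_radius <= 0:  # glint-free scene (e.g. illuminator off)
            return np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = self.glint_center
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.glint_radius**2


def gen_eye_frame(
    truth: EyeSceneTruth | None = None,
    frame_index: int = 0,
    seed: int = 0,
    shape: tuple[int, int] = (120, 160),
    eye_side: str = "left",
    **overrides,
) -> tuple[EyeFrame, EyeSceneTruth]:
    """Render one synthetic NIR eye frame and return it with its truth record.

    With ``truth=None`` a default scene is built (pupil r=22 at (80, 60),
    glint r=4 at (85, 55), iris 120) and ``overrides`` patch individual
    truth fields, e.g. ``noise_sigma=10``.
    """
    if truth is None:
        defaults = dict(
            pupil_center=(80.0, 60.0),
            pupil_radius=22.0,
            pupil_intensity=25.0,
            glint_center=(85.0, 55.0),
            glint_radius=4.0,
            glint_intensity=250.0,
            iris_level=120.0,
            noise_sigma=0.0,
            chord_offset=None,
            seed=seed,
        )
        defaults.update(overrides)
        truth = EyeSceneTruth(**defaults)
    cx, cy = truth.pupil_center
    r = truth.pupil_radius
    if not (0 <= cx - r and cx + r < shape[1] and 0 <= cy - r and cy + r < shape[0]):
        raise ValueError("invalid scene: pupil out of frame")

    img = np.full(shape, truth.iris_level, dtype=float)
    img[truth.pupil_mask(shape)] = truth.pupil_intensity
    img[truth.glint_mask(shape)] = truth.glint_intensity
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed + frame_index)
        img = img + rng.normal(0.0, truth.noise_sigma, size=shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return EyeFrame(pixels=img, frame_index=frame_index, eye_side=eye_side), truth


def gen_monitor_image(
    texture_density: float = 0.5,
    seed: int = 0,
    shape: tuple[int, int] = (300, 400),
    n_sites: int = 12,
    patch_radius: int = 30,
    background: float = 128.0,
    contrast: float = 60.0,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Flat background with band-limited texture patches; returns (image, patch centers).

    ``texture_density`` in [0, 1] sets the fraction of the ``n_sites``
    candidate sites that receive a texture patch. Patch texture is
    Gaussian-band-passed white noise windowed by a radial envelope.
    """
    if not (0.0 <= texture_density <= 1.0):
        raise ValueError("texture_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    # candidate sites on a jittered grid, away from the borders
    margin = patch_radius + 5
    sites = [
        (
            int(rng.integers(margin, shape[1] - margin)),
            int(rng.integers(margin, shape[0] - margin)),
        )
        for _ in range(n_sites)
    ]
    n_patches = int(round(texture_density * n_sites))
    centers = sites[:n_patches]
    yy, xx = np.mgrid[-patch_radius : patch_radius + 1, -patch_radius : patch_radius + 1]
    envelope = np.clip(1.0 - np.sqrt(xx**2 + yy**2) / patch_radius, 0.0, 1.0)
    for cx, cy in centers:
        noise = rng.normal(0.0, 1.0, envelope.shape)
        band = ndimage.gaussian_filter(noise, 1.0) - ndimage.gaussian_filter(noise, 4.0)
        band = band / max(1e-12, np.abs(band).max())
        patch = contrast * band * envelope
        img[cy - patch_radius : cy + patch_radius + 1, cx - patch_radius : cx + patch_radius + 1] += patch
    return np.clip(np.round(img), 0, 255).astype(np.uint8), centers


@dataclass
class SyntheticSession:
    """Signal-level session: per-frame pupil sizes and gaze, per-event labels.

    ``events`` holds (start_frame, end_frame_exclusive, label) with label
    1 for selection (TP) and 0 for non-selection (TN). ``monitor`` is the
    screenshot the texture feature reads; ``patch_centers`` the textured
    sites; ``blank_points`` texture-free gaze targets used by TN events.
    """

    pupil_sizes: np.ndarray
    gaze: np.ndarray  # (n_frames, 2) monitor px
    events: list[tuple[int, int, int]]
    monitor: np.ndarray
    patch_centers: list[tuple[int, int]]
    seed: int
    window: int = WINDOW_SIZE
    fps: float = 30.0

    @property
    def n_frames(self) -> int:
        return len(self.pupil_sizes)

    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.events])


def _constriction_shape(rng: np.random.Generator, window: int) -> np.ndarray:
    """A normalized dip profile drawn from the template family (jittered)."""
    bank = default_template_bank(window)
    base = bank[int(rng.integers(len(bank)))].values
    return np.clip(base + rng.normal(0.0, 0.03, size=window), 0.0, 1.2)

# Event layout: lead-in saccade frames, then the analysis window, then tail frames.
_LEAD, _TAIL = 4, 2


def gen_session(
    n_events: int = 10,
    window: int = WINDOW_SIZE,
    seed: int = 0,
    base_pupil_area: float = 1500.0,
    dip_fraction: float = 0.20,
    pupil_noise: float = 3.0,
    fixation_jitter: float = 1.0,
    drift_speed: float = 2.5,
    saccade_step: tuple[float, float] = (15.0, 40.0),
    monitor_shape: tuple[int, int] = (300, 400),
) -> SyntheticSession:
    """Generate a balanced TP/TN session at the signal level.

    Events alternate TP, TN, TP, ... (``n_events // 2`` of each when
    even). Each event spans ``_LEAD`` high-motion lead-in frames, the
    ``window``-frame analysis span, and ``_TAIL`` tail frames.

    TP events: the lead-in saccade completes onto a textured patch, the
    gaze then jitters by ``fixation_jitter`` per frame (below the
    5 px/frame stillness threshold) and the pupil follows a
    template-shaped constriction of ``dip_fraction`` relative depth.
    TN events alternate between (a) a wandering gaze (uniform saccade
    steps in ``saccade_step``, no fixation run) and (b) a casual
    fixation on a blank monitor point: the gaze drifts at
    ``drift_speed`` px/frame (within the stillness gate but less
    stable than an intent gaze) and the pupil dilates slowly (the
    relaxation drift of an unengaged fixation, the opposite of the
    constrict-and-recover accommodation signature).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    monitor, patches = gen_monitor_image(texture_density=0.5, seed=seed + 1, shape=monitor_shape)
    if not patches:
        raise ValueError("monitor must contain at least one textured patch for TP events")
    # Blank targets: far from every patch.
    blanks = []
    h, w = monitor_shape
    while len(blanks) < 8:
        cand = (int(rng.integers(40, w - 40)), int(rng.integers(40, h - 40)))
        if all(np.hypot(cand[0] - px, cand[1] - py) > 70 for px, py in patches):
            blanks.append(cand)

    span = _LEAD + window + _TAIL
    sizes: list[float] = []
    gaze: list[tuple[float, float]] = []
    events: list[tuple[int, int, int]] = []
    tn_kind = 0
    pos = np.array([w / 2, h / 2], dtype=float)
    for k in range(n_events):
        label = 1 if k % 2 == 0 else 0
        start = k * span
        # lead-in: saccadic travel toward the event target
        if label == 1:
            target = np.array(patches[int(rng.integers(len(patches)))], dtype=float)
        elif tn_kind == 1:
            target = np.array(blanks[int(rng.integers(len(blanks)))], dtype=float)
        else:
            target = pos  # wandering event has no destination
        fixating = label == 1 or tn_kind == 1
        for j in range(_LEAD):
            if fixating and j == _LEAD - 1:
                # the saccade completes: last lead-in frame lands on target
                pos = target + rng.normal(0.0, fixation_jitter / np.sqrt(2), 2)
            else:
                step = rng.uniform(*saccade_step)
                direction = target - pos
                norm = np.hypot(*direction)
                if fixating and norm <= saccade_step[0]:
                    # hover short of the target so the final landing saccade
                    # is the unambiguous start of the stillness run
                    angle = rng.uniform(0.0, 2 * np.pi)
                    pos = target + 15.0 * np.array([np.cos(angle), np.sin(angle)])
                elif norm > 1.0:
                    pos = pos + direction / norm * min(step, norm)
                else:
                    pos = pos + rng.normal(0.0, step, 2)
            pos = np.clip(pos, 0, [w - 1, h - 1])
            gaze.append(tuple(pos))
            sizes.append(base_pupil_area + rng.normal(0.0, pupil_noise))

        if label == 1:
            dip = _constriction_shape(rng, window)
            for j in range(window):
                pos = np.clip(target + rng.normal(0.0, fixation_jitter / np.sqrt(2), 2), 0, [w - 1, h - 1])
                gaze.append(tuple(pos))
                sizes.append(
                    base_pupil_area * (1.0 - dip_fraction * (1.0 - dip[j]))
                    + rng.normal(0.0, pupil_noise)
                )
        elif tn_kind == 1:  # casual fixation on a blank region: slow ocular
            # drift (below the stillness gate but well above intent-gaze
            # jitter) and a slowly relaxing (dilating) pupil
            slope = rng.uniform(1.0, 2.5)
            angle = rng.uniform(0.0, 2 * np.pi)
            velocity = drift_speed * np.array([np.cos(angle), np.sin(angle)])
            anchor = target.copy()
            for j in range(window):
                anchor = anchor + velocity
                pos = np.clip(anchor + rng.normal(0.0, fixation_jitter / np.sqrt(2), 2), 0, [w - 1, h - 1])
                gaze.append(tuple(pos))
                sizes.append(base_pupil_area + slope * j + rng.normal(0.0, pupil_noise))
        else:  # wandering gaze
            for _ in range(window):
                step = rng.uniform(*saccade_step)
                angle = rng.uniform(0.0, 2 * np.pi)
                pos = np.clip(pos + step * np.array([np.cos(angle), np.sin(angle)]), 0, [w - 1, h - 1])
                gaze.append(tuple(pos))
                sizes.append(base_pupil_area + rng.normal(0.0, pupil_noise))
        if label == 0:
            tn_kind = 1 - tn_kind
        for _ in range(_TAIL):
            pos = np.clip(pos + rng.normal(0.0, 1.0, 2), 0, [w - 1, h - 1])
            gaze.append(tuple(pos))
            sizes.append(base_pupil_area + rng.normal(0.0, pupil_noise))
        events.append((start, start + span, label))

    return SyntheticSession(
        pupil_sizes=np.asarray(sizes),
        gaze=np.asarray(gaze),
        events=events,
        monitor=monitor,
        patch_centers=patches,
        seed=seed,
        window=window,
    )
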