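"""Synthetic facial-video scenes with a known embedded pulse.

The generator emits frame stacks whose skin-pixel intensity follows the
additive reflectance decomposition

    P(x, y, t) = base(x, y) + alpha(x, y) p(t) + beta(x, y) w(t) + noise

where ``p(t)`` is the blood-volume pulse (a harmonic-rich periodic waveform
at the configured heart rate), ``w(t)`` a slow illumination drift, and
``alpha``/``beta`` location-dependent gains; ``alpha`` is zero off skin.
A face is an ellipse of skin-cluster chromaticity carrying a fixed landmark
template; rigid head motion moves face and landmarks together.  Non-skin
occluders (glasses, beard) and an oscillating nose-like occluder — whose
adjacent landmarks wobble so neighbouring triangles' pixel counts oscillate
— provide the disturbances the adaptive patch-selection stages must reject.

Everything downstream (skin model training, patch tracking, stability
selection, ICA voting) is testable against the stored ground truth without
any external data.

A companion toy *detection* task (dot-pattern faces in three poses) serves
the joint face detection/alignment module the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import FrameStack, LandmarkTrack
from .patch_mesh import TriangleMesh, triangulate
from .skin_map import ycbcr_to_rgb

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "MotionConfig",
    "IlluminationConfig",
    "SkinTrainingConfig",
    "ConfigError",
    "generate_scene",
    "generate_skin_training_set",
    "DetectionTaskConfig",
    "DetectionTask",
    "generate_detection_task",
    "plant_face_frame",
    "pose_shape",
    "POSES",
]


class ConfigError(ValueError):
    """Invalid scene configuration."""


# ---------------------------------------------------------------------------
# landmark template (27 points) in face-ellipse units: x in [-1, 1],
# y in [-1.3, 1.3], y grows downward.  Index groups:
#   0-6 jaw, 7-10 brows, 11-14 eye corners (11/14 = outer left/right),
#   15-17 nose, 18-21 mouth, 22-23 cheeks, 24-26 forehead.
_TEMPLATE = np.array(
    [
        (-0.95, 0.20), (-0.80, 0.70), (-0.45, 1.10), (0.00, 1.28),
        (0.45, 1.10), (0.80, 0.70), (0.95, 0.20),
        (-0.60, -0.75), (-0.20, -0.85), (0.20, -0.85), (0.60, -0.75),
        (-0.55, -0.45), (-0.25, -0.45), (0.25, -0.45), (0.55, -0.45),
        (-0.18, 0.05), (0.00, 0.25), (0.18, 0.05),
        (-0.35, 0.70), (0.00, 0.60), (0.35, 0.70), (0.00, 0.82),
        (-0.60, 0.15), (0.60, 0.15),
        (-0.50, -1.10), (0.50, -1.10), (0.00, -1.20),
    ]
)
NOSE_LANDMARKS = (15, 16, 17)
EYE_OUTER_CORNERS = (11, 14)

_GLASSES_RGB = (40, 40, 40)
_BEARD_RGB = (30, 20, 15)
_NOSE_OCCLUDER_RGB = (150, 145, 175)  # luma near skin, chroma far off
# pulse adds mostly to green (hemoglobin absorption peaks in the green band)
_PULSE_CHANNEL_WEIGHTS = np.array([0.5, 1.0, 0.5])


@dataclass
class MotionConfig:
    """Rigid head motion: sinusoidal sway plus a broadband tremor.

    The sway (translation + in-plane rotation at ``period_s``) models slow
    posture drift; ``tremor_px`` adds a low-pass-filtered random translation
    with spectral content reaching into the pulse band, as real head motion
    has.  Patches that track landmarks ride the tremor out; anything
    anchored to fixed frame coordinates sees it as in-band noise.
    """

    translation_px: float = 3.0
    rotation_deg: float = 3.0
    period_s: float = 8.0
    tremor_px: float = 1.0


@dataclass
class IlluminationConfig:
    """Illumination signal w(t): slow sinusoid + linear ramp + screen flicker.

    The sinusoid and ramp sit well below the 0.7 Hz pulse band; the flicker
    term is band-limited noise reaching into the pulse band, emulating a
    subject facing a flickering display.  All facial patches share one
    flicker realization through their beta gains; the background sees its
    own realization (a different mix of the room's light sources)."""

    amplitude: float = 0.08  # fraction of mean skin luma
    freq_hz: float = 0.1
    ramp: float = 0.5  # relative weight of the linear ramp component
    flicker: float = 0.5  # relative std of the band-limited flicker component


@dataclass
class SceneConfig:
    frame_rate: float = 30.0
    duration: float = 30.0
    image_size: tuple[int, int] = (96, 96)  # (width, height)
    hr_true: float = 72.0  # bpm
    pulse_amplitude: float = 0.02  # fraction of mean skin intensity
    illumination: IlluminationConfig = field(default_factory=IlluminationConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    n_landmarks: int = 27
    occluders: tuple[str, ...] = ("glasses", "beard")
    unstable_region: bool = True
    noise_sigma: float = 2.0  # per-pixel Gaussian std, intensity units
    background_noise_sigma: float = 6.0  # dynamic background (screen-lit) noise
    landmark_jitter: float = 0.1  # px, emulates aligner noise
    seed: int = 0
    skin_mean_cbcr: tuple[float, float] = (109.0, 152.0)
    skin_std_cbcr: float = 5.0
    skin_y_mean: float = 155.0
    skin_y_std: float = 8.0
    shading_std: float = 8.0  # smooth facial shading, intensity units
    allow_out_of_band: bool = False

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def validate(self) -> None:
        f_hr = self.hr_true / 60.0
        if not self.allow_out_of_band and not (0.7 <= f_hr <= 4.0):
            raise ConfigError("hr_true outside the 42-240 bpm pulse band")
        if self.frame_rate <= 2 * f_hr:
            raise ConfigError("frame rate violates Nyquist for hr_true")
        if self.n_frames < 64:
            raise ConfigError("clip too short for spectral estimation (< 64 frames)")
        if not 1 <= self.n_landmarks <= len(_TEMPLATE):
            raise ConfigError(f"n_landmarks must be in [1, {len(_TEMPLATE)}]")


@dataclass
class SceneTruth:
    """Ground truth emitted alongside a synthetic scene."""

    hr_true: float
    pulse_signal: np.ndarray
    illumination_signal: np.ndarray
    skin_mask_per_frame: np.ndarray
    landmark_track: LandmarkTrack
    mesh: TriangleMesh
    patch_stability_labels: np.ndarray  # True = unstable
    unstable_landmark_ids: tuple[int, ...]


def _pulse_waveform(t: np.ndarray, f_hr: float) -> np.ndarray:
    """Harmonic-rich pulse: fundamental plus a 0.3-amplitude first harmonic,
    normalized to unit peak."""
    p = np.sin(2 * np.pi * f_hr * t) + 0.3 * np.sin(4 * np.pi * f_hr * t)
    return p / np.max(np.abs(p))


def generate_scene(config: SceneConfig) -> tuple[FrameStack, SceneTruth]:
    """Render a synthetic facial clip and its ground truth.

    Deterministic given ``config.seed``.  Raises :class:`ConfigError` on
    Nyquist violation or clips shorter than 64 frames.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    width, height = config.image_size
    n_frames = config.n_frames
    t = np.arange(n_frames) / config.frame_rate
    f_hr = config.hr_true / 60.0

    # --- temporal signals -------------------------------------------------
    pulse = _pulse_waveform(t, f_hr)
    il = config.illumination
    drift = np.sin(2 * np.pi * il.freq_hz * t + 0.7)
    if config.duration > 0:
        drift = drift + il.ramp * (2 * t / config.duration - 1)
    # screen flicker: band-limited luminance noise reaching into the pulse
    # band.  The face and the scene behind it see different mixes of the
    # room's light sources, so the background gets its own realization.
    drift_bg = drift.copy()
    if il.flicker > 0:
        from scipy.ndimage import gaussian_filter1d

        def _band_noise():
            raw = rng.standard_normal(n_frames)
            flick = gaussian_filter1d(raw, 2.0, mode="nearest") - gaussian_filter1d(
                raw, 8.0, mode="nearest"
            )
            s = flick.std()
            return flick / s if s > 0 else flick

        drift = drift + il.flicker * _band_noise()
        drift_bg = drift_bg + il.flicker * _band_noise()
    pulse_gain = config.pulse_amplitude * config.skin_y_mean
    illum_gain = il.amplitude * config.skin_y_mean

    # --- static textures in reference (frame-0, motion-free) coords -------
    cx, cy = width / 2.0, height / 2.0
    rx, ry = 0.30 * width, 0.40 * height
    X, Y = np.meshgrid(np.arange(width, dtype=float), np.arange(height, dtype=float))

    cb = config.skin_mean_cbcr[0] + rng.normal(0, config.skin_std_cbcr, (height, width))
    cr = config.skin_mean_cbcr[1] + rng.normal(0, config.skin_std_cbcr, (height, width))
    luma = config.skin_y_mean + rng.normal(0, config.skin_y_std, (height, width))
    if config.shading_std > 0:
        # smooth shading field: faces are not flat — under head motion this
        # is what turns fixed-coordinate patches into artifact generators
        from scipy.ndimage import gaussian_filter

        shading = gaussian_filter(rng.standard_normal((height, width)), sigma=6.0)
        s = shading.std()
        if s > 0:
            luma = luma + config.shading_std * shading / s
    base_rgb = ycbcr_to_rgb(luma, cb, cr)
    bg_rgb = rng.integers(0, 256, (height, width, 3)).astype(float)

    # illumination gain: gradient across the scene, fixed in frame coords
    beta = 1.0 + 0.2 * (X / width - 0.5)

    template = _TEMPLATE[: config.n_landmarks]
    lm_ref = np.empty_like(template)
    lm_ref[:, 0] = cx + template[:, 0] * rx
    lm_ref[:, 1] = cy + template[:, 1] * ry

    # occluders are described analytically in reference coordinates so
    # their edges move smoothly with the face under sub-pixel motion
    glasses_rects = []
    if "glasses" in config.occluders and config.n_landmarks > max(EYE_OUTER_CORNERS):
        for lo, hi in ((11, 12), (13, 14)):
            x_lo = min(lm_ref[lo, 0], lm_ref[hi, 0]) - 0.08 * rx
            x_hi = max(lm_ref[lo, 0], lm_ref[hi, 0]) + 0.08 * rx
            y_c = lm_ref[lo, 1]
            glasses_rects.append((x_lo, x_hi, y_c - 0.10 * ry, y_c + 0.10 * ry))
    has_beard = "beard" in config.occluders

    def face_predicates(px, py):
        """Ellipse membership and occluder masks at reference coords."""
        uxf = (px - cx) / rx
        uyf = (py - cy) / ry
        inface = uxf**2 + (uyf / 1.3) ** 2 <= 1.0
        glasses = np.zeros_like(inface)
        for x_lo, x_hi, y_lo, y_hi in glasses_rects:
            glasses |= (px >= x_lo) & (px <= x_hi) & (py >= y_lo) & (py <= y_hi)
        glasses &= inface
        beard = (
            (np.abs(uxf) <= 0.55) & (uyf >= 0.88) & inface
            if has_beard
            else np.zeros_like(inface)
        )
        return inface, glasses, beard

    def sample_bilinear(tex, px, py):
        """Bilinear texture lookup (camera-like sub-pixel integration)."""
        px = np.clip(px, 0.0, width - 1.0)
        py = np.clip(py, 0.0, height - 1.0)
        x0i = np.clip(px.astype(int), 0, width - 2)
        y0i = np.clip(py.astype(int), 0, height - 2)
        fx = (px - x0i)[..., None] if tex.ndim == 3 else px - x0i
        fy = (py - y0i)[..., None] if tex.ndim == 3 else py - y0i
        v00 = tex[y0i, x0i]
        v01 = tex[y0i, x0i + 1]
        v10 = tex[y0i + 1, x0i]
        v11 = tex[y0i + 1, x0i + 1]
        return (
            v00 * (1 - fx) * (1 - fy)
            + v01 * fx * (1 - fy)
            + v10 * (1 - fx) * fy
            + v11 * fx * fy
        )

    # --- oscillating nose occluder / unstable landmarks -------------------
    osc_amp_px = 0.24 * rx
    osc_period = 2.0  # s -> 0.5 Hz, below the 0.7 Hz pulse band
    nose_r = 0.16 * rx
    nose_base = lm_ref[NOSE_LANDMARKS[1]] if config.n_landmarks > 16 else np.array([cx, cy])

    mo = config.motion
    omega = 2 * np.pi / mo.period_s if mo.period_s > 0 else 0.0
    rot_amp = math.radians(mo.rotation_deg)
    if mo.tremor_px > 0:
        from scipy.ndimage import gaussian_filter1d

        tremor = gaussian_filter1d(
            rng.standard_normal((n_frames, 2)), sigma=2.0, axis=0, mode="nearest"
        )
        std = tremor.std(axis=0)
        tremor = mo.tremor_px * tremor / np.where(std > 0, std, 1.0)
    else:
        tremor = np.zeros((n_frames, 2))
    if config.landmark_jitter > 0:
        from scipy.ndimage import gaussian_filter1d

        # aligner error is temporally correlated: smooth the jitter so its
        # frame-to-frame increments stay realistic
        lm_noise = gaussian_filter1d(
            rng.standard_normal((n_frames, config.n_landmarks, 2)),
            sigma=2.0, axis=0, mode="nearest",
        )
        s = lm_noise.std()
        lm_noise *= config.landmark_jitter / s if s > 0 else 0.0
    else:
        lm_noise = np.zeros((n_frames, config.n_landmarks, 2))

    frames = np.empty((n_frames, height, width, 3), dtype=np.uint8)
    skin_masks = np.empty((n_frames, height, width), dtype=bool)
    lm_track = np.empty((n_frames, config.n_landmarks, 2))
    lm_clean = np.empty_like(lm_track)  # jitter-free, for truth labelling

    for k in range(n_frames):
        ang = rot_amp * np.sin(omega * t[k]) if omega else 0.0
        tx = (mo.translation_px * np.sin(omega * t[k]) if omega else 0.0) + tremor[k, 0]
        ty = (0.6 * mo.translation_px * np.cos(omega * t[k]) if omega else 0.0) + tremor[k, 1]
        ca, sa = np.cos(ang), np.sin(ang)
        # inverse rigid map: frame pixel -> reference texture coords (float)
        dx = X - cx - tx
        dy = Y - cy - ty
        x0 = ca * dx + sa * dy + cx
        y0 = -sa * dx + ca * dy + cy
        inface, glasses, beard = face_predicates(x0, y0)
        bg_k = bg_rgb
        if config.background_noise_sigma > 0:
            # the scene behind the subject is lit by the same flickering
            # display and carries its own frame-to-frame variation
            bg_k = bg_rgb + rng.normal(
                0, config.background_noise_sigma, (height, width, 3)
            )
        rgb = np.where(inface[..., None], sample_bilinear(base_rgb, x0, y0), bg_k)
        rgb[glasses] = _GLASSES_RGB
        rgb[beard] = _BEARD_RGB
        # local pulse gain: smooth spatial variation, zero off skin
        alpha_k = 1.0 + 0.3 * np.sin(2 * np.pi * x0 / width) * np.cos(
            2 * np.pi * y0 / height
        )
        skin_k = inface & ~glasses & ~beard
        alpha_k = np.where(skin_k, alpha_k, 0.0)

        osc = osc_amp_px * np.sin(2 * np.pi * t[k] / osc_period)
        osc_y = 0.35 * osc_amp_px * np.cos(2 * np.pi * t[k] / osc_period)
        if config.unstable_region:
            # forward-map the displaced nose centre into frame coords
            qx, qy = nose_base[0] + osc, nose_base[1] + osc_y
            ncx = ca * (qx - cx) - sa * (qy - cy) + cx + tx
            ncy = sa * (qx - cx) + ca * (qy - cy) + cy + ty
            disk = (X - ncx) ** 2 + (Y - ncy) ** 2 <= nose_r**2
            disk &= inface
            rgb[disk] = _NOSE_OCCLUDER_RGB
            alpha_k[disk] = 0.0
            skin_k &= ~disk

        illum_field = np.where(inface, drift[k], drift_bg[k]) * beta
        out = (
            rgb
            + pulse_gain * pulse[k] * alpha_k[..., None] * _PULSE_CHANNEL_WEIGHTS
            + illum_gain * illum_field[..., None]
        )
        if config.noise_sigma > 0:
            out = out + rng.normal(0, config.noise_sigma, (height, width, 3))
        frames[k] = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        skin_masks[k] = skin_k

        lm = lm_ref.copy()
        if config.unstable_region:
            for i in NOSE_LANDMARKS:
                if i < config.n_landmarks:
                    lm[i, 0] += osc
                    lm[i, 1] += osc_y
        fx = ca * (lm[:, 0] - cx) - sa * (lm[:, 1] - cy) + cx + tx
        fy = sa * (lm[:, 0] - cx) + ca * (lm[:, 1] - cy) + cy + ty
        lm_k = np.stack([fx, fy], axis=1)
        lm_clean[k] = lm_k
        lm_track[k] = lm_k + lm_noise[k]

    track = LandmarkTrack(lm_track)
    if config.n_landmarks >= 3:
        mesh = triangulate(lm_track[0])
        # unstable = the triangle's geometric area genuinely oscillates
        # (relative range of the jitter-free area over the clip > 10%);
        # adjacency to moving landmarks alone is not enough — e.g. a
        # triangle whose opposite edge is parallel to the motion keeps
        # its area constant
        a = lm_clean[:, mesh.vertex_ids[:, 0]]
        b = lm_clean[:, mesh.vertex_ids[:, 1]]
        c = lm_clean[:, mesh.vertex_ids[:, 2]]
        areas = 0.5 * np.abs(
            (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1])
            - (b[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0])
        )
        mean_area = areas.mean(axis=0)
        rel_range = np.where(
            mean_area > 0, (areas.max(axis=0) - areas.min(axis=0)) / np.maximum(mean_area, 1e-9), 0.0
        )
        unstable = rel_range > 0.10
    else:
        mesh = TriangleMesh(np.empty((0, 3), dtype=int))
        unstable = np.zeros(0, dtype=bool)

    stack = FrameStack(
        frames,
        config.frame_rate,
        meta={"seed": config.seed, "hr_true": config.hr_true},
    )
    truth = SceneTruth(
        hr_true=config.hr_true,
        pulse_signal=pulse,
        illumination_signal=drift,
        skin_mask_per_frame=skin_masks,
        landmark_track=track,
        mesh=mesh,
        patch_stability_labels=unstable,
        unstable_landmark_ids=NOSE_LANDMARKS if config.unstable_region else (),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# skin-model training data
# ---------------------------------------------------------------------------


@dataclass
class SkinTrainingConfig:
    """Synthetic stand-in for a small masked skin/background image set."""

    n_images: int = 78
    image_size: tuple[int, int] = (32, 32)
    skin_mean_cbcr: tuple[float, float] = (109.0, 152.0)
    skin_cov: tuple = ((25.0, 0.0), (0.0, 25.0))
    skin_y_mean: float = 155.0
    skin_y_std: float = 8.0
    seed: int = 0


def generate_skin_training_set(
    config: SkinTrainingConfig,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Images containing both a skin region and background, with masks.

    Skin pixels draw their (Cb, Cr) from the configured Gaussian cluster;
    background pixels are uniform random RGB (chromaticity spread broadly).

    Raises
    ------
    ValueError
        If the skin covariance is degenerate.
    """
    cov = np.asarray(config.skin_cov, dtype=float)
    if cov.shape != (2, 2) or not np.all(np.isfinite(cov)):
        raise ValueError("skin_cov must be a finite 2x2 matrix")
    try:
        chol = np.linalg.cholesky(cov + 0.0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate skin covariance") from exc
    rng = np.random.default_rng(config.seed)
    w, h = config.image_size
    images, masks = [], []
    mean = np.asarray(config.skin_mean_cbcr, dtype=float)
    for _ in range(config.n_images):
        img = rng.integers(0, 256, (h, w, 3)).astype(float)
        ecx = rng.uniform(0.35, 0.65) * w
        ecy = rng.uniform(0.35, 0.65) * h
        erx = rng.uniform(0.25, 0.45) * w
        ery = rng.uniform(0.25, 0.45) * h
        X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        mask = ((X - ecx) / erx) ** 2 + ((Y - ecy) / ery) ** 2 <= 1.0
        n_skin = int(mask.sum())
        z = rng.standard_normal((n_skin, 2)) @ chol.T + mean
        luma = config.skin_y_mean + rng.normal(0, config.skin_y_std, n_skin)
        img[mask] = ycbcr_to_rgb(luma, z[:, 0], z[:, 1])
        images.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
        masks.append(mask)
    return images, masks


# ---------------------------------------------------------------------------
# toy detection/alignment task
# ---------------------------------------------------------------------------

POSES = ("left", "frontal", "right")

# 10-point face-dot layout in window-normalized [0, 1]^2 coordinates:
# brows (2), eye centres (2), nose, mouth corners + lower lip (3), cheeks (2)
_TOY_SHAPE = np.array(
    [
        (0.25, 0.18), (0.75, 0.18),
        (0.25, 0.32), (0.75, 0.32),
        (0.50, 0.50),
        (0.35, 0.70), (0.65, 0.70), (0.50, 0.78),
        (0.15, 0.50), (0.85, 0.50),
    ]
)
TOY_EYE_INDICES = (2, 3)


def pose_shape(pose: str) -> np.ndarray:
    """Mean toy shape of one pose family, window-normalized coordinates."""
    s = _TOY_SHAPE.copy()
    if pose == "frontal":
        return s
    direction = -1.0 if pose == "left" else 1.0
    if pose not in POSES:
        raise ValueError(f"unknown pose {pose!r}")
    # looking sideways compresses the face horizontally and shifts it
    s[:, 0] = 0.5 + (s[:, 0] - 0.5) * 0.72 + direction * 0.13
    # slight vertical shear away from the camera-facing side
    s[:, 1] = s[:, 1] + direction * 0.06 * (s[:, 0] - 0.5)
    return s


def _render_face_window(shape_norm: np.ndarray, size: int, rng) -> np.ndarray:
    """Bright face plate with soft dark blobs at the landmark positions.

    The blobs are Gaussian (sigma ~6% of the window) so shape-indexed
    features degrade smoothly under small misalignments and window rescaling.
    """
    img = np.clip(rng.normal(190, 8, (size, size)), 0, 255)
    X, Y = np.meshgrid(np.arange(size, dtype=float), np.arange(size, dtype=float))
    sigma = 0.06 * size
    for x, y in shape_norm * size:
        img -= 170.0 * np.exp(-((X - x) ** 2 + (Y - y) ** 2) / (2 * sigma**2))
    return np.clip(img, 0, 255).astype(np.uint8)


def _noise_window(size: int, rng) -> np.ndarray:
    return np.clip(rng.normal(120, 40, (size, size)), 0, 255).astype(np.uint8)


@dataclass
class DetectionTaskConfig:
    n_pos: int = 120
    n_neg: int = 480
    window: int = 32
    shape_jitter: float = 0.015
    seed: int = 0


@dataclass
class DetectionTask:
    """Training material for the toy joint detection/alignment problem.

    ``positives`` pair a face window with its (roughly aligned) shape in
    window-normalized units; ``negatives`` pair noise windows with any
    shape or face windows with a mismatched shape.
    """

    positives: list
    negatives: list
    window: int
    training_shapes: list  # (shape, pose) used by representative clustering


def generate_detection_task(config: DetectionTaskConfig) -> DetectionTask:
    rng = np.random.default_rng(config.seed)
    size = config.window
    positives, negatives, training_shapes = [], [], []
    for i in range(config.n_pos):
        pose = POSES[i % len(POSES)]
        shape = pose_shape(pose) + rng.normal(0, config.shape_jitter, (10, 2))
        win = _render_face_window(shape, size, rng)
        # a roughly aligned pairing: the shape placed on the window may be
        # off by a small offset, as a real detector's candidates are
        paired = shape
        if i % 3 != 0:
            paired = np.clip(shape + rng.uniform(-0.06, 0.06, 2), 0.02, 0.98)
        positives.append((win, paired))
        training_shapes.append((shape, pose))
    for i in range(config.n_neg):
        kind = i % 6
        pose = POSES[rng.integers(3)]
        shape = pose_shape(pose) + rng.normal(0, config.shape_jitter, (10, 2))
        if kind == 0:  # background window, any shape
            negatives.append((_noise_window(size, rng), pose_shape(pose)))
        elif kind == 5:  # wrong-scale face (zoomed in or out), correct shape
            zoom = rng.choice([0.65, 1.5])
            big = _render_face_window(shape, int(round(size * zoom)), rng)
            canvas = _noise_window(max(size, big.shape[0]), rng)
            off = (canvas.shape[0] - big.shape[0]) // 2
            canvas[off : off + big.shape[0], off : off + big.shape[0]] = big
            c0 = (canvas.shape[0] - size) // 2
            crop = canvas[c0 : c0 + size, c0 : c0 + size]
            negatives.append((crop.copy(), pose_shape(pose)))
        elif kind == 1:  # face window, grossly mismatched shape
            win = _render_face_window(shape, size, rng)
            bad = shape + rng.uniform(-0.25, 0.25, (10, 2))
            negatives.append((win, np.clip(bad, 0.02, 0.98)))
        elif kind == 2:  # face window, near-miss shape (localization negative)
            win = _render_face_window(shape, size, rng)
            off = rng.uniform(0.11, 0.2, 2) * rng.choice([-1.0, 1.0], 2)
            near = shape + off + rng.normal(0, 0.02, (10, 2))
            negatives.append((win, np.clip(near, 0.02, 0.98)))
        elif kind == 3:  # face window, wrong-pose shape
            win = _render_face_window(shape, size, rng)
            other = POSES[(POSES.index(pose) + 1 + int(rng.integers(2))) % 3]
            negatives.append((win, pose_shape(other)))
        else:  # window half off the face, correct shape (bad box negative)
            win = _render_face_window(shape, size, rng)
            canvas = _noise_window(2 * size, rng)
            ox = size // 2 + int(rng.integers(-size // 3, size // 3 + 1))
            oy = size // 2 + int(rng.integers(-size // 3, size // 3 + 1))
            canvas[oy : oy + size, ox : ox + size] = win
            shift = np.array([size // 2, size // 2])
            crop = canvas[shift[1] : shift[1] + size, shift[0] : shift[0] + size]
            negatives.append((crop.copy(), pose_shape(pose)))
    return DetectionTask(positives, negatives, size, training_shapes)


def plant_face_frame(
    seed: int,
    frame_size: int = 64,
    face_size: int = 32,
    pose: str | None = None,
) -> tuple[np.ndarray, tuple[int, int, int, int], np.ndarray, str]:
    """A noise frame with one planted toy face.

    Returns (frame, box, shape, pose) where ``box`` is (x, y, w, h) of the
    planted face window and ``shape`` the true landmarks in frame pixels.
    """
    rng = np.random.default_rng(seed)
    frame = _noise_window(frame_size, rng)
    if pose is None:
        pose = POSES[rng.integers(3)]
    shape = pose_shape(pose) + rng.normal(0, 0.015, (10, 2))
    win = _render_face_window(shape, face_size, rng)
    x = int(rng.integers(0, frame_size - face_size + 1))
    y = int(rng.integers(0, frame_size - face_size + 1))
    frame[y : y + face_size, x : x + face_size] = win
    shape_px = shape * face_size + np.array([x, y])
    return frame, (x, y, face_size, face_size), shape_px, pose
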