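"""Video ingestion, preprocessing, and synthetic scene generation.

Real sequences follow the OTB folder convention: ``<seq>/img/0001.jpg``
(or ``.png``) plus ``<seq>/groundtruth_rect.txt`` with one "x,y,w,h" line
per frame (1-based top-left origin).  The synthetic generator emulates the
same kind of material — a bright object moving over a noisy background —
so the whole stack is testable without external downloads.

Preprocessing: frames are resized to the network grid (bilinear), then
adjacent frames are differenced; the signed difference is the external
stimulus injected into the network.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

from .core import GridSpec
from .errors import ConfigurationError, InputError, LoadError

__all__ = [
    "VideoSequence",
    "GroundTruth",
    "SyntheticSceneConfig",
    "load_otb_sequence",
    "generate_synthetic_video",
    "export_otb_sequence",
    "resize_to_grid",
    "difference_frames",
]

# ITU-R 601 luma weights for color -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class VideoSequence:
    """Grayscale frames (float arrays in 0..255) at native resolution."""

    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise InputError("empty video sequence")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise InputError("frames have non-uniform sizes")

    @property
    def native_size(self) -> tuple[int, int]:
        return self.frames[0].shape  # (H0, W0)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class GroundTruth:
    """Per-frame (x, y, w, h) boxes, 0-based top-left origin internally."""

    boxes: np.ndarray  # (T, 4) float

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.boxes.ndim != 2 or self.boxes.shape[1] != 4:
            raise InputError("ground truth must be a (T, 4) array")
        if np.any(self.boxes[:, 2] <= 0) or np.any(self.boxes[:, 3] <= 0):
            raise InputError("ground-truth boxes must have positive width/height")

    def __len__(self) -> int:
        return len(self.boxes)

    def centers(self) -> np.ndarray:
        """(T, 2) array of (cx, cy) box centers."""
        return self.boxes[:, :2] + self.boxes[:, 2:] / 2.0


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Configuration of the built-in synthetic scene generator.

    The generator renders a bright object on a darker noisy background.
    Defaults give a contrast-to-noise ratio of 32 (160 / 5), comfortably
    above the 3x floor at which frame differencing still isolates motion.
    Trajectories wrap toroidally so the object never leaves the frame.

    The default start sits at a generic fractional position (not the frame
    center) and the default motion has components on both axes: an object
    whose center rides exactly on a downsampling-cell boundary for a whole
    sequence is a measure-zero degenerate geometry that no real video
    exhibits, and axis-aligned motion from a centered start produces
    exactly that.
    """

    frame_size: tuple[int, int] = (120, 224)  # (H0, W0)
    n_frames: int = 30
    object_shape: str = "square"  # "square" | "gaussian"
    object_size: int = 16
    trajectory: str = "linear"  # "linear" | "sine" | "random-walk"
    speed: tuple[float, float] = (2.0, 0.7)  # (dx, dy) px/frame
    start: tuple[float, float] | None = None  # (x, y) object center; default 0.35/0.45 of frame
    background_level: float = 40.0
    object_intensity: float = 200.0
    noise_sigma: float = 5.0
    sine_amplitude: float = 20.0
    sine_period: float = 40.0
    occlusions: tuple[tuple[int, int], ...] = ()  # (start_frame, end_frame) episodes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.object_size >= min(self.frame_size):
            raise ConfigurationError("object larger than frame")
        if self.object_shape not in ("square", "gaussian"):
            raise ConfigurationError(f"unknown object shape {self.object_shape!r}")
        if self.trajectory not in ("linear", "sine", "random-walk"):
            raise ConfigurationError(f"unknown trajectory {self.trajectory!r}")


# --------------------------------------------------------------------------
# OTB folder I/O
# --------------------------------------------------------------------------

def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return img.astype(float)
    return img[..., :3].astype(float) @ _LUMA


def load_otb_sequence(path: str | Path) -> tuple[VideoSequence, GroundTruth]:
    """Load an OTB-convention sequence folder.

    Frames are sorted by their numeric index; the ground-truth file is
    parsed tolerantly (comma, tab, or whitespace delimiters) and its 1-based
    box origin is converted to the 0-based convention used internally.
    """
    path = Path(path)
    img_dir = path / "img"
    if not img_dir.is_dir():
        raise LoadError(f"missing frame folder {img_dir}")
    frame_files = sorted(
        (p for p in img_dir.iterdir() if p.suffix.lower() in (".jpg", ".jpeg", ".png", ".bmp")),
        key=lambda p: int(re.sub(r"\D", "", p.stem) or 0),
    )
    if not frame_files:
        raise LoadError(f"no image frames found in {img_dir}")
    frames = [_to_gray(iio.imread(p)) for p in frame_files]

    gt_file = path / "groundtruth_rect.txt"
    if not gt_file.is_file():
        raise LoadError(f"missing ground-truth file {gt_file}")
    boxes = []
    for line in gt_file.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        parts = [p for p in re.split(r"[,\t ]+", line) if p]
        if len(parts) != 4:
            raise LoadError(f"malformed box line {line!r} in {gt_file}")
        boxes.append([float(v) for v in parts])
    if len(boxes) != len(frames):
        raise LoadError(
            f"{gt_file}: {len(boxes)} boxes for {len(frames)} frames"
        )
    boxes = np.asarray(boxes, dtype=float)
    boxes[:, :2] -= 1.0  # OTB 1-based origin -> 0-based
    return VideoSequence(frames), GroundTruth(boxes)


def export_otb_sequence(
    seq: VideoSequence, gt: GroundTruth, path: str | Path
) -> Path:
    """Write a sequence in the OTB folder layout (PNG frames, 1-based boxes)."""
    path = Path(path)
    img_dir = path / "img"
    img_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames, start=1):
        iio.imwrite(img_dir / f"{i:04d}.png",
                    np.clip(np.round(frame), 0, 255).astype(np.uint8))
    boxes = gt.boxes.copy()
    boxes[:, :2] += 1.0
    lines = [",".join(f"{v:g}" for v in b) for b in boxes]
    (path / "groundtruth_rect.txt").write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# Synthetic scene generator
# --------------------------------------------------------------------------

def _trajectory_centers(cfg: SyntheticSceneConfig, rng: np.random.Generator) -> np.ndarray:
    h0, w0 = cfg.frame_size
    if cfg.start is None:
        start = np.array([0.35 * w0, 0.45 * h0])
    else:
        start = np.asarray(cfg.start, dtype=float)
    t = np.arange(cfg.n_frames, dtype=float)
    if cfg.trajectory == "linear":
        centers = start[None, :] + t[:, None] * np.asarray(cfg.speed)
    elif cfg.trajectory == "sine":
        dx = t * cfg.speed[0]
        dy = t * cfg.speed[1] + cfg.sine_amplitude * np.sin(2 * np.pi * t / cfg.sine_period)
        centers = start[None, :] + np.stack([dx, dy], axis=1)
    else:  # random-walk
        steps = rng.normal(0.0, np.hypot(*cfg.speed) or 1.0, size=(cfg.n_frames - 1, 2))
        centers = start[None, :] + np.concatenate(
            [np.zeros((1, 2)), np.cumsum(steps, axis=0)]
        )
    # wrap so the object stays within the frame (toroidal trajectory)
    centers[:, 0] %= w0
    centers[:, 1] %= h0
    return centers


def _render_object(frame: np.ndarray, cx: float, cy: float,
                   cfg: SyntheticSceneConfig) -> None:
    h0, w0 = frame.shape
    half = cfg.object_size / 2.0
    if cfg.object_shape == "square":
        x0, x1 = int(round(cx - half)), int(round(cx + half))
        y0, y1 = int(round(cy - half)), int(round(cy + half))
        rows = np.arange(y0, y1) % h0
        cols = np.arange(x0, x1) % w0
        frame[np.ix_(rows, cols)] = cfg.object_intensity
    else:  # gaussian blob, sigma = size/4 so ~95% of mass inside the box
        yy, xx = np.mgrid[0:h0, 0:w0]
        dy = np.minimum(np.abs(yy - cy), h0 - np.abs(yy - cy))
        dx = np.minimum(np.abs(xx - cx), w0 - np.abs(xx - cx))
        sigma = cfg.object_size / 4.0
        blob = np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
        frame += (cfg.object_intensity - cfg.background_level) * blob


def generate_synthetic_video(
    cfg: SyntheticSceneConfig,
) -> tuple[VideoSequence, GroundTruth]:
    """Render a synthetic sequence; a pure function of the config.

    The ground-truth boxes follow the configured trajectory exactly (before
    pixel rasterization of the object), one ``object_size``-square box per
    frame centered on the trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    centers = _trajectory_centers(cfg, rng)
    h0, w0 = cfg.frame_size
    frames = []
    for t in range(cfg.n_frames):
        frame = np.full((h0, w0), cfg.background_level, dtype=float)
        occluded = any(s <= t < e for s, e in cfg.occlusions)
        if not occluded:
            _render_object(frame, centers[t, 0], centers[t, 1], cfg)
        if cfg.noise_sigma > 0:
            frame = frame + rng.normal(0.0, cfg.noise_sigma, size=frame.shape)
        frames.append(np.clip(frame, 0.0, 255.0))
    boxes = np.empty((cfg.n_frames, 4))
    boxes[:, 0] = centers[:, 0] - cfg.object_size / 2.0
    boxes[:, 1] = centers[:, 1] - cfg.object_size / 2.0
    boxes[:, 2] = boxes[:, 3] = cfg.object_size
    return VideoSequence(frames), GroundTruth(boxes)


# --------------------------------------------------------------------------
# Preprocessing: resize + frame differencing
# --------------------------------------------------------------------------

def resize_to_grid(
    seq: VideoSequence, grid: GridSpec
) -> tuple[list[np.ndarray], tuple[float, float]]:
    """Resize frames to the network grid; returns (frames, scale factors).

    Bilinear, antialiased.  ``scale = (H0/H, W0/W)`` maps grid coordinates
    back to native pixels.  Upscaling (grid larger than native) is allowed
    but unusual and is logged.
    """
    h0, w0 = seq.native_size
    sr, sc = h0 / grid.height, w0 / grid.width
    if (grid.height, grid.width) == (h0, w0):
        return [f.copy() for f in seq.frames], (1.0, 1.0)
    if sr < 1.0 or sc < 1.0:
        import logging
        logging.getLogger(__name__).warning(
            "upscaling native %s to grid %s", (h0, w0), grid.shape
        )
    out = [
        _sk_resize(f, grid.shape, order=1, anti_aliasing=(sr > 1 or sc > 1),
                   preserve_range=True, mode="wrap")
        for f in seq.frames
    ]
    return out, (sr, sc)


def difference_frames(frames: list[np.ndarray], gain: float = 1.0) -> list[np.ndarray]:
    """Signed adjacent-frame differences, scaled by ``gain``.

    T frames give T-1 stimuli: ``stim_t = gain * (frame_{t+1} - frame_t)``.
    The sign is retained; net-negative drive is clipped later by the ReLU in
    the potential update, which is what makes the ReLU non-vacuous.
    """
    if len(frames) < 2:
        raise InputError("need at least 2 frames to difference")
    return [gain * (b - a) for a, b in zip(frames[:-1], frames[1:])]
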