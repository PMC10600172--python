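"""Per-video metadata shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class VideoMeta:
    """Recording parameters for one home-cage video.

    Parameters
    ----------
    video_id : str
        Unique identifier; dam pose, pup detections and annotations for the
        same recording must carry the same id.
    fps : float
        Recording frame rate in frames per second. Must be positive.
    width_px, height_px : int
        Frame resolution in pixels.
    px_per_mm : float or None
        Pixel-to-millimetre calibration, conventionally set from the known
        width of the wire cage top at its lowest point (see
        :func:`damscore.pose_io.calibrate_px_per_mm`). Must be positive when
        set; ``None`` means uncalibrated (feature extraction will refuse to
        run until it is set).
    n_frames : int
        Number of frames in the recording (>= 0).
    """

    video_id: str
    fps: float
    width_px: int = 1280
    height_px: int = 780
    px_per_mm: float | None = None
    n_frames: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.px_per_mm is not None and self.px_per_mm <= 0:
            raise ValueError(f"px_per_mm must be > 0, got {self.px_per_mm}")
        if self.n_frames < 0:
            raise ValueError(f"n_frames must be >= 0, got {self.n_frames}")


def calibrate_px_per_mm(measured_px: float, known_mm: float) -> float:
    """Pixels-per-millimetre scale from a landmark of known physical size.

    The conventional landmark is the width of the wire cage top at its lowest
    point, measured in pixels on a representative frame.

    >>> calibrate_px_per_mm(580, 290)
    2.0
    """
    if measured_px <= 0:
        raise ValueError(f"measured_px must be > 0, got {measured_px}")
    if known_mm <= 0:
        raise ValueError(f"known_mm must be > 0, got {known_mm}")
    return measured_px / known_mm


def frames_to_hours(n_frames: int, fps: float) -> float:
    """Convert a frame count to hours of recording at the given frame rate.

    Summaries report this to one decimal place (e.g. 3,366,254 frames at
    30 fps is 31.1 h).
    """
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    if n_frames < 0:
        raise ValueError(f"n_frames must be >= 0, got {n_frames}")
    return n_frames / fps / 3600.0


def hours_display(n_frames: int, fps: float) -> float:
    """Recording hours as printed in summaries: one decimal place,
    truncated toward zero (3,366,254 frames at 30 fps reports 31.1 h)."""
    import math

    return math.floor(frames_to_hours(n_frames, fps) * 10.0) / 10.0
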