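"""Bout segmentation and per-video behavior summaries.

A bout is a maximal run of consecutive behavior-positive frames; a single
positive frame is a bout.  Bout spans are inclusive on both ends, so
``duration_s = (end - start + 1) / fps``.  Summaries report, per behavior,
total duration, percent of recording time, bout count and mean bout
duration.  Minimum-bout smoothing and (optional, off by default) gap
merging post-process the bout table; the headline summaries apply no
smoothing by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .meta import VideoMeta
from .pose_io import BEHAVIORS

BOUT_COLUMNS = ["behavior", "start_frame", "end_frame", "duration_s"]


def _empty_bouts() -> pd.DataFrame:
    return pd.DataFrame(columns=BOUT_COLUMNS).astype(
        {"behavior": str, "start_frame": int, "end_frame": int, "duration_s": float}
    )


def labels_to_bouts(labels, fps: float, behavior: str = "behavior") -> pd.DataFrame:
    """Run-length encode per-frame booleans into a bout table."""
    if fps <= 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    y = np.asarray(labels, dtype=bool)
    if y.size == 0 or not y.any():
        return _empty_bouts()
    padded = np.concatenate([[False], y, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return pd.DataFrame(
        {
            "behavior": behavior,
            "start_frame": starts,
            "end_frame": ends,
            "duration_s": (ends - starts + 1) / fps,
        }
    )


def bouts_to_labels(bouts: pd.DataFrame, n_frames: int, behavior: str | None = None) -> np.ndarray:
    """Rasterize a bout table back to per-frame booleans (inverse of
    :func:`labels_to_bouts` for a single behavior)."""
    y = np.zeros(n_frames, dtype=bool)
    rows = bouts if behavior is None else bouts[bouts["behavior"] == behavior]
    for _, row in rows.iterrows():
        y[int(row.start_frame): int(row.end_frame) + 1] = True
    return y


def smooth_min_bout(bouts: pd.DataFrame, min_s: float) -> pd.DataFrame:
    """Drop bouts shorter than ``min_s`` seconds (idempotent; never merges)."""
    if min_s < 0:
        raise ValueError(f"min_s must be >= 0, got {min_s}")
    if len(bouts) == 0:
        return bouts.copy()
    return bouts[bouts["duration_s"] >= min_s].reset_index(drop=True)


def merge_gaps(bouts: pd.DataFrame, max_gap_s: float, fps: float) -> pd.DataFrame:
    """Join same-behavior bouts separated by gaps of at most ``max_gap_s``.

    Off by default in the pipeline (only minimum-duration filtering is part
    of the standard workflow); provided for users who want it.
    """
    if max_gap_s < 0:
        raise ValueError(f"max_gap_s must be >= 0, got {max_gap_s}")
    if len(bouts) == 0:
        return bouts.copy()
    out = []
    for behavior, grp in bouts.groupby("behavior", sort=False):
        grp = grp.sort_values("start_frame")
        cur_start, cur_end = None, None
        for _, row in grp.iterrows():
            if cur_start is None:
                cur_start, cur_end = int(row.start_frame), int(row.end_frame)
            elif (int(row.start_frame) - cur_end - 1) / fps <= max_gap_s:
                cur_end = max(cur_end, int(row.end_frame))
            else:
                out.append((behavior, cur_start, cur_end))
                cur_start, cur_end = int(row.start_frame), int(row.end_frame)
        out.append((behavior, cur_start, cur_end))
    df = pd.DataFrame(out, columns=["behavior", "start_frame", "end_frame"])
    df["duration_s"] = (df.end_frame - df.start_frame + 1) / fps
    return df


@dataclass
class VideoBehaviorSummary:
    """Per-behavior totals for one video."""

    video_id: str
    fps: float
    n_frames: int
    table: pd.DataFrame  # index behavior; total_duration_s, percent_time, bout_count, mean_bout_s


def summarize_video(
    bouts: pd.DataFrame, meta: VideoMeta, behaviors: tuple[str, ...] = BEHAVIORS
) -> VideoBehaviorSummary:
    """Total duration, percent time, bout count and mean bout duration.

    Percent time is relative to the full recording (``n_frames / fps``);
    behaviors without bouts report zeros.  Because behaviors may co-occur,
    percentages may jointly exceed 100 (each individually never does).
    """
    if len(bouts) and (bouts["end_frame"] >= meta.n_frames).any():
        bad = bouts[bouts["end_frame"] >= meta.n_frames].iloc[0]
        raise ValueError(
            f"bout of {bad.behavior!r} ends at frame {int(bad.end_frame)} "
            f"but the video has only {meta.n_frames} frames"
        )
    video_s = meta.n_frames / meta.fps
    rows = {}
    for b in behaviors:
        sub = bouts[bouts["behavior"] == b] if len(bouts) else bouts
        count = len(sub)
        total = float(sub["duration_s"].sum()) if count else 0.0
        rows[b] = {
            "total_duration_s": total,
            "percent_time": 100.0 * total / video_s if video_s > 0 else 0.0,
            "bout_count": count,
            "mean_bout_s": total / count if count else 0.0,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "behavior"
    return VideoBehaviorSummary(
        video_id=meta.video_id, fps=meta.fps, n_frames=meta.n_frames, table=table
    )


def cohort_table(
    summaries: list[VideoBehaviorSummary],
    metadata: dict[str, dict] | None = None,
) -> pd.DataFrame:
    """Long-format export for external statistics packages.

    One row per video x behavior with litter id, postnatal day and all
    four summary measures; ``metadata`` maps video_id to
    ``{"litter_id": ..., "postnatal_day": ...}``.  Duplicate video ids are
    kept but warned about.
    """
    import logging

    metadata = metadata or {}
    seen = set()
    rows = []
    for s in summaries:
        if s.video_id in seen:
            logging.getLogger(__name__).warning("duplicate video_id %r in cohort", s.video_id)
        seen.add(s.video_id)
        extra = metadata.get(s.video_id, {})
        for behavior, r in s.table.iterrows():
            rows.append(
                {
                    "video_id": s.video_id,
                    "litter_id": extra.get("litter_id"),
                    "postnatal_day": extra.get("postnatal_day"),
                    "behavior": behavior,
                    "total_s": r.total_duration_s,
                    "percent": r.percent_time,
                    "bouts": int(r.bout_count),
                    "mean_bout_s": r.mean_bout_s,
                }
            )
    cols = ["video_id", "litter_id", "postnatal_day", "behavior",
            "total_s", "percent", "bouts", "mean_bout_s"]
    return pd.DataFrame(rows, columns=cols)
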