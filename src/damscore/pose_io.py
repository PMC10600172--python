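"""Reading, validation, conversion and joining of pose and annotation files.

The pipeline consumes three kinds of input per video:

* a single-animal pose table for the dam (32 keypoints), in the common
  three-row-header CSV dialect (``scorer`` / ``bodyparts`` / ``coords``
  with one ``x, y, likelihood`` triple per keypoint);
* raw multi-animal pup detections — per frame and per bodypart a
  variable-length list of ``(x, y, confidence)`` with **no identity**
  information, either as the tracker's native pickled "full" detections
  file or as an equivalent portable JSON dialect;
* a BORIS-style interval annotation table (behavior, start s, stop s).

Everything downstream operates on a single flat per-frame table
(:class:`JoinedPose`) whose column layout is fixed: the dam block first
(32 keypoints), then ``max_pups`` pup slots of 9 keypoints each, one
``x, y, likelihood`` triple per keypoint.  Pup slots are filled per frame
and per bodypart in descending confidence order; a point in slot *k* at
frame *t* and slot *k* at frame *t+1* need not belong to the same pup.
"""

from __future__ import annotations

import json
import logging
import pickle
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meta import VideoMeta, calibrate_px_per_mm, frames_to_hours  # noqa: F401
from .schemes import KeypointScheme, dam_scheme, pup_scheme

logger = logging.getLogger(__name__)

#: The closed vocabulary of maternal behaviors scored by the pipeline.
BEHAVIORS: tuple[str, ...] = (
    "nest_attendance",
    "active_nursing",
    "passive_nursing",
    "licking_grooming",
    "self_grooming",
    "eating",
    "drinking",
)


class SchemaError(ValueError):
    """A file does not conform to its declared schema."""


class ParseError(ValueError):
    """A file contains a cell that cannot be interpreted."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PoseSeries:
    """Per-frame ``(x, y, likelihood)`` for a fixed, ordered keypoint roster."""

    meta: VideoMeta
    scheme: KeypointScheme
    coords: np.ndarray  # (n_frames, n_keypoints, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.scheme) or self.coords.shape[2] != 3:
            raise SchemaError(
                f"coords must have shape (n, {len(self.scheme)}, 3), got {self.coords.shape}"
            )
        p = self.coords[:, :, 2]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("likelihoods must lie in [0, 1] (clip before constructing)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class RawDetections:
    """Identity-free pup detections: per frame, per bodypart, a list of points.

    ``frames[t][bodypart]`` is a float array of shape ``(k, 3)`` holding the
    *k* detections of that bodypart at frame *t* (possibly ``k == 0``).  No
    ordering of the list carries meaning.
    """

    meta: VideoMeta
    bodyparts: tuple[str, ...]
    frames: list[dict[str, np.ndarray]]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class PupBlock:
    """Pup slots of a joined table: ``coords`` has shape (n, max_pups, 9, 3)."""

    meta: VideoMeta
    scheme: KeypointScheme
    coords: np.ndarray

    @property
    def max_pups(self) -> int:
        return self.coords.shape[1]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


@dataclass
class JoinedPose:
    """Frame-aligned dam + pup table, the input of feature extraction.

    Column layout of the flat form is fixed: the 32 dam keypoints first,
    then pup slots 1..max_pups with 9 keypoints each, one x/y/likelihood
    triple per keypoint — ``(32 + max_pups * 9) * 3`` value columns.
    Unfilled pup slots carry ``(0, 0, p=0)``.
    """

    meta: VideoMeta
    dam: np.ndarray  # (n, 32, 3)
    pups: np.ndarray  # (n, max_pups, 9, 3)
    dam_scheme: KeypointScheme = field(default_factory=dam_scheme)
    pup_scheme: KeypointScheme = field(default_factory=pup_scheme)

    def __post_init__(self) -> None:
        if self.dam.shape[0] != self.pups.shape[0]:
            raise SchemaError(
                f"dam and pup blocks disagree on frame count: {self.dam.shape[0]} vs {self.pups.shape[0]}"
            )

    @property
    def n_frames(self) -> int:
        return self.dam.shape[0]

    @property
    def max_pups(self) -> int:
        return self.pups.shape[1]

    def column_names(self) -> list[tuple[str, str]]:
        """(keypoint, coord) pairs in the documented flat order."""
        cols = [(kp, c) for kp in self.dam_scheme.names for c in ("x", "y", "likelihood")]
        for slot in range(1, self.max_pups + 1):
            cols += [
                (f"pup{slot}_{kp}", c)
                for kp in self.pup_scheme.names
                for c in ("x", "y", "likelihood")
            ]
        return cols

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_frames
        flat_dam = self.dam.reshape(n, -1)
        flat_pup = self.pups.reshape(n, -1)
        values = np.hstack([flat_dam, flat_pup])
        columns = pd.MultiIndex.from_tuples(self.column_names(), names=["bodyparts", "coords"])
        return pd.DataFrame(values, columns=columns)


@dataclass
class AnnotationSet:
    """Interval annotations plus their per-frame rasterization.

    ``frame_labels`` is a boolean frame × behavior table built with the
    half-open convention: frame *f* is positive for an interval
    ``[start_s, stop_s)`` iff ``start_s <= f / fps < stop_s``.  Overlapping
    intervals of different behaviors are permitted (e.g. nursing always
    co-occurs with nest attendance).
    """

    behaviors: tuple[str, ...]
    intervals: list[tuple[str, float, float]]
    frame_labels: pd.DataFrame


def rasterize_intervals(
    intervals: list[tuple[str, float, float]],
    n_frames: int,
    fps: float,
    behaviors: tuple[str, ...] = BEHAVIORS,
) -> pd.DataFrame:
    """Boolean frame × behavior table from (behavior, start_s, stop_s) rows."""
    labels = pd.DataFrame(False, index=np.arange(n_frames), columns=list(behaviors))
    times = np.arange(n_frames) / fps
    for behavior, start, stop in intervals:
        labels.loc[(times >= start) & (times < stop), behavior] = True
    return labels


# ---------------------------------------------------------------------------
# single-animal pose CSV (three header rows)
# ---------------------------------------------------------------------------


def _clip_likelihood(p: np.ndarray, what: str) -> np.ndarray:
    bad = (p < 0) | (p > 1)
    if bad.any():
        logger.warning(
            "%s: %d likelihood values outside [0, 1] clipped (range %.3g..%.3g)",
            what, int(bad.sum()), float(np.nanmin(p)), float(np.nanmax(p)),
        )
        p = np.clip(p, 0.0, 1.0)
    return p


def read_dam_pose(path, meta: VideoMeta, scheme: KeypointScheme | None = None) -> PoseSeries:
    """Read a three-row-header single-animal pose CSV for the dam.

    The dialect has header rows ``scorer`` / ``bodyparts`` / ``coords`` and
    one ``x, y, likelihood`` column triple per keypoint.  Keypoints are
    reordered into the canonical roster; a missing keypoint raises
    :class:`SchemaError` naming it; out-of-range likelihoods are clipped to
    [0, 1] with a logged warning.
    """
    scheme = scheme or dam_scheme()
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    # drop the scorer level; key columns by (bodypart, coord)
    df.columns = pd.MultiIndex.from_arrays([df.columns.get_level_values(1),
                                            df.columns.get_level_values(2)])
    available = set(df.columns.get_level_values(0))
    n = len(df)
    out = np.empty((n, len(scheme), 3), dtype=float)
    for j, kp in enumerate(scheme.names):
        if kp not in available:
            raise SchemaError(f"keypoint column missing from pose file: {kp!r}")
        for c, coord in enumerate(("x", "y", "likelihood")):
            if (kp, coord) not in df.columns:
                raise SchemaError(f"column ({kp!r}, {coord!r}) missing from pose file")
            col = pd.to_numeric(df[(kp, coord)], errors="coerce")
            raw = df[(kp, coord)]
            bad = col.isna() & raw.notna()
            if bad.any():
                frame = int(np.nonzero(bad.to_numpy())[0][0])
                raise ParseError(
                    f"non-numeric value {raw.iloc[frame]!r} in column ({kp}, {coord}) at frame {frame}"
                )
            out[:, j, c] = col.to_numpy(dtype=float)
    out[:, :, 2] = _clip_likelihood(out[:, :, 2], f"{path}")
    return PoseSeries(meta=meta, scheme=scheme, coords=out)


def write_dam_pose(series: PoseSeries, path, scorer: str = "damscore") -> None:
    """Write a :class:`PoseSeries` in the three-row-header CSV dialect."""
    n = series.n_frames
    cols = pd.MultiIndex.from_tuples(
        [(scorer, kp, c) for kp in series.scheme.names for c in ("x", "y", "likelihood")],
        names=["scorer", "bodyparts", "coords"],
    )
    df = pd.DataFrame(series.coords.reshape(n, -1), columns=cols)
    # %.17g guarantees float64 round trips bit-identically through the CSV
    df.to_csv(path, index=True, float_format="%.17g")


# ---------------------------------------------------------------------------
# raw pup detections (pickle and JSON dialects)
# ---------------------------------------------------------------------------

_FRAME_KEY_RE = re.compile(r"^frame(\d+)$")


def _as_points(coords, conf) -> np.ndarray:
    xy = np.asarray(coords, dtype=float).reshape(-1, 2)
    c = np.asarray(conf, dtype=float).reshape(-1)
    if xy.shape[0] != c.shape[0]:
        raise SchemaError(
            f"coordinate/confidence length mismatch: {xy.shape[0]} vs {c.shape[0]}"
        )
    return np.column_stack([xy, c])


def read_detections(path, meta: VideoMeta, bodyparts: tuple[str, ...] | None = None) -> RawDetections:
    """Read raw pup detections from either accepted dialect.

    Dispatches on extension: ``.pickle``/``.pkl`` for the tracker's native
    serialized "full" detections file (a frame-keyed map of per-bodypart
    coordinate and confidence arrays), anything else for the portable JSON
    dialect.  Confidences outside [0, 1] are clipped with a warning.
    """
    spath = str(path)
    if spath.endswith((".pickle", ".pkl")):
        return _read_detections_pickle(path, meta, bodyparts)
    return _read_detections_json(path, meta, bodyparts)


def _read_detections_pickle(path, meta, bodyparts):
    with open(path, "rb") as fh:
        raw = pickle.load(fh)
    metadata = raw.get("metadata", {})
    names = bodyparts or tuple(metadata.get("all_joints_names", ())) or pup_scheme().names
    frame_items: dict[int, dict] = {}
    for key, value in raw.items():
        m = _FRAME_KEY_RE.match(str(key))
        if not m:
            continue
        frame_items[int(m.group(1))] = value
    n_frames = int(metadata.get("nframes", (max(frame_items) + 1) if frame_items else 0))
    frames: list[dict[str, np.ndarray]] = []
    for t in range(n_frames):
        entry = frame_items.get(t)
        per_bp: dict[str, np.ndarray] = {}
        if entry is not None:
            coords = entry["coordinates"]
            conf = entry["confidence"]
            # the native layout nests the per-bodypart lists one level down
            if len(coords) == 1 and len(coords[0]) == len(names):
                coords = coords[0]
            for j, bp in enumerate(names):
                pts = _as_points(coords[j], conf[j]) if len(coords[j]) else np.empty((0, 3))
                per_bp[bp] = pts
        else:
            per_bp = {bp: np.empty((0, 3)) for bp in names}
        frames.append(per_bp)
    return _finalize_detections(meta, tuple(names), frames, str(path))


def _read_detections_json(path, meta, bodyparts):
    with open(path) as fh:
        raw = json.load(fh)
    names = bodyparts or tuple(raw["bodyparts"])
    n_frames = int(raw.get("n_frames", 0)) or (
        (max(map(int, raw["frames"])) + 1) if raw.get("frames") else 0
    )
    frames = []
    by_frame = raw.get("frames", {})
    for t in range(n_frames):
        entry = by_frame.get(str(t), {})
        per_bp = {}
        for bp in names:
            pts = entry.get(bp, [])
            per_bp[bp] = np.asarray(pts, dtype=float).reshape(-1, 3) if len(pts) else np.empty((0, 3))
        frames.append(per_bp)
    return _finalize_detections(meta, names, frames, str(path))


def _finalize_detections(meta, names, frames, what):
    n_clipped = 0
    for per_bp in frames:
        for bp, pts in per_bp.items():
            if pts.size:
                bad = (pts[:, 2] < 0) | (pts[:, 2] > 1)
                if bad.any():
                    n_clipped += int(bad.sum())
                    pts[:, 2] = np.clip(pts[:, 2], 0.0, 1.0)
    if n_clipped:
        logger.warning("%s: clipped %d detection confidences to [0, 1]", what, n_clipped)
    return RawDetections(meta=meta, bodyparts=tuple(names), frames=frames)


def write_detections_json(d: RawDetections, path) -> None:
    """Write raw detections in the portable JSON dialect."""
    frames = {}
    for t, per_bp in enumerate(d.frames):
        entry = {bp: pts.tolist() for bp, pts in per_bp.items() if len(pts)}
        if entry:
            frames[str(t)] = entry
    payload = {
        "video_id": d.meta.video_id,
        "bodyparts": list(d.bodyparts),
        "n_frames": d.n_frames,
        "frames": frames,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_detections_pickle(d: RawDetections, path) -> None:
    """Write raw detections in the tracker's native serialized layout."""
    payload: dict = {
        "metadata": {"all_joints_names": list(d.bodyparts), "nframes": d.n_frames}
    }
    for t, per_bp in enumerate(d.frames):
        coords = [per_bp[bp][:, :2].copy() for bp in d.bodyparts]
        conf = [per_bp[bp][:, 2:3].copy() for bp in d.bodyparts]
        payload[f"frame{t:05d}"] = {"coordinates": [coords], "confidence": conf}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


# ---------------------------------------------------------------------------
# slot assignment and joining
# ---------------------------------------------------------------------------

DEFAULT_MAX_PUPS = 12


def detections_to_table(d: RawDetections, max_pups: int = DEFAULT_MAX_PUPS) -> PupBlock:
    """Assign identity-free detections to fixed pup slots.

    Per frame and per bodypart, detections fill slots ``1..k`` in descending
    confidence order (ties broken by ascending x then y, so the result is
    independent of input list order); surplus detections beyond ``max_pups``
    are dropped and unfilled slots carry ``(0, 0, p=0)``.  Slot assignment
    carries **no cross-frame identity**: the points placed in a slot do not
    necessarily belong to the same pup from one frame to the next.
    """
    if max_pups < 1:
        raise ValueError(f"max_pups must be >= 1, got {max_pups}")
    n = d.n_frames
    n_bp = len(d.bodyparts)
    out = np.zeros((n, max_pups, n_bp, 3), dtype=float)
    for t, per_bp in enumerate(d.frames):
        for j, bp in enumerate(d.bodyparts):
            pts = per_bp.get(bp)
            if pts is None or len(pts) == 0:
                continue
            order = np.lexsort((pts[:, 1], pts[:, 0], -pts[:, 2]))
            keep = order[:max_pups]
            out[t, : len(keep), j, :] = pts[keep]
    return PupBlock(meta=d.meta, scheme=pup_scheme(), coords=out)


def join_dam_pup(dam: PoseSeries, pups: PupBlock) -> JoinedPose:
    """Join dam pose and pup slots by frame number into one flat table.

    Both inputs must come from the same video.  If frame counts differ the
    longer block is truncated to the shorter with a logged warning (padding
    would fabricate detections); zero overlapping frames is an error.
    """
    if dam.meta.video_id != pups.meta.video_id:
        raise ValueError(
            f"video_id mismatch: dam {dam.meta.video_id!r} vs pups {pups.meta.video_id!r}"
        )
    n = min(dam.n_frames, pups.n_frames)
    if n == 0:
        raise ValueError("no overlapping frames between dam pose and pup detections")
    if dam.n_frames != pups.n_frames:
        logger.warning(
            "frame count mismatch (dam %d, pups %d): truncating to %d",
            dam.n_frames, pups.n_frames, n,
        )
    return JoinedPose(
        meta=dam.meta,
        dam=dam.coords[:n].copy(),
        pups=pups.coords[:n].copy(),
        dam_scheme=dam.scheme,
        pup_scheme=pups.scheme,
    )


def write_joined(joined: JoinedPose, path, scorer: str = "damscore") -> None:
    """Write a joined table in the single-animal flat CSV dialect."""
    df = joined.to_dataframe()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, kp, c) for kp, c in df.columns], names=["scorer", "bodyparts", "coords"]
    )
    df.to_csv(path, index=True, float_format="%.17g")


def read_joined(path, meta: VideoMeta) -> JoinedPose:
    """Read a joined table written by :func:`write_joined`.

    The pup slot count is inferred from the column layout; the round trip
    through :func:`write_joined` is bit-identical for finite values.
    """
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    n = values.shape[0]
    n_dam = len(dam_scheme())
    n_pup_kp = len(pup_scheme())
    n_cols = values.shape[1]
    pup_cols = n_cols - n_dam * 3
    if pup_cols < 0 or pup_cols % (n_pup_kp * 3):
        raise SchemaError(f"unexpected column count {n_cols} for a joined table")
    max_pups = pup_cols // (n_pup_kp * 3)
    dam = values[:, : n_dam * 3].reshape(n, n_dam, 3)
    pups = values[:, n_dam * 3:].reshape(n, max_pups, n_pup_kp, 3)
    return JoinedPose(meta=meta, dam=dam, pups=pups)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotations(path, meta: VideoMeta) -> AnnotationSet:
    """Read a BORIS-style interval table and rasterize it to frame labels.

    Accepts columns named (case-insensitively) ``behavior``, ``start`` and
    ``stop`` — BORIS exports label the time columns ``Start (s)`` /
    ``Stop (s)``.  Frame *f* is positive iff ``start <= f/fps < stop``
    (half-open, so adjacent bouts never double-count a frame).  Unknown
    behavior labels and non-positive interval lengths are rejected.
    """
    df = pd.read_csv(path)

    def _find(prefix: str) -> str:
        for col in df.columns:
            if str(col).strip().lower().startswith(prefix):
                return col
        raise SchemaError(f"annotation table lacks a '{prefix}' column (found {list(df.columns)})")

    b_col, s_col, e_col = _find("behavior"), _find("start"), _find("stop")
    intervals: list[tuple[str, float, float]] = []
    for i, row in df.iterrows():
        behavior = str(row[b_col]).strip()
        if behavior not in BEHAVIORS:
            raise ValueError(
                f"row {i}: unknown behavior {behavior!r} (allowed: {', '.join(BEHAVIORS)})"
            )
        start, stop = float(row[s_col]), float(row[e_col])
        if stop <= start:
            raise ValueError(f"row {i}: stop ({stop}) must be greater than start ({start})")
        intervals.append((behavior, start, stop))
    frame_labels = rasterize_intervals(intervals, meta.n_frames, meta.fps)
    return AnnotationSet(behaviors=BEHAVIORS, intervals=intervals, frame_labels=frame_labels)


def write_annotations(intervals: list[tuple[str, float, float]], path) -> None:
    """Write intervals as a BORIS-style aggregated-events CSV."""
    df = pd.DataFrame(intervals, columns=["Behavior", "Start (s)", "Stop (s)"])
    df.to_csv(path, index=False)
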