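"""Assembly of the 218-column frame-level feature matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..meta import VideoMeta
from ..pose_io import JoinedPose
from . import geometry as geom
from .manifest import FeatureManifest, default_manifest
from .rolling import pup_centroid_longwindow, rolling_stat


@dataclass(frozen=True)
class GeometryParams:
    """Tunable likelihood handling for geometric features.

    ``p_min`` (default 0.5, matching the pose models' likelihood cutoff)
    excludes occluded points from threshold-excluded families (hulls,
    arch fit, detected-point counts); weighted families scale by the raw
    likelihood instead.
    """

    p_min: float = geom.DEFAULT_P_MIN

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min <= 1.0:
            raise ValueError(f"p_min must lie in [0, 1], got {self.p_min}")


@dataclass
class FeatureMatrix:
    """frames x 218 feature values plus the manifest that names them."""

    meta: VideoMeta
    manifest: FeatureManifest
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.manifest.names:
            raise ValueError("feature columns do not match manifest order")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"NaN in feature columns {bad}")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: VideoMeta, manifest: FeatureManifest | None = None) -> "FeatureMatrix":
        manifest = manifest or default_manifest()
        df = pd.read_csv(path)
        return cls(meta=meta, manifest=manifest, values=df[manifest.names])


def _hull_series(block: np.ndarray, p_min: float, px_per_mm: float) -> np.ndarray:
    return np.array([
        geom.convex_hull_area(block[t], p_min=p_min, px_per_mm=px_per_mm)
        for t in range(block.shape[0])
    ])


def extract_features(
    joined: JoinedPose,
    params: GeometryParams | None = None,
    manifest: FeatureManifest | None = None,
) -> FeatureMatrix:
    """Compute the full feature matrix for one joined dam+pup table.

    Distances, areas and movement are reported in millimetre-based units
    (via the video's px/mm calibration); location features stay in pixel
    coordinates of the frame.  The computation is deterministic and
    invariant to any per-frame permutation of pup slots, since no pup
    feature depends on slot identity.
    """
    params = params or GeometryParams()
    manifest = manifest or default_manifest()
    meta = joined.meta
    if meta.px_per_mm is None:
        raise ValueError(
            "px_per_mm is unset: calibrate the video first "
            "(calibrate_px_per_mm on a landmark of known size, e.g. the cage-top width)"
        )
    ppm = meta.px_per_mm
    fps = meta.fps
    p_min = params.p_min
    dam = joined.dam
    pups = joined.pups
    n = joined.n_frames
    scheme = joined.dam_scheme
    cage_center = (meta.width_px / 2.0, meta.height_px / 2.0)

    base: dict[str, np.ndarray] = {}

    # dam centroid (likelihood weighted, hold-filled)
    dam_cent, _ = geom.weighted_centroid_series(dam, fallback=cage_center)
    base["dam_centroid_x"] = dam_cent[:, 0]
    base["dam_centroid_y"] = dam_cent[:, 1]

    def kp(name: str) -> np.ndarray:
        return dam[:, scheme.index(name), :]

    for name in ("nose", "head_center", "tail_base"):
        base[f"dam_{name}_x"] = kp(name)[:, 0]
        base[f"dam_{name}_y"] = kp(name)[:, 1]

    # areas and extent
    head_idx = scheme.group_indices("head_points") + scheme.group_indices("ear_points")
    body_idx = scheme.group_indices("body_points")
    base["dam_hull_area"] = _hull_series(dam, p_min, ppm)
    base["dam_head_hull_area"] = _hull_series(dam[:, head_idx], p_min, ppm)
    base["dam_body_hull_area"] = _hull_series(dam[:, body_idx], p_min, ppm)
    base["dam_body_length"] = (
        np.linalg.norm(kp("nose")[:, :2] - kp("tail_base")[:, :2], axis=1) / ppm
    )

    # angles
    back_idx = scheme.group_indices("back_points")
    arch, _ = geom.back_arch_angle_series(dam[:, back_idx], p_min=p_min)
    base["back_arch_angle"] = arch
    head_vec = kp("nose")[:, :2] - kp("head_center")[:, :2]
    body_vec = kp("neck")[:, :2] - kp("tail_base")[:, :2]
    base["head_body_angle"] = geom.angle_between_deg(head_vec, body_vec)
    base["head_bearing"] = geom.bearing_deg(head_vec)
    base["body_bearing"] = geom.bearing_deg(body_vec)

    # dam likelihood structure
    p_dam = dam[:, :, 2]
    base["dam_mean_likelihood"] = p_dam.mean(axis=1)
    base["dam_sum_likelihood"] = p_dam.sum(axis=1)
    base["dam_low_likelihood_count"] = (p_dam < p_min).sum(axis=1).astype(float)
    for group in ("head_points", "ear_points", "back_points", "ventrum_points",
                  "limb_points", "tail_points"):
        idx = scheme.group_indices(group)
        base[f"dam_{group}_mean_likelihood"] = p_dam[:, idx].mean(axis=1)

    # movement
    moves = geom.movement_block(dam, px_per_mm=ppm)
    for j, name in enumerate(scheme.names):
        base[f"dam_move_{name}"] = moves[:, j]
    cent_aug = np.column_stack([dam_cent, np.ones(n)])
    base["dam_centroid_move"] = geom.point_movement(cent_aug, px_per_mm=ppm)
    base["dam_back_mean_move"] = moves[:, back_idx].mean(axis=1)

    # pup features (slot-symmetric by construction)
    flat_pups = pups.reshape(n, -1, 3)
    p_pup = flat_pups[:, :, 2]
    base["pup_hull_area"] = _hull_series(flat_pups, p_min, ppm)
    base["pup_mean_likelihood"] = p_pup.mean(axis=1)
    base["pup_sum_likelihood"] = p_pup.sum(axis=1)
    base["pup_detected_count"] = (p_pup >= p_min).sum(axis=1).astype(float)

    # dam-pup distances
    pup_cent, _ = geom.weighted_centroid_series(flat_pups, fallback=cage_center)
    pup_cents = {
        "": pup_cent,
        "_30m": pup_centroid_longwindow(pups, 1800.0, fps, fallback=cage_center),
        "_60m": pup_centroid_longwindow(pups, 3600.0, fps, fallback=cage_center),
    }
    anchors = {
        "dam_centroid": dam_cent,
        "dam_nose": kp("nose")[:, :2],
        "dam_head_center": kp("head_center")[:, :2],
    }
    for aname, axy in anchors.items():
        for suffix, pxy in pup_cents.items():
            base[f"dist_{aname}_pup_centroid{suffix}"] = (
                np.linalg.norm(axy - pxy, axis=1) / ppm
            )

    # assemble in manifest order, applying rolling windows where declared
    cols: dict[str, np.ndarray] = {}
    for entry in manifest.entries:
        if entry.stat is None:
            if entry.name not in base:
                raise KeyError(f"no computation defined for feature {entry.name!r}")
            cols[entry.name] = base[entry.name]
        else:
            cols[entry.name] = rolling_stat(base[entry.base], entry.stat, entry.span_s, fps)

    values = pd.DataFrame(cols, columns=manifest.names)
    return FeatureMatrix(meta=meta, manifest=manifest, values=values)
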