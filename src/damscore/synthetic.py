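"""Seeded in-silico home-cage sessions for end-to-end pipeline testing.

The generator emits everything a real recording session provides — a dam
pose table (32 keypoints), identity-free pup detections, ground-truth
behavior intervals and video metadata — with the statistical structure
the pipeline assumes, so every stage can be exercised with no external
data.  Behaviors are driven by parametric posture templates (zone
occupancy, back-arch curvature, nose/ear oscillation) deliberately chosen
so that the feature families the classifiers rely on in practice
(dam-pup distances, convex hulls, ear movement, back angle) are what
separates the classes; it is a test oracle, not a biomechanical model.

All randomness flows from a single scenario seed through independent
spawned substreams (layout / script / dam / pups), so sessions are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .meta import VideoMeta
from .pose_io import (
    BEHAVIORS,
    AnnotationSet,
    JoinedPose,
    PoseSeries,
    RawDetections,
    detections_to_table,
    join_dam_pup,
    rasterize_intervals,
    write_annotations,
    write_dam_pose,
    write_detections_json,
    write_detections_pickle,
)
from .schemes import dam_scheme, pup_scheme

#: behaviors that keep the dam on the nest
ON_NEST = ("nest_attendance", "active_nursing", "passive_nursing", "licking_grooming")
#: behaviors that take place away from the nest, mutually exclusive
OFF_NEST = ("eating", "drinking", "self_grooming")


@dataclass(frozen=True)
class Rect:
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one simulated session.

    Defaults mirror a typical recording: 30 fps, a 1280x780 px side-view
    frame, 2 px/mm calibration, an 8-pup litter.  The nest zone is placed
    at a seed-dependent location (``nest_zone=None``) because real nests
    are built anywhere in the cage; food and water zones are fixed cage
    hardware.  ``behavior_script=None`` generates a seeded schedule that
    visits every behavior.  Pup keypoints drop out of the detection stream
    at ``pup_dropout_in_nest`` (litters are heavily occluded by bedding,
    each other and the dam), dam keypoints at ``dam_dropout`` (likelihood
    drawn 0 for dropped points); all coordinates carry Gaussian jitter of
    ``noise_sd_px``.
    """

    seed: int
    duration_s: float = 60.0
    fps: float = 30.0
    width_px: int = 1280
    height_px: int = 780
    px_per_mm: float = 2.0
    n_pups: int = 8
    nest_zone: Rect | None = None
    food_zone: Rect = Rect(40, 40, 240, 200)
    water_zone: Rect = Rect(1040, 40, 1240, 200)
    behavior_script: tuple[tuple[str, float, float], ...] | None = None
    pup_dropout_in_nest: float = 0.35
    pup_dropout_off_nest: float = 0.10
    dam_dropout: float = 0.08
    noise_sd_px: float = 2.0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration_s and fps must be positive")
        if not 0 <= self.n_pups <= 12:
            raise ValueError(f"n_pups must lie in [0, 12], got {self.n_pups}")
        for name in ("food_zone", "water_zone", "nest_zone"):
            zone = getattr(self, name)
            if zone is None:
                continue
            if not (0 <= zone.x0 < zone.x1 <= self.width_px
                    and 0 <= zone.y0 < zone.y1 <= self.height_px):
                raise ValueError(f"{name} must lie within the cage frame")
        if self.behavior_script is not None:
            _validate_script(self.behavior_script, self.duration_s)


def _validate_script(script, duration_s: float) -> None:
    for behavior, start, stop in script:
        if behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {behavior!r} in script")
        if not (0 <= start < stop <= duration_s):
            raise ValueError(
                f"interval ({behavior}, {start}, {stop}) outside [0, {duration_s}]"
            )
    # contradictory overlaps: off-nest behaviors exclude each other and all
    # on-nest behaviors; the two nursing postures exclude each other
    def _overlap(a, b):
        return a[1] < b[2] and b[1] < a[2]

    for i, a in enumerate(script):
        for b in script[i + 1:]:
            if not _overlap(a, b):
                continue
            ab = {a[0], b[0]}
            contradictory = (
                (a[0] in OFF_NEST and b[0] in OFF_NEST and a[0] != b[0])
                or (a[0] in OFF_NEST and b[0] in ON_NEST)
                or (b[0] in OFF_NEST and a[0] in ON_NEST)
                or ab == {"active_nursing", "passive_nursing"}
            )
            if contradictory:
                raise ValueError(f"contradictory overlapping script entries: {a} and {b}")


@dataclass
class SimSession:
    """One simulated recording: dam pose, pup detections, truth, metadata."""

    dam: PoseSeries
    pup_detections: RawDetections
    truth: AnnotationSet
    meta: VideoMeta
    scenario: SimScenario

    def joined(self, max_pups: int = 12) -> JoinedPose:
        """Assemble the flat dam+pup table exactly as the pipeline would."""
        block = detections_to_table(self.pup_detections, max_pups=max_pups)
        return join_dam_pup(self.dam, block)


# ---------------------------------------------------------------------------
# dam body template
# ---------------------------------------------------------------------------

# (longitudinal position 0=tail_base..1=nose, lateral offset px, is_back, segment)
_DAM_TEMPLATE: dict[str, tuple[float, float]] = {
    "nose": (1.00, 0.0),
    "left_eye": (0.95, 10.0),
    "right_eye": (0.95, -10.0),
    "head_center": (0.90, 0.0),
    "left_ear": (0.87, 16.0),
    "right_ear": (0.87, -16.0),
    "left_ear_tip": (0.85, 24.0),
    "right_ear_tip": (0.85, -24.0),
    "neck": (0.78, 0.0),
    "chest": (0.70, -14.0),
    "ventrum_1": (0.55, -16.0),
    "ventrum_2": (0.40, -16.0),
    "pelvis": (0.25, -14.0),
    "left_shoulder": (0.68, 20.0),
    "right_shoulder": (0.68, -20.0),
    "left_front_paw": (0.72, 30.0),
    "right_front_paw": (0.72, -30.0),
    "left_hip": (0.22, 20.0),
    "right_hip": (0.22, -20.0),
    "left_hind_paw": (0.18, 32.0),
    "right_hind_paw": (0.18, -32.0),
    "tail_base": (0.00, 0.0),
    "tail_mid": (-0.12, 4.0),
    "tail_tip": (-0.25, 8.0),
}
_BACK_SPANS = np.linspace(0.74, 0.10, 8)  # back_1 .. back_8 along the body

_BODY_LENGTH_PX = 360.0  # nose..tail_base at px_per_mm = 2 (180 mm dam)
_OSC_FREQ_HZ = 6.0
_OSC_AMP_PX = 14.0
_WALK_SPEED_PX = 8.0  # per frame


def _dam_frame_keypoints(
    center: np.ndarray,
    heading: np.ndarray,
    arch_deg: float,
    osc: float,
    *,
    stretch: float = 1.0,
    limb_spread: float = 1.0,
    head_pitch_deg: float = 0.0,
) -> np.ndarray:
    """Place all 32 dam keypoints for one frame (noise-free)."""
    scheme = dam_scheme()
    L = _BODY_LENGTH_PX * stretch
    u = heading / max(np.linalg.norm(heading), 1e-9)
    perp = np.array([-u[1], u[0]])
    tail = center - 0.5 * L * u

    def at(t: float, lat: float) -> np.ndarray:
        return tail + t * L * u + lat * perp

    out = np.zeros((len(scheme), 3))
    for name, (t, lat) in _DAM_TEMPLATE.items():
        lat_eff = lat * (limb_spread if ("paw" in name or "hip" in name or "shoulder" in name) else 1.0)
        pos = at(t, lat_eff)
        if name in ("nose", "left_eye", "right_eye") and (head_pitch_deg or osc):
            hc = at(*_DAM_TEMPLATE["head_center"])
            rel = pos - hc
            if head_pitch_deg:
                a = np.radians(head_pitch_deg)
                rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
                rel = rot @ rel
            pos = hc + rel
        if osc and name in ("nose", "left_ear", "right_ear", "left_ear_tip", "right_ear_tip"):
            pos = pos + osc * perp
        out[scheme.index(name), :2] = pos

    # back points on an exact circular arc subtending arch_deg at the centre
    chord_ends = (at(_BACK_SPANS[0], 0.0), at(_BACK_SPANS[-1], 0.0))
    p1, p2 = chord_ends
    chord = np.linalg.norm(p2 - p1)
    theta = np.radians(max(arch_deg, 1.0))
    r = chord / (2 * np.sin(theta / 2))
    mid = (p1 + p2) / 2
    cdir = perp  # arc bulges toward +perp (the dam's dorsal side)
    centre = mid - r * np.cos(theta / 2) * cdir
    a0 = np.arctan2((p1 - centre)[1], (p1 - centre)[0])
    a1 = np.arctan2((p2 - centre)[1], (p2 - centre)[0])
    # sweep the short way from a0 to a1
    sweep = (a1 - a0 + np.pi) % (2 * np.pi) - np.pi
    for i, frac in enumerate(np.linspace(0, 1, len(_BACK_SPANS))):
        ang = a0 + frac * sweep
        pos = centre + r * np.array([np.cos(ang), np.sin(ang)])
        out[scheme.index(f"back_{i+1}"), :2] = pos
    return out


# ---------------------------------------------------------------------------
# behavior schedule
# ---------------------------------------------------------------------------

_SEGMENTS: dict[str, tuple[str, ...]] = {
    "nest": ("nest_attendance",),
    "active_nursing": ("nest_attendance", "active_nursing"),
    "passive_nursing": ("nest_attendance", "passive_nursing"),
    "licking_grooming": ("nest_attendance", "licking_grooming"),
    "self_grooming": ("self_grooming",),
    "eating": ("eating",),
    "drinking": ("drinking",),
    "wander": (),
}


def _segment_location(kind: str, layout: dict) -> np.ndarray:
    if kind in ("nest", "active_nursing", "passive_nursing", "licking_grooming"):
        return np.array(layout["nest"].center)
    if kind == "eating":
        return np.array(layout["food"].center)
    if kind == "drinking":
        return np.array(layout["water"].center)
    if kind == "self_grooming":
        return np.array(layout["groom_spot"])
    return np.array(layout["cage_center"])


def _make_schedule(rng: np.random.Generator, duration_s: float) -> list[tuple[str, float]]:
    """Ordered (segment_kind, duration_s) covering every behavior at least
    once when the session is long enough, then random continuation."""
    mandatory = ["nest", "active_nursing", "licking_grooming", "eating",
                 "passive_nursing", "self_grooming", "drinking"]
    rng.shuffle(mandatory)
    kinds = list(_SEGMENTS)
    weights = np.array([0.22, 0.14, 0.10, 0.12, 0.10, 0.10, 0.08, 0.14])
    schedule: list[tuple[str, float]] = []
    total = 0.0
    i = 0
    while total < duration_s:
        if i < len(mandatory):
            kind = mandatory[i]
        else:
            kind = kinds[rng.choice(len(kinds), p=weights / weights.sum())]
        dur = float(rng.uniform(3.0, 7.0))
        schedule.append((kind, dur))
        total += dur
        i += 1
    return schedule


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate_session(scenario: SimScenario) -> SimSession:
    """Generate one deterministic session from a scenario.

    Behavior posture templates: nest attendance keeps the dam centroid in
    the nest zone near the pup centroid; active nursing adds a strongly
    arched back (130 deg), passive nursing a flat, laterally-stretched
    posture; licking/grooming adds high-frequency nose/ear oscillation at
    the nest; self-grooming the same oscillation away from the pups;
    eating places the dam in the food zone, drinking in the water zone
    with the head pitched up.  Pup detections cluster in the nest zone
    and drop out at the configured occlusion rate.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    rng_layout, rng_script, rng_dam, rng_pup = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    W, H, fps = scenario.width_px, scenario.height_px, scenario.fps
    n_frames = int(round(scenario.duration_s * fps))

    # layout: nests are built anywhere in the lower/central cage
    if scenario.nest_zone is None:
        nw, nh = 280.0, 220.0
        nx = float(rng_layout.uniform(0.05 * W, 0.9 * W - nw))
        ny = float(rng_layout.uniform(0.35 * H, 0.95 * H - nh))
        nest = Rect(nx, ny, nx + nw, ny + nh)
    else:
        nest = scenario.nest_zone
    # self-grooming happens on the cage floor, away from the wall-mounted
    # food hopper and water spout, so only floor corners are candidates
    corners = [(100.0, H - 100.0), (W - 100.0, H - 100.0)]
    ncx, ncy = nest.center
    groom_spot = max(corners, key=lambda c: (c[0] - ncx) ** 2 + (c[1] - ncy) ** 2)
    layout = {
        "nest": nest,
        "food": scenario.food_zone,
        "water": scenario.water_zone,
        "groom_spot": groom_spot,
        "cage_center": (W / 2, H / 2),
    }

    # per-frame behavior sets + dam targets
    active: list[set[str]] = [set() for _ in range(n_frames)]
    targets = np.zeros((n_frames, 2))
    if scenario.behavior_script is None:
        schedule = _make_schedule(rng_script, scenario.duration_s * 1.5)
        intervals: list[tuple[str, float, float]] = []
        pos = np.array(layout["cage_center"], dtype=float)
        t = 0
        for kind, dur in schedule:
            if t >= n_frames:
                break
            if kind == "wander":
                # dams idle anywhere off the nest; a fixed idle spot would
                # let location features shortcut nest attendance
                while True:
                    loc = np.array([rng_script.uniform(60, W - 60),
                                    rng_script.uniform(60, H - 60)])
                    if np.linalg.norm(loc - np.array(nest.center)) >= 320:
                        break
            else:
                loc = _segment_location(kind, layout)
            travel = int(np.ceil(np.linalg.norm(loc - pos) / _WALK_SPEED_PX)) + 5
            for _ in range(travel):  # unlabeled transit
                if t >= n_frames:
                    break
                targets[t] = loc
                t += 1
            start = t
            for _ in range(int(round(dur * fps))):
                if t >= n_frames:
                    break
                targets[t] = loc
                active[t].update(_SEGMENTS[kind])
                t += 1
            if t > start:
                for b in _SEGMENTS[kind]:
                    intervals.append((b, start / fps, t / fps))
            pos = loc
        targets[t:] = targets[t - 1] if t > 0 else layout["cage_center"]
    else:
        intervals = [tuple(iv) for iv in scenario.behavior_script]
        labels = rasterize_intervals(list(intervals), n_frames, fps)
        for t in range(n_frames):
            active[t] = set(labels.columns[labels.iloc[t]])
        for t in range(n_frames):
            a = active[t]
            if "eating" in a:
                kind = "eating"
            elif "drinking" in a:
                kind = "drinking"
            elif "self_grooming" in a:
                kind = "self_grooming"
            elif a & set(ON_NEST):
                kind = "nest"
            else:
                kind = "wander"
            targets[t] = _segment_location(kind, layout)

    # dam trajectory
    scheme = dam_scheme()
    dam = np.zeros((n_frames, len(scheme), 3))
    pos = np.array(layout["cage_center"], dtype=float)
    heading = np.array([1.0, 0.0])
    osc_phase = float(rng_dam.uniform(0, 2 * np.pi))
    for t in range(n_frames):
        a = active[t]
        step = targets[t] - pos
        dist = np.linalg.norm(step)
        if dist > _WALK_SPEED_PX:
            step = step / dist * _WALK_SPEED_PX
        pos = pos + step + rng_dam.normal(0, 0.8, size=2)
        pos = np.clip(pos, [30, 30], [W - 30, H - 30])
        if np.linalg.norm(step) > 1.0:
            heading = step / np.linalg.norm(step)

        arch = 40.0
        stretch, limb_spread, pitch = 1.0, 1.0, 0.0
        osc = 0.0
        if "active_nursing" in a:
            arch = 130.0
        elif "passive_nursing" in a:
            arch, stretch, limb_spread = 8.0, 1.15, 1.8
        if "licking_grooming" in a or "self_grooming" in a:
            osc = _OSC_AMP_PX * np.sin(2 * np.pi * _OSC_FREQ_HZ * t / fps + osc_phase)
        if "drinking" in a:
            pitch = 50.0

        kps = _dam_frame_keypoints(
            pos, heading, arch, osc,
            stretch=stretch, limb_spread=limb_spread, head_pitch_deg=pitch,
        )
        kps[:, :2] += rng_dam.normal(0, scenario.noise_sd_px, size=(len(scheme), 2))
        p = rng_dam.uniform(0.85, 1.0, size=len(scheme))
        dropped = rng_dam.random(len(scheme)) < scenario.dam_dropout
        p[dropped] = 0.0
        kps[:, 2] = p
        dam[t] = kps

    meta = VideoMeta(
        video_id=f"sim-{scenario.seed}",
        fps=fps,
        width_px=W,
        height_px=H,
        px_per_mm=scenario.px_per_mm,
        n_frames=n_frames,
    )
    dam_series = PoseSeries(meta=meta, scheme=scheme, coords=dam)

    # pups: stable individual offsets around the nest centre + slow wiggle
    pscheme = pup_scheme()
    n_pups = scenario.n_pups
    pup_offsets = rng_pup.normal(0, 40.0, size=(n_pups, 2)) if n_pups else np.zeros((0, 2))
    pup_heading = rng_pup.uniform(0, 2 * np.pi, size=n_pups)
    wiggle = np.zeros((n_pups, 2))
    pup_len = 60.0
    spans = np.linspace(1.0, 0.0, len(pscheme))
    lat = np.array([0.0, 0.0, 6.0, -6.0, 0.0, 3.0, -3.0, 0.0, 0.0])
    frames: list[dict[str, np.ndarray]] = []
    nest_c = np.array(nest.center)

    # litter-wide occlusion episodes: for long stretches the whole litter is
    # hidden by bedding or the dam (the reason the pipeline carries 30/60-min
    # pup-centroid windows).  The fraction of time occluded grows with the
    # dropout setting; while visible, individual points still drop
    # independently at a reduced rate.
    f_occ = min(scenario.pup_dropout_in_nest ** 2, 1.0)
    occluded = np.zeros(n_frames, dtype=bool)
    if f_occ >= 1.0:
        occluded[:] = True
    elif f_occ > 0.0:
        mean_occ = 8.0 * fps
        mean_vis = mean_occ * (1.0 - f_occ) / f_occ
        t0 = 0
        state = bool(rng_pup.random() < f_occ)
        while t0 < n_frames:
            dur = int(rng_pup.exponential(mean_occ if state else mean_vis)) + 1
            if state:
                occluded[t0: t0 + dur] = True
            t0 += dur
            state = not state

    for t in range(n_frames):
        wiggle = 0.95 * wiggle + rng_pup.normal(0, 0.8, size=(n_pups, 2)) if n_pups else wiggle
        per_bp: dict[str, list] = {bp: [] for bp in pscheme.names}
        for i in range(n_pups):
            if occluded[t]:
                continue
            c = nest_c + pup_offsets[i] + wiggle[i]
            u = np.array([np.cos(pup_heading[i]), np.sin(pup_heading[i])])
            perp = np.array([-u[1], u[0]])
            in_nest = nest.contains(c[0], c[1])
            drop_p = 0.4 * (scenario.pup_dropout_in_nest if in_nest
                            else scenario.pup_dropout_off_nest)
            tail = c - 0.5 * pup_len * u
            for j, bp in enumerate(pscheme.names):
                if rng_pup.random() < drop_p:
                    continue  # occluded: no detection at all
                xy = tail + spans[j] * pup_len * u + lat[j] * perp
                xy = xy + rng_pup.normal(0, scenario.noise_sd_px, size=2)
                conf = float(rng_pup.uniform(0.7, 1.0))
                per_bp[bp].append([xy[0], xy[1], conf])
        frames.append({
            bp: (np.asarray(v, dtype=float) if v else np.empty((0, 3)))
            for bp, v in per_bp.items()
        })
    detections = RawDetections(meta=meta, bodyparts=pscheme.names, frames=frames)

    _validate_script(tuple(intervals), scenario.duration_s * (2.0 if scenario.behavior_script is None else 1.0))
    truth = AnnotationSet(
        behaviors=BEHAVIORS,
        intervals=list(intervals),
        frame_labels=rasterize_intervals(list(intervals), n_frames, fps),
    )
    return SimSession(dam=dam_series, pup_detections=detections, truth=truth, meta=meta,
                      scenario=scenario)


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------

FIXTURE_FILES = {
    "dam_pose": "dam_pose.csv",
    "detections_pickle": "pup_detections_full.pickle",
    "detections_json": "pup_detections.json",
    "annotations": "annotations.csv",
    "metadata": "metadata.yaml",
}


def write_fixture_set(scenario: SimScenario, directory) -> dict[str, Path]:
    """Simulate a session and write every pipeline input format.

    Emits the dam pose CSV (three-row-header dialect), the pup detections
    in both accepted dialects, the BORIS-style annotation CSV and a
    metadata YAML — exactly the files the IO layer reads, so the fixture
    round-trips losslessly.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    session = simulate_session(scenario)
    paths = {k: d / v for k, v in FIXTURE_FILES.items()}
    write_dam_pose(session.dam, paths["dam_pose"])
    write_detections_pickle(session.pup_detections, paths["detections_pickle"])
    write_detections_json(session.pup_detections, paths["detections_json"])
    write_annotations(session.truth.intervals, paths["annotations"])
    m = session.meta
    paths["metadata"].write_text(yaml.safe_dump({
        "video_id": m.video_id, "fps": m.fps, "width_px": m.width_px,
        "height_px": m.height_px, "px_per_mm": m.px_per_mm, "n_frames": m.n_frames,
    }))
    return paths


def read_fixture_meta(directory) -> VideoMeta:
    raw = yaml.safe_load((Path(directory) / FIXTURE_FILES["metadata"]).read_text())
    return VideoMeta(**raw)


def default_scenario(seed: int, **overrides) -> SimScenario:
    """A standard 60 s session at the default noise/occlusion levels."""
    return replace(SimScenario(seed=seed), **overrides)
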