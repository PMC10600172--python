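"""The versioned roster of the 218 frame-level features.

Features fall into eight categories — dam location, dam areas, dam
keypoint angles, dam keypoint probabilities, dam movement, pup area, pup
probabilities and dam–pup distances — and split by data source into 172
dam-only, 19 pup-only and 27 joint (dam+pup) features.  Many features are
trailing rolling-window statistics (mean / sum / std over 0.1 s, 1 s and
2 s) of an instantaneous base series; some dam–pup distances additionally
use 30- and 60-minute rolling pup centroids that bridge long pup
occlusions.

The roster is fixed per manifest version: classifier bundles record the
version they were trained against and refuse to score features produced
under a different one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

MANIFEST_VERSION = "1"

CATEGORIES = (
    "dam_location",
    "dam_areas",
    "dam_angles",
    "dam_probabilities",
    "dam_movement",
    "pup_area",
    "pup_probabilities",
    "dam_pup_distances",
)

#: source split the roster must honour
SOURCE_COUNTS = {"dam": 172, "pup": 19, "both": 27}
N_FEATURES = 218

_CATEGORY_SOURCE = {
    "dam_location": "dam",
    "dam_areas": "dam",
    "dam_angles": "dam",
    "dam_probabilities": "dam",
    "dam_movement": "dam",
    "pup_area": "pup",
    "pup_probabilities": "pup",
    "dam_pup_distances": "both",
}

ROLL_SPANS = (0.1, 1.0, 2.0)
ROLL_STATS = ("mean", "sum", "std")


@dataclass(frozen=True)
class FeatureEntry:
    """One feature column.

    ``base`` names the instantaneous series a windowed feature derives
    from (``None`` for instantaneous features); ``translation`` records how
    the value responds to a rigid shift of all coordinates (``shift_x`` /
    ``shift_y`` / ``invariant``), and ``units`` its physical unit (``px``,
    ``mm``, ``mm2``, ``deg``, ``likelihood`` or ``count``).
    """

    name: str
    category: str
    units: str
    translation: str = "invariant"
    base: str | None = None
    stat: str | None = None
    span_s: float | None = None
    pup_centroid_span_s: float | None = None

    @property
    def source(self) -> str:
        return _CATEGORY_SOURCE[self.category]


def _span_tag(span_s: float) -> str:
    return f"{span_s:g}s"


def _windows(base: str, category: str, units: str, translation: str = "invariant",
             stats=ROLL_STATS, spans=ROLL_SPANS) -> list[FeatureEntry]:
    return [
        FeatureEntry(
            name=f"{base}_{stat}_{_span_tag(span)}",
            category=category,
            units=units,
            translation=translation if stat != "std" else "invariant",
            base=base,
            stat=stat,
            span_s=span,
        )
        for stat in stats
        for span in spans
    ]


def build_manifest() -> "FeatureManifest":
    """Construct manifest version 1 (218 features)."""
    e: list[FeatureEntry] = []

    # ---- dam_location (16): raw px coordinates of anchor points, plus
    # smoothed / dispersion summaries of the dam centroid track
    for kp in ("dam_centroid", "dam_nose", "dam_head_center", "dam_tail_base"):
        e.append(FeatureEntry(f"{kp}_x", "dam_location", "px", "shift_x"))
        e.append(FeatureEntry(f"{kp}_y", "dam_location", "px", "shift_y"))
    for axis, shift in (("x", "shift_x"), ("y", "shift_y")):
        base = f"dam_centroid_{axis}"
        e += _windows(base, "dam_location", "px", shift, stats=("mean",))
        e.append(FeatureEntry(f"{base}_std_1s", "dam_location", "px", "invariant",
                              base=base, stat="std", span_s=1.0))

    # ---- dam_areas (40): convex hulls and body extent
    for base, units in (
        ("dam_hull_area", "mm2"),
        ("dam_head_hull_area", "mm2"),
        ("dam_body_hull_area", "mm2"),
        ("dam_body_length", "mm"),
    ):
        e.append(FeatureEntry(base, "dam_areas", units))
        e += _windows(base, "dam_areas", units)

    # ---- dam_angles (22): back arch, head/body orientation
    for base in ("back_arch_angle", "head_body_angle"):
        e.append(FeatureEntry(base, "dam_angles", "deg"))
        e += _windows(base, "dam_angles", "deg")
    e.append(FeatureEntry("head_bearing", "dam_angles", "deg"))
    e.append(FeatureEntry("body_bearing", "dam_angles", "deg"))

    # ---- dam_probabilities (15): occlusion structure of the dam pose
    e.append(FeatureEntry("dam_mean_likelihood", "dam_probabilities", "likelihood"))
    e.append(FeatureEntry("dam_sum_likelihood", "dam_probabilities", "likelihood"))
    e.append(FeatureEntry("dam_low_likelihood_count", "dam_probabilities", "count"))
    for group in ("head_points", "ear_points", "back_points", "ventrum_points",
                  "limb_points", "tail_points"):
        e.append(FeatureEntry(f"dam_{group}_mean_likelihood", "dam_probabilities", "likelihood"))
    for base in ("dam_mean_likelihood", "dam_low_likelihood_count"):
        units = "likelihood" if "likelihood" in base else "count"
        e += _windows(base, "dam_probabilities", units, stats=("mean",))

    # ---- dam_movement (79): per-keypoint displacement plus windowed
    # summaries of the most behavior-informative trackers (centroid, nose,
    # ears, back)
    from ..schemes import dam_scheme

    scheme = dam_scheme()
    for kp in scheme.names:
        e.append(FeatureEntry(f"dam_move_{kp}", "dam_movement", "mm"))
    e.append(FeatureEntry("dam_centroid_move", "dam_movement", "mm"))
    for base in ("dam_centroid_move", "dam_move_nose", "dam_move_left_ear", "dam_move_right_ear"):
        e += _windows(base, "dam_movement", "mm")
    e.append(FeatureEntry("dam_back_mean_move", "dam_movement", "mm"))
    e += _windows("dam_back_mean_move", "dam_movement", "mm")

    # ---- pup_area (10): litter convex hull
    e.append(FeatureEntry("pup_hull_area", "pup_area", "mm2"))
    e += _windows("pup_hull_area", "pup_area", "mm2")

    # ---- pup_probabilities (9): litter visibility
    for base in ("pup_mean_likelihood", "pup_sum_likelihood", "pup_detected_count"):
        units = "count" if "count" in base else "likelihood"
        e.append(FeatureEntry(base, "pup_probabilities", units))
    for base in ("pup_mean_likelihood", "pup_sum_likelihood", "pup_detected_count"):
        units = "count" if "count" in base else "likelihood"
        e += _windows(base, "pup_probabilities", units, stats=("mean",), spans=(1.0, 2.0))

    # ---- dam_pup_distances (27): dam anchors vs instantaneous and
    # long-window pup centroids
    long_spans = {"": None, "_30m": 1800.0, "_60m": 3600.0}
    for anchor in ("dam_centroid", "dam_nose", "dam_head_center"):
        for suffix, span in long_spans.items():
            e.append(FeatureEntry(
                f"dist_{anchor}_pup_centroid{suffix}", "dam_pup_distances", "mm",
                pup_centroid_span_s=span,
            ))
    for anchor in ("dam_centroid", "dam_nose"):
        e += _windows(f"dist_{anchor}_pup_centroid", "dam_pup_distances", "mm")

    return FeatureManifest(entries=tuple(e), version=MANIFEST_VERSION)


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered, versioned collection of :class:`FeatureEntry`."""

    entries: tuple[FeatureEntry, ...]
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        names = [en.name for en in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        for en in self.entries:
            if en.category not in CATEGORIES:
                raise ValueError(f"unknown category {en.category!r} for feature {en.name!r}")

    @property
    def names(self) -> list[str]:
        return [en.name for en in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
        for en in self.entries:
            out[en.category].append(en.name)
        return out

    def source_counts(self) -> dict[str, int]:
        out = {"dam": 0, "pup": 0, "both": 0}
        for en in self.entries:
            out[en.source] += 1
        return out

    def to_yaml(self, path) -> None:
        payload = {
            "version": self.version,
            "features": [
                {k: v for k, v in asdict(en).items() if v is not None}
                for en in self.entries
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureManifest":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        entries = tuple(FeatureEntry(**d) for d in payload["features"])
        return cls(entries=entries, version=str(payload["version"]))


_DEFAULT: FeatureManifest | None = None


def default_manifest() -> FeatureManifest:
    """The shipped manifest (version 1), cached."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_manifest()
    return _DEFAULT
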