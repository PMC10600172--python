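"""Keypoint rosters for dam and pup pose estimation.

The dam is tracked with 32 anatomical landmarks and each pup with 9
(nose to tail base).  Feature code addresses keypoints through named
groups (``back_points``, ``ear_points``, ...), never through roster
positions, so the roster lives in a versioned data file shipped with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import yaml

N_DAM_KEYPOINTS = 32
N_PUP_KEYPOINTS = 9

SCHEME_VERSION = "1"


@dataclass(frozen=True)
class KeypointScheme:
    """An ordered keypoint roster with named anatomical groups."""

    animal: str  # "dam" or "pup"
    names: tuple[str, ...]
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    version: str = SCHEME_VERSION

    def __post_init__(self) -> None:
        if self.animal not in ("dam", "pup"):
            raise ValueError(f"animal must be 'dam' or 'pup', got {self.animal!r}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("keypoint names must be unique")
        expected = N_DAM_KEYPOINTS if self.animal == "dam" else N_PUP_KEYPOINTS
        if len(self.names) != expected:
            raise ValueError(
                f"{self.animal} scheme must have exactly {expected} keypoints, "
                f"got {len(self.names)}"
            )
        for gname, members in self.groups.items():
            missing = set(members) - set(self.names)
            if missing:
                raise ValueError(f"group {gname!r} references unknown keypoints {sorted(missing)}")
        if self.animal == "dam":
            back = self.groups.get("back_points", ())
            if len(back) < 3:
                raise ValueError("dam scheme requires an ordered back_points group of >= 3 points")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def group_indices(self, group: str) -> list[int]:
        return [self.names.index(n) for n in self.groups[group]]

    def __len__(self) -> int:
        return len(self.names)


@lru_cache(maxsize=1)
def _load_roster() -> dict:
    with resources.files("damscore.data").joinpath("keypoints_v1.yaml").open() as fh:
        return yaml.safe_load(fh)


@lru_cache(maxsize=1)
def dam_scheme() -> KeypointScheme:
    """The canonical 32-point dam roster."""
    raw = _load_roster()
    return KeypointScheme(
        animal="dam",
        names=tuple(raw["dam"]["names"]),
        groups={k: tuple(v) for k, v in raw["dam"]["groups"].items()},
        version=str(raw["version"]),
    )


@lru_cache(maxsize=1)
def pup_scheme() -> KeypointScheme:
    """The canonical 9-point pup roster (nose to tail base)."""
    raw = _load_roster()
    return KeypointScheme(
        animal="pup",
        names=tuple(raw["pup"]["names"]),
        groups={k: tuple(v) for k, v in raw["pup"]["groups"].items()},
        version=str(raw["version"]),
    )
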