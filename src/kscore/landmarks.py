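"""Landmark naming and column conventions.

The canonical skeleton has 11 landmarks: five on the trunk (neck, both
shoulders, mid-spine, spine base) and six on the lower extremities (hips,
knees, ankles). Positions are stored landmark-major, three scalar channels
(x, y, z) per landmark, in meters.

Coordinate convention (configurable downstream): right-handed, ``y`` superior
(gravity-opposed), ``z`` anterior, ``x`` subject's left-to-right lateral axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AXES = ("x", "y", "z")

CANONICAL_NAMES = (
    "neck",
    "shoulder_l",
    "shoulder_r",
    "spine_mid",
    "spine_base",
    "hip_l",
    "hip_r",
    "knee_l",
    "knee_r",
    "ankle_l",
    "ankle_r",
)

TRUNK_NAMES = ("neck", "shoulder_l", "shoulder_r", "spine_mid", "spine_base")


@dataclass(frozen=True)
class LandmarkSet:
    """Ordered, unique set of landmark identifiers."""

    names: tuple[str, ...] = field(default=CANONICAL_NAMES)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")
        if not self.names:
            raise ValueError("landmark set may not be empty")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    @property
    def n_channels(self) -> int:
        """Number of scalar position channels (3 per landmark)."""
        return 3 * len(self.names)

    def column_labels(self) -> list[str]:
        """Channel labels in storage order: ``<landmark>_<axis>``, landmark-major."""
        return [f"{n}_{a}" for n in self.names for a in AXES]

    def slice_of(self, name: str) -> slice:
        """Column slice of one landmark's (x, y, z) triplet."""
        i = self.index(name)
        return slice(3 * i, 3 * i + 3)

    def channel_index(self, name: str, axis: str) -> int:
        return 3 * self.index(name) + AXES.index(axis)


CANONICAL = LandmarkSet(CANONICAL_NAMES)
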