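"""Activity labels and the normal/abnormal grouping used by the cascade.

The system recognises five leaf activities from a chest-worn accelerometer:
two risk events (cough, fall) and three routine activities (sit, walk,
sleep).  The two-level grouping drives the cascade: a binary gate separates
the risk events ("abnormal") from routine behaviour ("normal"), and a
dedicated sub-model refines each branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import InvalidConfigError, InvalidLabelError

#: The five leaf activities, in canonical reporting order.
ACTIVITIES: tuple[str, ...] = ("cough", "fall", "sit", "walk", "sleep")

NORMAL_GROUP = "normal"
ABNORMAL_GROUP = "abnormal"

_DEFAULT_GROUPS: dict[str, str] = {
    "cough": ABNORMAL_GROUP,
    "fall": ABNORMAL_GROUP,
    "sit": NORMAL_GROUP,
    "walk": NORMAL_GROUP,
    "sleep": NORMAL_GROUP,
}


@dataclass(frozen=True)
class Taxonomy:
    """Total mapping from leaf activity to its coarse group.

    The default is the canonical grouping (cough/fall abnormal; sit/walk/
    sleep normal).  The mapping is configurable so the same cascade
    machinery applies to other two-level label trees, but every leaf must
    be assigned to exactly one of the two groups.
    """

    group_of: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        groups = set(self.group_of.values())
        if not groups <= {NORMAL_GROUP, ABNORMAL_GROUP}:
            raise InvalidConfigError(f"unknown group names: {groups - {NORMAL_GROUP, ABNORMAL_GROUP}}")
        if len(groups) != 2:
            raise InvalidConfigError("taxonomy must use both the normal and the abnormal group")

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(self.group_of)

    @property
    def normal(self) -> tuple[str, ...]:
        return tuple(l for l, g in self.group_of.items() if g == NORMAL_GROUP)

    @property
    def abnormal(self) -> tuple[str, ...]:
        return tuple(l for l, g in self.group_of.items() if g == ABNORMAL_GROUP)

    def group(self, label: str) -> str:
        try:
            return self.group_of[label]
        except KeyError:
            raise InvalidLabelError(f"unknown activity label {label!r}") from None


DEFAULT_TAXONOMY = Taxonomy()


def validate_labels(labels) -> None:
    """Raise :class:`InvalidLabelError` if any label is not a leaf activity."""
    unknown = set(labels) - set(ACTIVITIES)
    if unknown:
        raise InvalidLabelError(f"unknown activity labels: {sorted(unknown)}")
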