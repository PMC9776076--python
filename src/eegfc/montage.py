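"""Electrode montage: the 29-channel 10-10 layout and named channel groups.

The default montage is the 32-channel actiCAP layout with Fp1/Fp2 excluded
(covered by a VR headset in the motivating experiment) and Fz used as the
recording reference, leaving 29 scalp channels. Channel groups name the
anatomically motivated blocks used for coupling presets and for hub/pathway
reporting: the posterior block, the left/right frontal blocks, and the
fronto-posterior interaction blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

#: The 29 scalp channels, in recording order.
DEFAULT_LABELS: tuple[str, ...] = (
    "F7", "F3", "F4", "F9", "FT9", "FC5", "FC1", "FC2", "FC6", "FT10",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6",
    "TP10", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
)

# Named channel blocks. "posterior" is the parieto-occipital block; the
# frontal blocks split by hemisphere; the "frontal_posterior_*" groups are the
# unions used for long-range fronto-posterior coupling.
_DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "posterior": ("Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8", "TP10"),
    "frontal_right": ("FT10", "FC6", "FC2", "F4", "F9"),
    "frontal_left": ("F3", "F7", "FT9", "FC5", "FC1"),
    "posterior_extended": ("CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4",
                           "P8", "TP10"),
    "occipital": ("O1", "Oz", "O2"),
    "frontal": ("F7", "F3", "F4", "F9", "FT9", "FC5", "FC1", "FC2", "FC6",
                "FT10"),
}


@dataclass(frozen=True)
class Montage:
    """An ordered set of channel labels with named subsets.

    Parameters
    ----------
    labels
        Ordered, unique channel names.
    groups
        Mapping from group name to a subset of ``labels``.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        for name, members in self.groups.items():
            missing = set(members) - set(self.labels)
            if missing:
                raise ValueError(
                    f"group {name!r} contains unknown channels: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Position of ``label`` in the montage."""
        return self.labels.index(label)

    def indices(self, labels: Sequence[str]) -> list[int]:
        return [self.index(l) for l in labels]


def default_montage() -> Montage:
    """The 29-channel 10-10 montage with default groups."""
    return Montage()
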