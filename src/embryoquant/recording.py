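"""In-memory representation of a 4D recording.

A recording is a set of channels; each channel is an ordered list of 3D
image stacks with per-stack wall-clock acquisition time and exposure time.
Fluorescent channels carry the quantified signal; a DIC channel, when
present, is a morphology placeholder and is never quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ShellAnnotation, VoxelGrid
from .timenorm import AnchorAnnotations

__all__ = ["Stack", "Channel", "Recording"]


@dataclass
class Stack:
    """One 3D image stack: integer counts, shape (Z, Y, X)."""

    data: np.ndarray
    time_s: float
    exposure_ms: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (Z, Y, X)")
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be positive")


@dataclass
class Channel:
    name: str
    stacks: list[Stack] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [s.time_s for s in self.stacks]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"channel {self.name!r}: stack timestamps must strictly increase")

    @property
    def times_s(self) -> np.ndarray:
        return np.array([s.time_s for s in self.stacks])

    @property
    def exposures_ms(self) -> np.ndarray:
        return np.array([s.exposure_ms for s in self.stacks])


@dataclass
class Recording:
    """A multi-channel 4D recording plus its annotations."""

    channels: dict[str, Channel]
    grid: VoxelGrid
    bit_depth: int = 12
    binning: int = 1
    shell: ShellAnnotation | None = None
    founders: dict[str, np.ndarray] | None = None
    anchors: AnchorAnnotations | None = None
    saturation_warning: bool = False
    recording_id: str = "recording"

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    def channel(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"no channel {name!r}; available: {sorted(self.channels)}"
            ) from None

    def fluorescent_channel(self) -> Channel:
        """The single non-DIC channel, erroring if ambiguous."""
        names = [n for n in self.channels if n.lower() != "dic"]
        if len(names) != 1:
            raise ValueError(f"expected one fluorescent channel, found {names}")
        return self.channels[names[0]]
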