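"""In-memory containers for multi-channel fluorescence fields.

A *field of view* is one captured image region: a set of registered
2-D intensity grids, one per fluorescence channel, sharing identical
dimensions. Channel identity is carried explicitly by role name — never
guessed from file metadata. Pixel coordinates are 0-based, row-major,
``(row, column)`` order throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import DimensionMismatchError

#: Channel roles the pipelines understand.
CHANNEL_ROLES = ("eGFP", "TagRFP", "LysoTracker", "Hoechst", "PI")

#: Nuclear counter-stains, excluded from the cytoplasmic composite by default.
COUNTER_STAINS = frozenset({"Hoechst", "PI"})


@dataclass
class FieldImage:
    """One field of view: role -> 2-D non-negative intensity grid.

    Parameters
    ----------
    channels
        Mapping from channel role (e.g. ``"eGFP"``, ``"TagRFP"``,
        ``"LysoTracker"``, ``"Hoechst"``, ``"PI"``) to a 2-D float array.
        All grids must share the same shape, and intensities must be
        finite and non-negative.
    field_id
        Identifier for this field (stable across IO round trips).
    condition
        Experimental condition label.
    """

    channels: dict[str, np.ndarray]
    field_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage requires at least one channel")
        shapes = {role: np.asarray(grid).shape for role, grid in self.channels.items()}
        first = next(iter(shapes.values()))
        if any(len(s) != 2 for s in shapes.values()):
            raise DimensionMismatchError(f"channel grids must be 2-D, got {shapes}")
        if any(s != first for s in shapes.values()):
            raise DimensionMismatchError(f"channel dimensions differ: {shapes}")
        for role, grid in self.channels.items():
            arr = np.asarray(grid, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {role!r} contains non-finite intensities")
            if np.any(arr < 0):
                raise ValueError(f"channel {role!r} contains negative intensities")
            self.channels[role] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]

    def __contains__(self, role: str) -> bool:
        return role in self.channels


@dataclass
class ConditionBatch:
    """Ordered collection of fields sharing one condition label."""

    condition: str
    fields: list[FieldImage] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        for f in self.fields:
            if f.condition and f.condition != self.condition:
                raise ValueError(
                    f"field {f.field_id!r} labelled {f.condition!r}, "
                    f"batch is {self.condition!r}"
                )

    def __len__(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(self.fields)
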