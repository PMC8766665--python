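"""Planar multi-electrode array geometry.

An :class:`ElectrodeArray` describes a rectangular grid of stimulation
electrodes (e.g. an 8x8 planar array at 200 um pitch) and the bijective
mapping between (row, col) grid positions and flat channel indices used by
the stimulator.  Channels are 0-based internally; reports use 1-based
(row, col) to match the electrophysiology convention of naming pins like
"row 3, column 5".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeArray", "mea_8x8"]


@dataclass(frozen=True)
class ElectrodeArray:
    """Rectangular electrode grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions.
    pitch_um
        Center-to-center electrode spacing in micrometers.
    channel_map
        Optional permutation: ``channel_map[row * n_cols + col]`` is the
        channel index of the electrode at (row, col).  Defaults to row-major
        identity.  Must be a bijection onto ``range(n_rows * n_cols)``.
    """

    n_rows: int
    n_cols: int
    pitch_um: float = 200.0
    channel_map: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("array must have at least one row and one column")
        if self.pitch_um <= 0:
            raise ValueError("pitch must be positive")
        if self.channel_map is not None:
            cm = tuple(int(c) for c in self.channel_map)
            if sorted(cm) != list(range(self.n_channels)):
                raise ValueError("channel_map must be a bijection onto channel indices")
            object.__setattr__(self, "channel_map", cm)

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def channel_of(self, row: int, col: int) -> int:
        """Channel index of the electrode at 0-based (row, col)."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"(row={row}, col={col}) outside {self.n_rows}x{self.n_cols} grid")
        flat = row * self.n_cols + col
        return flat if self.channel_map is None else self.channel_map[flat]

    def rowcol_of(self, channel: int) -> tuple[int, int]:
        """0-based (row, col) of a channel index."""
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} outside array with {self.n_channels} channels")
        flat = channel if self.channel_map is None else self.channel_map.index(channel)
        return divmod(flat, self.n_cols)

    def position_um(self, channel: int) -> tuple[float, float]:
        """(x, y) position of a channel in um; x grows with column, y with row."""
        row, col = self.rowcol_of(channel)
        return (col * self.pitch_um, row * self.pitch_um)

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of electrode (x, y) positions in um."""
        out = np.empty((self.n_channels, 2))
        for ch in range(self.n_channels):
            out[ch] = self.position_um(ch)
        return out

    def channels_in_grid_order(self) -> list[int]:
        """Channel indices in row-major (row, col) order."""
        return [self.channel_of(r, c) for r in range(self.n_rows) for c in range(self.n_cols)]

    def column_channels(self, col: int) -> list[int]:
        return [self.channel_of(r, col) for r in range(self.n_rows)]

    def label_of(self, channel: int) -> str:
        """Human-readable 1-based '(row, col)' label for reports."""
        r, c = self.rowcol_of(channel)
        return f"({r + 1}, {c + 1})"

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_um": self.pitch_um,
            "channel_map": list(self.channel_map) if self.channel_map else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeArray":
        cm = d.get("channel_map")
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch_um=float(d.get("pitch_um", 200.0)),
            channel_map=tuple(cm) if cm else None,
        )


def mea_8x8(pitch_um: float = 200.0) -> ElectrodeArray:
    """The default 8x8 planar array at 200 um spacing."""
    return ElectrodeArray(n_rows=8, n_cols=8, pitch_um=pitch_um)
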