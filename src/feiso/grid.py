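"""Vertical grid of the water column.

The default grid carries the 31 depth levels of the host ocean model
(bounds 0, 10, 20, ... 5500 m); shallower columns (e.g. a shelf station)
are built by truncating to the first ``n`` levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DEFAULT_LEVEL_BOUNDS", "VerticalGrid"]

#: Depth-level bounds (m) of the host model: 31 layers from 32 bounds.
DEFAULT_LEVEL_BOUNDS = (
    0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 101.0, 111.0,
    123.0, 135.0, 150.0, 169.0, 197.0, 241.0, 313.0, 430.0, 612.0, 873.0,
    1212.0, 1613.0, 2057.0, 2527.0, 3012.0, 3504.0, 4001.0, 4500.0, 5000.0,
    5500.0,
)


@dataclass(frozen=True)
class VerticalGrid:
    """Layered vertical grid defined by strictly increasing level bounds."""

    bounds: tuple = field(default=DEFAULT_LEVEL_BOUNDS)

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("grid needs at least two level bounds")
        if not np.all(np.diff(b) > 0):
            raise ValueError("level bounds must be strictly increasing")

    @classmethod
    def default(cls, n_levels: int | None = None) -> "VerticalGrid":
        """The host model's 31-level grid, optionally truncated to n levels."""
        if n_levels is None:
            return cls()
        if not 1 <= n_levels <= len(DEFAULT_LEVEL_BOUNDS) - 1:
            raise ValueError(f"n_levels must be in [1, {len(DEFAULT_LEVEL_BOUNDS) - 1}]")
        return cls(DEFAULT_LEVEL_BOUNDS[: n_levels + 1])

    @property
    def n(self) -> int:
        return len(self.bounds) - 1

    @property
    def top(self) -> np.ndarray:
        return np.asarray(self.bounds[:-1], dtype=float)

    @property
    def bottom(self) -> np.ndarray:
        return np.asarray(self.bounds[1:], dtype=float)

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.top + self.bottom)

    @property
    def dz(self) -> np.ndarray:
        return self.bottom - self.top

    @property
    def depth(self) -> float:
        """Seafloor depth (m) of the column."""
        return float(self.bounds[-1])

    def level_of(self, depth: np.ndarray) -> np.ndarray:
        """Index of the layer containing each depth (clipped to the column)."""
        d = np.asarray(depth, dtype=float)
        idx = np.searchsorted(np.asarray(self.bounds), d, side="right") - 1
        return np.clip(idx, 0, self.n - 1)
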