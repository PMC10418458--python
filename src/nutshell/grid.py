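"""Wavenumber grid for FT-NIR spectra.

Spectra live on a fixed, descending, evenly spaced wavenumber axis:
11,550 down to 3950 cm^-1 in steps of 4 cm^-1, i.e. 1901 channels, the
acquisition grid of a benchtop FT-NIR instrument operated in the
overtone/combination region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

__all__ = ["WavenumberGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class WavenumberGrid:
    """Descending, evenly spaced wavenumber axis in cm^-1.

    Parameters
    ----------
    start : float
        First (largest) wavenumber, cm^-1.
    stop : float
        Last (smallest) wavenumber, cm^-1.
    step : float
        Positive channel spacing, cm^-1. Values run ``start, start-step,
        ..., stop``.
    """

    start: float = 11550.0
    stop: float = 3950.0
    step: float = 4.0
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise GridError(f"grid step must be positive, got {self.step}")
        if self.start <= self.stop:
            raise GridError(
                f"grid must be descending: start={self.start} <= stop={self.stop}"
            )
        span = self.start - self.stop
        n_steps = span / self.step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise GridError(
                f"span {span} cm^-1 is not an integer multiple of step {self.step}"
            )
        vals = self.start - self.step * np.arange(round(n_steps) + 1)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``; error if outside."""
        if not (self.stop <= wavenumber <= self.start):
            raise GridError(
                f"wavenumber {wavenumber} cm^-1 outside grid "
                f"[{self.stop}, {self.start}]"
            )
        return int(round((self.start - wavenumber) / self.step))

    @classmethod
    def from_values(cls, values: np.ndarray, atol: float = 1e-6) -> "WavenumberGrid":
        """Reconstruct and validate a grid from an explicit wavenumber axis.

        Raises
        ------
        GridError
            If the axis is not strictly descending with constant spacing
            (e.g. a missing channel).
        """
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise GridError("grid axis needs at least two wavenumbers")
        diffs = np.diff(values)
        if np.any(diffs >= 0):
            raise GridError("wavenumber axis must be strictly descending")
        step = -diffs[0]
        if np.any(np.abs(diffs + step) > atol):
            raise GridError(
                "uneven wavenumber spacing (missing or duplicated channel?)"
            )
        return cls(start=float(values[0]), stop=float(values[-1]), step=float(step))


#: The instrument grid: 11,550-3950 cm^-1 at 4 cm^-1, 1901 channels.
DEFAULT_GRID = WavenumberGrid()
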