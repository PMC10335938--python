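"""Shared lightweight containers: genomic tracks, contact maps, time series.

All containers live on a binned genomic axis described by ``(chrom, origin,
bin_size, n_bins)``. Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Axis", "Track", "ContactMap", "CurveSeries"]


@dataclass(frozen=True)
class Axis:
    """A binned 1D genomic axis.

    Parameters
    ----------
    chrom : str
        Chromosome label (treated as an opaque axis name).
    origin : int
        Genomic coordinate (bp) of the left edge of bin 0.
    bin_size : int
        Width of each bin in bp.
    n_bins : int
        Number of bins.
    """

    chrom: str
    origin: int
    bin_size: int
    n_bins: int

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_bins <= 0:
            raise ValueError("n_bins must be positive")

    @property
    def end(self) -> int:
        return self.origin + self.bin_size * self.n_bins

    def bp_to_bin(self, pos: int) -> int:
        """Bin index containing genomic position ``pos``."""
        if not (self.origin <= pos < self.end):
            raise ValueError(f"position {pos} outside axis [{self.origin}, {self.end})")
        return (pos - self.origin) // self.bin_size

    def bin_interval(self, b: int) -> tuple[int, int]:
        """Genomic (start, end) of bin ``b`` (half-open)."""
        if not (0 <= b < self.n_bins):
            raise ValueError(f"bin {b} outside lattice of {self.n_bins} bins")
        start = self.origin + b * self.bin_size
        return start, start + self.bin_size

    def bp_range_to_bins(self, start: int, end: int) -> tuple[int, int]:
        """Inclusive bin range covering the half-open bp interval [start, end)."""
        lo = self.bp_to_bin(start)
        hi = self.bp_to_bin(min(end - 1, self.end - 1))
        return lo, hi

    def bin_midpoints(self) -> np.ndarray:
        return self.origin + (np.arange(self.n_bins) + 0.5) * self.bin_size


@dataclass
class Track:
    """Per-bin signal vector on an :class:`Axis` (bedGraph-compatible)."""

    axis: Axis
    values: np.ndarray
    name: str = "track"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} does not match axis "
                f"({self.axis.n_bins} bins)"
            )

    def copy(self) -> "Track":
        return Track(self.axis, self.values.copy(), self.name)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        return (
            isinstance(other, Track)
            and self.axis == other.axis
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ContactMap:
    """Symmetric per-bin contact frequency matrix on an :class:`Axis`."""

    axis: Axis
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.axis.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({n}, {n})")

    def validate(self, rtol: float = 1e-9) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("contact matrix contains non-finite values")
        if not np.allclose(self.matrix, self.matrix.T, rtol=rtol, atol=1e-12):
            raise ValueError("contact matrix is not symmetric")


@dataclass
class CurveSeries:
    """Time-indexed list of tracks sharing one axis."""

    times: list[float] = field(default_factory=list)
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self):
        if len(self.times) != len(self.tracks):
            raise ValueError("times and tracks must have equal length")
        if len(self.times) > 1:
            t = np.asarray(self.times)
            if not np.all(np.diff(t) > 0):
                raise ValueError("times must be strictly increasing")
        axes = {tr.axis for tr in self.tracks}
        if len(axes) > 1:
            raise ValueError("all tracks in a series must share one axis")

    @property
    def axis(self) -> Axis:
        if not self.tracks:
            raise ValueError("empty series has no axis")
        return self.tracks[0].axis

    def __len__(self) -> int:
        return len(self.times)

    def stack(self) -> np.ndarray:
        """(n_times, n_bins) matrix of values."""
        return np.vstack([tr.values for tr in self.tracks])
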