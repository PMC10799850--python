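"""3D scalar volumes with physical voxel pitch.

A :class:`Volume` is the unit of all image processing in this package: a
refractive-index (RI) contrast or intensity tomogram stored in ``(z, y, x)``
axis order, with the gel surface at slice index 0 and the z index increasing
with depth into the gel.  Physical coordinates are always micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume"]


@dataclass
class Volume:
    """A 3D scalar field with voxel pitch.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; float32 or float64.
    pitch
        Voxel pitch in micrometres, ``(dz, dy, dx)``.
    metadata
        Free-form provenance (seed, generator parameters, processing log).
    """

    data: np.ndarray
    pitch: tuple[float, float, float]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        self.pitch = tuple(float(p) for p in self.pitch)
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValueError(f"pitch must be three positive floats, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_size(self) -> tuple[float, float, float]:
        """Extent of the volume along (z, y, x) in micrometres."""
        return tuple(n * p for n, p in zip(self.data.shape, self.pitch))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        dz, dy, dx = self.pitch
        return dz * dy * dx

    def copy(self, data: np.ndarray | None = None, **meta) -> "Volume":
        """Return a copy, optionally with new data and extra metadata."""
        d = self.data.copy() if data is None else np.asarray(data)
        md = dict(self.metadata)
        md.update(meta)
        return Volume(d, self.pitch, md)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, Volume):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and np.array_equal(self.data, other.data)
            and self.pitch == other.pitch
        )
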