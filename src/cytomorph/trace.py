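"""Time-ordered per-cell geometry traces and their CSV schema."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical descriptor column names, shared by the generator's ground-truth
#: CSV and the measurement pipeline so the two can be joined directly
TRACE_COLUMNS = [
    "frame",
    "cell_id",
    "volume_um3",
    "surface_um2",
    "aspect_ratio",
    "hull_volume_um3",
    "chvr",
    "furrow_diameter_um",
]

#: descriptor name -> trace column
DESCRIPTORS = {
    "volume": "volume_um3",
    "surface_area": "surface_um2",
    "aspect_ratio": "aspect_ratio",
    "hull_volume": "hull_volume_um3",
    "chvr": "chvr",
    "furrow_diameter": "furrow_diameter_um",
}


@dataclass
class GeometryTrace:
    """One cell's shape descriptors over time.

    ``times`` are seconds from movie start, strictly increasing and
    uniformly spaced; ``data`` holds one row per frame with the
    :data:`TRACE_COLUMNS` schema.
    """

    cell_id: int
    times: np.ndarray
    data: pd.DataFrame
    genotype_tag: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.data):
            raise ValueError("times and data length mismatch")
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if not (dt > 0).all():
                raise ValueError("times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be uniformly spaced")

    @property
    def frame_interval(self) -> float:
        if len(self.times) < 2:
            return float("nan")
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)

    def values(self, descriptor: str) -> np.ndarray:
        """Descriptor series by short name (e.g. ``'aspect_ratio'``)."""
        col = DESCRIPTORS.get(descriptor, descriptor)
        if col not in self.data.columns:
            raise KeyError(f"unknown descriptor {descriptor!r}")
        return self.data[col].to_numpy(dtype=float)

    def shifted(self, t0: float) -> "GeometryTrace":
        """Copy with ``times`` re-referenced so that ``t0`` maps to 0."""
        return GeometryTrace(self.cell_id, self.times - t0, self.data.copy(),
                             self.genotype_tag)
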