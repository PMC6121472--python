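"""Planar multielectrode-array geometry.

The recordings this package targets come from a planar 8 x 8 grid of 64
extracellular electrodes (50 x 50 um sites on a 150 um pitch).  Electrode
indices are row-major: electrode ``k`` sits at row ``k // n_cols``, column
``k % n_cols``.  Inter-electrode distance enters the analysis twice: burst
activation patterns are read against it, and the delayed-synchrony window
converts it into an axonal conduction delay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ElectrodeGeometry:
    """Regular rectangular electrode grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; the default 8 x 8 gives 64 electrodes.
    pitch_um
        Centre-to-centre spacing in micrometres.
    electrode_size_um
        Side length of the square recording site (metadata only; it does
        not enter any computation).
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_um: float = 150.0
    electrode_size_um: float = 50.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must contain at least one electrode")
        if self.pitch_um <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch_um}")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def position_um(self, electrode: int) -> tuple[float, float]:
        """(x, y) centre of an electrode in micrometres."""
        if not 0 <= electrode < self.n_electrodes:
            raise ValueError(f"electrode {electrode} out of range")
        row, col = divmod(electrode, self.n_cols)
        return col * self.pitch_um, row * self.pitch_um

    def distance_um(self, i: int, j: int) -> float:
        """Euclidean centre distance between electrodes ``i`` and ``j``."""
        xi, yi = self.position_um(i)
        xj, yj = self.position_um(j)
        return float(np.hypot(xi - xj, yi - yj))

    def distance_matrix_um(self) -> np.ndarray:
        """Full pairwise distance matrix, shape (n_electrodes, n_electrodes)."""
        idx = np.arange(self.n_electrodes)
        rows, cols = np.divmod(idx, self.n_cols)
        dx = (cols[:, None] - cols[None, :]) * self.pitch_um
        dy = (rows[:, None] - rows[None, :]) * self.pitch_um
        return np.hypot(dx, dy)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "pitch_um": self.pitch_um,
            "electrode_size_um": self.electrode_size_um,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGeometry":
        return cls(**{k: d[k] for k in ("n_rows", "n_cols", "pitch_um", "electrode_size_um") if k in d})
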