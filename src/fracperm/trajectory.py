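"""Uniformly sampled permeant trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Time series of permeant coordinates with timestep metadata.

    Positions in Å; ``dt`` is the sampling interval in ns (MD logs usually
    quote ps — the text I/O layer converts).
    """

    dt: float
    z: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("x", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.z.shape:
                    raise ValueError(f"{name} length differs from z")
                setattr(self, name, v)

    def __len__(self):
        return self.z.size

    @property
    def t(self) -> np.ndarray:
        return self.dt * np.arange(self.z.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.z.size - 1)

    def displacements(self, lag: float, stride: float | None = None):
        """(z_start, z_end) pairs over the lag; stride defaults to the lag
        (non-overlapping segments, as when a trajectory is split)."""
        k = int(round(lag / self.dt))
        if k < 1 or abs(lag / self.dt - k) > 1e-6:
            raise ValueError("lag must be a positive multiple of dt")
        s = k if stride is None else int(round(stride / self.dt))
        starts = np.arange(0, self.z.size - k, s)
        return self.z[starts], self.z[starts + k]
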