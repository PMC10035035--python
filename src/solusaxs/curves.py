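"""Universal exchange containers: momentum-transfer grids and 1D curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class QGrid:
    """Strictly increasing, positive momentum-transfer grid in 1/Angstrom."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("QGrid needs a non-empty 1D array")
        if np.any(v < 0):
            raise ValueError("Q values must be non-negative")
        if np.any(np.diff(v) <= 0):
            raise ValueError("Q values must be strictly increasing")
        object.__setattr__(self, "values", v)

    @classmethod
    def geomspace(cls, q_min: float = 0.004, q_max: float = 0.5, n: int = 600) -> "QGrid":
        return cls(np.geomspace(q_min, q_max, n))

    @classmethod
    def linspace(cls, q_min: float, q_max: float, n: int) -> "QGrid":
        return cls(np.linspace(q_min, q_max, n))

    def __len__(self):
        return self.values.size


@dataclass
class ScatteringCurve:
    """1D SAXS curve: Q [1/A], absolute intensity I(Q) [1/cm], optional sigma.

    The standard product of azimuthal integration at a synchrotron
    beamline and the exchange object for every model and fit in the
    package.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where present")

    def __len__(self):
        return self.q.size

    @property
    def qgrid(self) -> QGrid:
        return QGrid(self.q)

    def rescale_q(self, factor: float) -> "ScatteringCurve":
        """Return a copy with q multiplied by `factor` (unit changes)."""
        return ScatteringCurve(
            self.q * factor, self.intensity.copy(),
            None if self.sigma is None else self.sigma.copy(),
            dict(self.metadata),
        )
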