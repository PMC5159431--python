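"""Shared in-memory containers for concentration–time data."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = ["ConcentrationProfile"]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Time-ordered concentrations for one matrix (plasma or a tissue).

    ``times`` are minutes post-dose, strictly increasing; ``values`` are
    ug/mL. ``dose`` (ug) and ``species`` record the dosing context used by
    downstream non-compartmental analysis.
    """

    times: np.ndarray
    values: np.ndarray
    matrix: str = "plasma"
    species: str | None = None
    dose: float | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.times.size

    def restricted(self, t_end: float) -> "ConcentrationProfile":
        """Profile truncated to times <= ``t_end``."""
        mask = self.times <= t_end
        return ConcentrationProfile(
            self.times[mask], self.values[mask], self.matrix,
            self.species, self.dose, dict(self.meta),
        )
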