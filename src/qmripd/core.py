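"""Shared containers for voxelwise quantitative maps.

A :class:`ParameterMap` is the common currency between fitting stages:
a named 3-D array of voxel values in stated units plus a validity mask
marking voxels where the fit succeeded. Downstream statistics (VOI
medians, pixel tables) consume valid voxels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical parameter names and their units
PARAMETER_UNITS = {
    "adc": "mm^2/s",
    "t1": "s",
    "iauc": "mM*s",
    "ktrans": "1/min",
    "ve": "",
    "vp": "",
    "m0": "a.u.",
}

#: direction of the expected pharmacodynamic change for each parameter:
#: stromal hyaluronan depletion lowers tumor water content (ADC, T1 fall)
#: and raises perfusion, permeability and extracellular space (the rest).
PARAMETER_DIRECTION = {
    "adc": "decrease",
    "t1": "decrease",
    "iauc": "increase",
    "ktrans": "increase",
    "ve": "increase",
    "vp": "increase",
}


@dataclass
class ParameterMap:
    """A named voxelwise quantitative map with a validity mask."""

    name: str
    values: np.ndarray
    units: str = ""
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.values.shape:
                raise ValueError(
                    f"valid mask shape {self.valid.shape} does not match "
                    f"values shape {self.values.shape}"
                )
        if not self.units and self.name in PARAMETER_UNITS:
            self.units = PARAMETER_UNITS[self.name]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def masked_values(self, mask: np.ndarray) -> np.ndarray:
        """Valid values inside a boolean region mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match map shape "
                f"{self.values.shape}"
            )
        return self.values[mask & self.valid]


def check_same_grid(*arrays: np.ndarray) -> tuple[int, ...]:
    """Raise if the arrays do not share one grid shape; return it."""
    shapes = {np.asarray(a).shape[:3] for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"arrays are not on a common grid: shapes {sorted(shapes)}")
    return shapes.pop()
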