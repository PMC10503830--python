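"""Apparent diffusion coefficient (ADC) mapping from diffusion-weighted MRI.

Mono-exponential model: S(b) = S0 * exp(-b * ADC), with b the diffusion
weighting in s/mm^2. Two b-values give the closed form
ADC = ln(S0/Sb)/b; more b-values are fit by log-linear least squares.
Replicate acquisitions are fitted independently and averaged voxelwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import ParameterMap, check_same_grid

log = logging.getLogger(__name__)


@dataclass
class DwiSeries:
    """One DWI replicate: signal stacks keyed by b-value (s/mm^2)."""

    volumes: dict[float, np.ndarray]
    replicate_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bvals = sorted(self.volumes)
        if any(b < 0 for b in bvals):
            raise ValueError("b-values must be non-negative")
        if len(set(bvals)) < 2:
            raise ValueError(
                "ADC requires >= 2 distinct b-values; got "
                f"{bvals} (a series missing its companion b-value cannot "
                "be fitted)"
            )
        check_same_grid(*self.volumes.values())
        self.volumes = {float(b): np.asarray(self.volumes[b], dtype=float) for b in bvals}

    @property
    def b_values(self) -> np.ndarray:
        return np.array(sorted(self.volumes), dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.volumes.values())).shape


def fit_adc(series: DwiSeries) -> ParameterMap:
    """Fit the mono-exponential decay per voxel.

    ADC is the slope of -ln S(b) against b. Voxels with any non-positive
    signal are marked invalid (log undefined). Negative ADC values —
    signal increasing with b, pure noise behaviour — are returned as-is
    but flagged invalid rather than clipped, so that downstream medians
    are not biased by truncation.
    """
    bvals = series.b_values
    shape = series.shape
    signals = np.stack([series.volumes[b].ravel() for b in bvals])
    positive = (signals > 0).all(axis=0)

    logs = np.full_like(signals, np.nan)
    np.log(signals, out=logs, where=signals > 0)

    if len(bvals) == 2:
        b0, b1 = bvals
        with np.errstate(invalid="ignore"):
            adc = (logs[0] - logs[1]) / (b1 - b0)
    else:
        # least squares of ln S = ln S0 - b*ADC over all b-values
        b_c = bvals - bvals.mean()
        denom = (b_c**2).sum()
        with np.errstate(invalid="ignore"):
            adc = -(b_c[:, None] * (logs - logs.mean(axis=0))).sum(axis=0) / denom

    valid = positive & np.isfinite(adc) & (adc >= 0)
    n_invalid = int((~valid).sum())
    if n_invalid:
        log.info("fit_adc: %d of %d voxels invalid (non-positive signal "
                 "or negative ADC)", n_invalid, adc.size)
    return ParameterMap("adc", adc.reshape(shape), units="mm^2/s",
                        valid=valid.reshape(shape))


def average_adc(maps: list[ParameterMap]) -> ParameterMap:
    """Voxelwise mean of replicate ADC maps over their valid voxels.

    A voxel is valid in the average if it is valid in at least one
    replicate; the mean is taken over the valid replicates only.
    """
    if not maps:
        raise ValueError("no ADC maps to average")
    shape = check_same_grid(*(m.values for m in maps))
    stack = np.stack([m.values for m in maps])
    valid = np.stack([m.valid for m in maps])
    count = valid.sum(axis=0)
    total = np.where(valid, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ParameterMap("adc", mean.reshape(shape), units="mm^2/s",
                        valid=(count > 0).reshape(shape))
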