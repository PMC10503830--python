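"""Repeatability coefficients (RC) from replicate measurements.

Following the QIBA convention, the within-subject variance sigma_w^2 is
the pooled one-way components-of-variance estimate over replicate sets,
and RC = 2.77 * sqrt(sigma_w^2) (2.77 = 1.96*sqrt(2)): 95% of
test-retest differences of a stable quantity fall within +/-RC, so a
change beyond RC is unlikely to be measurement noise.

For parameters without replicate acquisitions, literature RC values are
shipped as defaults: T1 0.27 s, iAUC +/-32% of baseline, ktrans -45%/+83%
of baseline, ve 0.076, vp 0.0062.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ParameterMap

RC_FACTOR = 2.77  # 1.96 * sqrt(2), rounded as conventionally quoted

#: ADC repeatability defaults when a tumor has no baseline replicates:
#: whole-data VOI-median RC and group pixelwise RC, mm^2/s
DEFAULT_GROUP_ADC_RC_VOI = 0.8e-3
DEFAULT_GROUP_ADC_RC_PIXEL = 1.4e-3


@dataclass
class RcSpec:
    """A repeatability threshold for one parameter.

    ``mode`` is ``absolute`` (bounds in parameter units), ``relative``
    (bounds as fractions of the baseline value) or ``asymmetric``
    (relative with direction-specific bounds). ``lower`` is negative,
    ``upper`` positive.
    """

    parameter: str
    mode: str  # absolute | relative | asymmetric
    lower: float
    upper: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.mode not in {"absolute", "relative", "asymmetric"}:
            raise ValueError(f"unknown RC mode {self.mode!r}")
        if not (self.lower < 0 < self.upper):
            raise ValueError("RC bounds must satisfy lower < 0 < upper")

    @property
    def is_relative(self) -> bool:
        return self.mode in {"relative", "asymmetric"}

    @classmethod
    def symmetric(cls, parameter: str, rc: float, mode: str = "absolute",
                  units: str = "") -> "RcSpec":
        return cls(parameter, mode, -rc, rc, units)


#: literature repeatability coefficients for parameters lacking replicates
LITERATURE_RC: dict[str, RcSpec] = {
    "t1": RcSpec.symmetric("t1", 0.27, units="s"),
    "iauc": RcSpec.symmetric("iauc", 0.32, mode="relative"),
    "ktrans": RcSpec("ktrans", "asymmetric", -0.45, 0.83),
    "ve": RcSpec.symmetric("ve", 0.076),
    "vp": RcSpec.symmetric("vp", 0.0062),
}


@dataclass
class ReplicateSet:
    """Replicate measurements of one quantity for one subject/tumor."""

    subject_id: str
    tumor_id: str
    values: np.ndarray
    level: str = "voi-median"  # voi-median | pixel

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def within_subject_variance(sets) -> float:
    """Pooled one-way within-subject variance over replicate sets.

    sigma_w^2 = sum_i sum_j (x_ij - mean_i)^2 / sum_i (n_i - 1).
    Accepts ReplicateSet objects or plain sequences; sets with fewer
    than two replicates contribute nothing.
    """
    ss = 0.0
    dof = 0
    for s in sets:
        vals = np.asarray(s.values if isinstance(s, ReplicateSet) else s, dtype=float)
        if vals.size < 2:
            continue
        ss += float(((vals - vals.mean()) ** 2).sum())
        dof += vals.size - 1
    if dof == 0:
        raise ValueError("no replicate set with >= 2 measurements")
    return ss / dof


def repeatability_coefficient(sigma_w2: float) -> float:
    """RC = 2.77 * sqrt(within-subject variance)."""
    if sigma_w2 < 0:
        raise ValueError("within-subject variance must be >= 0")
    return RC_FACTOR * float(np.sqrt(sigma_w2))


@dataclass
class BlandAltman:
    mean_diff: float
    loa_lower: float
    loa_upper: float
    diffs: np.ndarray
    means: np.ndarray


def bland_altman(pairs) -> BlandAltman:
    """Difference-vs-mean summary of paired repeat measurements.

    Limits of agreement are mean(d) +/- 1.96*SD(d) with the sample SD
    (ddof=1).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 replicate pairs, shape (n, 2)")
    d = arr[:, 0] - arr[:, 1]
    m = arr.mean(axis=1)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BlandAltman(mean_d, mean_d - 1.96 * sd_d, mean_d + 1.96 * sd_d, d, m)


def pixelwise_rc(
    replicate_maps: dict[str, list[ParameterMap]],
    masks: dict[str, np.ndarray],
    seed: int,
) -> float:
    """Group pixelwise RC with equal pixel counts per subject.

    From each subject, the replicate pixel values inside the mask are
    sampled without replacement down to the smallest subject's masked
    pixel count (so large tumors do not dominate), pooled, and passed
    through the pooled-variance RC estimator. Deterministic given seed.
    """
    if not replicate_maps:
        raise ValueError("no replicate maps")
    rng = np.random.default_rng(seed)
    per_subject: dict[str, np.ndarray] = {}
    for subject in sorted(replicate_maps):
        maps = replicate_maps[subject]
        if len(maps) < 2:
            continue
        mask = np.asarray(masks[subject], dtype=bool)
        valid = mask & np.all([m.valid for m in maps], axis=0)
        vals = np.stack([m.values[valid] for m in maps], axis=1)  # (pix, reps)
        if vals.shape[0] > 0:
            per_subject[subject] = vals
    if not per_subject:
        raise ValueError("no subject has >= 2 replicate maps with valid pixels")
    n = min(v.shape[0] for v in per_subject.values())
    sets = []
    for subject in sorted(per_subject):
        vals = per_subject[subject]
        pick = rng.choice(vals.shape[0], size=n, replace=False)
        sets.extend(vals[pick])
    return repeatability_coefficient(within_subject_variance(sets))
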