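"""Seeded digital phantoms emulating a multi-visit quantitative-MRI trial.

A phantom is a 3-D grid of ellipsoidal tissue regions (tumors, a
reference tissue, an artery, background), each carrying ground-truth
ADC, T1, ktrans, ve, vp and M0 values with smooth intra-region
heterogeneity. A programmed treatment effect multiplies the tumor
parameters at the first post-treatment visit (day 1) — ADC and T1 down,
perfusion parameters up, mimicking stromal hyaluronan depletion — and
decays toward baseline at later visits. An optional response gate
restricts the effect to voxels satisfying a baseline predicate (e.g.
ve < 0.39), giving the pixel-level analysis a learnable structure.

From the truth maps, forward simulators produce the acquisitions the
fitting stages consume: replicated two-point DWI, a four-angle SPGR
series for T1, and a dynamic contrast series driven by a biexponential
population arterial input function through the extended Tofts model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .dce import Aif, tofts_forward
from .t1 import spgr_signal

log = logging.getLogger(__name__)

PARAMS = ("adc", "t1", "ktrans", "ve", "vp", "m0")

#: physical bounds for ground-truth maps (lower, upper)
TRUTH_BOUNDS = {
    "adc": (1e-6, 4e-3),
    "t1": (0.05, 4.0),
    "ktrans": (0.0, 5.0),
    "ve": (1e-4, 1.0),
    "vp": (0.0, 0.5),
    "m0": (1e-6, np.inf),
}


@dataclass
class TissueTruth:
    """Ground-truth tissue properties of one region."""

    adc: float  # mm^2/s
    t1: float  # s
    ktrans: float  # 1/min
    ve: float
    vp: float
    m0: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 < self.adc <= 4e-3:
            raise ValueError(f"adc {self.adc} outside (0, 4e-3] mm^2/s")
        if not 0.05 < self.t1 <= 4.0:
            raise ValueError(f"t1 {self.t1} outside (0.05, 4] s")
        if not 0 <= self.ktrans <= 5.0:
            raise ValueError(f"ktrans {self.ktrans} outside [0, 5] 1/min")
        if not 0 <= self.ve <= 1.0:
            raise ValueError(f"ve {self.ve} outside [0, 1]")
        if not 0 <= self.vp <= 0.5:
            raise ValueError(f"vp {self.vp} outside [0, 0.5]")
        if self.ve + self.vp > 1.0:
            raise ValueError("ve + vp must not exceed 1")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")

    def as_dict(self) -> dict[str, float]:
        return {p: getattr(self, p) for p in PARAMS}


@dataclass
class RegionSpec:
    """An ellipsoidal region with uniform nominal tissue properties."""

    label: str  # tumor | reference | artery | background
    center: tuple[float, float, float]  # voxels
    radii: tuple[float, float, float]  # voxels
    truth: TissueTruth
    heterogeneity_sd: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if self.label not in {"tumor", "reference", "artery", "background"}:
            raise ValueError(f"unknown region label {self.label!r}")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if any(sd < 0 for sd in self.heterogeneity_sd.values()):
            raise ValueError("heterogeneity SDs must be >= 0")
        if not self.name:
            self.name = self.label

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=float)
        d2 = sum(
            ((idx[a] - self.center[a]) / self.radii[a]) ** 2 for a in range(3)
        )
        return d2 <= 1.0


@dataclass
class ResponseGate:
    """Baseline predicate restricting which voxels respond to treatment."""

    parameter: str
    threshold: float
    side: str = "below"  # respond where baseline value is below/above threshold

    def evaluate(self, baseline: dict[str, np.ndarray]) -> np.ndarray:
        vals = baseline[self.parameter]
        return vals < self.threshold if self.side == "below" else vals > self.threshold


@dataclass
class TreatmentEffect:
    """Multiplicative day-1 effect on tumor parameters, decaying by visit."""

    multipliers: dict[str, float] = field(default_factory=dict)
    decay: dict[str, float] = field(default_factory=dict)  # visit -> fraction remaining
    response_gate: ResponseGate | None = None

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("effect multipliers must be positive")
        if any(not 0 <= d <= 1 for d in self.decay.values()):
            raise ValueError("decay fractions must lie in [0, 1]")


@dataclass
class NoiseSpec:
    """Acquisition noise: SD as a fraction of the reference-region signal."""

    model: str = "gaussian"  # gaussian | rician
    sigma_rel: float = 0.02

    def __post_init__(self) -> None:
        if self.model not in {"gaussian", "rician"}:
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


@dataclass
class AcquisitionSpec:
    """Acquisition settings mirroring the trial protocol."""

    dwi_b_values: tuple[float, ...] = (0.0, 450.0)  # s/mm^2
    dwi_replicates: int = 3
    vfa_flip_angles: tuple[float, ...] = (15.0, 23.0, 30.0, 60.0)  # degrees
    vfa_tr: float = 3e-3  # s
    dce_flip_angle: float = 30.0
    dce_tr: float = 3e-3
    dce_n_frames: int = 48
    dce_frame_interval: float = 8.0  # s
    injection_frame: int = 8
    relaxivity_r1: float = 4.5  # s^-1 mM^-1

    def __post_init__(self) -> None:
        if len(set(self.dwi_b_values)) < 2:
            raise ValueError("need >= 2 distinct b-values")
        if any(b < 0 for b in self.dwi_b_values):
            raise ValueError("b-values must be non-negative")
        if len(set(self.vfa_flip_angles)) < 2:
            raise ValueError("need >= 2 distinct flip angles")
        if not (4 <= self.injection_frame < self.dce_n_frames):
            raise ValueError("injection_frame must satisfy 4 <= i < n_frames")

    @property
    def dce_times(self) -> np.ndarray:
        return np.arange(self.dce_n_frames) * self.dce_frame_interval


def default_regions() -> list[RegionSpec]:
    """Two tumors, a reference tissue and an artery on a 32x32x8 grid."""
    return [
        RegionSpec(
            "tumor", (9, 9, 3.5), (5, 5, 2.5),
            TissueTruth(adc=1.6e-3, t1=1.0, ktrans=0.12, ve=0.35, vp=0.03),
            heterogeneity_sd={"adc": 0.08, "t1": 0.08, "ktrans": 0.15,
                              "ve": 0.15, "vp": 0.2, "m0": 0.05},
            name="tumor1",
        ),
        RegionSpec(
            "tumor", (22, 9, 3.5), (4, 4, 2.5),
            TissueTruth(adc=1.1e-3, t1=0.7, ktrans=0.25, ve=0.5, vp=0.05),
            heterogeneity_sd={"adc": 0.08, "t1": 0.08, "ktrans": 0.15,
                              "ve": 0.15, "vp": 0.2, "m0": 0.05},
            name="tumor2",
        ),
        RegionSpec(
            "reference", (15, 22, 3.5), (6, 5, 2.5),
            TissueTruth(adc=1.0e-3, t1=0.58, ktrans=0.1, ve=0.3, vp=0.02),
            name="reference",
        ),
        RegionSpec(
            "artery", (28, 22, 3.5), (1.8, 1.8, 3.2),
            TissueTruth(adc=3.0e-3, t1=1.4, ktrans=0.0, ve=0.1, vp=0.5),
            name="artery",
        ),
    ]


def default_effect() -> TreatmentEffect:
    """Day-1 stromal-depletion effect decaying over later visits."""
    return TreatmentEffect(
        multipliers={"adc": 0.8, "t1": 0.8, "ktrans": 1.8, "ve": 1.4, "vp": 1.5},
        decay={"day1": 1.0, "visit2": 0.4, "last": 0.1},
    )


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (32, 32, 8)
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 8.0)  # mm
    regions: list[RegionSpec] = field(default_factory=default_regions)
    visits: tuple[str, ...] = ("baseline", "day1", "visit2", "last")
    effect: TreatmentEffect = field(default_factory=default_effect)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < m for s, m in zip(self.grid_shape, (16, 16, 4))):
            raise ValueError("grid_shape must be at least (16, 16, 4)")
        labels = [r.label for r in self.regions]
        for needed in ("tumor", "reference", "artery"):
            if needed not in labels:
                raise ValueError(f"phantom needs at least one {needed} region")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Serializable form of a phantom spec (inverse of :func:`spec_from_dict`)."""
    import dataclasses

    d = dataclasses.asdict(spec)
    d["grid_shape"] = list(spec.grid_shape)
    d["voxel_size"] = list(spec.voxel_size)
    d["visits"] = list(spec.visits)
    for r, rs in zip(d["regions"], spec.regions):
        r["center"] = list(rs.center)
        r["radii"] = list(rs.radii)
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    """Build a phantom spec from a plain dict (e.g. parsed YAML/JSON)."""
    d = dict(d)
    regions = []
    for r in d.pop("regions", []):
        r = dict(r)
        truth = TissueTruth(**r.pop("truth"))
        regions.append(RegionSpec(truth=truth, center=tuple(r.pop("center")),
                                  radii=tuple(r.pop("radii")), **r))
    effect = d.pop("effect", None)
    if isinstance(effect, dict):
        gate = effect.get("response_gate")
        effect = TreatmentEffect(
            multipliers=dict(effect.get("multipliers", {})),
            decay=dict(effect.get("decay", {})),
            response_gate=ResponseGate(**gate) if gate else None,
        )
    noise = d.pop("noise", None)
    if isinstance(noise, dict):
        noise = NoiseSpec(**noise)
    acq = d.pop("acquisition", None)
    if isinstance(acq, dict):
        for key in ("dwi_b_values", "vfa_flip_angles"):
            if key in acq:
                acq[key] = tuple(acq[key])
        acq = AcquisitionSpec(**acq)
    kwargs = {}
    for key in ("grid_shape", "voxel_size", "visits"):
        if key in d:
            kwargs[key] = tuple(d.pop(key))
    if "seed" in d:
        kwargs["seed"] = int(d.pop("seed"))
    if regions:
        kwargs["regions"] = regions
    if effect is not None:
        kwargs["effect"] = effect
    if noise is not None:
        kwargs["noise"] = noise
    if acq is not None:
        kwargs["acquisition"] = acq
    return PhantomSpec(**kwargs)


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom: per-visit parameter maps and masks."""

    spec: PhantomSpec
    maps: dict[str, dict[str, np.ndarray]]  # visit -> parameter -> 3-D array
    masks: dict[str, np.ndarray]  # region name -> boolean mask
    label_map: np.ndarray  # integer-labelled volume, 0 = outside all regions
    responding: np.ndarray  # voxels whose truth changes at day 1

    @property
    def tumor_mask(self) -> np.ndarray:
        out = np.zeros(self.spec.grid_shape, dtype=bool)
        for r in self.spec.regions:
            if r.label == "tumor":
                out |= self.masks[r.name]
        return out

    def region_mask(self, label: str) -> np.ndarray:
        out = np.zeros(self.spec.grid_shape, dtype=bool)
        for r in self.spec.regions:
            if r.label == label:
                out |= self.masks[r.name]
        return out


def _smooth_field(rng: np.random.Generator, shape, corr_len: float = 3.0) -> np.ndarray:
    """Unit-SD Gaussian random field with ~corr_len-voxel correlation."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=corr_len / 2.0, mode="reflect")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build ground-truth maps for every visit, deterministically by seed."""
    shape = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    masks: dict[str, np.ndarray] = {}
    label_map = np.zeros(shape, dtype=np.int16)
    occupied = np.zeros(shape, dtype=bool)
    for i, region in enumerate(spec.regions, start=1):
        m = region.mask(shape)
        if (m & occupied).any():
            raise ValueError(f"region {region.name!r} overlaps another region")
        occupied |= m
        masks[region.name] = m
        label_map[m] = i

    # background defaults: water-like tissue so simulators stay finite
    baseline = {
        "adc": np.full(shape, 2.0e-3),
        "t1": np.full(shape, 1.0),
        "ktrans": np.zeros(shape),
        "ve": np.full(shape, 0.2),
        "vp": np.zeros(shape),
        "m0": np.full(shape, 100.0),
    }
    n_clipped = 0
    for region in spec.regions:
        m = masks[region.name]
        for p in PARAMS:
            base_val = getattr(region.truth, p)
            sd = region.heterogeneity_sd.get(p, 0.0)
            if sd > 0:
                fld = _smooth_field(rng, shape)
                vals = base_val * (1.0 + sd * fld[m])
            else:
                vals = np.full(m.sum(), base_val)
            lo, hi = TRUTH_BOUNDS[p]
            n_clipped += int(((vals < lo) | (vals > hi)).sum())
            baseline[p][m] = np.clip(vals, lo, hi)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} heterogeneous truth values clipped to physical bounds",
            stacklevel=2,
        )

    tumor = np.zeros(shape, dtype=bool)
    for r in spec.regions:
        if r.label == "tumor":
            tumor |= masks[r.name]
    gate = spec.effect.response_gate
    responding = tumor & gate.evaluate(baseline) if gate is not None else tumor.copy()

    maps: dict[str, dict[str, np.ndarray]] = {}
    for visit in spec.visits:
        decay = 0.0 if visit == spec.visits[0] else spec.effect.decay.get(visit, 0.0)
        vm: dict[str, np.ndarray] = {}
        for p in PARAMS:
            arr = baseline[p].copy()
            mult = spec.effect.multipliers.get(p, 1.0)
            if decay > 0 and mult != 1.0:
                factor = 1.0 + (mult - 1.0) * decay
                arr[responding] = arr[responding] * factor
                lo, hi = TRUTH_BOUNDS[p]
                arr[responding] = np.clip(arr[responding], lo, hi)
            vm[p] = arr
        maps[visit] = vm

    return PhantomTruth(spec=spec, maps=maps, masks=masks, label_map=label_map,
                        responding=responding)


def _noise_sigma(noise: NoiseSpec, reference_signal: float) -> float:
    return noise.sigma_rel * reference_signal


def _add_noise(rng: np.random.Generator, signal: np.ndarray, sigma: float,
               model: str) -> np.ndarray:
    if sigma == 0:
        return signal
    if model == "gaussian":
        return signal + rng.normal(0.0, sigma, signal.shape)
    # rician: magnitude of a complex signal with gaussian noise per channel
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def simulate_dwi(
    truth: dict[str, np.ndarray],
    acq: AcquisitionSpec,
    noise: NoiseSpec,
    seed: int,
    reference_mask: np.ndarray | None = None,
) -> list[dict[float, np.ndarray]]:
    """Replicated DWI stacks: S(b) = M0 exp(-b*ADC) + noise.

    Returns one ``{b: volume}`` dict per replicate; replicates differ
    only by their noise draws. Noise SD is ``sigma_rel`` times the
    reference-region (or global) mean b=0 signal.
    """
    if any(b < 0 for b in acq.dwi_b_values):
        raise ValueError("b-values must be non-negative")
    adc, m0 = truth["adc"], truth["m0"]
    ref = m0[np.asarray(reference_mask, bool)] if reference_mask is not None else m0
    sigma = _noise_sigma(noise, float(ref.mean()))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(acq.dwi_replicates):
        rep = {}
        for b in acq.dwi_b_values:
            clean = m0 * np.exp(-b * adc)
            rep[float(b)] = _add_noise(rng, clean, sigma, noise.model)
        out.append(rep)
    return out


def simulate_vfa(
    truth: dict[str, np.ndarray],
    acq: AcquisitionSpec,
    noise: NoiseSpec,
    seed: int,
    fa_scale: float = 1.0,
    volume_scales: dict[float, float] | None = None,
    reference_mask: np.ndarray | None = None,
) -> dict[float, np.ndarray]:
    """Multi-flip-angle SPGR stacks keyed by nominal angle.

    ``fa_scale`` emulates a global flip-angle miscalibration (signals
    are generated at ``fa_scale`` times the nominal angles) and
    ``volume_scales`` per-volume intensity-gain differences.
    """
    t1_map, m0 = truth["t1"], truth["m0"]
    if np.any(t1_map <= 0):
        raise ValueError("t1 truth must be positive")
    # noise scale anchors to the observed T1w signal level (first angle),
    # not M0: at ms-scale TR the SPGR signal is a small fraction of M0
    sel = np.asarray(reference_mask, bool) if reference_mask is not None else ...
    first = min(acq.vfa_flip_angles)
    ref_sig = spgr_signal(m0[sel], t1_map[sel], first, acq.vfa_tr)
    sigma = _noise_sigma(noise, float(np.mean(ref_sig)))
    rng = np.random.default_rng(seed)
    out = {}
    for a in acq.vfa_flip_angles:
        clean = spgr_signal(m0, t1_map, fa_scale * a, acq.vfa_tr)
        if volume_scales:
            clean = clean * volume_scales.get(a, 1.0)
        out[float(a)] = _add_noise(rng, clean, sigma, noise.model)
    return out


def population_aif(
    times: np.ndarray,
    injection_time: float,
    dose: float = 0.1,
    amplitudes: tuple[float, float] = (3.99, 4.78),  # kg/L
    rates: tuple[float, float] = (0.144, 0.0111),  # 1/min
) -> Aif:
    """Biexponential population bolus model of plasma concentration.

    C_p(t) = dose * sum_i a_i exp(-m_i (t - t0)) for t >= t0, zero
    before; dose in mmol/kg so C_p is in mM. Times in seconds, decay
    rates in 1/min.
    """
    times = np.asarray(times, dtype=float)
    tau = np.maximum(times - injection_time, 0.0) / 60.0  # minutes
    cp = dose * sum(a * np.exp(-m * tau) for a, m in zip(amplitudes, rates))
    cp = np.where(times >= injection_time, cp, 0.0)
    arrival = int(np.searchsorted(times, injection_time))
    return Aif(times, cp, arrival_frame=arrival)


def simulate_dce(
    truth: dict[str, np.ndarray],
    aif: Aif,
    acq: AcquisitionSpec,
    noise: NoiseSpec,
    seed: int,
    artery_mask: np.ndarray | None = None,
    reference_mask: np.ndarray | None = None,
) -> np.ndarray:
    """DCE frame series (x, y, z, t) from the extended Tofts forward model.

    Tissue concentration per voxel is converted to SPGR signal through
    T1(t) = 1/(1/T1_pre + r1*C(t)). Artery voxels carry the AIF itself
    as their concentration. Pre-arrival plasma concentration must be
    zero, so pre-injection frames are contrast-free.
    """
    times = acq.dce_times
    if aif.times.shape != times.shape or not np.allclose(aif.times, times):
        raise ValueError("AIF time grid does not match the DCE acquisition grid")
    shape = truth["t1"].shape
    n_vox = int(np.prod(shape))
    kt = truth["ktrans"].reshape(-1)
    ve = np.maximum(truth["ve"].reshape(-1), 1e-4)
    vp = truth["vp"].reshape(-1)
    conc = tofts_forward(aif, times, kt, ve, vp)
    if artery_mask is not None:
        conc[np.asarray(artery_mask, bool).reshape(-1)] = aif.cp

    t1_pre = truth["t1"].reshape(-1)
    m0 = truth["m0"].reshape(-1)
    with np.errstate(divide="ignore"):
        t1_t = 1.0 / (1.0 / t1_pre[:, None] + acq.relaxivity_r1 * conc)
    signal = spgr_signal(m0[:, None], t1_t, acq.dce_flip_angle, acq.dce_tr)

    ref = m0[np.asarray(reference_mask, bool).reshape(-1)] if reference_mask is not None else m0
    pre_sig = spgr_signal(ref, t1_pre[np.asarray(reference_mask, bool).reshape(-1)]
                          if reference_mask is not None else t1_pre,
                          acq.dce_flip_angle, acq.dce_tr)
    sigma = _noise_sigma(noise, float(pre_sig.mean()))
    rng = np.random.default_rng(seed)
    signal = _add_noise(rng, signal, sigma, noise.model)
    return signal.reshape(*shape, len(times))
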