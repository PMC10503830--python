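"""NIfTI volume IO, study manifests and run configuration.

NIfTI-1 is the interchange format; a study manifest is a CSV table
linking subjects, tumors and visits to the series files each analysis
stage needs (columns: subject_id, tumor_id, visit, kind, path, key,
value with per-file acquisition metadata carried in key/value pairs or a
JSON sidecar). Configuration is a YAML file whose keys mirror
:class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import ParameterMap

MANIFEST_COLUMNS = ["subject_id", "tumor_id", "visit", "kind", "path", "metadata"]


@dataclass
class ImageVolume:
    values: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float]


def read_volume(path: str | Path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    affine = img.affine
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data, affine, tuple(float(z) for z in zooms))


def write_volume(
    values: np.ndarray,
    path: str | Path,
    affine: np.ndarray | None = None,
    voxel_size: tuple[float, float, float] = (1.5, 1.5, 8.0),
    units: str = "",
) -> Path:
    """Write a float array as NIfTI; units go into the header description."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if affine is None:
        affine = np.diag([*voxel_size, 1.0])
    values = np.asarray(values)
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    if units:
        img.header["descrip"] = units.encode()[:79]
    nib.save(img, str(path))
    return path


def write_parameter_map(pmap: ParameterMap, path: str | Path, **kw) -> Path:
    """Write a map and its validity mask (``<stem>_valid.nii.gz``)."""
    path = Path(path)
    write_volume(pmap.values, path, units=pmap.units, **kw)
    stem = path.name.removesuffix(".nii.gz").removesuffix(".nii")
    write_volume(pmap.valid, path.with_name(stem + "_valid.nii.gz"), **kw)
    return path


def check_grids_match(volume: np.ndarray, mask: np.ndarray) -> None:
    v, m = np.asarray(volume), np.asarray(mask)
    if v.shape[:3] != m.shape[:3]:
        raise ValueError(
            f"volume grid {v.shape[:3]} does not match mask grid {m.shape[:3]}"
        )


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks columns {missing}")
    return df


def write_manifest(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the trial protocol."""

    dwi_b_values: tuple[float, ...] = (0.0, 450.0)
    allowed_b_values: tuple[float, ...] = (0.0, 450.0)  # protocol-deviation filter
    vfa_tr: float = 3e-3
    dce_flip_angle: float = 30.0
    dce_tr: float = 3e-3
    dce_frame_interval: float = 8.0
    injection_frame: int = 8
    relaxivity_r1: float = 4.5  # s^-1 mM^-1
    iauc_window: float = 90.0
    iauc_anchor: str = "arrival"  # arrival | injection_frame
    t1_smoothness: float = 0.0
    reference_t1: dict[str, float] = field(
        default_factory=lambda: {"blood": 1.4, "liver": 0.58, "muscle": 0.85}
    )
    tree_max_depth: int = 1
    tree_iterations: int = 10
    min_valid_voxels: int = 5
    seed: int = 0
    output_dir: str = "qmripd_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dwi_b_values", "allowed_b_values"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["dwi_b_values"] = list(self.dwi_b_values)
        data["allowed_b_values"] = list(self.allowed_b_values)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path


def write_phantom_study(truth, out_dir: str | Path, noise=None,
                        seed: int | None = None, subject_id: str = "phantom"):
    """Simulate and write a full phantom study to disk.

    Produces per-visit DWI/VFA/DCE NIfTI files, region masks, and a
    manifest CSV, laid out the way the pipeline expects real data.
    Returns the manifest path.
    """
    from . import phantom as ph

    out_dir = Path(out_dir)
    spec = truth.spec
    acq = spec.acquisition
    noise = noise if noise is not None else spec.noise
    root_seed = spec.seed if seed is None else seed
    voxel_size = spec.voxel_size
    ref_mask = truth.region_mask("reference")
    artery_mask = truth.region_mask("artery")
    rows = []
    meta_common = {
        "vfa_tr": acq.vfa_tr, "dce_tr": acq.dce_tr,
        "dce_flip_angle": acq.dce_flip_angle,
        "dce_frame_interval": acq.dce_frame_interval,
        "injection_frame": acq.injection_frame,
        "relaxivity_r1": acq.relaxivity_r1,
    }
    ss = np.random.SeedSequence(root_seed)
    for vi, visit in enumerate(spec.visits):
        vm = truth.maps[visit]
        vdir = out_dir / visit
        sub_seeds = ss.spawn(3)
        dwi = ph.simulate_dwi(vm, acq, noise, sub_seeds[0].generate_state(1)[0] % 2**31,
                              reference_mask=ref_mask)
        for rep, stacks in enumerate(dwi):
            for b, vol in stacks.items():
                p = vdir / f"dwi_rep{rep}_b{int(b)}.nii.gz"
                write_volume(vol, p, voxel_size=voxel_size)
                rows.append({"subject_id": subject_id, "tumor_id": "", "visit": visit,
                             "kind": "dwi", "path": str(p),
                             "metadata": json.dumps({"b": b, "replicate": rep})})
        vfa = ph.simulate_vfa(vm, acq, noise, sub_seeds[1].generate_state(1)[0] % 2**31,
                              reference_mask=ref_mask)
        for a, vol in vfa.items():
            p = vdir / f"vfa_fa{int(a)}.nii.gz"
            write_volume(vol, p, voxel_size=voxel_size)
            rows.append({"subject_id": subject_id, "tumor_id": "", "visit": visit,
                         "kind": "vfa", "path": str(p),
                         "metadata": json.dumps({"flip_angle": a, **meta_common})})
        aif = ph.population_aif(acq.dce_times,
                                acq.injection_frame * acq.dce_frame_interval)
        dce = ph.simulate_dce(vm, aif, acq, noise,
                              sub_seeds[2].generate_state(1)[0] % 2**31,
                              artery_mask=artery_mask, reference_mask=ref_mask)
        p = vdir / "dce.nii.gz"
        write_volume(dce, p, voxel_size=voxel_size)
        rows.append({"subject_id": subject_id, "tumor_id": "", "visit": visit,
                     "kind": "dce", "path": str(p),
                     "metadata": json.dumps(meta_common)})
    # masks are visit-independent (phantoms are generated co-registered)
    for region in spec.regions:
        p = out_dir / f"mask_{region.name}.nii.gz"
        write_volume(truth.masks[region.name], p, voxel_size=voxel_size)
        rows.append({"subject_id": subject_id,
                     "tumor_id": region.name if region.label == "tumor" else "",
                     "visit": "", "kind": "mask", "path": str(p),
                     "metadata": json.dumps({"label": region.label})})
    p = out_dir / "labels.nii.gz"
    write_volume(truth.label_map, p, voxel_size=voxel_size)
    return write_manifest(rows, out_dir / "manifest.csv")
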