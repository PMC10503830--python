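"""End-to-end orchestration: manifest in, maps + response tables out.

Stages run in dependency order per subject and visit — ADC from DWI
replicates; T1 from the VFA series; signal-to-concentration; AIF; iAUC;
extended Tofts — then study-level statistics: ADC repeatability
coefficients from baseline replicates, VOI medians and responder labels,
baseline-threshold rules, and the pixel-level decision-tree analysis
when all six maps coexist. Missing series skip their stage with a
machine-readable exclusion entry rather than aborting the run, mirroring
per-patient inclusion logic in multi-site trials.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adc as adc_mod
from . import dce as dce_mod
from . import phantom as ph
from . import pixelwise as px
from . import repeatability as rep
from . import response as resp
from .core import ParameterMap
from .io import RunConfig, read_manifest, read_volume, write_parameter_map

log = logging.getLogger(__name__)

PARAMETERS = px.PARAMETERS


@dataclass
class Exclusion:
    subject_id: str
    tumor_id: str
    visit: str
    stage: str
    reason_code: str
    detail: str = ""


@dataclass
class PipelineResult:
    maps: dict  # subject -> visit -> parameter -> ParameterMap
    masks: dict  # subject -> {tumor_id: mask} (+ special keys reference/artery)
    adc_replicates: dict  # subject -> visit -> list[ParameterMap]
    measurements: pd.DataFrame
    labels: pd.DataFrame
    rc_table: pd.DataFrame
    threshold_rules: dict
    pixel_table: pd.DataFrame | None
    pixel_rule: px.DecisionRule | None
    pixel_cv: px.CvResult | None
    exclusions: list[Exclusion] = field(default_factory=list)


def _meta(row) -> dict:
    return json.loads(row["metadata"]) if row["metadata"] else {}


def _load_masks(manifest: pd.DataFrame, subject: str):
    tumors: dict[str, np.ndarray] = {}
    special: dict[str, np.ndarray] = {}
    rows = manifest[(manifest.subject_id == subject) & (manifest.kind == "mask")]
    for _, row in rows.iterrows():
        vol = read_volume(row["path"]).values.astype(bool)
        label = _meta(row).get("label", "")
        if label == "tumor" and row["tumor_id"]:
            tumors[row["tumor_id"]] = vol
        elif label in {"reference", "artery"}:
            special[label] = vol
    return tumors, special


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute every runnable stage for every subject and visit."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    config = config or RunConfig()
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    exclusions: list[Exclusion] = []
    maps: dict = {}
    masks: dict = {}
    adc_reps: dict = {}

    subjects = sorted(manifest.subject_id.unique())
    for subject in subjects:
        tumors, special = _load_masks(manifest, subject)
        masks[subject] = {"tumors": tumors, **special}
        maps[subject] = {}
        adc_reps[subject] = {}
        sub_rows = manifest[manifest.subject_id == subject]
        visits = [v for v in sub_rows.visit.unique() if v]
        for visit in visits:
            vrows = sub_rows[sub_rows.visit == visit]
            vm: dict[str, ParameterMap] = {}

            # ---- ADC -------------------------------------------------
            dwi_rows = vrows[vrows.kind == "dwi"]
            if len(dwi_rows):
                rep_maps = _fit_adc_stage(dwi_rows, config, subject, visit, exclusions)
                if rep_maps:
                    adc_reps[subject][visit] = rep_maps
                    vm["adc"] = adc_mod.average_adc(rep_maps)
            else:
                exclusions.append(Exclusion(subject, "", visit, "adc",
                                            "NO_DWI", "no DWI series in manifest"))

            # ---- T1 --------------------------------------------------
            vfa_rows = vrows[vrows.kind == "vfa"]
            t1_fit = None
            if len(vfa_rows):
                try:
                    t1_fit = _fit_t1_stage(vfa_rows, config)
                    vm["t1"] = t1_fit.t1
                except ValueError as err:
                    exclusions.append(Exclusion(subject, "", visit, "t1",
                                                "T1_FIT_FAILED", str(err)))
            else:
                exclusions.append(Exclusion(subject, "", visit, "t1",
                                            "NO_VFA", "no VFA series in manifest"))

            # ---- DCE -------------------------------------------------
            dce_rows = vrows[vrows.kind == "dce"]
            if len(dce_rows):
                t1_pre = vm.get("t1")
                if t1_pre is None:
                    # reference-T1 fallback when pre-contrast mapping is absent
                    ref_t1 = config.reference_t1.get("liver", 0.58)
                    shape = read_volume(dce_rows.iloc[0]["path"]).values.shape[:3]
                    t1_pre = ParameterMap("t1", np.full(shape, ref_t1))
                    exclusions.append(Exclusion(subject, "", visit, "dce",
                                                "REFERENCE_T1_FALLBACK",
                                                f"using reference T1 {ref_t1} s"))
                try:
                    dce_maps = _fit_dce_stage(
                        dce_rows.iloc[0], t1_pre, special.get("artery"), config,
                        analysis_mask=_analysis_mask(tumors, special),
                    )
                    vm.update(dce_maps)
                except ValueError as err:
                    exclusions.append(Exclusion(subject, "", visit, "dce",
                                                "DCE_FIT_FAILED", str(err)))
            else:
                exclusions.append(Exclusion(subject, "", visit, "dce",
                                            "NO_DCE", "no DCE series in manifest"))

            maps[subject][visit] = vm
            for name, pmap in vm.items():
                write_parameter_map(pmap, out / subject / visit / f"{name}.nii.gz")

    rc_table, adc_rc_by_tumor, group_rc = _rc_stage(maps, adc_reps, masks, exclusions)
    measurements, labels = _voi_stage(maps, masks, adc_rc_by_tumor, group_rc,
                                      config, exclusions)
    threshold_rules = _threshold_stage(measurements, labels)

    pixel_table = pixel_rule = pixel_cv = None
    try:
        pixel_table, pixel_labels = _pixel_stage(maps, masks, config)
        if pixel_table is not None and len(pixel_table):
            pixel_rule = px.train_balanced_tree(
                pixel_table, pixel_labels, max_depth=config.tree_max_depth,
                n_iterations=config.tree_iterations, seed=config.seed,
            )
            if pixel_table["subject_id"].nunique() >= 3:
                pixel_cv = px.lopo_evaluate(
                    pixel_table, pixel_labels, max_depth=config.tree_max_depth,
                    n_iterations=config.tree_iterations, seed=config.seed,
                )
    except ValueError as err:
        exclusions.append(Exclusion("", "", "", "pixelwise", "PIXELWISE_SKIPPED",
                                    str(err)))

    result = PipelineResult(maps, masks, adc_reps, measurements, labels, rc_table,
                            threshold_rules, pixel_table, pixel_rule, pixel_cv,
                            exclusions)
    _write_outputs(result, out)
    return result


def _fit_adc_stage(dwi_rows, config, subject, visit, exclusions):
    by_rep: dict[int, dict[float, np.ndarray]] = {}
    for _, row in dwi_rows.iterrows():
        meta = _meta(row)
        b = float(meta.get("b", 0.0))
        if b not in config.allowed_b_values:
            exclusions.append(Exclusion(subject, "", visit, "adc",
                                        "PROTOCOL_DEVIATION",
                                        f"b={b} not in allowed set"))
            continue
        by_rep.setdefault(int(meta.get("replicate", 0)), {})[b] = (
            read_volume(row["path"]).values
        )
    rep_maps = []
    for rep_id in sorted(by_rep):
        stacks = by_rep[rep_id]
        if len(stacks) < 2:
            exclusions.append(Exclusion(subject, "", visit, "adc",
                                        "MISSING_B_VALUE",
                                        f"replicate {rep_id} has b-values "
                                        f"{sorted(stacks)} only"))
            continue
        rep_maps.append(adc_mod.fit_adc(adc_mod.DwiSeries(stacks, rep_id)))
    return rep_maps


def _fit_t1_stage(vfa_rows, config):
    from .t1 import VfaSeries, fit_t1_vfa

    volumes = {}
    tr = config.vfa_tr
    for _, row in vfa_rows.iterrows():
        meta = _meta(row)
        volumes[float(meta["flip_angle"])] = read_volume(row["path"]).values
        tr = float(meta.get("vfa_tr", tr))
    series = VfaSeries(volumes, tr)
    return fit_t1_vfa(series, smoothness_weight=config.t1_smoothness)


def _analysis_mask(tumors: dict, special: dict) -> np.ndarray | None:
    """Tumor + reference voxels: the regions whose kinetics are analyzed.

    The artery carries the input function itself and is excluded from
    tissue fitting.
    """
    parts = list(tumors.values())
    if "reference" in special:
        parts.append(special["reference"])
    if not parts:
        return None
    out = np.zeros_like(parts[0], dtype=bool)
    for p in parts:
        out |= p
    return out


def _fit_dce_stage(dce_row, t1_pre, artery_mask, config, analysis_mask=None):
    meta = _meta(dce_row)
    frames = read_volume(dce_row["path"]).values
    interval = float(meta.get("dce_frame_interval", config.dce_frame_interval))
    times = np.arange(frames.shape[-1]) * interval
    series = dce_mod.DceSeries(
        frames, times,
        flip_angle=float(meta.get("dce_flip_angle", config.dce_flip_angle)),
        tr=float(meta.get("dce_tr", config.dce_tr)),
        injection_frame=int(meta.get("injection_frame", config.injection_frame)),
    )
    conc = dce_mod.signal_to_concentration(
        series, t1_pre, r1=float(meta.get("relaxivity_r1", config.relaxivity_r1))
    )
    if artery_mask is not None and artery_mask.any():
        aif = dce_mod.extract_aif(conc, artery_mask)
    else:
        aif = ph.population_aif(times, series.injection_frame * interval)
        aif.arrival_frame = dce_mod.detect_bolus_arrival(aif)
    anchor = (aif.arrival_frame if config.iauc_anchor == "arrival"
              else series.injection_frame)
    iauc = dce_mod.compute_iauc(conc, anchor, window=config.iauc_window)
    fit_mask = np.isfinite(conc.conc).all(axis=-1)
    if analysis_mask is not None:
        fit_mask &= analysis_mask
    tofts = dce_mod.fit_extended_tofts(conc, aif, fit_mask)
    return {"iauc": iauc, "ktrans": tofts.ktrans, "ve": tofts.ve, "vp": tofts.vp}


def _rc_stage(maps, adc_reps, masks, exclusions):
    """Per-tumor ADC RC from baseline replicates, with whole-data fallback."""
    rows = []
    per_tumor_sets = {}
    for subject, visits in adc_reps.items():
        reps = visits.get("baseline", [])
        if len(reps) < 2:
            continue
        for tumor_id, mask in masks[subject]["tumors"].items():
            medians = []
            for m in reps:
                vals = m.masked_values(mask)
                if vals.size:
                    medians.append(float(np.median(vals)))
            if len(medians) >= 2:
                per_tumor_sets[(subject, tumor_id)] = medians
    group_rc = None
    if per_tumor_sets:
        group_rc = rep.repeatability_coefficient(
            rep.within_subject_variance(list(per_tumor_sets.values()))
        )
    adc_rc = {}
    for subject, sub_masks in masks.items():
        for tumor_id in sub_masks["tumors"]:
            key = (subject, tumor_id)
            if key in per_tumor_sets:
                rc = rep.repeatability_coefficient(
                    rep.within_subject_variance([per_tumor_sets[key]])
                )
                source = "per-tumor"
            elif group_rc is not None:
                rc, source = group_rc, "whole-data"
            else:
                rc, source = rep.DEFAULT_GROUP_ADC_RC_VOI, "literature-default"
                exclusions.append(Exclusion(subject, tumor_id, "baseline", "rc",
                                            "NO_ADC_REPLICATES",
                                            "using shipped whole-data RC"))
            adc_rc[key] = rc
            rows.append({"subject_id": subject, "tumor_id": tumor_id,
                         "parameter": "adc", "rc": rc, "source": source})
    for p, spec in rep.LITERATURE_RC.items():
        rows.append({"subject_id": "", "tumor_id": "", "parameter": p,
                     "rc": spec.upper, "source": f"literature-{spec.mode}"})
    return pd.DataFrame(rows), adc_rc, group_rc


def _voi_stage(maps, masks, adc_rc_by_tumor, group_rc, config, exclusions):
    meas_rows, label_rows = [], []
    for subject, visits in maps.items():
        tumors = masks[subject]["tumors"]
        baseline_meas = {}
        for visit in visits:
            for tumor_id, mask in tumors.items():
                for p, pmap in visits[visit].items():
                    if p == "m0":
                        continue
                    try:
                        m = resp.summarize_voi(pmap, mask, subject, tumor_id, visit)
                    except ValueError:
                        exclusions.append(Exclusion(subject, tumor_id, visit, "voi",
                                                    "NO_VALID_VOXELS", p))
                        continue
                    if m.n_valid_voxels < config.min_valid_voxels:
                        exclusions.append(Exclusion(subject, tumor_id, visit, "voi",
                                                    "TOO_FEW_VALID_VOXELS",
                                                    f"{p}: {m.n_valid_voxels}"))
                        continue
                    meas_rows.append(m)
                    if visit == "baseline":
                        baseline_meas[(tumor_id, p)] = m
        for m in [r for r in meas_rows
                  if r.subject_id == subject and r.visit != "baseline"]:
            base = baseline_meas.get((m.tumor_id, m.parameter))
            if base is None:
                continue
            if m.parameter == "adc":
                rc_val = adc_rc_by_tumor.get((subject, m.tumor_id),
                                             rep.DEFAULT_GROUP_ADC_RC_VOI)
                # RC of exactly 0 (identical replicates) still needs a
                # valid interval; any nonzero change is then significant
                spec = rep.RcSpec.symmetric("adc", max(rc_val, 1e-15),
                                            units="mm^2/s")
            else:
                spec = rep.LITERATURE_RC[m.parameter]
            try:
                label_rows.append(resp.label_response(base, m, spec))
            except ValueError as err:
                exclusions.append(Exclusion(subject, m.tumor_id, m.visit, "label",
                                            "LABEL_FAILED", f"{m.parameter}: {err}"))
    meas = pd.DataFrame([vars(m) for m in meas_rows])
    labels = pd.DataFrame([vars(l) for l in label_rows])
    return meas, labels


def _threshold_stage(measurements, labels):
    """Learn baseline-threshold response predictors per parameter (day 1)."""
    rules = {}
    if measurements.empty or labels.empty:
        return rules
    base = measurements[measurements.visit == "baseline"]
    day1 = labels[labels.visit == "day1"]
    for p in PARAMETERS:
        merged = base[base.parameter == p].merge(
            day1[day1.parameter == p], on=["subject_id", "tumor_id", "parameter"]
        )
        if merged.empty:
            continue
        y = merged["label"].to_numpy()
        if (y == "P").all() or (y == "N").all():
            continue
        side = "above" if p in ("adc", "t1") else "below"
        try:
            rule = resp.optimize_threshold(
                merged["median_value"].to_numpy(float), y, side
            )
            rule.parameter = p
            rules[p] = rule
        except ValueError as err:
            log.info("threshold search skipped for %s: %s", p, err)
    return rules


def _pixel_stage(maps, masks, config):
    subject_maps, subject_masks = {}, {}
    for subject, visits in maps.items():
        if not {"baseline", "day1"} <= set(visits):
            continue
        if not all(p in visits[v] for v in ("baseline", "day1") for p in PARAMETERS):
            continue
        subject_maps[subject] = {v: visits[v] for v in ("baseline", "day1")}
        subject_masks[subject] = masks[subject]["tumors"]
    if not subject_maps:
        return None, None
    table = px.build_pixel_table(subject_maps, subject_masks)
    if not len(table):
        return table, np.zeros(0, bool)
    labelled = px.label_pixels(table, rep.LITERATURE_RC)
    return table, labelled["responder"].to_numpy()


def _write_outputs(result: PipelineResult, out: Path) -> None:
    if len(result.measurements):
        result.measurements.to_csv(out / "voi_measurements.csv", index=False)
    if len(result.labels):
        result.labels.to_csv(out / "voi_labels.csv", index=False)
    result.rc_table.to_csv(out / "rc_table.csv", index=False)
    if result.threshold_rules:
        pd.DataFrame([vars(r) for r in result.threshold_rules.values()]).to_csv(
            out / "threshold_rules.csv", index=False
        )
    if result.pixel_table is not None and len(result.pixel_table):
        result.pixel_table.to_csv(out / "pixel_table.csv", index=False)
    if result.pixel_rule is not None:
        (out / "pixel_rule.json").write_text(
            json.dumps(result.pixel_rule.describe(), indent=2)
        )
    if result.pixel_cv is not None:
        pd.DataFrame({"subject_id": result.pixel_cv.subjects,
                      "ba": result.pixel_cv.per_subject_ba}).to_csv(
            out / "pixel_lopo.csv", index=False
        )
    with open(out / "exclusions.log", "w") as fh:
        for e in result.exclusions:
            fh.write(f"{e.stage}\t{e.reason_code}\t{e.subject_id}\t{e.tumor_id}\t"
                     f"{e.visit}\t{e.detail}\n")
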