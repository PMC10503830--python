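"""Pixel-level pharmacodynamic response analysis.

Co-registered baseline and day-1 parameter maps are flattened into a
table with one row per tumor voxel. A pixel is a "p-responder" when at
least one of the six parameters changes beyond its directional
repeatability coefficient. A decision tree (default: a depth-1 stump,
the form the analysis ultimately selects) predicts the pixel class from
baseline values, trained with equal pixel counts per patient (85% of the
smallest tumor) and equal class counts, and evaluated per patient and by
leave-one-patient-out cross-validation on balanced accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .core import PARAMETER_DIRECTION, ParameterMap
from .repeatability import DEFAULT_GROUP_ADC_RC_PIXEL, RcSpec
from .response import classification_metrics

log = logging.getLogger(__name__)

PARAMETERS = ("adc", "t1", "iauc", "ktrans", "ve", "vp")
BASELINE_COLS = [f"base_{p}" for p in PARAMETERS]
DAY1_COLS = [f"day1_{p}" for p in PARAMETERS]


def build_pixel_table(
    subject_maps: dict[str, dict[str, dict[str, ParameterMap]]],
    subject_masks: dict[str, dict[str, np.ndarray]],
    baseline_visit: str = "baseline",
    followup_visit: str = "day1",
) -> pd.DataFrame:
    """One row per tumor voxel with baseline and day-1 values of all six
    parameters.

    ``subject_maps[subject][visit][parameter]`` are co-registered maps on
    one grid per subject; ``subject_masks[subject][tumor_id]`` the tumor
    masks. Voxels where any parameter is invalid at either visit are
    dropped (count logged).
    """
    rows = []
    for subject in sorted(subject_maps):
        visits = subject_maps[subject]
        for visit in (baseline_visit, followup_visit):
            if visit not in visits:
                raise ValueError(f"subject {subject} lacks visit {visit!r}")
            missing = [p for p in PARAMETERS if p not in visits[visit]]
            if missing:
                raise ValueError(
                    f"subject {subject} visit {visit} lacks maps for {missing}"
                )
        grid = visits[baseline_visit][PARAMETERS[0]].shape
        for tumor_id in sorted(subject_masks[subject]):
            mask = np.asarray(subject_masks[subject][tumor_id], dtype=bool)
            if mask.shape != grid:
                raise ValueError(
                    f"mask grid {mask.shape} does not match map grid {grid} "
                    f"for subject {subject}: maps must be co-registered"
                )
            idx = np.flatnonzero(mask.reshape(-1))
            complete = np.ones(idx.size, dtype=bool)
            cols = {}
            for prefix, visit in (("base", baseline_visit), ("day1", followup_visit)):
                for p in PARAMETERS:
                    m = visits[visit][p]
                    cols[f"{prefix}_{p}"] = m.values.reshape(-1)[idx]
                    complete &= m.valid.reshape(-1)[idx]
            n_drop = int((~complete).sum())
            if n_drop:
                log.info("build_pixel_table: %s/%s dropped %d incomplete voxels",
                         subject, tumor_id, n_drop)
            df = pd.DataFrame(cols)
            df.insert(0, "voxel", idx)
            df.insert(0, "tumor_id", tumor_id)
            df.insert(0, "subject_id", subject)
            rows.append(df[complete])
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["subject_id", "tumor_id", "voxel", *BASELINE_COLS, *DAY1_COLS]
    )
    return out


def label_pixels(
    table: pd.DataFrame,
    rc_specs: dict[str, RcSpec],
    adc_rc: float | dict[tuple[str, str], float] = DEFAULT_GROUP_ADC_RC_PIXEL,
) -> pd.DataFrame:
    """Label each pixel a p-responder if any parameter change beats its RC.

    ``adc_rc`` is either the group pixelwise RC (mm^2/s) applied to every
    tumor, or a per-(subject, tumor) dict for tumors with their own
    baseline-replicate RC, falling back to the group value. The other
    five parameters use the supplied (literature) RC specs. Returns the
    table with a boolean ``responder`` column and one ``trig_<param>``
    column per parameter.
    """
    missing = [p for p in PARAMETERS if p != "adc" and p not in rc_specs]
    if missing:
        raise ValueError(f"missing RC specs for {missing}")
    out = table.copy()
    any_trig = np.zeros(len(out), dtype=bool)
    for p in PARAMETERS:
        base = out[f"base_{p}"].to_numpy(dtype=float)
        day1 = out[f"day1_{p}"].to_numpy(dtype=float)
        direction = PARAMETER_DIRECTION[p]
        if p == "adc":
            if isinstance(adc_rc, dict):
                keys = list(zip(out["subject_id"], out["tumor_id"]))
                rc_vals = np.array([
                    adc_rc.get(k, DEFAULT_GROUP_ADC_RC_PIXEL) for k in keys
                ])
            else:
                rc_vals = np.full(len(out), float(adc_rc))
            change = day1 - base
            trig = change < -rc_vals
        else:
            spec = rc_specs[p]
            if spec.is_relative:
                with np.errstate(divide="ignore", invalid="ignore"):
                    change = np.where(base != 0, (day1 - base) / base, np.nan)
            else:
                change = day1 - base
            if direction == "decrease":
                trig = change < spec.lower
            else:
                trig = change > spec.upper
            trig = np.where(np.isfinite(change), trig, False).astype(bool)
        out[f"trig_{p}"] = trig
        any_trig |= trig
    out["responder"] = any_trig
    return out


@dataclass
class DecisionRule:
    """A fitted CART tree over baseline parameter values.

    For the default depth-1 stump, ``splits`` holds the single
    (parameter, threshold) pair and the rule reads "predict p-responder
    on the <side> side of the threshold".
    """

    tree: DecisionTreeClassifier
    feature_names: list[str]
    max_depth: int
    training_ba: float
    validation_ba: float
    splits: list[tuple[str, float]] = field(default_factory=list)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.feature_names].to_numpy(dtype=float)
        return self.tree.predict(x).astype(bool)

    def describe(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "splits": [
                {"parameter": p.removeprefix("base_"), "threshold": t}
                for p, t in self.splits
            ],
            "training_ba": self.training_ba,
            "validation_ba": self.validation_ba,
        }


def _extract_splits(tree: DecisionTreeClassifier, names: list[str]):
    t = tree.tree_
    return [
        (names[t.feature[i]], float(t.threshold[i]))
        for i in range(t.node_count)
        if t.children_left[i] != -1
    ]


def _per_subject_sample_size(table: pd.DataFrame, fraction: float = 0.85) -> int:
    """85% of the smallest tumor's pixel count, the per-subject draw size."""
    smallest = table.groupby(["subject_id", "tumor_id"]).size().min()
    n = int(np.floor(fraction * smallest))
    if n < 1:
        raise ValueError("smallest tumor too small to sample from")
    return n


def train_balanced_tree(
    table: pd.DataFrame,
    labels: np.ndarray,
    max_depth: int = 1,
    n_iterations: int = 10,
    seed: int = 0,
    sample_fraction: float = 0.85,
) -> DecisionRule:
    """Train a class-balanced, per-patient-sampled decision tree.

    Each iteration draws ``floor(sample_fraction * smallest-tumor pixel
    count)`` pixels per subject without replacement, down-samples the
    majority class in the pooled draw to equal class counts, fits a
    Gini CART tree of ``max_depth``, and scores balanced accuracy per
    subject on that subject's held-out pixels. The iteration with the
    best mean validation BA wins. Deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=bool)
    if len(labels) != len(table):
        raise ValueError("labels length does not match table")
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present overall")
    rng = np.random.default_rng(seed)
    n_per_subject = _per_subject_sample_size(table, sample_fraction)
    subj_idx = {s: np.flatnonzero(table["subject_id"].to_numpy() == s)
                for s in subjects}
    x_all = table[BASELINE_COLS].to_numpy(dtype=float)

    best: DecisionRule | None = None
    for it in range(n_iterations):
        train_idx = []
        for s in subjects:
            pool = subj_idx[s]
            take = min(n_per_subject, len(pool))
            train_idx.append(rng.choice(pool, size=take, replace=False))
        train_idx = np.concatenate(train_idx)
        y = labels[train_idx]
        pos, neg = train_idx[y], train_idx[~y]
        if len(pos) == 0 or len(neg) == 0:
            log.warning("iteration %d: training draw lacks a class; skipped", it)
            continue
        k = min(len(pos), len(neg))
        pos = rng.choice(pos, size=k, replace=False)
        neg = rng.choice(neg, size=k, replace=False)
        bal = np.concatenate([pos, neg])

        clf = DecisionTreeClassifier(
            criterion="gini", max_depth=max_depth,
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(x_all[bal], labels[bal])
        _, _, train_ba = classification_metrics(clf.predict(x_all[bal]), labels[bal])

        in_train = np.zeros(len(table), dtype=bool)
        in_train[train_idx] = True
        fold_bas = []
        for s in subjects:
            held = subj_idx[s][~in_train[subj_idx[s]]]
            if len(held) == 0:
                continue
            y_h = labels[held]
            if y_h.all() or not y_h.any():
                continue  # BA undefined for this subject's validation pixels
            _, _, ba = classification_metrics(clf.predict(x_all[held]), y_h)
            fold_bas.append(ba)
        val_ba = float(np.mean(fold_bas)) if fold_bas else float("nan")
        rule = DecisionRule(clf, BASELINE_COLS, max_depth, train_ba, val_ba,
                            _extract_splits(clf, BASELINE_COLS))
        if best is None or (np.isfinite(val_ba) and
                            (not np.isfinite(best.validation_ba)
                             or val_ba > best.validation_ba)):
            best = rule
    if best is None:
        raise ValueError("no training iteration produced a usable tree")
    return best


@dataclass
class CvResult:
    subjects: list[str]
    per_subject_ba: list[float]  # NaN where a fold's BA is undefined
    mean_ba: float
    rules: list[DecisionRule]


def lopo_evaluate(
    table: pd.DataFrame,
    labels: np.ndarray,
    max_depth: int = 1,
    n_iterations: int = 10,
    seed: int = 0,
    sample_fraction: float = 0.85,
) -> CvResult:
    """Leave-one-patient-out cross-validation of the balanced tree.

    For each subject, a tree is trained on all other subjects and scored
    on the held-out subject's pixels. Folds whose held-out pixels contain
    a single class are reported as NaN and excluded from the mean.
    """
    labels = np.asarray(labels, dtype=bool)
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("leave-one-patient-out needs >= 3 subjects")
    rng = np.random.default_rng(seed)
    bas, rules = [], []
    for s in subjects:
        held = table["subject_id"] == s
        rule = train_balanced_tree(
            table[~held].reset_index(drop=True), labels[~held.to_numpy()],
            max_depth=max_depth, n_iterations=n_iterations,
            seed=int(rng.integers(2**31 - 1)), sample_fraction=sample_fraction,
        )
        y_h = labels[held.to_numpy()]
        if y_h.all() or not y_h.any():
            log.info("lopo_evaluate: fold %s has a single class; BA undefined", s)
            bas.append(float("nan"))
        else:
            _, _, ba = classification_metrics(
                rule.predict(table[held]), y_h
            )
            bas.append(ba)
        rules.append(rule)
    finite = [b for b in bas if np.isfinite(b)]
    return CvResult(subjects, bas, float(np.mean(finite)) if finite else float("nan"),
                    rules)
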