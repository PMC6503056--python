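"""Multiparametric phenotype classification: resting / NETotic / apoptotic.

A regularized linear discriminant (logistic regression as an alternative)
on standardized features assigns each cell its phenotype; a *lytic gate*
then enforces the rule that a cell counts as NETotic only when lytic NET
formation is morphologically plausible: the chromatin region must be large
(area above the 5th percentile of NETotic training areas) and texturally
homogeneous (Haralick contrast below the 95th percentile of the NETotic
training class — decondensed chromatin is diffuse, not granular). A cell
scored NETotic but failing the gate is relabeled to its runner-up class
and flagged "NET-like but non-lytic".

Training labels come from the simulator's ground truth; with real images
they would be human-curated — the substitution is intentional and is the
only difference in the training protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from nethcs import plate_io
from nethcs.plate_io import PlateLayout
from nethcs.synthetic_imaging import PHENOTYPES

GATE_AREA_PERCENTILE = 5.0       # area_min = this pct of netotic training areas
GATE_CONTRAST_PERCENTILE = 95.0  # contrast_max = this pct of netotic contrast


@dataclass
class ClassifierModel:
    """Serializable linear phenotype classifier with the lytic gate."""

    feature_names: list[str]
    classes: list[str]
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    coef: np.ndarray              # (n_classes, n_features) on standardized X
    intercept: np.ndarray         # (n_classes,)
    priors: np.ndarray
    kind: str = "lda"
    gate_area_min_um2: float = 0.0
    gate_contrast_max: float = float("inf")
    cv_accuracy: float = float("nan")
    cv_seed: int = 0

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.standardize_mean) / self.standardize_sd
        return Z @ self.coef.T + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "classes": self.classes,
            "standardize_mean": self.standardize_mean,
            "standardize_sd": self.standardize_sd,
            "coef": self.coef,
            "intercept": self.intercept,
            "priors": self.priors,
            "gate_area_min_um2": self.gate_area_min_um2,
            "gate_contrast_max": self.gate_contrast_max,
            "cv_accuracy": self.cv_accuracy,
            "cv_seed": self.cv_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassifierModel":
        return cls(
            feature_names=list(d["feature_names"]),
            classes=list(d["classes"]),
            standardize_mean=np.asarray(d["standardize_mean"], dtype=float),
            standardize_sd=np.asarray(d["standardize_sd"], dtype=float),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            kind=str(d["kind"]),
            gate_area_min_um2=float(d["gate_area_min_um2"]),
            gate_contrast_max=float(d["gate_contrast_max"]),
            cv_accuracy=float(d["cv_accuracy"]),
            cv_seed=int(d["cv_seed"]),
        )

    def save(self, path: str | Path) -> None:
        plate_io.save_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        return cls.from_dict(plate_io.load_json(path))


def _as_matrix(cells: pd.DataFrame | Sequence[Mapping], feature_names: Sequence[str]):
    if isinstance(cells, pd.DataFrame):
        missing = [f for f in feature_names if f not in cells.columns]
        if missing:
            raise KeyError(f"cells are missing model features: {missing}")
        return cells[list(feature_names)].to_numpy(dtype=float)
    rows = list(cells)
    for f in feature_names:
        if any(f not in r for r in rows):
            raise KeyError(f"cells are missing model feature {f!r}")
    return np.array([[r[f] for f in feature_names] for r in rows], dtype=float)


def train(
    cells: pd.DataFrame,
    kind: str = "lda",
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    label_column: str = "label",
    cv_folds: int = 5,
) -> ClassifierModel:
    """Fit the phenotype classifier on labeled per-cell features.

    Requires at least 2 classes with >= 10 examples each. Zero-variance
    features are dropped with a warning; stratified ``cv_folds``-fold
    cross-validated accuracy (seeded fold assignment) is recorded on the
    model. The lytic gate is derived from the NETotic training class.
    """
    import warnings

    if label_column not in cells.columns:
        raise ValueError(f"no {label_column!r} column in training cells")
    labels = cells[label_column].to_numpy()
    class_names, counts = np.unique(labels, return_counts=True)
    if len(class_names) < 2:
        raise ValueError("training requires at least 2 classes")
    if counts.min() < 10:
        lacking = class_names[counts < 10]
        raise ValueError(f"need >= 10 examples per class; short: {list(lacking)}")

    if feature_names is None:
        from nethcs.features import feature_names as default_names

        feature_names = [f for f in default_names() if f in cells.columns]
    X = _as_matrix(cells, feature_names)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(feature_names, keep) if not k]
        warnings.warn(f"dropping zero-variance features: {dropped}")
        feature_names = [f for f, k in zip(feature_names, keep) if k]
        X, mean, sd = X[:, keep], mean[keep], sd[keep]
    if X.shape[1] == 0:
        raise ValueError("all features are zero-variance")
    Z = (X - mean) / sd

    if kind == "lda":
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    elif kind == "logistic":
        clf = LogisticRegression(max_iter=2000, C=1.0)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")

    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    cv_acc = float(np.mean(cross_val_score(clf, Z, labels, cv=cv)))
    clf.fit(Z, labels)

    coef = np.asarray(clf.coef_, dtype=float)
    intercept = np.asarray(clf.intercept_, dtype=float)
    classes = [str(c) for c in clf.classes_]
    if coef.shape[0] == 1 and len(classes) == 2:  # binary: expand to 2 rows
        coef = np.vstack([-coef[0], coef[0]])
        intercept = np.array([-intercept[0], intercept[0]])
    priors = counts / counts.sum()

    gate_area, gate_contrast = 0.0, float("inf")
    if "netotic" in classes:
        net = cells[labels == "netotic"]
        if "area_um2" in net.columns:
            gate_area = float(np.percentile(net["area_um2"], GATE_AREA_PERCENTILE))
        if "haralick_contrast" in net.columns:
            gate_contrast = float(
                np.percentile(net["haralick_contrast"], GATE_CONTRAST_PERCENTILE))

    return ClassifierModel(
        feature_names=list(feature_names), classes=classes,
        standardize_mean=mean, standardize_sd=sd,
        coef=coef, intercept=intercept, priors=priors, kind=kind,
        gate_area_min_um2=gate_area, gate_contrast_max=gate_contrast,
        cv_accuracy=cv_acc, cv_seed=seed,
    )


def classify(model: ClassifierModel, cells: pd.DataFrame | Sequence[Mapping]) -> pd.DataFrame:
    """Assign phenotype labels with class scores and the lytic gate.

    Returns a DataFrame with ``label``, one score column per class, and
    ``net_like_nonlytic`` (True where the discriminant preferred NETotic
    but the lytic gate relabeled the cell to its runner-up class).
    Deterministic: a pure function of (model, features).
    """
    X = _as_matrix(cells, model.feature_names)
    scores = model.decision_scores(X)
    order = np.argsort(-scores, axis=1)
    labels = np.array(model.classes)[order[:, 0]]
    flags = np.zeros(len(labels), dtype=bool)

    if "netotic" in model.classes:
        if isinstance(cells, pd.DataFrame):
            areas = cells["area_um2"].to_numpy(dtype=float) if "area_um2" in cells.columns else None
            contrasts = (cells["haralick_contrast"].to_numpy(dtype=float)
                         if "haralick_contrast" in cells.columns else None)
        else:
            rows = list(cells)
            areas = np.array([r.get("area_um2", np.nan) for r in rows], dtype=float)
            contrasts = np.array([r.get("haralick_contrast", np.nan) for r in rows], dtype=float)
        is_net = labels == "netotic"
        fail = np.zeros(len(labels), dtype=bool)
        if areas is not None:
            fail |= areas < model.gate_area_min_um2
        if contrasts is not None:
            fail |= contrasts > model.gate_contrast_max
        gate_out = is_net & fail
        runner = np.array(model.classes)[order[:, 1]]
        labels = np.where(gate_out, runner, labels)
        flags = gate_out

    out = pd.DataFrame({"label": labels, "net_like_nonlytic": flags})
    for j, c in enumerate(model.classes):
        out[f"score_{c}"] = scores[:, j]
    return out


@dataclass
class WellSummary:
    """Per-well cell counts and phenotype fractions; pct_netotic is the
    assay's primary readout."""

    well_id: str
    n_cells: int
    n_excluded: int
    frac_resting: float
    frac_netotic: float
    frac_apoptotic: float

    @property
    def pct_netotic(self) -> float:
        return 100.0 * self.frac_netotic

    def to_dict(self) -> dict:
        return {
            "well_id": self.well_id, "n_cells": self.n_cells,
            "n_excluded": self.n_excluded,
            "frac_resting": self.frac_resting,
            "frac_netotic": self.frac_netotic,
            "frac_apoptotic": self.frac_apoptotic,
            "pct_netotic": self.pct_netotic,
        }


def summarize_well(
    cells: pd.DataFrame,
    layout: PlateLayout | None = None,
    label_column: str = "label",
    exclude_border: bool = True,
    exclude_gated: bool = True,
) -> list[WellSummary]:
    """Aggregate per-cell labels into per-well phenotype fractions.

    ``cells`` must carry ``well_id`` and the label column. Cells flagged
    ``touches_border`` (partial objects) and, when ``exclude_gated``,
    cells flagged ``net_like_nonlytic`` (NET-like but not clearly lytic —
    ambiguous by construction) are excluded from the denominator and
    counted in ``n_excluded``. Fractions sum to 1 for every well with at
    least one counted cell.
    """
    if "well_id" not in cells.columns or label_column not in cells.columns:
        raise ValueError("cells need well_id and label columns")
    if layout is not None:
        known = set(layout.well_ids)
        unknown = set(cells["well_id"].unique()) - known
        if unknown:
            raise KeyError(f"cells reference wells not in layout: {sorted(unknown)}")
    out = []
    for well_id, grp in cells.groupby("well_id", sort=True):
        n_total = len(grp)
        counted = grp
        if exclude_border and "touches_border" in counted.columns:
            counted = counted[~counted["touches_border"].astype(bool)]
        if exclude_gated and "net_like_nonlytic" in counted.columns:
            counted = counted[~counted["net_like_nonlytic"].astype(bool)]
        n = len(counted)
        fracs = {p: 0.0 for p in PHENOTYPES}
        if n:
            vc = counted[label_column].value_counts()
            for p in PHENOTYPES:
                fracs[p] = float(vc.get(p, 0)) / n
        out.append(WellSummary(
            well_id=str(well_id), n_cells=n, n_excluded=n_total - n,
            frac_resting=fracs["resting"], frac_netotic=fracs["netotic"],
            frac_apoptotic=fracs["apoptotic"],
        ))
    return out


# ---------------------------------------------------------------------------
# Pipeline helpers: simulator -> segmentation -> features -> labels


def build_training_set(
    n_per_class: int = 300,
    seed: int = 0,
    config=None,
    seg_params=None,
    feat_params=None,
) -> pd.DataFrame:
    """Segment single-phenotype simulated fields and label each matched
    object with the simulator's ground truth.

    Objects are matched to truth masks (Jaccard >= 0.5); unmatched
    segmentations are discarded, so training features come from the same
    segmentation pipeline later used at screening time.
    """
    from nethcs.features import DEFAULT_FEATURES, extract_features
    from nethcs.segmentation import DEFAULT_SEGMENTATION, match_to_truth, segment_nuclei
    from nethcs.synthetic_imaging import DEFAULT_CONFIG, simulate_field

    config = config or DEFAULT_CONFIG
    seg_params = seg_params or DEFAULT_SEGMENTATION
    feat_params = feat_params or DEFAULT_FEATURES
    frames = []
    for ci, phenotype in enumerate(PHENOTYPES):
        fractions = tuple(1.0 if p == phenotype else 0.0 for p in PHENOTYPES)
        rng = np.random.default_rng([seed, ci])
        collected = 0
        field_i = 0
        while collected < n_per_class and field_i < 50:
            img, truth = simulate_field(
                config.cells_per_field, fractions, rng, config,
                well_id=f"T{ci}", field_index=field_i,
            )
            lo = segment_nuclei(img, seg_params)
            match = match_to_truth(lo, truth)
            matched_ids = {pid for pid, _, _ in match.pairs}
            keep = [o for o in lo.objects if o.id in matched_ids]
            rows = extract_features(img, type(lo)(lo.label_image, keep), feat_params)
            df = pd.DataFrame(rows)
            df["label"] = phenotype
            frames.append(df.iloc[: n_per_class - collected])
            collected += len(df)
            field_i += 1
    return pd.concat(frames, ignore_index=True)


def process_fields(
    fields,
    model: ClassifierModel,
    seg_params=None,
    feat_params=None,
) -> pd.DataFrame:
    """Segment, featurize and classify every field; returns per-cell rows."""
    from nethcs.features import DEFAULT_FEATURES, extract_features
    from nethcs.segmentation import DEFAULT_SEGMENTATION, segment_nuclei

    seg_params = seg_params or DEFAULT_SEGMENTATION
    feat_params = feat_params or DEFAULT_FEATURES
    frames = []
    for img in fields:
        lo = segment_nuclei(img, seg_params)
        if not lo.objects:
            continue
        df = pd.DataFrame(extract_features(img, lo, feat_params))
        df["touches_border"] = [o.touches_border for o in lo.objects]
        pred = classify(model, df)
        df = pd.concat([df, pred], axis=1)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["well_id", "field_index", "object_id", "label"])
    return pd.concat(frames, ignore_index=True)
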