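"""Morphometric outputs and segmentation evaluation.

Morphometrics follow the conventions of the clinical quantities they feed:
the nuclear-to-cytoplasmic ratio (NCR) is total nuclear area divided by the
*remaining* area of the active field of view, and the mean nuclear diameter
is derived from the mean area as the equivalent-disk diameter
``2 * sqrt(mean_area / pi)``.

Evaluation against a gold-standard mask uses an any-pixel object rule: a
gold object counts as detected (object TP) if at least one of its pixels is
covered by any predicted object; a predicted object overlapping no gold
object is an object FP. Pixel counts are plain set intersections and
differences of the object pixel sets, and pixel TNs are the active-FOV area
minus TP, FP and FN pixels. The F-measure is the harmonic mean of
pixel-based sensitivity and pixel-based specificity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import TrainedClassifier, extract_features, \
    filter_objects, train_classifier
from .config import (ClassifierConfig, FilterPolicy, GrowthPolicy,
                     ImageModelConfig, SCMParameters)
from .errors import DataError, DegenerateInputError, ShapeMismatchError
from .pipeline import normalize_fov, segment
from .synthetic import generate_frame

__all__ = [
    "MorphometricsReport",
    "EvaluationReport",
    "compute_ncr",
    "morphometrics",
    "evaluate",
    "f_measure",
    "sensitivity_map",
    "train_on_synthetic_frames",
    "contrast_sweep",
    "aggregate_sweep",
]


@dataclass(frozen=True)
class MorphometricsReport:
    """Nuclear morphometrics of one segmented frame (physical units)."""

    n_objects: int
    ncr: float
    mean_area: float
    area_std: float
    mean_diameter: float
    pixel_scale: float

    def to_dict(self) -> dict:
        return {
            "n_objects": self.n_objects,
            "ncr": self.ncr,
            "mean_area": self.mean_area,
            "area_std": self.area_std,
            "mean_diameter": self.mean_diameter,
            "pixel_scale": self.pixel_scale,
        }


@dataclass(frozen=True)
class EvaluationReport:
    """Object- and pixel-level confusion counts and derived rates."""

    object_tp: int
    object_fn: int
    object_fp: int
    pixel_tp: int
    pixel_fp: int
    pixel_fn: int
    pixel_tn: int
    object_sensitivity: float
    pixel_sensitivity: float
    pixel_specificity: float
    f_measure: float

    def to_dict(self) -> dict:
        return {
            "object_tp": self.object_tp,
            "object_fn": self.object_fn,
            "object_fp": self.object_fp,
            "pixel_tp": self.pixel_tp,
            "pixel_fp": self.pixel_fp,
            "pixel_fn": self.pixel_fn,
            "pixel_tn": self.pixel_tn,
            "object_sensitivity": self.object_sensitivity,
            "pixel_sensitivity": self.pixel_sensitivity,
            "pixel_specificity": self.pixel_specificity,
            "f_measure": self.f_measure,
        }


def compute_ncr(mask: np.ndarray, fov_area: int) -> float:
    """Nuclear-to-cytoplasmic ratio: A / (fov_area - A).

    ``A`` is the total object pixel count of the mask. Raises if the
    objects fill the entire FOV (the ratio is then undefined).
    """
    mask = np.asarray(mask)
    area = int((mask > 0).sum())
    if area > fov_area:
        raise DataError(
            f"object area {area} exceeds FOV area {fov_area}"
        )
    if area == fov_area:
        raise DegenerateInputError(
            "objects fill the whole FOV; NCR is undefined"
        )
    return float(area) / float(fov_area - area)


def morphometrics(mask: np.ndarray,
                  pixel_scale: float = 0.75) -> MorphometricsReport:
    """Per-frame nuclear morphometrics in physical units.

    Object areas in px² are converted to µm² with ``pixel_scale²``; the
    mean diameter is that of a disk with the mean area. An empty mask
    yields a zero-count report with all statistics zero.
    """
    if pixel_scale <= 0:
        raise DataError(f"pixel_scale must be positive, got {pixel_scale}")
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return MorphometricsReport(0, 0.0, 0.0, 0.0, 0.0, pixel_scale)
    areas_px = np.bincount(mask.ravel())[labels]
    areas_um2 = areas_px.astype(np.float64) * pixel_scale**2
    mean_area = float(areas_um2.mean())
    total_px = int(areas_px.sum())
    ncr = float(total_px) / float(mask.size - total_px) \
        if total_px < mask.size else np.inf
    return MorphometricsReport(
        n_objects=int(labels.size),
        ncr=ncr,
        mean_area=mean_area,
        area_std=float(areas_um2.std()),
        mean_diameter=float(2.0 * np.sqrt(mean_area / np.pi)),
        pixel_scale=pixel_scale,
    )


def f_measure(sensitivity: float, specificity: float) -> float:
    """Harmonic mean of pixel sensitivity and pixel specificity."""
    if sensitivity == 0.0 and specificity == 0.0:
        raise DegenerateInputError("F-measure undefined at (0, 0)")
    return 2.0 * sensitivity * specificity / (sensitivity + specificity)


def evaluate(pred: np.ndarray, gold: np.ndarray,
             fov_area: int) -> EvaluationReport:
    """Score a predicted label mask against a gold-standard label mask.

    A gold object is a TP if any of its pixels is covered by any predicted
    object (no one-to-one matching: one predicted object overlapping two
    gold objects credits both, and is itself not an FP). Pixel FPs are all
    predicted-object pixels outside every gold object, including those of
    object-level-TP predictions. Pixel TNs are ``fov_area`` minus TP, FP
    and FN pixels.
    """
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ShapeMismatchError(
            f"pred shape {pred.shape} != gold shape {gold.shape}"
        )
    pred_any = pred > 0
    gold_any = gold > 0

    gold_labels = np.unique(gold[gold_any])
    covered = np.unique(gold[gold_any & pred_any])
    object_tp = int(covered.size)
    object_fn = int(gold_labels.size - covered.size)

    pred_labels = np.unique(pred[pred_any])
    overlapping = np.unique(pred[pred_any & gold_any])
    object_fp = int(pred_labels.size - overlapping.size)

    pixel_tp = int((pred_any & gold_any).sum())
    pixel_fp = int((pred_any & ~gold_any).sum())
    pixel_fn = int((gold_any & ~pred_any).sum())
    pixel_tn = int(fov_area) - pixel_tp - pixel_fp - pixel_fn
    if pixel_tn < 0:
        raise DataError(
            "fov_area smaller than the union of mask extents"
        )

    obj_sens = object_tp / gold_labels.size if gold_labels.size else 0.0
    denom_sens = pixel_tp + pixel_fn
    px_sens = pixel_tp / denom_sens if denom_sens else 0.0
    denom_spec = pixel_tn + pixel_fp
    px_spec = pixel_tn / denom_spec if denom_spec else 0.0
    f1 = f_measure(px_sens, px_spec) if (px_sens or px_spec) else 0.0
    return EvaluationReport(
        object_tp=object_tp,
        object_fn=object_fn,
        object_fp=object_fp,
        pixel_tp=pixel_tp,
        pixel_fp=pixel_fp,
        pixel_fn=pixel_fn,
        pixel_tn=pixel_tn,
        object_sensitivity=float(obj_sens),
        pixel_sensitivity=float(px_sens),
        pixel_specificity=float(px_spec),
        f_measure=float(f1),
    )


def sensitivity_map(pred: np.ndarray, gold: np.ndarray,
                    source: np.ndarray | None = None) -> np.ndarray:
    """RGB overlay of the pixel confusion classes.

    Green: true-positive pixels (in both masks); blue: false negatives
    (gold only); red: false positives (predicted only). Remaining pixels
    show the grayscale ``source`` if given, else black. Returns uint8
    (H, W, 3).
    """
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ShapeMismatchError(
            f"pred shape {pred.shape} != gold shape {gold.shape}"
        )
    pred_any = pred > 0
    gold_any = gold > 0
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    if source is not None:
        source = np.asarray(source, dtype=np.float64)
        if source.shape != pred.shape:
            raise ShapeMismatchError("source shape differs from masks")
        gray = np.clip(source, 0.0, 1.0)
        out[:] = (gray[..., None] * 255).astype(np.uint8)
    out[pred_any & gold_any] = (0, 255, 0)
    out[gold_any & ~pred_any] = (0, 0, 255)
    out[pred_any & ~gold_any] = (255, 0, 0)
    return out


def _pipeline_kwargs(scm=None, filter_policy=None, growth_policy=None,
                     otsu_scale=0.5):
    return dict(
        params=scm or SCMParameters(),
        filter_policy=filter_policy or FilterPolicy(),
        growth_policy=growth_policy or GrowthPolicy(),
        otsu_scale=otsu_scale,
    )


def train_on_synthetic_frames(
    train_levels: Sequence[float],
    seed: int,
    base_config: ImageModelConfig | None = None,
    scm: SCMParameters | None = None,
    filter_policy: FilterPolicy | None = None,
    growth_policy: GrowthPolicy | None = None,
    classifier_config: ClassifierConfig | None = None,
    otsu_scale: float = 0.5,
    n_noise_frames: int = 1,
) -> TrainedClassifier:
    """Train the object classifier on separately generated synthetic frames.

    One frame is generated per level in ``train_levels`` (seeds derived
    from ``seed``), segmented with the pipeline, and its objects labeled by
    any-pixel overlap with the ground truth: overlapping objects are
    positives (true nuclei), the rest negatives. ``n_noise_frames``
    additional nucleus-free frames contribute pure-noise detections as
    further negative examples, teaching the network what spurious objects
    look like in signal-free fields. The pooled objects train the
    classifier. This stands in for a manually segmented object database.
    """
    base = base_config or ImageModelConfig()
    rng = np.random.default_rng(seed)
    kw = _pipeline_kwargs(scm, filter_policy, growth_policy, otsu_scale)
    feats, labels = [], []
    all_levels = list(train_levels) + [None] * n_noise_frames
    for level in all_levels:
        frame_seed = int(rng.integers(0, 2**31 - 1))
        cfg = ImageModelConfig(
            frame_size=base.frame_size,
            n_objects=base.n_objects if level is not None else 0,
            object_area=base.object_area,
            contrast=float(level) if level is not None else 2.0,
            background_mean=base.background_mean,
            background_variance=base.background_variance,
            peak_jitter=base.peak_jitter,
            pixel_scale=base.pixel_scale,
            seed=frame_seed,
        )
        frame, gt = generate_frame(cfg)
        mask, fov = segment(frame, **kw)
        norm = normalize_fov(frame, fov.mask)
        f = extract_features(mask, norm)
        if f.shape[0] == 0:
            continue
        present = np.unique(mask)
        present = present[present > 0]
        overlapping = np.unique(mask[(mask > 0) & (gt.label_mask > 0)])
        y = np.isin(present, overlapping)
        feats.append(f)
        labels.append(y)
    if not feats:
        raise DataError("no objects segmented on the training frames")
    X = np.vstack(feats)
    y = np.concatenate(labels)
    clf_seed = int(rng.integers(0, 2**31 - 1))
    return train_classifier(X, y, seed=clf_seed, config=classifier_config)


def contrast_sweep(
    levels: Sequence[float],
    replicates: int = 3,
    seed: int = 0,
    classifier: TrainedClassifier | None = None,
    base_config: ImageModelConfig | None = None,
    scm: SCMParameters | None = None,
    filter_policy: FilterPolicy | None = None,
    growth_policy: GrowthPolicy | None = None,
    otsu_scale: float = 0.5,
) -> pd.DataFrame:
    """Full evaluation of the pipeline across a contrast sweep.

    For every contrast level, ``replicates`` frames are generated with
    seeds ``seed, seed+1, ...``, pushed through segmentation and the
    object classifier, and scored against their ground truth. If no
    trained ``classifier`` is passed, one is first trained on a disjoint
    set of synthetic frames (one per level, seeds derived from
    ``seed + 10000``).

    Returns a tidy frame with one row per (contrast, replicate) holding
    the evaluation metrics and morphometrics, ordered by contrast.
    """
    if not len(levels):
        raise DataError("levels must be nonempty")
    if replicates < 1:
        raise DataError("replicates must be >= 1")
    base = base_config or ImageModelConfig()
    kw = _pipeline_kwargs(scm, filter_policy, growth_policy, otsu_scale)
    if classifier is None:
        classifier = train_on_synthetic_frames(
            sorted(levels), seed=seed + 10000, base_config=base,
            scm=scm, filter_policy=filter_policy,
            growth_policy=growth_policy, otsu_scale=otsu_scale,
        )
    rows = []
    for level in sorted(levels):
        for rep in range(replicates):
            cfg = ImageModelConfig(
                frame_size=base.frame_size,
                n_objects=base.n_objects,
                object_area=base.object_area,
                contrast=float(level),
                background_mean=base.background_mean,
                background_variance=base.background_variance,
                peak_jitter=base.peak_jitter,
                pixel_scale=base.pixel_scale,
                seed=seed + rep,
            )
            frame, gt = generate_frame(cfg)
            mask, fov = segment(frame, **kw)
            norm = normalize_fov(frame, fov.mask)
            final = filter_objects(classifier, mask, norm)
            report = evaluate(final, gt.label_mask, fov.area)
            morpho = morphometrics(final, base.pixel_scale)
            ncr = compute_ncr(final, fov.area)
            rows.append({
                "contrast": float(level),
                "replicate": rep,
                "seed": seed + rep,
                "object_sens": report.object_sensitivity,
                "pixel_sens": report.pixel_sensitivity,
                "pixel_spec": report.pixel_specificity,
                "f_measure": report.f_measure,
                "n_objects": morpho.n_objects,
                "ncr": ncr,
            })
    return pd.DataFrame(rows)


def aggregate_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of the sweep metrics per contrast level."""
    metrics = ["object_sens", "pixel_sens", "pixel_spec", "f_measure",
               "n_objects", "ncr"]
    grouped = sweep.groupby("contrast")[metrics]
    mean = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=0).add_suffix("_sd")
    return mean.join(sd).reset_index().sort_values("contrast",
                                                   ignore_index=True)
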