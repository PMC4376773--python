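"""End-to-end nuclei segmentation pipeline.

Stages, in order:

1. **Background removal** — an Otsu threshold scaled down by a configurable
   factor flags candidate dark pixels; only large contiguous candidate
   regions touching the frame border are removed (the non-tissue part of
   the field of view). The complement is the *active FOV*, whose area is
   the denominator basis for the nuclear-to-cytoplasmic ratio and for
   pixel specificity.
2. **Normalization** — min-max over the active FOV to [0, 1].
3. **SCM filtering** — the spiking cortical model is run and its first six
   pulse outputs analysed; large objects pulsing early are darkened and
   small round objects pulsing late are brightened with gamma corrections.
   Repeated for a configurable number of passes.
4. **Time matrix and mask growth** — a final time matrix is computed; its
   regional minima (the brightest coherent cores) seed objects that are
   grown by annexing adjacent pixels of successively later pulse
   iterations, each object stopping before an annexation would push it
   past the area or eccentricity limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import local_minima

from ._regions import label_areas, label_eccentricities
from .config import FilterPolicy, GrowthPolicy, SCMParameters
from .errors import DataError, ScmsegError
from .scm import compute_time_matrix, iter_pulse_outputs

__all__ = [
    "ActiveFOV",
    "remove_background",
    "normalize_fov",
    "scm_filter_pass",
    "build_segmentation_mask",
    "segment",
]

#: Fraction of the frame a candidate-background component must exceed to be
#: treated as true background rather than a dark feature inside tissue.
_BACKGROUND_MIN_FRACTION = 0.05

#: Cap on flood sub-steps when annexing one time-matrix level. An object at
#: the default area limit spans ~11 px in radius, so growth that a limit
#: would permit always completes within this many dilations.
_MAX_SUBSTEPS = 16

#: Below this area the moment-matched ellipse is degenerate (2-3 collinear
#: pixels already read as eccentricity 1), so the eccentricity limit is not
#: enforced for smaller objects.
_ECC_MIN_AREA = 8


@dataclass(frozen=True)
class ActiveFOV:
    """Tissue-occupied portion of the frame after background removal."""

    mask: np.ndarray
    area: int


def remove_background(image: np.ndarray, scale: float = 0.5) -> ActiveFOV:
    """Split the frame into active FOV and (removed) dark background.

    The Otsu threshold of the intensity histogram is scaled by ``scale``;
    pixels below the scaled threshold are background *candidates*. Assuming
    true background is a large contiguous dark area at the frame edge, only
    candidate components covering more than 5% of the frame and touching
    the border are removed. Isolated dark pixels inside tissue stay in the
    FOV.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise DataError("empty image")
    if not 0.0 < scale <= 1.0:
        raise DataError(f"scale must be in (0, 1], got {scale}")
    if image.min() == image.max():
        warnings.warn(
            "constant image: histogram is degenerate, keeping full frame "
            "as active FOV",
            stacklevel=2,
        )
        mask = np.ones(image.shape, dtype=bool)
        return ActiveFOV(mask=mask, area=int(mask.sum()))

    threshold = scale * threshold_otsu(image)
    candidates = image < threshold
    # Keep only *solid* dark areas: a small opening breaks the speckle
    # chains that dark noise forms inside tissue, which could otherwise
    # percolate into one giant "contiguous" candidate region.
    candidates = ndi.binary_opening(candidates,
                                    structure=np.ones((3, 3), dtype=bool),
                                    iterations=2)
    comp, n_comp = cc_label(candidates, connectivity=2, return_num=True)
    mask = np.ones(image.shape, dtype=bool)
    if n_comp:
        areas = np.bincount(comp.ravel(), minlength=n_comp + 1)
        border = np.zeros(n_comp + 1, dtype=bool)
        for edge in (comp[0], comp[-1], comp[:, 0], comp[:, -1]):
            border[np.unique(edge)] = True
        border[0] = False
        big = areas > _BACKGROUND_MIN_FRACTION * image.size
        remove = big & border
        if remove.any():
            mask &= ~remove[comp]
    return ActiveFOV(mask=mask, area=int(mask.sum()))


def normalize_fov(image: np.ndarray, fov_mask: np.ndarray) -> np.ndarray:
    """Min-max normalize intensities over the active FOV to [0, 1].

    Pixels outside the FOV are set to 0 (stimulus-free: their neurons never
    fire and end up at the time-matrix sentinel).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != fov_mask.shape:
        raise DataError("image and FOV mask shapes differ")
    out = np.zeros_like(image)
    vals = image[fov_mask]
    if vals.size == 0:
        return out
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        return out
    out[fov_mask] = (image[fov_mask] - lo) / (hi - lo)
    return out


def scm_filter_pass(image: np.ndarray, params: SCMParameters,
                    policy: FilterPolicy) -> np.ndarray:
    """One SCM-guided gamma-correction pass over a normalized image.

    The network's first six pulse outputs are segmented into connected
    objects. Pixels of early-iteration objects larger than
    ``large_area_threshold`` are darkened (``x ** gamma_darken``); pixels
    of late-iteration objects with area inside ``small_area_range`` and
    eccentricity at most ``eccentricity_limit`` are brightened
    (``x ** gamma_brighten``). Everything else is unchanged; the output
    stays in [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    out = image.copy()
    n_analyse = max(max(policy.early_iters, default=0),
                    max(policy.late_iters, default=0))
    lo, hi = policy.small_area_range
    for it, pulse in enumerate(iter_pulse_outputs(image, params, n_analyse),
                               start=1):
        early = it in policy.early_iters
        late = it in policy.late_iters
        if not (early or late) or not pulse.any():
            continue
        comp, n_comp = cc_label(pulse, connectivity=2, return_num=True)
        if n_comp == 0:
            continue
        areas = label_areas(comp, n_comp)
        if early:
            sel = areas > policy.large_area_threshold
            sel[0] = False
            if sel.any():
                px = sel[comp]
                out[px] = image[px] ** policy.gamma_darken
        if late:
            sel = (areas >= lo) & (areas <= hi)
            sel[0] = False
            if sel.any():
                ecc = label_eccentricities(comp, n_comp)
                sel &= ecc <= policy.eccentricity_limit
                if sel.any():
                    px = sel[comp]
                    out[px] = image[px] ** policy.gamma_brighten
    return out


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Re-index nonzero labels to 1..n preserving order."""
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


def build_segmentation_mask(tm: np.ndarray,
                            policy: GrowthPolicy,
                            sentinel: int | None = None) -> np.ndarray:
    """Grow a labeled segmentation mask from the time matrix.

    Seeds are the regional minima of the time matrix (pixels at the
    sentinel — neurons that never fired — are excluded; pass the
    network's sentinel value, or leave ``None`` if every pixel fired).
    Each seed object then annexes adjacent unclaimed pixels of
    successively later pulse iterations — levels strictly after its own
    seed level; an annexation that would push the object past
    ``area_limit`` or ``eccentricity_limit`` is undone and the object
    frozen. Distinct seeds always keep distinct labels — objects never
    merge. Objects whose final area is below ``min_area`` are discarded as
    noise seeds.
    """
    tm = np.asarray(tm)
    if tm.ndim != 2:
        raise DataError("time matrix must be 2-D")
    if sentinel is None:
        valid = np.ones_like(tm, dtype=bool)
    else:
        valid = tm < sentinel
    if not valid.any():
        return np.zeros(tm.shape, dtype=np.int32)

    conn = 2 if policy.minima_connectivity == 8 else 1
    tm_f = tm.astype(np.float64)
    tm_f[~valid] = np.inf
    minima = local_minima(tm_f, connectivity=conn) & valid
    if not minima.any():
        # A constant (plateau) region has no strict minima; every valid
        # pixel of the global-minimum level then counts as a minimum.
        minima = (tm_f == tm_f[valid].min()) & valid
    if not minima.any():
        return np.zeros(tm.shape, dtype=np.int32)

    labels, n_obj = cc_label(minima, connectivity=conn, return_num=True)
    labels = labels.astype(np.int32)
    areas = label_areas(labels, n_obj).astype(np.int64)
    ecc = label_eccentricities(labels, n_obj)
    active = np.ones(n_obj + 1, dtype=bool)
    active[0] = False
    # Seeds already past a limit are kept as-is but never grown.
    active &= ~(areas > policy.area_limit)
    active &= ~((ecc > policy.eccentricity_limit)
                & (areas >= _ECC_MIN_AREA))

    footprint = np.ones((3, 3), dtype=bool) if conn == 2 else np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    # Level at which each seed pulsed: objects only annex later levels.
    seed_level = ndi.minimum(tm, labels, index=np.arange(n_obj + 1))
    seed_level = np.asarray(seed_level, dtype=np.int64)
    levels = np.unique(tm[valid])
    start = int(tm[minima].min()) + 1

    for t in levels[levels >= start]:
        if not active.any():
            break
        level_px = tm == t
        if not level_px.any():
            continue
        annexed = np.zeros(tm.shape, dtype=bool)
        overflow = np.zeros(n_obj + 1, dtype=bool)
        prev_shell = tm == t - 1
        for _ in range(_MAX_SUBSTEPS):
            growable = active & ~overflow & (seed_level < t)
            if not growable.any():
                break
            # Strictly successive growth: iteration-t pixels attach only
            # to object pixels that pulsed at t-1 (or were annexed at t),
            # so stale object boundary never collects late-firing noise.
            source = growable[labels] & (prev_shell | annexed)
            labels_active = np.where(source, labels, 0)
            neigh = ndi.grey_dilation(labels_active, footprint=footprint)
            # Solid-ring test: a pixel joins only where the advancing
            # shell is locally solid (>= 2 source pixels in its
            # 8-neighbourhood), which isolated noise rarely offers. A
            # single-pixel object cannot offer 2 and is exempt, else it
            # could never grow its first ring.
            support = ndi.correlate((labels_active > 0).astype(np.uint8),
                                    np.ones((3, 3), dtype=np.uint8),
                                    mode="constant", cval=0)
            solid = (support >= 2) | (areas[neigh] == 1)
            cand = level_px & (labels == 0) & (neigh > 0) & solid
            if not cand.any():
                break
            labels[cand] = neigh[cand]
            annexed |= cand
            areas += np.bincount(neigh[cand], minlength=n_obj + 1)
            overflow |= areas > policy.area_limit
        grew = np.zeros(n_obj + 1, dtype=bool)
        grew[np.unique(labels[annexed])] = True
        if grew.any():
            ecc = label_eccentricities(labels, n_obj)
            too_eccentric = (ecc > policy.eccentricity_limit) & (
                areas >= _ECC_MIN_AREA)
            bad = grew & (overflow | too_eccentric)
            if bad.any():
                undo = annexed & bad[labels]
                areas -= np.bincount(labels[undo], minlength=n_obj + 1)
                labels[undo] = 0
                active &= ~bad

    if policy.min_area > 0:
        small = label_areas(labels, n_obj) < policy.min_area
        small[0] = False
        if small.any():
            labels[small[labels]] = 0
    return _relabel_sequential(labels)


def segment(
    image: np.ndarray,
    params: SCMParameters | None = None,
    filter_policy: FilterPolicy | None = None,
    growth_policy: GrowthPolicy | None = None,
    otsu_scale: float = 0.5,
) -> tuple[np.ndarray, ActiveFOV]:
    """Segment nuclei in a raw grayscale frame.

    Runs background removal, FOV normalization, ``n_passes`` SCM filter
    passes, the final time matrix and mask growth, then restricts objects
    to the active FOV. Returns the label mask and the FOV. Errors raised by
    a stage are re-raised tagged with the stage name.
    """
    params = params or SCMParameters()
    filter_policy = filter_policy or FilterPolicy()
    growth_policy = growth_policy or GrowthPolicy()

    image = np.asarray(image, dtype=np.float64)

    def run(stage: str, fn, *args):
        try:
            return fn(*args)
        except ScmsegError as exc:
            raise type(exc)(f"[{stage}] {exc}") from exc

    fov = run("background_removal", remove_background, image, otsu_scale)
    norm = run("normalization", normalize_fov, image, fov.mask)
    for _ in range(filter_policy.n_passes):
        norm = run("scm_filter", scm_filter_pass, norm, params,
                   filter_policy)
    tm = run("time_matrix", compute_time_matrix, norm, params)
    labels = run("mask_growth", build_segmentation_mask, tm, growth_policy,
                 params.sentinel)
    # Objects must lie entirely within the active FOV.
    labels[~fov.mask] = 0
    labels = _relabel_sequential(labels)
    return labels, fov
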