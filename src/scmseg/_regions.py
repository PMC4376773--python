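"""Vectorized per-label region statistics.

The filter and growth stages need the area and eccentricity of every
connected object in label images that can contain tens of thousands of
small regions, many times per frame. Computing these through per-region
property objects is too slow at that scale, so the second-order central
moments are accumulated for all labels at once with ``np.bincount`` and the
eccentricity of the moment-matched ellipse is evaluated in closed form.
"""

from __future__ import annotations

import numpy as np

__all__ = ["label_areas", "label_eccentricities"]


def label_areas(labels: np.ndarray, n_labels: int | None = None) -> np.ndarray:
    """Pixel count per label; index 0 is the background count.

    ``n_labels`` is the highest label expected; defaults to ``labels.max()``.
    """
    if n_labels is None:
        n_labels = int(labels.max())
    return np.bincount(labels.ravel(), minlength=n_labels + 1)


def label_eccentricities(labels: np.ndarray,
                         n_labels: int | None = None) -> np.ndarray:
    """Eccentricity of the moment-matched ellipse for every label.

    Returns an array of length ``n_labels + 1`` (index 0, background, is 0).
    Conventions for degenerate shapes: a single pixel has eccentricity 0; a
    set of collinear pixels has eccentricity 1.

    The ellipse is matched to the normalized second central moments of the
    pixel coordinates (each pixel treated as a point mass at its centre);
    eccentricity is ``sqrt(1 - l2/l1)`` with ``l1 >= l2`` the eigenvalues
    of the covariance matrix. This matches the usual region-properties
    definition, which uses the same eigenvalue ratio.
    """
    if n_labels is None:
        n_labels = int(labels.max())
    flat = labels.ravel()
    rr, cc = np.indices(labels.shape)
    rr = rr.ravel().astype(np.float64)
    cc = cc.ravel().astype(np.float64)

    m = n_labels + 1
    cnt = np.bincount(flat, minlength=m).astype(np.float64)
    sr = np.bincount(flat, weights=rr, minlength=m)
    sc = np.bincount(flat, weights=cc, minlength=m)
    srr = np.bincount(flat, weights=rr * rr, minlength=m)
    scc = np.bincount(flat, weights=cc * cc, minlength=m)
    src = np.bincount(flat, weights=rr * cc, minlength=m)

    with np.errstate(divide="ignore", invalid="ignore"):
        mu_rr = srr / cnt - (sr / cnt) ** 2
        mu_cc = scc / cnt - (sc / cnt) ** 2
        mu_rc = src / cnt - (sr / cnt) * (sc / cnt)
    mean = 0.5 * (mu_rr + mu_cc)
    delta = np.sqrt(np.maximum(
        (0.5 * (mu_rr - mu_cc)) ** 2 + mu_rc**2, 0.0))
    l1 = mean + delta
    l2 = np.maximum(mean - delta, 0.0)

    ecc = np.zeros(m, dtype=np.float64)
    ok = l1 > 0
    ecc[ok] = np.sqrt(np.clip(1.0 - l2[ok] / l1[ok], 0.0, 1.0))
    ecc[cnt == 0] = 0.0
    ecc[0] = 0.0
    return ecc
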