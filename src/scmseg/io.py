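"""Image, mask and report I/O.

Images come in as single-channel 8- or 16-bit TIFF or PNG and are mapped to
float in [0, 1] by bit depth. Label masks travel as 16-bit TIFF (0 =
background), FOV masks as 8-bit 0/1 TIFF. Reports are written as CSV (one
row per image, fixed column order, floats at 4 decimals) or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DataError

__all__ = [
    "load_image",
    "load_label_mask",
    "write_image",
    "write_label_mask",
    "write_fov_mask",
    "write_report",
]

_TIFF_SUFFIXES = {".tif", ".tiff"}
_PNG_SUFFIXES = {".png"}

#: Fixed column order of per-image CSV reports.
REPORT_COLUMNS = (
    "image",
    "n_objects",
    "ncr",
    "mean_area",
    "area_std",
    "mean_diameter",
    "fov_area",
    "object_sensitivity",
    "pixel_sensitivity",
    "pixel_specificity",
    "f_measure",
)


def _read_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    try:
        if suffix in _TIFF_SUFFIXES:
            return tifffile.imread(path)
        if suffix in _PNG_SUFFIXES:
            return iio.imread(path)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"cannot read {path}: {exc}") from exc
    raise DataError(
        f"unsupported format '{suffix}' (expected TIFF or PNG): {path}"
    )


def load_image(path: str | Path) -> np.ndarray:
    """Load a single-channel image and normalize intensities to [0, 1].

    Integer images are divided by the maximum of their bit depth (255 for
    8-bit, 65535 for 16-bit); float images must already lie in [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    arr = _read_array(path)
    if arr.ndim != 2:
        raise DataError(
            f"expected a single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float64)
        if out.size and (out.min() < 0.0 or out.max() > 1.0):
            raise DataError(
                f"float image {path} must lie in [0, 1]"
            )
        return out
    raise DataError(f"unsupported dtype {arr.dtype} in {path}")


def load_label_mask(path: str | Path) -> np.ndarray:
    """Load a 16-bit labeled TIFF mask (0 = background)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    arr = _read_array(path)
    if arr.ndim != 2 or not np.issubdtype(arr.dtype, np.integer):
        raise DataError(f"{path} is not a 2-D integer label mask")
    return arr.astype(np.int32)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF."""
    image = np.asarray(image, dtype=np.float64)
    quantized = np.round(np.clip(image, 0.0, 1.0) * 65535.0)
    tifffile.imwrite(Path(path), quantized.astype(np.uint16))


def write_label_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a label mask as 16-bit TIFF (labels must fit in uint16)."""
    mask = np.asarray(mask)
    if mask.size and mask.max() > np.iinfo(np.uint16).max:
        raise DataError("more than 65535 labels cannot be written as "
                        "16-bit TIFF")
    if mask.size and mask.min() < 0:
        raise DataError("label masks must be nonnegative")
    tifffile.imwrite(Path(path), mask.astype(np.uint16))


def write_fov_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean FOV mask as 8-bit 0/1 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=bool)
                     .astype(np.uint8))


def _format_value(value: Any) -> Any:
    if isinstance(value, (float, np.floating)):
        return round(float(value), 4)
    if isinstance(value, (int, np.integer)):
        return int(value)
    return value


def write_report(rows: Sequence[Mapping[str, Any]] | Mapping[str, Any],
                 path: str | Path, format: str | None = None) -> None:
    """Write one or many report rows as CSV or JSON.

    ``format`` defaults to the path suffix. CSV output keeps a fixed
    column order — the known report columns first, any extra keys after,
    floats rounded to 4 decimals — and an empty batch produces a
    header-only file.
    """
    path = Path(path)
    if isinstance(rows, Mapping):
        rows = [rows]
    rows = [dict(r) for r in rows]
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        payload = [{k: _format_value(v) for k, v in r.items()}
                   for r in rows]
        if len(payload) == 1:
            path.write_text(json.dumps(payload[0], indent=2))
        else:
            path.write_text(json.dumps(payload, indent=2))
        return
    if fmt != "csv":
        raise DataError(f"unsupported report format '{fmt}'")
    keys = [c for c in REPORT_COLUMNS
            if any(c in r for r in rows)] or list(REPORT_COLUMNS)
    extra = sorted({k for r in rows for k in r} - set(keys))
    keys += extra
    lines = [",".join(keys)]
    for r in rows:
        lines.append(",".join(str(_format_value(r.get(k, "")))
                              for k in keys))
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise DataError(f"cannot write report to {path}: {exc}") from exc
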