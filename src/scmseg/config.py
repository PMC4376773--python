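"""Run configuration for the segmentation pipeline and the image model.

All tunable parameters of the method live in small frozen dataclasses that
validate their invariants on construction and round-trip losslessly through
JSON/YAML. Defaults reproduce the published network parameters where those
are stated (the SCM coefficients and coupling kernel) and otherwise document
this package's own operating point.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ConfigError

#: Default 3x3 coupling kernel of the spiking cortical model. The centre
#: entry is zero: a neuron does not feed back onto itself.
DEFAULT_W = (
    (0.0125, 0.025, 0.0125),
    (0.025, 0.0, 0.025),
    (0.0125, 0.025, 0.0125),
)

#: Contrast levels of the synthetic sweep, highest first.
DEFAULT_CONTRAST_LEVELS = (2.6, 2.4, 2.2, 2.0, 1.8, 1.6)


@dataclass(frozen=True)
class SCMParameters:
    """Coefficients of the spiking cortical model neuron update.

    Attributes
    ----------
    f : float
        Decay coefficient of the internal activity ``U``; controls how fast
        a neuron forgets past stimulation (0 < f < 1).
    g : float
        Decay coefficient of the dynamic threshold ``E``. With g > 1 the
        threshold of a silent neuron *grows* geometrically, so dimmer pixels
        fire in later iterations.
    h : float
        Threshold amplitude added when a neuron fires.
    W : tuple of tuples
        3x3 nonnegative coupling kernel; weight of each 8-neighbour's
        previous output in the activity update. Centre entry must be 0.
    max_iter : int
        Iteration cap for time-matrix construction; pixels that never fire
        within the cap receive the sentinel value ``max_iter + 1``.
    """

    f: float = 0.928
    g: float = 1.078
    h: float = 1.4
    W: tuple = DEFAULT_W
    max_iter: int = 40

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ConfigError(f"f must be in (0, 1), got {self.f}")
        if self.g <= 0.0:
            raise ConfigError(f"g must be positive, got {self.g}")
        if self.h <= 0.0:
            raise ConfigError(f"h must be positive, got {self.h}")
        if self.max_iter < 1:
            raise ConfigError(f"max_iter must be >= 1, got {self.max_iter}")
        W = np.asarray(self.W, dtype=float)
        if W.shape != (3, 3):
            raise ConfigError(f"W must be 3x3, got shape {W.shape}")
        if (W < 0).any():
            raise ConfigError("W entries must be nonnegative")
        if W[1, 1] != 0.0:
            raise ConfigError("centre entry of W must be 0")
        object.__setattr__(self, "W", tuple(tuple(row) for row in W.tolist()))

    @property
    def kernel(self) -> np.ndarray:
        """Coupling kernel as a float ndarray."""
        return np.asarray(self.W, dtype=float)

    @property
    def sentinel(self) -> int:
        """Time-matrix value assigned to pixels that never fire."""
        return self.max_iter + 1


@dataclass(frozen=True)
class FilterPolicy:
    """Policy of the time-matrix-guided gamma-correction filter.

    Only the first six pulse outputs of the network are analysed: bright
    image features pulse early, dim features late. Large objects pulsing in
    the early iterations are darkened (saturated patches); small round
    objects pulsing late are brightened (dim nuclei).
    """

    n_passes: int = 2
    early_iters: tuple = (1, 2)
    late_iters: tuple = (4, 5, 6)
    large_area_threshold: float = 1000.0
    small_area_range: tuple = (30.0, 200.0)
    eccentricity_limit: float = 0.85
    gamma_darken: float = 1.5
    gamma_brighten: float = 0.6

    def __post_init__(self) -> None:
        if self.n_passes < 0:
            raise ConfigError("n_passes must be >= 0")
        for name in ("early_iters", "late_iters"):
            its = tuple(int(i) for i in getattr(self, name))
            if any(i < 1 or i > 6 for i in its):
                raise ConfigError(f"{name} must lie within iterations 1..6")
            object.__setattr__(self, name, its)
        lo, hi = self.small_area_range
        if not 0 < lo <= hi:
            raise ConfigError("small_area_range must satisfy 0 < lo <= hi")
        object.__setattr__(self, "small_area_range", (float(lo), float(hi)))
        if self.large_area_threshold <= 0:
            raise ConfigError("large_area_threshold must be positive")
        if not 0.0 <= self.eccentricity_limit <= 1.0:
            raise ConfigError("eccentricity_limit must be in [0, 1]")
        if not self.gamma_darken > 1.0 > self.gamma_brighten > 0.0:
            raise ConfigError(
                "gammas must satisfy gamma_darken > 1 > gamma_brighten > 0"
            )


@dataclass(frozen=True)
class GrowthPolicy:
    """Policy for growing seed regions over the final time matrix.

    Seeds are the regional minima of the time matrix (the earliest-pulsing,
    i.e. brightest, cores). Each seed annexes adjacent pixels of successively
    later pulse iterations until the next annexation would push it past the
    area or eccentricity limit.
    """

    area_limit: float = 90.0
    eccentricity_limit: float = 0.9
    minima_connectivity: int = 8
    min_area: float = 10.0

    def __post_init__(self) -> None:
        if self.area_limit <= 0:
            raise ConfigError("area_limit must be positive")
        if not 0.0 <= self.eccentricity_limit <= 1.0:
            raise ConfigError("eccentricity_limit must be in [0, 1]")
        if self.minima_connectivity not in (4, 8):
            raise ConfigError("minima_connectivity must be 4 or 8")
        if self.min_area < 0:
            raise ConfigError("min_area must be >= 0")


@dataclass(frozen=True)
class ImageModelConfig:
    """Parameters of the synthetic epithelium image model.

    The model renders ``n_objects`` non-overlapping circular nuclei of
    ``object_area`` px² as truncated 2-D Gaussian intensity bumps over a
    Gaussian-white-noise background, at a prescribed nuclear-to-background
    contrast (mean nuclear intensity / mean background intensity).

    ``background_mean`` and ``background_variance`` are the background
    statistics at the reference contrast 2.0; for other contrast levels the
    nuclear signal is scaled down and the background scaled up symmetrically
    in log-ratio, emulating loss of contrast with imaging depth.
    """

    frame_size: int = 1000
    n_objects: int = 750
    object_area: float = 90.0
    contrast: float = 2.0
    background_mean: float = 0.25
    background_variance: float = 0.0025
    peak_jitter: float = 0.1
    pixel_scale: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_size < 1:
            raise ConfigError("frame_size must be >= 1")
        if self.n_objects < 0:
            raise ConfigError("n_objects must be >= 0")
        if self.object_area <= 0:
            raise ConfigError("object_area must be positive")
        if self.contrast <= 1.0:
            raise ConfigError(f"contrast must exceed 1, got {self.contrast}")
        if self.n_objects * self.object_area >= 0.5 * self.frame_size**2:
            raise ConfigError(
                "objects would cover more than half the frame; "
                "reduce n_objects or object_area"
            )
        if not 0.0 < self.background_mean < 1.0:
            raise ConfigError("background_mean must be in (0, 1)")
        if self.background_variance < 0:
            raise ConfigError("background_variance must be >= 0")
        sigma = float(np.sqrt(self.background_variance))
        if not (0.0 <= self.background_mean - 3 * sigma
                and self.background_mean + 3 * sigma <= 1.0):
            raise ConfigError(
                "background_mean +/- 3 sigma must stay within [0, 1]"
            )
        if not 0.0 <= self.peak_jitter < 1.0:
            raise ConfigError("peak_jitter must be in [0, 1)")
        if self.pixel_scale <= 0:
            raise ConfigError("pixel_scale must be positive")

    @property
    def nominal_radius(self) -> float:
        """Radius in px of a disk with area ``object_area``."""
        return float(np.sqrt(self.object_area / np.pi))


@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture and training settings of the object classifier.

    ``decision_threshold`` is the posterior probability above which an
    object is kept as a nucleus.
    """

    hidden_units: int = 10
    train_fraction: float = 0.70
    val_fraction: float = 0.15
    test_fraction: float = 0.15
    patience: int = 10
    max_epochs: int = 500
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        if min(self.train_fraction, self.val_fraction, self.test_fraction) <= 0:
            raise ConfigError("split fractions must be positive")
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError("decision_threshold must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    """Bundle of all stage configurations plus run-level settings."""

    scm: SCMParameters = field(default_factory=SCMParameters)
    filter: FilterPolicy = field(default_factory=FilterPolicy)
    growth: GrowthPolicy = field(default_factory=GrowthPolicy)
    image_model: ImageModelConfig = field(default_factory=ImageModelConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    otsu_scale: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.otsu_scale <= 1.0:
            raise ConfigError("otsu_scale must be in (0, 1]")


_SECTIONS = {
    "scm": SCMParameters,
    "filter": FilterPolicy,
    "growth": GrowthPolicy,
    "image_model": ImageModelConfig,
    "classifier": ClassifierConfig,
}


def config_to_dict(cfg: RunConfig) -> dict[str, Any]:
    """Plain-dict form of a :class:`RunConfig` (JSON/YAML serialisable)."""
    out: dict[str, Any] = {}
    for f_ in dataclasses.fields(cfg):
        value = getattr(cfg, f_.name)
        if dataclasses.is_dataclass(value):
            out[f_.name] = dataclasses.asdict(value)
        else:
            out[f_.name] = value
    return out


def config_from_dict(data: dict[str, Any]) -> RunConfig:
    """Rebuild a :class:`RunConfig` from its plain-dict form.

    Unknown keys raise :class:`ConfigError` rather than being ignored, so
    typos in config files surface immediately.
    """
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            valid = {f_.name for f_ in dataclasses.fields(cls)}
            unknown = set(value) - valid
            if unknown:
                raise ConfigError(f"unknown keys in '{key}': {sorted(unknown)}")
            try:
                kwargs[key] = cls(**value)
            except TypeError as exc:  # wrong field name type
                raise ConfigError(str(exc)) from exc
        elif key in ("otsu_scale", "seed", "log_level"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown config section '{key}'")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a run configuration to ``path`` as YAML or JSON (by suffix)."""
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    """Load a run configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)
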