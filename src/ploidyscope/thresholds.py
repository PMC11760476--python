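"""Decision constants for the ploidy classifiers.

Defaults are the published operating points of the assay: AB rate <= 5% is
haploid (the platform mis-call noise floor) and >= 18% diploid; the chrX
mean-LRR bounds are the euploid-library extrema (max over 46XY, min over
46XX); autosomal BAF in the 0.2-0.3 and 0.7-0.8 windows is compared to the
euploid cut-offs 5.89% and 4.31%. All are overridable from a YAML config,
and the LRR bounds may be set to ``"calibrate"`` to force library
calibration at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple, Union

import yaml

CALIBRATE = "calibrate"


class ThresholdsError(ValueError):
    """Raised when a thresholds configuration is internally inconsistent."""


@dataclass(frozen=True)
class ThresholdsConfig:
    ab_haploid_max: float = 0.05
    ab_diploid_min: float = 0.18
    baf_window_low: Tuple[float, float] = (0.2, 0.3)
    baf_window_high: Tuple[float, float] = (0.7, 0.8)
    baf_cut_low: float = 0.0589
    baf_cut_high: float = 0.0431
    x_lrr_one_copy_max: Union[float, str] = -1.0750221
    x_lrr_two_copy_min: Union[float, str] = -1.0396700
    y_hom_min_fraction: float = 0.80
    y_min_called: int = 10
    qc_ranges: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"call_rate": (0.90, 1.0)}
    )

    def __post_init__(self):
        if not self.ab_haploid_max < self.ab_diploid_min:
            raise ThresholdsError(
                f"ab_haploid_max ({self.ab_haploid_max}) must be below "
                f"ab_diploid_min ({self.ab_diploid_min})"
            )
        lo, hi = tuple(self.baf_window_low), tuple(self.baf_window_high)
        object.__setattr__(self, "baf_window_low", lo)
        object.__setattr__(self, "baf_window_high", hi)
        for name, (a, b) in (("baf_window_low", lo), ("baf_window_high", hi)):
            if not (0.0 <= a < b <= 1.0):
                raise ThresholdsError(f"{name} must be an interval within [0, 1]")
        if lo[1] > hi[0]:
            raise ThresholdsError("BAF windows must not overlap")
        if self.has_x_bounds and not self.x_lrr_one_copy_max < self.x_lrr_two_copy_min:
            raise ThresholdsError(
                "x_lrr_one_copy_max must be below x_lrr_two_copy_min"
            )
        if self.y_min_called < 1:
            raise ThresholdsError("y_min_called must be >= 1")
        if not 0.0 <= self.y_hom_min_fraction <= 1.0:
            raise ThresholdsError("y_hom_min_fraction must lie in [0, 1]")

    @property
    def has_x_bounds(self) -> bool:
        """True when both chrX LRR bounds are explicit numbers."""
        return not (
            self.x_lrr_one_copy_max == CALIBRATE
            or self.x_lrr_two_copy_min == CALIBRATE
        )

    def with_x_bounds(self, one_copy_max: float, two_copy_min: float) -> "ThresholdsConfig":
        return replace(
            self, x_lrr_one_copy_max=one_copy_max, x_lrr_two_copy_min=two_copy_min
        )

    def to_yaml(self, path) -> None:
        d = {
            "ab_haploid_max": self.ab_haploid_max,
            "ab_diploid_min": self.ab_diploid_min,
            "baf_window_low": list(self.baf_window_low),
            "baf_window_high": list(self.baf_window_high),
            "baf_cut_low": self.baf_cut_low,
            "baf_cut_high": self.baf_cut_high,
            "x_lrr_one_copy_max": self.x_lrr_one_copy_max,
            "x_lrr_two_copy_min": self.x_lrr_two_copy_min,
            "y_hom_min_fraction": self.y_hom_min_fraction,
            "y_min_called": self.y_min_called,
            "qc_ranges": {k: list(v) for k, v in self.qc_ranges.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def thresholds_from_dict(d: Mapping) -> ThresholdsConfig:
    """Build a config from a (possibly partial) mapping; absent keys default."""
    d = dict(d or {})
    known = set(ThresholdsConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ThresholdsError(f"unknown threshold keys: {sorted(unknown)}")
    for key in ("baf_window_low", "baf_window_high"):
        if key in d:
            d[key] = tuple(d[key])
    if "qc_ranges" in d:
        d["qc_ranges"] = {k: tuple(v) for k, v in d["qc_ranges"].items()}
    return ThresholdsConfig(**d)


def load_thresholds(path) -> ThresholdsConfig:
    """Load a thresholds YAML file; an empty file yields all defaults."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if d is None:
        d = {}
    if not isinstance(d, Mapping):
        raise ThresholdsError(f"thresholds config {path} is not a mapping")
    return thresholds_from_dict(d)
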