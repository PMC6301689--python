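"""Run configuration shared by the scoring pipeline and the CLI."""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the scoring pipeline.

    The two HU thresholds default to the clinical conventions (detection at
    130 HU, candidate extension above 90 HU) but are configurable, e.g. for
    analyses with lowered detection thresholds. ``xmin_mode`` selects what
    counts as the minimum lesion intensity when scaling per-voxel calcium
    fractions: the minimum over the supra-threshold lesion voxels (default),
    the minimum over the whole calcification mask, or the mixture-derived
    threshold itself.
    """

    detection_threshold_hu: float = 130.0
    extension_threshold_hu: float = 90.0
    min_lesion_voxels: int = 1
    em_tol: float = 1e-6
    em_max_iter: int = 200
    em_sigma_floor_hu: float = 0.5
    xmin_mode: str = "supra_threshold"
    seed: int = 0
    verbosity: int = 0

    _XMIN_MODES = ("supra_threshold", "literal_lesion_min", "threshold")

    def __post_init__(self) -> None:
        if not (math.isfinite(self.detection_threshold_hu) and math.isfinite(self.extension_threshold_hu)):
            raise ValueError("thresholds must be finite")
        if self.extension_threshold_hu >= self.detection_threshold_hu:
            raise ValueError(
                f"extension threshold ({self.extension_threshold_hu} HU) must be "
                f"below the detection threshold ({self.detection_threshold_hu} HU)"
            )
        if self.min_lesion_voxels < 1:
            raise ValueError("min_lesion_voxels must be >= 1")
        if self.em_tol <= 0 or self.em_max_iter < 1 or self.em_sigma_floor_hu <= 0:
            raise ValueError("EM settings must be strictly positive")
        if self.xmin_mode not in self._XMIN_MODES:
            raise ValueError(f"xmin_mode must be one of {self._XMIN_MODES}")

    def to_dict(self) -> dict:
        return asdict(self)
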