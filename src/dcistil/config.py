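"""Run configuration for the scoring pipeline.

All geometric quantities are in microns; the pixel scale of each image
(microns per pixel, mpp) converts them to pixel units at run time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import InvalidSpecError

SCORE_MODES = ("area_fraction", "count_per_mm2")


@dataclass(frozen=True)
class LymphocyteRule:
    """Morphometric rule labelling a nucleus as a lymphocyte.

    Lymphocytes are small, round and hyperchromatic: the rule requires the
    nucleus area to fall in ``[area_min_um2, area_max_um2]`` (inclusive),
    circularity ``4*pi*A/P**2`` to be at least ``min_circularity`` and mean
    hematoxylin optical density at least ``min_hematoxylin_od``.
    """

    area_min_um2: float = 15.0
    area_max_um2: float = 80.0
    min_circularity: float = 0.80
    min_hematoxylin_od: float = 0.40


@dataclass(frozen=True)
class ScoreConfig:
    """Parameters of the TIL scoring pipeline.

    radius_um
        Radius of the periductal microenvironment ring around the annotated
        DCIS boundary (default 250 um; 200 um used for sensitivity analysis).
    patch_size_um
        Side of the square stromal patches the ring is partitioned into.
    score_mode
        ``area_fraction`` -- per-patch TIL fraction is lymphocyte-nucleus
        area over stromal area; ``count_per_mm2`` -- lymphocyte count per
        mm^2 of stroma.
    threshold
        Optional frozen dichotomisation threshold on the x10 score scale;
        when absent the cohort median of evaluable scores is used.
    min_stroma_mm2
        Minimum stromal area inside the ring for a patient to be evaluable.
    """

    radius_um: float = 250.0
    patch_size_um: float = 100.0
    score_mode: str = "area_fraction"
    threshold: float | None = None
    min_stroma_mm2: float = 0.01
    lymphocyte_rule: LymphocyteRule = field(default_factory=LymphocyteRule)
    # tissue / background separation in HSV space
    tissue_saturation_min: float = 0.05
    tissue_value_max: float = 0.95
    # nuclei segmentation
    min_nucleus_area_um2: float = 10.0
    opening_radius_um: float = 1.0
    watershed_min_separation_um: float = 3.0

    def __post_init__(self) -> None:
        for name in ("radius_um", "patch_size_um", "min_stroma_mm2",
                     "min_nucleus_area_um2", "opening_radius_um",
                     "watershed_min_separation_um"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.score_mode not in SCORE_MODES:
            raise InvalidSpecError(
                f"score_mode must be one of {SCORE_MODES}, got {self.score_mode!r}")
        if self.threshold is not None and self.threshold < 0:
            raise InvalidSpecError("threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreConfig":
        """Load a config from YAML, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScoreConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        if "lymphocyte_rule" in raw and isinstance(raw["lymphocyte_rule"], dict):
            rule_known = {f.name for f in dataclasses.fields(LymphocyteRule)}
            rule_unknown = set(raw["lymphocyte_rule"]) - rule_known
            if rule_unknown:
                raise InvalidSpecError(
                    f"unknown lymphocyte_rule keys: {sorted(rule_unknown)}")
            raw = dict(raw)
            raw["lymphocyte_rule"] = LymphocyteRule(**raw["lymphocyte_rule"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable short hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
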