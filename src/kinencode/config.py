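"""Analysis configuration: one flat YAML file, sections optional.

Example::

    bin_width_s: 0.030
    smoothing_window_bins: 3
    camera_mirrored_x: false
    alpha: 0.05
    max_lag_s: 0.5
    null: pearson          # or "shuffle"
    n_shuffles: 1000
    rate_smoothing_sigma_bins: 0
    cell_rule:
      rate_max_da_hz: 12.0
      fwhm_min_da_ms: 0.5
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .unit_processing import CellClassRule


@dataclass
class AnalysisConfig:
    bin_width_s: float = 0.030
    smoothing_window_bins: int = 3
    camera_mirrored_x: bool = False
    alpha: float = 0.05
    max_lag_s: float = 0.5
    null: str = "pearson"
    n_shuffles: int = 1000
    rate_smoothing_sigma_bins: float = 0.0
    min_overlap_bins: int = 100
    seed: int = 0
    cell_rule: CellClassRule = field(default_factory=CellClassRule)

    def __post_init__(self) -> None:
        if isinstance(self.cell_rule, dict):
            self.cell_rule = CellClassRule(**self.cell_rule)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.null not in ("pearson", "shuffle"):
            raise ValueError("null must be 'pearson' or 'shuffle'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
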