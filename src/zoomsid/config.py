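"""Pipeline configuration.

One YAML file with blocks ``ptm``, ``isotope``, ``alignment``, ``scoring``
and ``io``; every field has a documented default so an empty config is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PTMConfig:
    """Hydroxylation / deamidation model parameters.

    Hydroxylation probabilities are per-proline-site estimates keyed to the
    Gly-Xaa-Yaa motif phase: prolines in the Yaa position are hydroxylated
    with high probability, Xaa-position and off-motif prolines rarely.
    The exact values are not experimentally determined; these defaults are
    estimates, exposed for calibration.
    """

    p_yaa: float = 0.9
    p_xaa: float = 0.05
    p_nonmotif: float = 0.05
    retention_threshold: float = 0.05
    deamidation: bool = False
    #: "chemical" = true Q->E delta (+0.984016 Da per Q); "paper" = +1.0 Da per Q
    deamidation_delta: str = "chemical"


@dataclass
class IsotopeConfig:
    """Isotope envelope and template rendering parameters."""

    prune: float = 1e-3          # drop isotopologue peaks below prune * max
    max_peaks: int = 10
    sigma: float = 0.1           # Gaussian smoothing SD, Da
    #: True = natural isotopic spacing (~1.0029 Da for C); False = exact 1.0 Da
    true_spacing: bool = True


@dataclass
class AlignmentConfig:
    max_lag: float = 0.5         # Da; lag grid step equals the 0.01 Da sample grid
    min_overlap_frac: float = 0.5


@dataclass
class ScoringConfig:
    threshold_start: float = 0.0
    threshold_stop: float = 1.0
    threshold_step: float = 0.05
    min_score: float = 0.0


@dataclass
class IOConfig:
    mass_window: tuple[float, float] = (800.0, 3500.0)  # Da, marker mass filter
    min_peptide_length: int = 3


@dataclass
class PipelineConfig:
    ptm: PTMConfig = field(default_factory=PTMConfig)
    isotope: IsotopeConfig = field(default_factory=IsotopeConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    io: IOConfig = field(default_factory=IOConfig)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config; missing blocks and fields keep their defaults."""
    cfg = PipelineConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for block_name, block in (
        ("ptm", cfg.ptm),
        ("isotope", cfg.isotope),
        ("alignment", cfg.alignment),
        ("scoring", cfg.scoring),
        ("io", cfg.io),
    ):
        for key, value in (raw.get(block_name) or {}).items():
            if not hasattr(block, key):
                raise KeyError(f"unknown config key {block_name}.{key}")
            if key == "mass_window":
                value = tuple(value)
            setattr(block, key, value)
    return cfg
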