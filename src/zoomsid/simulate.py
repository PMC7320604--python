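"""Seeded synthetic MALDI-ToF replicates with known ground truth.

The simulator produces the degradations the classifier must tolerate in
real parchment spectra: a global mass-calibration drift (within the ±0.5 Da
the alignment searches), per-marker peak dropout (peptides that fail to
"fly"), per-marker amplitude jitter, Gaussian peak shapes, and an additive
noise floor.  Spectra are sampled on a 0.02 Da raw grid — deliberately
coarser than the 0.01 Da analysis grid, so resampling by interpolation is
genuinely exercised.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .config import IsotopeConfig
from .isotopes import pattern_for_variant
from .markers import MarkerTable
from .ptm import PeptideVariant
from .spectra import RawSpectrum

RAW_GRID_STEP = 0.02  # Da


@dataclass
class SimulationConfig:
    """Ground-truth generating conditions for one synthetic sample."""

    taxon: str
    markers: list[PeptideVariant]
    drift: float = 0.0            # Da, global shift added to all peak masses
    peak_sigma: float = 0.1       # Da, Gaussian peak width
    dropout_prob: float = 0.0     # per marker per replicate
    noise_sd: float = 0.0         # relative to unit peak height
    n_replicates: int = 3
    mass_range: tuple[float, float] = (1100.0, 3200.0)
    seed: int = 0
    amplitude_range: tuple[float, float] = (0.3, 1.0)
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if abs(self.drift) > 0.5:
            raise ValueError("|drift| must be <= 0.5 Da")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.mass_range[0] >= self.mass_range[1]:
            raise ValueError("mass_range must satisfy lo < hi")


def markers_for_simulation(
    table: MarkerTable, taxon: str
) -> list[PeptideVariant]:
    """All marker PTM states of one taxon, as simulation input peaks."""
    out = []
    for row in table.rows_for(taxon):
        out.extend(row.variants())
    if not out:
        raise ValueError(f"no markers for taxon {taxon!r}")
    return out


def simulate_replicates(
    cfg: SimulationConfig, iso_config: IsotopeConfig | None = None
) -> list[RawSpectrum]:
    """Generate the replicate spectra of one synthetic sample.

    Each replicate sums, over the markers that were not dropped, the
    marker's isotope envelope rendered as Gaussians at (true mass + drift)
    with a per-marker uniform random amplitude, then adds a zero-clipped
    white Gaussian noise floor.
    """
    iso_config = iso_config or IsotopeConfig()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mass_range
    grid = np.arange(lo, hi + RAW_GRID_STEP / 2, RAW_GRID_STEP)
    patterns = [pattern_for_variant(v, iso_config) for v in cfg.markers]
    replicates = []
    for r in range(cfg.n_replicates):
        intensity = np.zeros_like(grid)
        for pattern in patterns:
            dropped = rng.random() < cfg.dropout_prob
            amplitude = rng.uniform(*cfg.amplitude_range)
            if dropped:
                continue
            for m, a in pattern.peaks:
                centre = m + cfg.drift
                # evaluate each Gaussian only on its ±6 sigma support
                w = 6.0 * cfg.peak_sigma
                i0 = np.searchsorted(grid, centre - w)
                i1 = np.searchsorted(grid, centre + w)
                if i0 >= i1:
                    continue
                x = grid[i0:i1]
                intensity[i0:i1] += (
                    amplitude * a * np.exp(-0.5 * ((x - centre) / cfg.peak_sigma) ** 2)
                )
        if cfg.noise_sd > 0:
            intensity = intensity + rng.normal(0.0, cfg.noise_sd, size=grid.shape)
            np.clip(intensity, 0.0, None, out=intensity)
        replicates.append(
            RawSpectrum(
                grid.copy(), intensity,
                replicate_id=str(r + 1), sample_id=cfg.sample_id,
            )
        )
    return replicates


def write_simulation(
    cfg: SimulationConfig,
    out_dir: str | Path,
    iso_config: IsotopeConfig | None = None,
) -> list[Path]:
    """Write ``<sample>_<replicate>.txt`` spectra plus a ground-truth JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for spec in simulate_replicates(cfg, iso_config):
        path = out_dir / f"{cfg.sample_id}_{spec.replicate_id}.txt"
        with open(path, "w") as fh:
            fh.write("# synthetic MALDI-ToF replicate\n")
            for m, i in zip(spec.masses, spec.intensities):
                fh.write(f"{m:.4f} {i:.6f}\n")
        paths.append(path)
    truth = asdict(cfg)
    truth["markers"] = [
        {"sequence": v.sequence, "nh": v.n_hydroxyl, "deamidated": v.deamidated,
         "mass_mh": v.mass_mh}
        for v in cfg.markers
    ]
    with open(out_dir / f"{cfg.sample_id}_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
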