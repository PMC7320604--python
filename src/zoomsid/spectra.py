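"""Observed MALDI-ToF spectrum I/O and local resampling.

Spectra arrive as plain-text two-column (mass, intensity) exports.  For
alignment, a local window around each candidate peptide is resampled onto
the shared 0.01 Da grid by linear interpolation and normalized to [0, 1];
normalization is per window, which makes the subsequent correlation
insensitive to regional baseline differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .isotopes import GRID_STEP

log = logging.getLogger(__name__)


class SpectrumError(ValueError):
    """Raised for malformed spectrum files or invalid windows."""


@dataclass
class RawSpectrum:
    """One replicate spectrum: strictly increasing masses, non-negative counts."""

    masses: np.ndarray
    intensities: np.ndarray
    replicate_id: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.masses.shape != self.intensities.shape or self.masses.ndim != 1:
            raise SpectrumError("masses and intensities must be 1-D and equal length")
        if len(self.masses) == 0:
            raise SpectrumError("empty spectrum")
        if np.any(np.diff(self.masses) <= 0):
            i = int(np.argmax(np.diff(self.masses) <= 0))
            raise SpectrumError(f"masses not strictly increasing at index {i + 1}")
        if np.any(self.intensities < 0):
            raise SpectrumError("negative intensity")

    def __len__(self) -> int:
        return len(self.masses)


def read_spectrum(
    path: str | Path,
    replicate_id: str = "",
    sample_id: str = "",
    sort: bool = False,
) -> RawSpectrum:
    """Read a two-column whitespace/tab-separated text spectrum.

    Lines starting with ``#`` are ignored.  Non-monotone masses are an
    error unless ``sort=True``.  Malformed lines are reported with their
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumError(f"spectrum file not found: {path}")
    masses, intensities = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError:
                raise SpectrumError(f"{path}:{lineno}: non-numeric value") from None
            masses.append(m)
            intensities.append(i)
    if not masses:
        raise SpectrumError(f"{path}: no data lines")
    masses = np.array(masses)
    intensities = np.array(intensities)
    if sort:
        order = np.argsort(masses, kind="stable")
        masses, intensities = masses[order], intensities[order]
    else:
        bad = np.nonzero(np.diff(masses) <= 0)[0]
        if bad.size:
            raise SpectrumError(
                f"{path}: masses out of order at data row {int(bad[0]) + 2}"
            )
    if not replicate_id or not sample_id:
        # "<sample>_<replicate>.txt" naming convention
        stem = path.stem
        if "_" in stem:
            s, _, r = stem.rpartition("_")
            sample_id = sample_id or s
            replicate_id = replicate_id or r
        else:
            sample_id = sample_id or stem
            replicate_id = replicate_id or "1"
    return RawSpectrum(masses, intensities, replicate_id=replicate_id, sample_id=sample_id)


@dataclass
class ResampledSegment:
    """A local spectrum window on the 0.01 Da grid, normalized to [0, 1]."""

    start_mass: float
    values: np.ndarray
    step: float = GRID_STEP
    all_zero: bool = field(default=False)

    @property
    def masses(self) -> np.ndarray:
        return self.start_mass + self.step * np.arange(len(self.values))


def extract_segment(
    spec: RawSpectrum, centre: float, half_width: float
) -> ResampledSegment:
    """Resample the window ``centre ± half_width`` onto the 0.01 Da grid.

    Linear interpolation between recorded points; grid points registered on
    multiples of 0.01 Da (window start rounded down), so segments and
    theoretical templates share sample positions.  Values outside the
    recorded mass range are zero-padded (with a warning).  The segment is
    rescaled to a maximum of 1 unless it is entirely zero, in which case it
    is returned as zeros and flagged.
    """
    lo, hi = centre - half_width, centre + half_width
    if hi < spec.masses[0] or lo > spec.masses[-1]:
        raise SpectrumError(
            f"window [{lo:.2f}, {hi:.2f}] outside spectrum range "
            f"[{spec.masses[0]:.2f}, {spec.masses[-1]:.2f}]"
        )
    start = np.floor(lo / GRID_STEP) * GRID_STEP
    n = int(np.ceil((hi - start) / GRID_STEP)) + 1
    grid = start + GRID_STEP * np.arange(n)
    values = np.interp(grid, spec.masses, spec.intensities, left=0.0, right=0.0)
    if lo < spec.masses[0] or hi > spec.masses[-1]:
        log.warning(
            "window [%.2f, %.2f] extends beyond recorded range; zero-padded",
            lo, hi,
        )
    top = values.max()
    if top > 0:
        values = values / top
        all_zero = False
    else:
        all_zero = True
    return ResampledSegment(start_mass=float(start), values=values, all_zero=all_zero)
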