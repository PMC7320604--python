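"""Cross-correlation alignment of theoretical templates with observed spectra.

MALDI-ToF mass calibration can drift by up to ~0.5 Da, so a template cannot
simply be read off at its theoretical mass.  Instead the Gaussian-smoothed
theoretical envelope is slid across a local window of the observed spectrum
(both on the shared 0.01 Da grid) and the Pearson correlation is evaluated
at every integer-sample lag within ±max_lag.  The maximum correlation
measures how well the peptide explains the local peaks; the lag at the
maximum is the shift that must be *added to the observed masses* to align
them with the theory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AlignmentConfig, IsotopeConfig, PTMConfig
from .isotopes import GRID_STEP, TheoreticalTemplate, pattern_for_variant, render_template
from .markers import MarkerTable
from .ptm import PeptideVariant
from .spectra import RawSpectrum, ResampledSegment, SpectrumError, extract_segment

log = logging.getLogger(__name__)


@dataclass
class AlignmentResult:
    """Best correlation and lag for one (replicate, peptide-variant) pair."""

    score: float
    lag: float                      # Da added to observed masses
    sample_id: str = ""
    replicate_id: str = ""
    marker_code: str = ""
    variant: PeptideVariant | None = None
    flags: frozenset[str] = field(default_factory=frozenset)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    sy = y.std()
    # values are normalized to [0,1]; guard against rounding-level variance
    if sx <= 1e-12 or sy <= 1e-12:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def cross_correlate(
    segment: ResampledSegment,
    template: TheoreticalTemplate,
    max_lag: float = 0.5,
    min_overlap_frac: float = 0.5,
) -> AlignmentResult:
    """Maximum Pearson correlation between template and segment over ±max_lag.

    The lag grid is the 0.01 Da sample grid (101 lags at the default ±0.5
    Da).  At each lag the correlation is computed over the samples where the
    template and the (shifted) segment overlap.  Ties are broken toward the
    smallest |lag|, then toward the negative lag.  A zero-variance observed
    window yields score 0 with the ``zero_variance`` flag; overlap below
    ``min_overlap_frac`` of the template support sets ``low_overlap``.
    """
    if abs(segment.step - template.step) > 1e-12:
        raise ValueError("segment and template must share the 0.01 Da grid")
    t = template.values
    s = segment.values
    # grids are registered on multiples of 0.01 Da, so offsets are integral
    offset = round((template.start_mass - segment.start_mass) / GRID_STEP)
    n_lags = round(max_lag / GRID_STEP)
    flags = set()
    best = (-np.inf, 0)
    any_valid = False
    max_overlap = 0
    for k in range(-n_lags, n_lags + 1):
        # shifting observed masses by +k*step means template[i] pairs with
        # segment[offset + i - k]
        j0 = offset - k
        lo = max(0, -j0)
        hi = min(len(t), len(s) - j0)
        if hi - lo <= 1:
            continue
        max_overlap = max(max_overlap, hi - lo)
        c = _pearson(t[lo:hi], s[j0 + lo : j0 + hi])
        if np.isnan(c):
            continue
        any_valid = True
        key = (c, -abs(k), 1 if k < 0 else 0)
        if key > (best[0], -abs(best[1]), 1 if best[1] < 0 else 0):
            best = (c, k)
    if max_overlap < min_overlap_frac * len(t):
        flags.add("low_overlap")
    if not any_valid:
        flags.add("zero_variance")
        return AlignmentResult(score=0.0, lag=0.0, flags=frozenset(flags))
    return AlignmentResult(
        score=best[0], lag=best[1] * GRID_STEP, flags=frozenset(flags)
    )


def align_variant(
    spec: RawSpectrum,
    variant: PeptideVariant,
    iso_config: IsotopeConfig | None = None,
    ptm_config: PTMConfig | None = None,
    align_config: AlignmentConfig | None = None,
) -> AlignmentResult:
    """Align one peptide variant against one replicate spectrum."""
    iso_config = iso_config or IsotopeConfig()
    align_config = align_config or AlignmentConfig()
    pattern = pattern_for_variant(variant, iso_config, ptm_config)
    template = render_template(pattern, sigma=iso_config.sigma)
    # window centred on the template midpoint with enough margin to cover
    # the full envelope across the whole lag sweep
    half_width = pattern.span() / 2 + 2.0
    try:
        segment = extract_segment(spec, template.midpoint, half_width)
    except SpectrumError:
        return AlignmentResult(
            score=0.0, lag=0.0, variant=variant,
            sample_id=spec.sample_id, replicate_id=spec.replicate_id,
            flags=frozenset({"out_of_range"}),
        )
    if segment.all_zero:
        return AlignmentResult(
            score=0.0, lag=0.0, variant=variant,
            sample_id=spec.sample_id, replicate_id=spec.replicate_id,
            flags=frozenset({"zero_variance"}),
        )
    res = cross_correlate(
        segment, template, align_config.max_lag, align_config.min_overlap_frac
    )
    res.variant = variant
    res.sample_id = spec.sample_id
    res.replicate_id = spec.replicate_id
    return res


def align_all(
    replicates: list[RawSpectrum],
    markers: MarkerTable,
    iso_config: IsotopeConfig | None = None,
    ptm_config: PTMConfig | None = None,
    align_config: AlignmentConfig | None = None,
) -> pd.DataFrame:
    """Align every replicate against every marker of every taxon.

    For a marker with several retained PTM states the per-marker score is
    the maximum over its variants; the winning variant is recorded.  One
    row per (replicate, taxon, marker code):
    sample, replicate, taxon, marker_code, nh, deamidated, score, lag, flags.
    Per-pair failures are flagged (score 0), never abort the batch.
    """
    ptm_config = ptm_config or PTMConfig()
    if not replicates:
        log.warning("align_all called with no replicates")
    rows = []
    for spec in replicates:
        for row in markers.rows:
            best: AlignmentResult | None = None
            best_var: PeptideVariant | None = None
            for variant in row.variants(ptm_config):
                res = align_variant(spec, variant, iso_config, ptm_config, align_config)
                if best is None or res.score > best.score:
                    best, best_var = res, variant
            assert best is not None and best_var is not None
            rows.append(
                {
                    "sample": spec.sample_id,
                    "replicate": spec.replicate_id,
                    "taxon": row.taxon,
                    "marker_code": row.code,
                    "nh": best_var.n_hydroxyl,
                    "deamidated": best_var.deamidated,
                    "score": best.score,
                    "lag": best.lag,
                    "flags": ",".join(sorted(best.flags)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "replicate", "taxon", "marker_code",
            "nh", "deamidated", "score", "lag", "flags",
        ],
    )
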