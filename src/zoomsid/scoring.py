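"""Threshold-sweep scoring and classification.

No single correlation threshold separates true from spurious peptide
alignments in degraded samples, so hits are counted over a *sweep* of
thresholds C_t = 0.00, 0.05, ..., 1.00.  For taxon i at threshold t the hit
count is

    H[i, t] = #{ (replicate r, marker p in P_i) : c_{r,p} > C_t }

and the taxon score accumulates i's margin over its best rival across the
sweep:

    S_i = sum_t max(0, H[i, t] - max_{j != i} H[j, t]).

S_i is large when one taxon consistently out-hits all rivals, small for
ambiguous or degraded samples, and low when the sample's true species is
not among the candidates.  The classification is the arg-max taxon; an
all-zero or tied score surface is reported as unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScoringConfig

log = logging.getLogger(__name__)


def threshold_grid(
    start: float = 0.0, stop: float = 1.0, step: float = 0.05
) -> np.ndarray:
    """The correlation-threshold sweep; defaults give the 21-value grid 0..1."""
    n = round((stop - start) / step)
    grid = start + step * np.arange(n + 1)
    if len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    return grid


def count_hits(
    correlations: pd.DataFrame, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Hit matrix H[i, t] from a per-(replicate, marker) correlation table.

    ``correlations`` needs columns ``taxon``, ``replicate``, ``marker_code``
    and ``score`` (as produced by :func:`zoomsid.alignment.align_all`).
    A hit requires the score to be *strictly* greater than the threshold —
    so a perfect score of 1.0 is still not a hit at C_t = 1.0.  Returns a
    DataFrame indexed by taxon with one column per threshold.
    """
    if grid is None:
        grid = threshold_grid()
    scores = correlations["score"].to_numpy(dtype=float)
    # flagged / failed alignments arrive as score 0 and simply never clear
    # a positive threshold
    taxa = list(dict.fromkeys(correlations["taxon"]))
    sizes = {
        i: correlations[correlations["taxon"] == i]["marker_code"].nunique()
        for i in taxa
    }
    if len(set(sizes.values())) > 1:
        log.warning("unequal marker-set sizes across taxa: %s", sizes)
    rows = {}
    for taxon in taxa:
        s = scores[(correlations["taxon"] == taxon).to_numpy()]
        rows[taxon] = [(s > t).sum() for t in grid]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{t:.2f}" for t in grid]
    ).astype(int)


@dataclass(frozen=True)
class TaxonScore:
    taxon: str
    score: float


def taxon_scores(hits: pd.DataFrame) -> list[TaxonScore]:
    """Margin-sum score S_i per taxon from a hit matrix.

    At each threshold only the taxon strictly ahead of every rival
    contributes (a positive margin); the scores sum those margins over the
    sweep.  Requires at least two taxa (the rival maximum is otherwise
    undefined).
    """
    if len(hits) < 2:
        raise ValueError("taxon_scores needs at least two candidate taxa")
    H = hits.to_numpy(dtype=float)
    out = []
    for k, taxon in enumerate(hits.index):
        rivals = np.delete(H, k, axis=0).max(axis=0)
        margins = np.maximum(0.0, H[k] - rivals)
        out.append(TaxonScore(str(taxon), float(margins.sum())))
    return out


@dataclass(frozen=True)
class Classification:
    sample_id: str
    label: str                      # winning taxon or "unclassified"
    ambiguous: bool
    scores: tuple[TaxonScore, ...] = field(default_factory=tuple)

    def score_dict(self) -> dict[str, float]:
        return {s.taxon: s.score for s in self.scores}


def classify(
    scores: list[TaxonScore],
    min_score: float = 0.0,
    sample_id: str = "",
) -> Classification:
    """Label a sample by its highest-scoring taxon.

    All-zero scores, a tie at the top, or a top score below ``min_score``
    give ``"unclassified"`` with ``ambiguous=True``.  The full score
    surface is always carried in the result as the confidence report.
    """
    if not scores:
        raise ValueError("empty score list")
    ordered = sorted(scores, key=lambda s: -s.score)
    top = ordered[0]
    tied = len(ordered) > 1 and ordered[1].score == top.score
    if top.score <= 0 or tied or top.score < min_score:
        return Classification(sample_id, "unclassified", True, tuple(scores))
    return Classification(sample_id, top.taxon, False, tuple(scores))


def classify_sample(
    correlations: pd.DataFrame,
    config: ScoringConfig | None = None,
    sample_id: str = "",
) -> tuple[Classification, pd.DataFrame]:
    """Convenience: correlations -> (classification, hit matrix)."""
    config = config or ScoringConfig()
    grid = threshold_grid(
        config.threshold_start, config.threshold_stop, config.threshold_step
    )
    hits = count_hits(correlations, grid)
    scores = taxon_scores(hits)
    return classify(scores, config.min_score, sample_id=sample_id), hits
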