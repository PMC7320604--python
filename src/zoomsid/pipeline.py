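"""End-to-end orchestration: spectra + marker panel -> classification report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .alignment import align_all
from .config import PipelineConfig
from .markers import MarkerTable, parchment_markers, read_marker_table
from .scoring import classify_sample
from .spectra import RawSpectrum, read_spectrum

log = logging.getLogger(__name__)


def classify_replicates(
    replicates: list[RawSpectrum],
    markers: MarkerTable,
    config: PipelineConfig | None = None,
):
    """Align, score and classify one sample's replicates.

    Returns ``(classification, hit_matrix, correlations)``.
    """
    config = config or PipelineConfig()
    correlations = align_all(
        replicates, markers,
        iso_config=config.isotope,
        ptm_config=config.ptm,
        align_config=config.alignment,
    )
    sample_id = replicates[0].sample_id if replicates else ""
    classification, hits = classify_sample(
        correlations, config.scoring, sample_id=sample_id
    )
    return classification, hits, correlations


def run_pipeline(
    spectra_paths: list[str | Path],
    out_dir: str | Path,
    markers_path: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """Classify one sample from its replicate spectrum files.

    Writes ``correlations.tsv``, ``hits.tsv`` and ``classification.json``
    under ``out_dir``; returns the report dict.  Unreadable replicates are
    logged and skipped; the run fails only if no replicate loads.
    """
    config = config or PipelineConfig()
    log.info("pipeline defaults in effect: %s", config.to_dict())
    markers = (
        read_marker_table(markers_path) if markers_path else parchment_markers()
    )
    replicates = []
    for p in spectra_paths:
        try:
            replicates.append(read_spectrum(p))
        except Exception as exc:  # keep scoring the remaining replicates
            log.error("skipping unreadable spectrum %s: %s", p, exc)
    if not replicates:
        raise RuntimeError("no readable replicate spectra")
    classification, hits, correlations = classify_replicates(
        replicates, markers, config
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    correlations.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)
    hits.to_csv(out_dir / "hits.tsv", sep="\t")
    report = {
        "sample": classification.sample_id,
        "label": classification.label,
        "ambiguous": classification.ambiguous,
        "scores": classification.score_dict(),
        "hit_matrix": {
            str(taxon): [int(v) for v in row]
            for taxon, row in hits.iterrows()
        },
        "thresholds": [float(c) for c in hits.columns],
        "n_replicates": len(replicates),
        "correlations": correlations.drop(columns=["flags"]).to_dict("records"),
    }
    with open(out_dir / "classification.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def summary_table(reports: list[dict]) -> pd.DataFrame:
    """Cross-sample summary: one row per sample with label and top scores."""
    rows = []
    for rep in reports:
        row = {"sample": rep["sample"], "label": rep["label"],
               "ambiguous": rep["ambiguous"]}
        row.update({f"S_{k}": v for k, v in rep["scores"].items()})
        rows.append(row)
    return pd.DataFrame(rows)
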