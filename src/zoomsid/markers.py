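"""Marker-peptide tables.

A marker table lists, per candidate taxon, the tryptic collagen peptides
(with their retained hydroxylation levels) whose masses discriminate the
taxa — the peptide set P_i that drives hit counting.  The packaged table
``data/parchment_markers.tsv`` covers the classic parchment panel *Ovis*,
*Capra*, *Bos* plus the outlier control *Cervus* (codes A1/A2, F1, G1/G2;
the F1 marker arises from a missed cleavage).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import PTMConfig
from .isotopes import monoisotopic_mh
from .proteome import CollagenSequence, Peptide
from .ptm import (
    DEAMIDATION_MASS_CHEMICAL,
    DEAMIDATION_MASS_NOMINAL,
    PeptideVariant,
)

#: reference masses must agree with computed masses to this tolerance, Da
MASS_VALIDATION_TOL = 0.1


class MarkerTableError(ValueError):
    """Raised when a marker table fails validation."""


def peptide_from_sequence(
    sequence: str, taxon: str = "?", chain: str = "marker"
) -> Peptide:
    """Wrap a bare marker sequence as a Peptide that is its own parent chain.

    Motif phasing then reads off the marker sequence itself, which is exact
    for collagen markers that start on a triplet boundary.
    """
    parent = CollagenSequence(taxon, chain, sequence)
    n_missed = sum(1 for aa in sequence[:-1] if aa in "KR")
    return Peptide(sequence, 1, len(sequence), n_missed, parent)


@dataclass(frozen=True)
class MarkerRow:
    """One marker: a peptide sequence with its retained hydroxylation levels."""

    code: str
    taxon: str
    sequence: str
    nh_levels: tuple[int, ...]
    mass: float  # reference [M+H]+ at the lowest retained level, Da

    def variants(self, ptm: PTMConfig | None = None) -> list[PeptideVariant]:
        """Expand into explicit PTM states (one per nH level, plus
        deamidated twins when deamidation is enabled)."""
        ptm = ptm or PTMConfig()
        pep = peptide_from_sequence(self.sequence, self.taxon)
        n_q = self.sequence.count("Q")
        delta = (
            DEAMIDATION_MASS_NOMINAL
            if ptm.deamidation_delta == "paper"
            else DEAMIDATION_MASS_CHEMICAL
        )
        out = []
        for nh in self.nh_levels:
            base = monoisotopic_mh(self.sequence, n_hydroxyl=nh)
            out.append(PeptideVariant(pep, nh, False, 1.0, base))
            if ptm.deamidation and n_q:
                out.append(PeptideVariant(pep, nh, True, 1.0, base + delta * n_q))
        return out


@dataclass(frozen=True)
class MarkerTable:
    rows: tuple[MarkerRow, ...]

    @property
    def taxa(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rows:
            seen.setdefault(r.taxon, None)
        return list(seen)

    def rows_for(self, taxon: str) -> list[MarkerRow]:
        return [r for r in self.rows if r.taxon == taxon]

    def __len__(self) -> int:
        return len(self.rows)


def _validate(rows: list[MarkerRow]) -> None:
    seen = set()
    for row in rows:
        key = (row.code, row.taxon)
        if key in seen:
            raise MarkerTableError(f"duplicate marker (code, taxon) = {key}")
        seen.add(key)
        computed = monoisotopic_mh(row.sequence, n_hydroxyl=min(row.nh_levels))
        if abs(computed - row.mass) > MASS_VALIDATION_TOL:
            raise MarkerTableError(
                f"marker {row.code}/{row.taxon}: reference mass {row.mass:.1f} "
                f"differs from computed {computed:.4f} at nH={min(row.nh_levels)} "
                f"by more than {MASS_VALIDATION_TOL} Da"
            )


def read_marker_table(path: str | Path) -> MarkerTable:
    """Read a TSV with columns code, taxon, sequence, nh_levels, mass.

    ``nh_levels`` is a comma-separated list of retained hydroxylation
    counts; ``mass`` is the reference [M+H]+ at the lowest listed level and
    is validated against the computed mass (0.1 Da tolerance, the failing
    row is named).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"code", "taxon", "sequence", "nh_levels", "mass"}
    missing = required - set(df.columns)
    if missing:
        raise MarkerTableError(f"marker table missing columns: {sorted(missing)}")
    rows = []
    for _, rec in df.iterrows():
        levels = tuple(int(x) for x in str(rec["nh_levels"]).split(","))
        rows.append(
            MarkerRow(
                code=rec["code"].strip(),
                taxon=rec["taxon"].strip(),
                sequence=rec["sequence"].strip(),
                nh_levels=levels,
                mass=float(rec["mass"]),
            )
        )
    _validate(rows)
    return MarkerTable(tuple(rows))


def parchment_markers() -> MarkerTable:
    """The packaged Ovis/Capra/Bos/Cervus parchment marker panel."""
    ref = importlib.resources.files("zoomsid") / "data" / "parchment_markers.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_marker_table(path)
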