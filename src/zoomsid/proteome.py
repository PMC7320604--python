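"""Collagen sequences and in-silico tryptic digestion.

Peptide mass fingerprinting of collagen starts from the candidate species'
collagen chain sequences (typically COL1A1 and COL1A2).  Trypsin cleaves
C-terminal to lysine (K) and arginine (R); this module predicts the resulting
peptides, including peptides with missed cleavages, and compares digests
between taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class SequenceError(ValueError):
    """Raised for malformed or chemically invalid sequence input."""


@dataclass(frozen=True)
class CollagenSequence:
    """One collagen chain of one taxon.

    Parameters
    ----------
    taxon_id : str
        Taxon label, e.g. ``"Ovis"``.
    chain_id : str
        Chain label, e.g. ``"COL1A1"``.
    residues : str
        Amino-acid sequence in one-letter code.  Ambiguity codes
        (B, J, O, U, X, Z) are rejected.
    """

    taxon_id: str
    chain_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(
                f"{self.taxon_id}|{self.chain_id}: empty sequence"
            )
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in VALID_RESIDUES:
                raise SequenceError(
                    f"{self.taxon_id}|{self.chain_id}: invalid residue "
                    f"{aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with parent-chain coordinates.

    ``start`` and ``end`` are 1-based inclusive positions in the parent
    chain; ``n_missed`` counts internal K/R sites (i.e. missed cleavages).
    """

    sequence: str
    start: int
    end: int
    n_missed: int
    parent: CollagenSequence = field(compare=False)

    def __post_init__(self) -> None:
        if self.parent.residues[self.start - 1 : self.end] != self.sequence:
            raise SequenceError(
                f"peptide {self.sequence!r} does not match parent "
                f"{self.parent.taxon_id}|{self.parent.chain_id} at "
                f"[{self.start}, {self.end}]"
            )
        internal = sum(1 for aa in self.sequence[:-1] if aa in "KR")
        if internal != self.n_missed:
            raise SequenceError(
                f"peptide {self.sequence!r}: n_missed={self.n_missed} but "
                f"{internal} internal K/R sites"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _parse_header(header: str) -> tuple[str, str]:
    """Map a FASTA header to (taxon, chain).

    The convention is ``taxon|chain`` (extra ``|``-separated fields are
    ignored); a header with no ``|`` becomes taxon with chain ``"?"``.
    """
    parts = [p.strip() for p in header.split("|")]
    if len(parts) >= 2 and parts[0] and parts[1]:
        return parts[0], parts[1]
    return header.strip() or "?", "?"


def read_fasta(path: str | Path) -> list[CollagenSequence]:
    """Read collagen chains from a (possibly line-wrapped) FASTA file.

    Headers of the form ``>taxon|chain`` map to the two identity fields.
    Raises :class:`SequenceError` for a missing or empty file or for any
    invalid residue (the offending record and position are named).
    """
    path = Path(path)
    if not path.exists():
        raise SequenceError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        taxon, chain = _parse_header(rec.description)
        residues = str(rec.seq).strip().upper()
        out.append(CollagenSequence(taxon, chain, residues))
    return out


def digest(seq: CollagenSequence, max_missed: int = 1) -> list[Peptide]:
    """Tryptic digest: cut after every K and R, then add missed cleavages.

    The baseline rule cuts after each K/R occurrence including K/R–P bonds
    (pass ``no_cut_before_proline=True`` via :func:`digest_ex` for the
    textbook trypsin rule).  Peptides with up to ``max_missed`` retained
    internal sites are produced by concatenating consecutive fully-cleaved
    fragments.  Output is ordered by (start, end).
    """
    return digest_ex(seq, max_missed, no_cut_before_proline=False)


def digest_ex(
    seq: CollagenSequence,
    max_missed: int = 1,
    *,
    no_cut_before_proline: bool = False,
) -> list[Peptide]:
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    res = seq.residues
    # 0-based cut points: a cut after index i means fragments split at i+1
    cuts = []
    for i, aa in enumerate(res[:-1]):
        if aa in "KR":
            if no_cut_before_proline and res[i + 1] == "P":
                continue
            cuts.append(i + 1)
    bounds = [0] + cuts + [len(res)]
    frags = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
    peptides = []
    for k in range(len(frags)):
        for span in range(min(max_missed + 1, len(frags) - k)):
            lo = frags[k][0]
            hi = frags[k + span][1]
            pep = res[lo:hi]
            peptides.append(
                Peptide(
                    sequence=pep,
                    start=lo + 1,
                    end=hi,
                    n_missed=sum(1 for aa in pep[:-1] if aa in "KR"),
                    parent=seq,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def peptide_differences(
    digest_a: Iterable[Peptide], digest_b: Iterable[Peptide]
) -> int:
    """Number of distinct peptide sequences in ``digest_a`` absent from ``digest_b``.

    Set semantics on sequence strings.  For taxa that differ only by
    substitutions the count is symmetric; use fully-cleaved digests
    (``max_missed=0``) when comparing species repertoires.
    """
    set_a = {p.sequence for p in digest_a}
    set_b = {p.sequence for p in digest_b}
    return len(set_a - set_b)


def digest_table(peptides: Iterable[Peptide]):
    """Digest export as a DataFrame (taxon, chain, start, end, n_missed, sequence)."""
    import pandas as pd

    rows = [
        {
            "taxon": p.parent.taxon_id,
            "chain": p.parent.chain_id,
            "start": p.start,
            "end": p.end,
            "n_missed": p.n_missed,
            "sequence": p.sequence,
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=["taxon", "chain", "start", "end", "n_missed", "sequence"])
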