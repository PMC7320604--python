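"""Synthetic reference collagen sequences for the parchment taxon panel.

The published reference chains for *Ovis*, *Capra*, *Bos* and *Cervus* are
held in external sequence databases and are not shipped here.  This module
builds a SYNTHETIC stand-in panel of COL1A1/COL1A2 chains that preserves the
properties the classifier depends on:

* each taxon's chains contain its marker peptides (codes A, F, G), with the
  F1 marker arising only through a missed cleavage (the chain carries the
  ...GDK|GET... junction);
* the fully-cleaved digests reproduce the inter-taxon difference structure
  of the real panel: 15 distinct peptides between *Bos* and *Capra*, 14
  between *Bos* and *Ovis*, and only 3 between *Ovis* and *Capra*,
  reflecting the close sheep/goat relationship;
* chains are collagen-like (Gly-Xaa-Yaa repeats, proline-rich) so the
  hydroxylation model sees realistic motif phasing.

They are synthetic sequences: suitable for exercising and demonstrating the
pipeline, not for classifying real samples.
"""

from __future__ import annotations

from pathlib import Path

from .proteome import CollagenSequence

TAXA = ("Ovis", "Capra", "Bos", "Cervus")

# -- marker peptides ---------------------------------------------------------

_A_MARKER = {
    "Ovis": "TGQPGAVGPAGIR",
    "Capra": "TGQPGAVGPAGIR",
    "Bos": "IGQPGAVGPAGIR",
    "Cervus": "TGQPGAVGPAGIR",
}
# F1 = F_a + F_b joined by a missed cleavage at the internal K
_F_A = {
    "Ovis": "GLTGPIGPPGPAGAPGDK",
    "Capra": "GLTGPIGPPGPAGAPGDK",
    "Bos": "GLTGPIGPPGPAGAPGDK",
    "Cervus": "GITGPIGPPGPAGAPGDK",
}
_F_B = {
    "Ovis": "GETGPSGPAGPTGAR",
    "Capra": "GETGPSGPAGPTGAR",
    "Bos": "GEAGPSGPAGPTGAR",
    "Cervus": "GETGPSGPAGPTGAR",
}
_G_MARKER = {
    "Ovis": "GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR",
    "Capra": "GPSGEPGTAGPPGTPGPQGFLGPPGFLGLPGSR",
    "Bos": "GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR",
    "Cervus": "GPSGEPGTAGPPGTPGPQGIIGPPGFIGIPGSR",
}

# -- variable (non-marker) tryptic loci --------------------------------------
# Twelve loci where Bos carries a private allele; at the last two, Ovis and
# Capra also differ from each other.  Cervus shares the Ovis allele
# throughout.  Each allele is one tryptic fragment (no internal K/R, ends K).

_LOCUS_LETTERS = "ASTVLINQDEFH"          # identity letter per locus


def _allele(locus: int, variant_letter: str) -> str:
    return f"G{_LOCUS_LETTERS[locus]}PGA{variant_letter}GPPGEK"


def _locus_allele(locus: int, taxon: str) -> str:
    if taxon == "Bos":
        return _allele(locus, "S")
    if taxon == "Capra" and locus >= 10:
        return _allele(locus, "T")
    return _allele(locus, "A")            # Ovis, Cervus, and Capra elsewhere


# -- conserved filler fragments ----------------------------------------------

_FILL_1 = ["GPMGPSGPR", "GLPGPPGAPGPQGFQGPPGEPGEPGASGPMGPR"]
_FILL_2 = ["GPPGPAGPVGK", "GESGPSGPAGPTGAR"]
_FILL_3 = ["GNSGEPGAPGSK", "GDTGAPGAPGSQGAPGLQGMPGER"]
_FILL_4 = ["GPSGPPGPDGNK", "GAAGLPGVAGAPGLPGPR"]
_FILL_5 = ["GEPGSPGENGAPGQMGPR", "GLPGER"]
_FILL_6 = ["GAPGDRGEPGPPGPAGFAGPPGADGQPGAK", "GEPGDAGAK", "GDAGPPGPAGPAGPPGPIGNVGAPGPK"]
_TAIL_1 = "GVQGPPGPAGPPGPPGV"            # C-terminal fragment, no K/R end
_TAIL_2 = "GFSGLQGPPGPPGSPGEQ"


def build_chains(taxon: str) -> tuple[CollagenSequence, CollagenSequence]:
    """The synthetic COL1A1 and COL1A2 chains of one panel taxon."""
    if taxon not in TAXA:
        raise ValueError(f"unknown panel taxon {taxon!r}; choose from {TAXA}")
    col1a1 = "".join(
        _FILL_1
        + [_A_MARKER[taxon]]
        + _FILL_2
        + [_locus_allele(i, taxon) for i in range(6)]
        + _FILL_3
        + [_TAIL_1]
    )
    col1a2 = "".join(
        _FILL_4
        + [_F_A[taxon], _F_B[taxon]]
        + _FILL_5
        + [_G_MARKER[taxon]]
        + [_locus_allele(i, taxon) for i in range(6, 12)]
        + _FILL_6
        + [_TAIL_2]
    )
    return (
        CollagenSequence(taxon, "COL1A1", col1a1),
        CollagenSequence(taxon, "COL1A2", col1a2),
    )


def reference_sequences() -> list[CollagenSequence]:
    """All eight synthetic chains (two per panel taxon)."""
    out = []
    for taxon in TAXA:
        out.extend(build_chains(taxon))
    return out


def write_reference_fasta(path: str | Path, width: int = 60) -> Path:
    """Write the synthetic panel to a wrapped FASTA file (``>taxon|chain``)."""
    path = Path(path)
    with open(path, "w") as fh:
        for seq in reference_sequences():
            fh.write(f">{seq.taxon_id}|{seq.chain_id} synthetic collagen stand-in\n")
            for k in range(0, len(seq.residues), width):
                fh.write(seq.residues[k : k + width] + "\n")
    return path
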