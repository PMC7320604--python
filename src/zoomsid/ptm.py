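"""Post-translational modification modelling for collagen peptides.

Two modifications dominate collagen mass fingerprints:

* **Proline hydroxylation** (+15.99491 Da per site).  Collagen's repeating
  Gly-Xaa-Yaa motif makes hydroxylation strongly position dependent: prolines
  in the Yaa position are usually hydroxylated, Xaa-position prolines rarely.
  Treating sites as independent Bernoulli events, the number of hydroxylations
  in a peptide follows a Poisson-binomial distribution, computed exactly here
  by dynamic programming (equivalent to walking a binary decision tree over
  the sites, but O(N^2) instead of O(2^N)).

* **Glutamine deamidation** (Q -> E-like mass), modelled as an all-or-nothing
  event over every Q in the peptide.

`enumerate_variants` keeps the hydroxylation levels whose probability clears a
retention threshold and expands deamidation states, yielding the peptide
variants that are rendered into theoretical templates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PTMConfig
from .proteome import Peptide

#: mass added by hydroxylation of one proline (one oxygen atom), Da
HYDROXYLATION_MASS = 15.9949146221
#: true glutamine -> glutamate monoisotopic shift (NH -> O), Da
DEAMIDATION_MASS_CHEMICAL = 0.984016
#: nominal +1 Da per glutamine shift
DEAMIDATION_MASS_NOMINAL = 1.0

XAA = "Xaa"
YAA = "Yaa"
NONMOTIF = "nonmotif"


@dataclass(frozen=True)
class ProlineSite:
    """A proline within a peptide, classified by Gly-Xaa-Yaa motif phase."""

    index: int           # 1-based position of the P within the peptide
    motif_class: str     # "Xaa", "Yaa" or "nonmotif"
    p_hydroxyl: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hydroxyl <= 1.0:
            raise ValueError(f"p_hydroxyl out of [0,1]: {self.p_hydroxyl}")


def classify_proline(parent_residues: str, pos: int) -> str:
    """Motif phase of the proline at 1-based ``pos`` in the parent chain.

    The Gly-Xaa-Yaa frame is anchored on glycine: the residue immediately
    after a G is Xaa, the next one Yaa.  A proline with no G one or two
    residues upstream is off-motif.
    """
    if parent_residues[pos - 1] != "P":
        raise ValueError(f"residue at position {pos} is not proline")
    if pos >= 2 and parent_residues[pos - 2] == "G":
        return XAA
    if pos >= 3 and parent_residues[pos - 3] == "G":
        return YAA
    return NONMOTIF


def assign_site_probabilities(
    peptide: Peptide, config: PTMConfig | None = None
) -> list[ProlineSite]:
    """Classify every proline in the peptide and assign its hydroxylation probability.

    The motif phase is read from the *parent chain* at the peptide's
    coordinates, because tryptic fragments need not begin on a motif
    boundary (a peptide-initial proline still sees its upstream glycine).
    """
    config = config or PTMConfig()
    prob = {XAA: config.p_xaa, YAA: config.p_yaa, NONMOTIF: config.p_nonmotif}
    parent = peptide.parent.residues
    sites = []
    for i, aa in enumerate(peptide.sequence, start=1):
        if aa == "P":
            cls = classify_proline(parent, peptide.start + i - 1)
            sites.append(ProlineSite(index=i, motif_class=cls, p_hydroxyl=prob[cls]))
    return sites


@dataclass(frozen=True)
class HydroxylationDistribution:
    """Exact distribution of the hydroxylation count over a peptide's sites."""

    probabilities: tuple[float, ...]   # index nH = 0..N

    def __post_init__(self) -> None:
        total = sum(self.probabilities)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"distribution sums to {total}, not 1")
        if any(p < 0 for p in self.probabilities):
            raise ValueError("negative probability")

    def __getitem__(self, n_hydroxyl: int) -> float:
        return self.probabilities[n_hydroxyl]

    def __len__(self) -> int:
        return len(self.probabilities)

    @property
    def mean(self) -> float:
        return float(sum(n * p for n, p in enumerate(self.probabilities)))


def hydroxylation_distribution(
    sites: list[ProlineSite] | list[float],
) -> HydroxylationDistribution:
    """Poisson-binomial distribution of the number of hydroxylated sites.

    Accepts either classified sites or bare probabilities.  Dynamic program:
    fold each site into the running distribution, O(N^2) total.
    """
    probs = [s.p_hydroxyl if isinstance(s, ProlineSite) else float(s) for s in sites]
    dist = np.zeros(len(probs) + 1)
    dist[0] = 1.0
    for k, p in enumerate(probs):
        new = dist.copy()
        new[: k + 1] *= 1.0 - p
        new[1 : k + 2] += dist[: k + 1] * p
        dist = new
    return HydroxylationDistribution(tuple(float(x) for x in dist))


@dataclass(frozen=True)
class PeptideVariant:
    """A peptide in one specific PTM state."""

    peptide: Peptide
    n_hydroxyl: int
    deamidated: bool
    probability: float
    mass_mh: float       # monoisotopic [M+H]+, Da

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    def __post_init__(self) -> None:
        n_pro = self.peptide.sequence.count("P")
        if self.n_hydroxyl > n_pro:
            raise ValueError(
                f"{self.n_hydroxyl} hydroxylations on {n_pro} prolines"
            )
        if self.deamidated and "Q" not in self.peptide.sequence:
            raise ValueError("deamidated variant of a glutamine-free peptide")


def enumerate_variants(
    peptide: Peptide, config: PTMConfig | None = None
) -> list[PeptideVariant]:
    """Enumerate the retained PTM states of a peptide.

    Hydroxylation levels with probability >= ``retention_threshold`` are
    kept.  With deamidation enabled and at least one Q present, each level
    also yields an all-or-nothing deamidated twin (same probability; the
    deamidation propensity itself is not modelled).  Variants are sorted by
    descending probability.
    """
    from .isotopes import monoisotopic_mh   # local import: avoid cycle

    config = config or PTMConfig()
    sites = assign_site_probabilities(peptide, config)
    dist = hydroxylation_distribution(sites)
    delta_q = (
        DEAMIDATION_MASS_NOMINAL
        if config.deamidation_delta == "paper"
        else DEAMIDATION_MASS_CHEMICAL
    )
    n_q = peptide.sequence.count("Q")
    variants = []
    for nh, p in enumerate(dist.probabilities):
        if p < config.retention_threshold:
            continue
        base = monoisotopic_mh(peptide.sequence, n_hydroxyl=nh)
        variants.append(
            PeptideVariant(peptide, nh, False, p, base)
        )
        if config.deamidation and n_q > 0:
            variants.append(
                PeptideVariant(peptide, nh, True, p, base + delta_q * n_q)
            )
    variants.sort(key=lambda v: (-v.probability, v.n_hydroxyl, v.deamidated))
    return variants
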