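"""Elemental compositions, monoisotopic masses, isotope envelopes, templates.

A peptide's MALDI-ToF signature is not one spike but an envelope of
isotopologue peaks spaced ~1 Da apart, with relative abundances fixed by the
natural isotope frequencies of C, H, N, O and S.  This module computes that
envelope exactly (per-element convolution, aggregated at unit nominal mass)
and renders it, Gaussian-smoothed, onto the 0.01 Da analysis grid used for
cross-correlation.

Atomic masses and isotopic abundances are the CODATA/IUPAC standard values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import IsotopeConfig, PTMConfig

GRID_STEP = 0.01  # Da, shared analysis grid

PROTON_MASS = 1.007276

# monoisotopic atomic masses, Da
MONO_MASS = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# (mass, natural abundance) per isotope, in increasing mass order
ISOTOPES = {
    "C": [(12.0, 0.9893), (13.0033548378, 0.0107)],
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "N": [(14.0030740052, 0.99632), (15.0001088984, 0.00368)],
    "O": [(15.9949146221, 0.99757), (16.9991315, 0.00038), (17.9991604, 0.00205)],
    "S": [(31.97207069, 0.9493), (32.97145850, 0.0076), (33.96786683, 0.0429),
          (35.96708088, 0.0002)],
}

# residue (= amino acid minus water) elemental formulas: (C, H, N, O, S)
RESIDUE_FORMULAS = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

_ELEMENTS = ("C", "H", "N", "O", "S")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a (modified) peptide, water termini included."""

    C: int
    H: int
    N: int
    O: int
    S: int = 0

    def __post_init__(self) -> None:
        if min(self.C, self.H, self.N, self.O, self.S) < 0:
            raise ValueError("negative atom count")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            self.C + other.C, self.H + other.H, self.N + other.N,
            self.O + other.O, self.S + other.S,
        )

    def monoisotopic_mass(self) -> float:
        return (
            self.C * MONO_MASS["C"] + self.H * MONO_MASS["H"]
            + self.N * MONO_MASS["N"] + self.O * MONO_MASS["O"]
            + self.S * MONO_MASS["S"]
        )


def elemental_composition(
    sequence: str,
    n_hydroxyl: int = 0,
    n_deamidated_q: int = 0,
) -> ElementalComposition:
    """Composition of a peptide: residue sum + H2O termini + modifications.

    Each hydroxylation adds one oxygen; each chemically deamidated glutamine
    substitutes O for NH (the Q -> E conversion).  Nominal "+1 Da" style
    deamidation is a mass offset, not a composition change, and is handled
    by the callers that need it.
    """
    c = h = n = o = s = 0
    for pos, aa in enumerate(sequence, start=1):
        try:
            dc, dh, dn, do, ds = RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {pos}") from None
        c += dc; h += dh; n += dn; o += do; s += ds
    h += 2
    o += 1  # water termini
    o += n_hydroxyl
    if n_deamidated_q:
        if sequence.count("Q") < n_deamidated_q:
            raise ValueError("more deamidated Q than glutamines present")
        n -= n_deamidated_q
        h -= n_deamidated_q
        o += n_deamidated_q
    return ElementalComposition(c, h, n, o, s)


def monoisotopic_mh(sequence: str, n_hydroxyl: int = 0) -> float:
    """Monoisotopic [M+H]+ of a peptide carrying ``n_hydroxyl`` hydroxyprolines."""
    return elemental_composition(sequence, n_hydroxyl).monoisotopic_mass() + PROTON_MASS


@dataclass(frozen=True)
class IsotopePattern:
    """Stick isotope envelope: (mass, abundance) pairs, tallest peak = 1."""

    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.peaks]
        if any(b <= a for a, b in zip(masses, masses[1:])):
            raise ValueError("pattern masses not strictly increasing")
        for a, b in zip(masses, masses[1:]):
            if not 0.99 <= b - a <= 1.01:
                raise ValueError(f"isotope spacing {b - a:.4f} Da outside [0.99, 1.01]")
        if abs(max(ab for _, ab in self.peaks) - 1.0) > 1e-12:
            raise ValueError("pattern not normalized to max 1")

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])

    def span(self) -> float:
        return self.peaks[-1][0] - self.peaks[0][0]


def isotope_pattern(
    comp: ElementalComposition,
    prune: float = 1e-3,
    max_peaks: int = 10,
    mass_offset: float = PROTON_MASS,
    true_spacing: bool = True,
) -> IsotopePattern:
    """Aggregated isotopologue envelope of a composition.

    Per-element single-atom isotope distributions are convolved atom by
    atom; isotopologues are aggregated at unit nominal mass (the neutron
    count), each bin carrying its abundance-weighted mean mass.  Peaks below
    ``prune`` x the tallest are dropped and at most ``max_peaks`` are kept.
    ``mass_offset`` (default: one proton, for the [M+H]+ ion) is added to
    every peak.  With ``true_spacing=False`` the peaks are forced onto an
    exact 1.0 Da ladder anchored at the monoisotopic mass.
    """
    if not 0.0 < prune < 1.0:
        raise ValueError("prune must be in (0, 1)")
    # state: probs[k] and wsum[k] = sum of (prob * excess mass) in nominal bin k
    nbins = max_peaks + 15
    probs = np.zeros(nbins)
    wsum = np.zeros(nbins)
    probs[0] = 1.0
    for elem in _ELEMENTS:
        count = getattr(comp, elem)
        if count == 0:
            continue
        iso = ISOTOPES[elem]
        base_mass = iso[0][0]
        shifts = [round(m - base_mass) for m, _ in iso]
        excesses = [m - base_mass - s for (m, _), s in zip(iso, shifts)]
        abunds = [a for _, a in iso]
        total = sum(abunds)
        abunds = [a / total for a in abunds]
        for _ in range(count):
            new_p = np.zeros(nbins)
            new_w = np.zeros(nbins)
            for s, ex, a in zip(shifts, excesses, abunds):
                if s == 0:
                    new_p += probs * a
                    new_w += (wsum + probs * ex) * a
                else:
                    new_p[s:] += probs[:-s] * a
                    new_w[s:] += (wsum[:-s] + probs[:-s] * ex) * a
            probs, wsum = new_p, new_w
    mono = comp.monoisotopic_mass()
    peaks = []
    for k in range(nbins):
        if probs[k] <= 0:
            continue
        mean_excess = wsum[k] / probs[k]
        peaks.append((mono + k + mean_excess, probs[k]))
    top = max(a for _, a in peaks)
    peaks = [(m, a / top) for m, a in peaks if a / top >= prune]
    peaks = sorted(peaks, key=lambda p: p[0])[:max_peaks]
    top = max(a for _, a in peaks)
    if not true_spacing:
        first = peaks[0][0]
        peaks = [(first + i * 1.0, a) for i, (_, a) in enumerate(peaks)]
    return IsotopePattern(
        tuple((m + mass_offset, a / top) for m, a in peaks)
    )


def pattern_for_variant(
    variant,
    iso_config: IsotopeConfig | None = None,
    ptm_config: PTMConfig | None = None,
) -> IsotopePattern:
    """Isotope envelope of a :class:`~zoomsid.ptm.PeptideVariant` as [M+H]+."""
    iso_config = iso_config or IsotopeConfig()
    ptm_config = ptm_config or PTMConfig()
    seq = variant.sequence
    n_q = seq.count("Q")
    offset = PROTON_MASS
    if variant.deamidated and ptm_config.deamidation_delta == "paper":
        comp = elemental_composition(seq, variant.n_hydroxyl)
        offset += 1.0 * n_q
    elif variant.deamidated:
        comp = elemental_composition(seq, variant.n_hydroxyl, n_deamidated_q=n_q)
    else:
        comp = elemental_composition(seq, variant.n_hydroxyl)
    return isotope_pattern(
        comp,
        prune=iso_config.prune,
        max_peaks=iso_config.max_peaks,
        mass_offset=offset,
        true_spacing=iso_config.true_spacing,
    )


@dataclass(frozen=True)
class TheoreticalTemplate:
    """Gaussian-smoothed envelope sampled on the 0.01 Da grid, max value 1."""

    start_mass: float
    values: np.ndarray
    step: float = GRID_STEP

    @property
    def masses(self) -> np.ndarray:
        return self.start_mass + self.step * np.arange(len(self.values))

    @property
    def end_mass(self) -> float:
        return self.start_mass + self.step * (len(self.values) - 1)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_mass + self.end_mass)


def render_template(pattern: IsotopePattern, sigma: float = 0.1) -> TheoreticalTemplate:
    """Render a stick envelope as a sum of Gaussians on the 0.01 Da grid.

    Each isotope peak becomes a Gaussian of standard deviation ``sigma``
    scaled by its abundance; the grid runs from 1.5 Da below the first peak
    to 1.5 Da above the last, registered on multiples of 0.01 Da so that
    observed and theoretical grids stay commensurate.  The sum is
    renormalized to a maximum of 1.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    first = pattern.peaks[0][0]
    last = pattern.peaks[-1][0]
    start = np.floor((first - 1.5) / GRID_STEP) * GRID_STEP
    n = int(np.ceil((last + 1.5 - start) / GRID_STEP)) + 1
    grid = start + GRID_STEP * np.arange(n)
    values = np.zeros(n)
    for m, a in pattern.peaks:
        values += a * np.exp(-0.5 * ((grid - m) / sigma) ** 2)
    values /= values.max()
    return TheoreticalTemplate(start_mass=float(start), values=values)
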