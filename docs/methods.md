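# Methods

`zoomsid` automates species identification from MALDI-ToF mass spectra of
collagen-bearing samples (ZooMS).  Instead of manual peak reading, it derives
theoretical peptide-marker templates from collagen sequences, aligns them to
the observed spectra by cross-correlation, and combines the evidence into a
per-taxon confidence score.  This note documents the model, its parameters,
the numerical choices, and what the synthetic-data tests do and do not show.

## 1. Theoretical templates

**Tryptic digestion.**  Collagen chains are cut after every K and R
(`proteome.digest`).  The baseline rule also cuts K/R–P bonds; textbook
trypsin chemistry suppresses cleavage before proline, so a
`no_cut_before_proline` flag is available (off by default — the baseline rule
is the one the marker panel was derived under).  Peptides with up to
`max_missed` retained internal sites (default 1, sufficient for the F1 marker,
which is a single missed cleavage) are generated by concatenating consecutive
fully-cleaved fragments.  `digest` itself is lossless; length/mass filtering
(defaults: ≥3 residues, 800–3500 Da) is applied only downstream.

**Hydroxylation.**  Collagen's Gly-Xaa-Yaa repeat makes proline hydroxylation
position dependent.  Each proline is classified by motif phase read from the
*parent chain* (a residue directly after a G is Xaa; two after, Yaa; prolines
with no glycine anchor are off-motif) and assigned a per-site probability:

| class     | default p | rationale                                   |
|-----------|-----------|---------------------------------------------|
| Yaa       | 0.90      | Yaa-position prolines are usually modified  |
| Xaa       | 0.05      | rarely modified                             |
| off-motif | 0.05      | rarely modified                             |

These are *estimates* — no sequence-specific hydroxylation model exists — and
they are exposed in the `ptm` config block.  Treating sites as independent,
the number of hydroxylations follows a Poisson-binomial distribution,
computed exactly by an O(N²) dynamic program (`ptm.hydroxylation_distribution`);
the unit tests verify it against 2^N enumeration.  Hydroxylation levels with
probability ≥ 0.05 (`retention_threshold`) are retained; under the defaults
this reproduces exactly two retained levels for the A and G markers, matching
the reference panel.

**Deamidation.**  Glutamine deamidation is modelled all-or-nothing over every
Q in a peptide.  Two mass conventions are supported: `chemical`
(+0.984016 Da per Q, the true Q→E delta; default) and the nominal `paper`
convention (+1.0 Da per Q).  Deamidation is off by default in the
classification pipeline because the packaged marker panel pins each marker to
explicit hydroxylation states; enabling it adds deamidated twins that compete
within each marker via the max rule (below).

**Masses and isotope envelopes.**  Elemental compositions are residue-formula
sums plus water termini, one O per hydroxylation, and (in chemical mode)
NH→O per deamidated Q.  Monoisotopic [M+H]+ uses standard monoisotopic atomic
masses and a proton of 1.007276 Da.  Isotope envelopes are computed by exact
per-atom convolution of the natural C/H/N/O/S isotope distributions,
aggregated at unit nominal mass with abundance-weighted mean masses per bin —
fine isotopic structure is irrelevant at the 0.01 Da analysis grid and the
±0.5 Da lag search.  Peaks below 10⁻³ of the tallest are pruned and at most
10 peaks are kept.  True isotopic spacing (~1.0029 Da for carbon) is the
default; an exact-1.0-Da ladder is available via `isotope.true_spacing: false`.
Templates render each stick peak as a Gaussian of SD `sigma` (default 0.1 Da,
a typical reflector-mode peak width; never stated by the original method and
therefore configurable), sampled on the 0.01 Da grid 1.5 Da beyond the
envelope on each side, renormalized to max 1.

The packaged parchment panel (`data/parchment_markers.tsv`) carries the five
discriminating markers (A1/A2, F1, G1/G2) for sheep, goat, cattle and the
outlier control red deer.  Reference masses are validated against computed
masses on load (0.1 Da tolerance).  Note that the red-deer G marker carries
one more hydroxyproline than its sheep/goat/cattle homologues (levels 5 and 6,
giving the established 3059.5/3075.5 Da deer markers).

## 2. Alignment

Observed spectra are two-column text files.  For each marker variant a local
window (template span/2 + 2 Da around the template midpoint — wide enough to
cover the envelope across the whole lag sweep) is resampled to the 0.01 Da
grid by linear interpolation and normalized to [0, 1] *per window*, making
the correlation insensitive to regional baseline.  No baseline subtraction,
smoothing or peak picking is applied to observed data: the method aligns raw
profiles by design.

The template is slid across the segment over integer-sample lags spanning
±0.5 Da (101 lags; no sub-sample interpolation of the correlation peak — the
threshold sweep does not benefit from finer lags) and the Pearson correlation
is computed over the overlapping support at each lag.  Pearson is used
because it is affine-invariant in intensity and bounded in [−1, 1], which the
threshold grid requires.  The reported lag is the shift *added to observed
masses* to reach the best alignment (a +0.2 Da calibration drift is recovered
as lag −0.2).  Ties break toward the smallest |lag|, then the negative lag.
Zero-variance windows score 0 and are flagged; overlap below 50% of the
template support sets a `low_overlap` flag.  Negative correlations are kept —
they simply never clear a positive threshold.  For a marker with several
retained PTM states the per-marker score is the maximum over its variants: a
marker "matches" if any retained state explains the local peaks.

## 3. Scoring and classification

No single correlation threshold separates genuine from spurious alignments in
degraded samples, so hits are counted over a sweep of 21 thresholds
C_t = 0.00, 0.05, …, 1.00:

    H[i, t] = #{ (replicate r, marker p of taxon i) : c_{r,p} > C_t }
    S_i     = Σ_t max(0, H[i, t] − max_{j≠i} H[j, t])

The inequality is strict, so a perfect correlation of 1.0 is not a hit at
C_t = 1.0 (a deliberate, documented edge).  With 5 markers and 3 replicates
the hit ceiling is 15 per threshold.  S_i accumulates taxon i's hit margin
over its best rival across the sweep: large when one taxon dominates at all
thresholds, small for ambiguous or degraded samples, and small when the true
species is not among the candidates.  The label is the arg-max taxon; an
all-zero surface, an exact tie at the top (behaviour for ties is this
package's convention: unclassified + ambiguous), or a top score below
`min_score` (default 0) yields "unclassified".  Replicate counts other than 3
and unequal marker-set sizes are supported (the latter with a warning, since
raw hit counts are then not directly comparable).  The full score surface is
always reported so users can read confidence qualitatively (single-digit
scores are weak; scores of many tens are unambiguous).

## 4. Synthetic data

Real parchment spectra are not distributable with the package, so two
synthetic stand-ins make the pipeline testable end to end:

* **Sequences** (`reference.py`): a synthetic COL1A1/COL1A2 panel for the
  four taxa, collagen-like (Gly-Xaa-Yaa, proline-rich), containing each
  taxon's markers (F1 only via missed cleavage) and engineered so the
  fully-cleaved digests differ by 15 peptides cattle–goat, 14 cattle–sheep
  and 3 sheep–goat — the difference structure of the real panel.  These are
  labelled synthetic throughout and are not usable for classifying real
  samples.
* **Spectra** (`simulate.py`): each replicate sums the non-dropped markers'
  isotope envelopes as Gaussians at (true mass + drift), with per-marker
  amplitude jitter uniform in [0.3, 1] emulating variable peptide
  "flyability", plus a zero-clipped white Gaussian noise floor, on a 0.02 Da
  raw grid (coarser than the analysis grid, so interpolation is genuinely
  exercised), fully reproducible from the seed.

The recovery tests simulate 3 replicates at noise SD 0.05 (relative to unit
peak height), dropout 0.2 per marker per replicate, and a per-run drift drawn
uniformly from ±0.4 Da (inside the ±0.5 Da search with margin), and require
≥95% correct labels over 100 seeded runs plus monotone mean-score degradation
over dropout ∈ {0, 0.3, 0.6, 0.9} (50 seeds each).  What this does **not**
show: robustness to chemical noise, contaminant peaks (keratin, trypsin
autolysis), baseline drift, mass-dependent resolution loss, or real
collagen sequence variation — the simulator models none of these, so passing
tests validate the pipeline's internal consistency, not field performance on
degraded archaeological samples.

## 5. Numerical choices and limitations

* Grids: analysis 0.01 Da; simulation raw grid 0.02 Da; window start rounded
  down to a 0.01 Da multiple so observed and theoretical grids coincide.
* Degenerate inputs: all-zero segments are flagged, never divide by zero;
  windows entirely outside a truncated spectrum score 0 with an
  `out_of_range` flag instead of aborting the batch.
* Only singly protonated ions are modelled — no adducts, charge states ≥ 2,
  or internal fragments.  Hydroxylysine and glycosylation are out of scope.
* Scores are not calibrated probabilities; cross-sample joint inference
  (e.g. over a manuscript's quire structure) is out of scope.
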