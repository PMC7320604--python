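import numpy as np
import pytest

from zoomsid.alignment import align_all, align_variant, cross_correlate
from zoomsid.isotopes import (
    GRID_STEP,
    monoisotopic_mh,
    pattern_for_variant,
    render_template,
)
from zoomsid.markers import peptide_from_sequence
from zoomsid.ptm import PeptideVariant
from zoomsid.spectra import RawSpectrum, ResampledSegment


def _variant(seq="TGQPGAVGPAGIR", nh=0):
    pep = peptide_from_sequence(seq)
    return PeptideVariant(pep, nh, False, 1.0, monoisotopic_mh(seq, nh))


def _template(seq="TGQPGAVGPAGIR", nh=0):
    return render_template(pattern_for_variant(_variant(seq, nh)), sigma=0.1)


def _embed(template, pad=1.0, shift=0.0, scale=1.0):
    """Observed spectrum = template values at (masses + shift), zero-padded."""
    n_pad = int(pad / GRID_STEP)
    masses = (template.start_mass + shift
              + GRID_STEP * np.arange(-n_pad, len(template.values) + n_pad))
    values = np.concatenate(
        [np.zeros(n_pad), scale * template.values, np.zeros(n_pad)])
    return RawSpectrum(masses, values, "1", "s")


def _segment_around(spec, template):
    from zoomsid.spectra import extract_segment

    half = (template.end_mass - template.start_mass) / 2 + 1.0
    return extract_segment(spec, template.midpoint, half)


def oracle_best_lag(segment, template, max_lag=0.5):
    """Independent exhaustive-lag Pearson search, mass-array based."""
    best = (-np.inf, None)
    n = round(max_lag / GRID_STEP)
    tmass = template.masses
    smass = segment.masses
    for k in range(-n, n + 1):
        lag = k * GRID_STEP
        shifted = smass + lag
        # pair template sample i with the shifted observed sample at the
        # same mass, if one exists
        idx = np.rint((tmass - shifted[0]) / GRID_STEP).astype(int)
        ok = (idx >= 0) & (idx < len(smass))
        if ok.sum() <= 1:
            continue
        x = template.values[ok]
        y = segment.values[idx[ok]]
        if x.std() == 0 or y.std() == 0:
            continue
        c = float(np.corrcoef(x, y)[0, 1])
        if c > best[0] + 1e-12:
            best = (c, lag)
    return best


class TestCrossCorrelate:
    def test_self_correlation_is_perfect_at_zero_lag(self):
        t = _template()
        seg = _segment_around(_embed(t), t)
        res = cross_correlate(seg, t)
        assert res.score == pytest.approx(1.0, abs=1e-9)
        assert res.lag == 0.0
        assert not res.flags

    @pytest.mark.parametrize("shift", [0.10, -0.10, 0.30, -0.30])
    def test_recovers_injected_mass_shift(self, shift):
        t = _template()
        seg = _segment_around(_embed(t, shift=shift), t)
        res = cross_correlate(seg, t)
        # the lag is the correction *added* to observed masses
        assert res.lag == pytest.approx(-shift, abs=GRID_STEP / 2)
        assert res.score > 0.999

    def test_equals_exhaustive_lag_oracle_on_random_input(self):
        rng = np.random.default_rng(7)
        t = _template()
        for _ in range(20):
            masses = (t.start_mass
                      + GRID_STEP * np.arange(-100, len(t.values) + 100))
            values = rng.random(masses.size)
            spec = RawSpectrum(masses, values, "1", "s")
            seg = _segment_around(spec, t)
            res = cross_correlate(seg, t)
            oracle_score, _ = oracle_best_lag(seg, t)
            assert res.score == pytest.approx(oracle_score, abs=1e-9)

    def test_best_score_dominates_every_other_lag(self):
        rng = np.random.default_rng(11)
        t = _template()
        masses = t.start_mass + GRID_STEP * np.arange(-80, len(t.values) + 80)
        spec = RawSpectrum(masses, rng.random(masses.size), "1", "s")
        seg = _segment_around(spec, t)
        res = cross_correlate(seg, t)
        offset = round((t.start_mass - seg.start_mass) / GRID_STEP)
        for k in range(-50, 51):
            j0 = offset - k
            lo, hi = max(0, -j0), min(len(t.values), len(seg.values) - j0)
            if hi - lo <= 1:
                continue
            x, y = t.values[lo:hi], seg.values[j0 + lo: j0 + hi]
            if y.std() == 0:
                continue
            assert res.score >= float(np.corrcoef(x, y)[0, 1]) - 1e-9

    def test_invariant_to_affine_intensity_transforms(self):
        t = _template()
        rng = np.random.default_rng(3)
        masses = t.start_mass + GRID_STEP * np.arange(-60, len(t.values) + 60)
        base = rng.random(masses.size)
        res1 = cross_correlate(
            _segment_around(RawSpectrum(masses, base, "1", "s"), t), t)
        res2 = cross_correlate(
            _segment_around(RawSpectrum(masses, 5.0 * base + 2.0, "1", "s"), t), t)
        assert res1.score == pytest.approx(res2.score, abs=1e-9)
        assert res1.lag == res2.lag

    def test_uniform_noise_rarely_correlates_well(self):
        t = _template()
        masses = t.start_mass + GRID_STEP * np.arange(-60, len(t.values) + 60)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            spec = RawSpectrum(masses, rng.uniform(size=masses.size), "1", "s")
            res = cross_correlate(_segment_around(spec, t), t)
            assert res.score < 0.5

    def test_zero_variance_window_is_flagged(self):
        t = _template()
        seg = ResampledSegment(t.start_mass, np.full(len(t.values), 0.7))
        res = cross_correlate(seg, t)
        assert res.score == 0.0 and "zero_variance" in res.flags

    def test_low_overlap_is_flagged(self):
        t = _template()
        short = ResampledSegment(t.start_mass, t.values[: len(t.values) // 4].copy())
        res = cross_correlate(short, t)
        assert "low_overlap" in res.flags


class TestAlignAll:
    def test_one_row_per_replicate_marker_pair(self, marker_table):
        from zoomsid.simulate import (
            SimulationConfig, markers_for_simulation, simulate_replicates)

        cfg = SimulationConfig(
            taxon="Ovis",
            markers=markers_for_simulation(marker_table, "Ovis"),
            seed=1,
        )
        reps = simulate_replicates(cfg)
        table = align_all(reps, marker_table)
        assert len(table) == 3 * len(marker_table.rows)
        for taxon in marker_table.taxa:
            assert (table.taxon == taxon).sum() == 15  # 3 replicates x 5 markers

    def test_empty_replicate_list_gives_empty_table(self, marker_table):
        table = align_all([], marker_table)
        assert len(table) == 0
        assert "score" in table.columns

    def test_out_of_range_marker_scores_zero_without_aborting(self, marker_table):
        # replicate truncated below the G markers: those alignments are
        # flagged, the rest are still scored
        masses = np.arange(1100.0, 1400.0, 0.02)
        rng = np.random.default_rng(5)
        spec = RawSpectrum(masses, rng.uniform(size=masses.size), "1", "s")
        table = align_all([spec], marker_table)
        g_rows = table[table.marker_code.isin(["G1", "G2"])]
        assert (g_rows.score == 0.0).all()
        assert (g_rows["flags"] == "out_of_range").all()
        a_rows = table[table.marker_code == "A1"]
        assert (a_rows["flags"] == "").all()
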