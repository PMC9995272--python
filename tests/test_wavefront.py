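import numpy as np
import pytest

from polwave import wavefront as wf
from polwave.errors import ConfigError, FitError
from polwave.models import GeneModel, OccupancyTrack


def _gene(gid, start, length, strand="+", biotype="protein_coding"):
    return GeneModel(gid, "chrS", start, start + length, strand, biotype)


class TestSelection:
    def test_strict_length_bounds(self):
        lengths_kb = [50, 60, 100, 300, 299]
        genes = [
            _gene(f"g{i}", i * 400_000, kb * 1000) for i, kb in enumerate(lengths_kb)
        ]
        kept = {g.length for g in wf.select_rate_genes(genes)}
        assert kept == {100_000, 299_000}

    def test_overlap_excludes_both_partners(self):
        a = _gene("a", 0, 100_000)
        b = _gene("b", 50_000, 10_000, strand="-")
        c = _gene("c", 500_000, 100_000)
        assert [g.gene_id for g in wf.select_rate_genes([a, b, c])] == ["c"]

    def test_non_coding_excluded_and_empty_ok(self):
        g = _gene("nc", 0, 100_000, biotype="lincRNA")
        assert wf.select_rate_genes([g]) == []
        assert wf.select_rate_genes([]) == []


def _uniform_tracks(gene_values, length=2_000):
    """One track where each gene has constant coverage; genes tiled on +."""
    genes, arrays = [], []
    contig = np.zeros(len(gene_values) * (length + 100) + 100)
    for i, v in enumerate(gene_values):
        start = 100 + i * (length + 100)
        contig[start:start + length] = v
        genes.append(_gene(f"g{i}", start, length))
    tr = OccupancyTrack("s", assay="ttseq", counts={("chrS", "+"): contig})
    tr.recompute_library_size()
    return genes, tr


class TestMetagene:
    def test_trimmed_mean_definition(self):
        genes, tr = _uniform_tracks([0, 1, 2, 3, 100])
        prof = wf.metagene([tr], genes, region_kb=1.0, trim_fraction=0.2)
        np.testing.assert_allclose(prof.raw, 2.0)

    def test_trim_zero_is_plain_mean(self):
        genes, tr = _uniform_tracks([0, 1, 2, 3, 100])
        prof = wf.metagene([tr], genes, region_kb=1.0, trim_fraction=0.0)
        np.testing.assert_allclose(prof.raw, np.mean([0, 1, 2, 3, 100]))

    def test_identical_genes_reproduce_the_track(self):
        genes, tr = _uniform_tracks([7, 7, 7])
        prof = wf.metagene([tr], genes, region_kb=1.0)
        np.testing.assert_allclose(prof.raw, 7.0)
        assert prof.n_genes == 3

    def test_bad_trim_fraction(self):
        genes, tr = _uniform_tracks([1, 2])
        with pytest.raises(ConfigError):
            wf.metagene([tr], genes, region_kb=1.0, trim_fraction=0.5)


def _profile(raw, timepoint, grid_bp=100):
    offsets = np.arange(raw.size) * grid_bp + grid_bp / 2.0
    return wf.MetageneProfile(offsets, raw, timepoint, 1)


def _peaked_profile(center_kb, timepoint, n=800, sd_kb=2.0):
    x = (np.arange(n) * 100 + 50) / 1000.0
    return _profile(np.exp(-0.5 * ((x - center_kb) / sd_kb) ** 2), timepoint)


class TestSmoothing:
    def test_clean_peak_position_preserved(self):
        prof = _peaked_profile(20.0, 10.0)
        sm = wf.smooth_profile(prof)
        assert abs(prof.offsets[np.argmax(sm.smooth)] - prof.offsets[np.argmax(prof.raw)]) <= 100

    def test_strong_smoothing_contracts_white_noise(self):
        rng = np.random.default_rng(1)
        prof = _profile(rng.normal(5, 1, 500), 0.0)
        sm = wf.smooth_profile(prof, lam=1e12)
        assert np.var(sm.smooth) < np.var(prof.raw)

    def test_constant_profile_smooths_to_itself(self):
        prof = _profile(np.full(50, 3.0), 0.0)
        sm = wf.smooth_profile(prof)
        np.testing.assert_allclose(sm.smooth, 3.0)

    def test_noisy_wave_at_20kb_located_within_1kb(self):
        rng = np.random.default_rng(2)
        prof = _peaked_profile(20.0, 10.0)
        prof = _profile(prof.raw + rng.normal(0, 0.05, prof.raw.size), 10.0)
        sm = wf.smooth_profile(prof)
        peak = sm.offsets[np.nanargmax(sm.smooth)] / 1000.0
        assert abs(peak - 20.0) <= 1.0


class TestPeakCalling:
    def test_monotone_series_accepted(self):
        profs = [
            _peaked_profile(0.05, 0.0, sd_kb=0.2),
            _peaked_profile(22.0, 10.0),
            _peaked_profile(44.0, 20.0),
            _peaked_profile(66.0, 30.0),
        ]
        series = wf.call_wave_peaks(profs)
        assert series.accepted
        peaks = series.peaks()
        assert peaks[10.0] == pytest.approx(22.0, abs=0.2)
        offs = [p for _t, p in series.entries]
        assert offs == sorted(offs)

    def test_regressing_peak_flagged_non_advancing(self):
        profs = [
            _peaked_profile(0.05, 0.0, sd_kb=0.2),
            _peaked_profile(22.0, 10.0),
            _peaked_profile(21.0, 20.0),
        ]
        series = wf.call_wave_peaks(profs, constrain=False)
        assert not series.accepted and series.reason == "non-advancing"

    def test_single_timepoint_not_rate_fittable(self):
        series = wf.call_wave_peaks([_peaked_profile(22.0, 10.0)])
        assert len(series.entries) == 1
        with pytest.raises(FitError):
            wf.fit_rate(series)


class TestRateFit:
    def test_collinear_worked_example(self):
        series = wf.series_from_peaks([(10, 22), (20, 44), (30, 66)])
        fit = wf.fit_rate(series)
        assert fit.rate_kb_min == pytest.approx(2.2, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_per_timepoint_rates(self):
        series = wf.series_from_peaks([(10, 20), (20, 40)])
        fit = wf.fit_rate(series)
        assert fit.rate_kb_min == pytest.approx(2.0)
        assert fit.per_timepoint_rates == {10.0: 2.0, 20.0: 2.0}

    def test_scale_invariance_of_rate(self):
        """Scaling every track (or renormalizing spikes) moves profile heights,
        not argmax positions, so the fitted rate is unchanged."""
        profs = [
            _peaked_profile(0.05, 0.0, sd_kb=0.2),
            _peaked_profile(20.0, 10.0),
            _peaked_profile(40.0, 20.0),
        ]
        scaled = [
            wf.MetageneProfile(p.offsets, p.raw * 17.3, p.timepoint_min, 1)
            for p in profs
        ]
        f1 = wf.fit_rate(wf.call_wave_peaks(profs))
        f2 = wf.fit_rate(wf.call_wave_peaks(scaled))
        assert f1.rate_kb_min == f2.rate_kb_min


class TestPerGeneFilters:
    def _series(self, peaks):
        return wf.series_from_peaks(peaks, scope="g")

    def test_expression_boundary_strict(self):
        s = self._series([(0, 0.05), (10, 18), (20, 39), (30, 61)])
        assert not wf.per_gene_rate_filters(99.0, s).expression
        assert not wf.per_gene_rate_filters(100.0, s).expression
        assert wf.per_gene_rate_filters(100.5, s).expression

    def test_anchoring_at_10kb(self):
        good = self._series([(0, 0.05), (10, 18), (20, 39), (30, 61)])
        far = self._series([(0, 12.0), (10, 18), (20, 39), (30, 61)])
        assert wf.per_gene_rate_filters(200, good).anchored
        assert not wf.per_gene_rate_filters(200, far).anchored

    def test_monotone_chain(self):
        good = self._series([(0, 0.05), (10, 18), (20, 39), (30, 61)])
        bad = self._series([(0, 0.05), (10, 22), (20, 21), (30, 61)])
        assert wf.per_gene_rate_filters(200, good).monotone
        assert wf.per_gene_rate_filters(200, good).eligible
        assert not wf.per_gene_rate_filters(200, bad).monotone

    def test_eligible_count_monotone_in_rpm_threshold(self):
        s = self._series([(0, 0.05), (10, 18), (20, 39), (30, 61)])
        rpms = [10, 50, 120, 500, 1000]
        counts = [
            sum(wf.per_gene_rate_filters(r, s, rpm_min=thr).eligible for r in rpms)
            for thr in (0, 100, 400, 2000)
        ]
        assert counts == sorted(counts, reverse=True)
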