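import hashlib

import numpy as np
import pytest

import polwave as pw
from polwave import io as gio
from polwave.errors import ConfigError, DataError
from polwave.normalize import window_density
from polwave.sim import expected_promoter_decay


def _noiseless(**kw):
    base = dict(noise="none", replicate_jitter_sd=0.0, replicates=1, dispersion=0.0)
    base.update(kw)
    return pw.SimConfig(**base)


class TestGenome:
    def test_empty_cohort(self):
        genes, truth = pw.simulate_genome(pw.SimConfig(n_genes=0))
        assert genes == [] and truth.empty

    def test_placement_nonoverlapping_lengths_in_range(self):
        cfg = pw.SimConfig(n_genes=2, gene_length_range=(60_000, 300_000),
                           intergenic_gap=10_000, seed=1)
        genes, _ = pw.simulate_genome(cfg)
        assert len(genes) == 2
        a, b = sorted(genes, key=lambda g: g.start)
        assert a.end + 10_000 <= b.start
        for g in genes:
            assert 60_000 <= g.length <= 300_000
        assert {g.strand for g in genes} == {"+", "-"}

    def test_seed_determinism_byte_identical_truth(self):
        cfg = pw.SimConfig(n_genes=200, gene_length_range=(5_000, 9_000), seed=7)
        _, t1 = pw.simulate_genome(cfg)
        _, t2 = pw.simulate_genome(cfg)
        assert t1.to_csv() == t2.to_csv()

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ConfigError):
            pw.simulate_genome(pw.SimConfig(gene_length_range=(300, 300)))

    def test_missing_truth_record_names_gene(self):
        cfg = _noiseless(n_genes=2, gene_length_range=(2_000, 3_000))
        genes, truth = pw.simulate_genome(cfg)
        with pytest.raises(DataError, match=genes[1].gene_id):
            pw.simulate_triptolide_timecourse(genes, truth.iloc[:1], cfg)


class TestInitiationBlock:
    def test_promoter_decay_matches_closed_form(self):
        """Expected promoter density at time t over t=0 is exp(-ln2 t/h)."""
        cfg = _noiseless(n_genes=4, gene_length_range=(2_000, 4_000), seed=2)
        genes, truth = pw.simulate_genome(cfg)
        tracks = pw.simulate_triptolide_timecourse(genes, truth, cfg)
        by_t = {tr.timepoint_min: tr for tr in tracks}
        for g in genes:
            h = float(truth.set_index("gene_id").loc[g.gene_id, "half_life_min"])
            d0 = window_density(by_t[0.0], g, 0, 300)
            for t in (5.0, 10.0, 20.0, 40.0):
                assert window_density(by_t[t], g, 0, 300) / d0 == pytest.approx(
                    expected_promoter_decay(t, h), rel=1e-12
                )

    def test_half_life_5_gives_2_pow_8_at_40min(self):
        cfg = _noiseless(n_genes=1, gene_length_range=(2_000, 4_000), seed=2)
        genes, truth = pw.simulate_genome(cfg)
        truth = pw.uniform_truth(truth, half_life_min=5.0)
        tracks = pw.simulate_triptolide_timecourse(genes, truth, cfg)
        by_t = {tr.timepoint_min: tr for tr in tracks}
        ratio = (window_density(by_t[40.0], genes[0], 0, 300)
                 / window_density(by_t[0.0], genes[0], 0, 300))
        assert ratio == pytest.approx(2.0 ** -8, rel=1e-12)

    def test_body_signal_unchanged_by_block(self):
        cfg = _noiseless(n_genes=2, gene_length_range=(4_000, 6_000), seed=2)
        genes, truth = pw.simulate_genome(cfg)
        tracks = pw.simulate_triptolide_timecourse(genes, truth, cfg)
        by_t = {tr.timepoint_min: tr for tr in tracks}
        g = genes[0]
        b0 = window_density(by_t[0.0], g, 300, g.length)
        b40 = window_density(by_t[40.0], g, 300, g.length)
        assert b40 == pytest.approx(b0, rel=1e-12)


class TestRelease:
    def test_front_support_is_v_times_t(self):
        """v=2 kb/min, t=10, label=10 -> labeled support ~ [0, 20 kb]."""
        cfg = _noiseless(n_genes=2, gene_length_range=(60_000, 61_000), seed=4,
                         timepoints_drb=(0.0, 10.0), front_pulse=0.0,
                         velocity_sd_within=0.0, front_sd=0.05)
        genes, truth = pw.simulate_genome(cfg)
        truth = pw.uniform_truth(truth, velocity_kb_min=2.0)
        tracks = pw.simulate_drb_release(genes, truth, cfg)
        tr = next(t for t in tracks if t.timepoint_min == 10.0)
        g = genes[0]
        inside = tr.window_values(g, 1_000, 19_000)
        beyond = tr.window_values(g, 21_000, 40_000)
        body = float(truth.set_index("gene_id").loc[g.gene_id, "body_level"])
        assert inside.min() > 0.9 * body
        assert beyond.max() < 1e-6 * body

    def test_no_body_signal_before_release(self):
        cfg = _noiseless(n_genes=2, gene_length_range=(60_000, 61_000), seed=4,
                         timepoints_drb=(0.0, 10.0))
        genes, truth = pw.simulate_genome(cfg)
        tracks = pw.simulate_drb_release(genes, truth, cfg)
        t0 = next(t for t in tracks if t.timepoint_min == 0.0)
        assert t0.window_values(genes[0], 2_000, 50_000).max() < 1e-6

    def test_max_gradient_sits_at_front(self):
        """With a vanishing edge sd and no front pulse, the steepest coverage
        drop at release time t is at v*t, within one base."""
        cfg = _noiseless(n_genes=2, gene_length_range=(80_000, 81_000), seed=4,
                         timepoints_drb=(0.0, 20.0), front_pulse=0.0,
                         velocity_sd_within=0.0, front_sd=0.002)
        genes, truth = pw.simulate_genome(cfg)
        truth = pw.uniform_truth(truth, velocity_kb_min=3.0)
        tracks = pw.simulate_drb_release(genes, truth, cfg)
        tr = next(t for t in tracks if t.timepoint_min == 20.0)
        vals = tr.window_values(genes[0], 0, 70_000)
        front = int(np.argmin(np.diff(vals)))
        assert abs(front - 60_000) <= 1

    def test_label_duration_must_be_positive(self):
        cfg = _noiseless(n_genes=1, gene_length_range=(60_000, 61_000),
                         label_duration=0.0)
        genes, truth = pw.simulate_genome(cfg)
        with pytest.raises(ConfigError, match="label_duration"):
            pw.simulate_drb_release(genes, truth, cfg)


class TestFixture:
    def _cohort(self):
        cfg = pw.SimConfig(n_genes=4, gene_length_range=(3_000, 6_000), seed=9,
                           timepoints_triptolide=(0.0, 5.0), replicates=2)
        genes, truth = pw.simulate_genome(cfg)
        tracks = pw.simulate_triptolide_timecourse(genes, truth, cfg)
        return genes, truth, tracks

    def test_roundtrip_through_io(self, tmp_path):
        genes, truth, tracks = self._cohort()
        pw.write_fixture(tmp_path / "fx", genes, truth, tracks)
        genes2, truth2, tracks2 = gio.read_fixture(tmp_path / "fx")
        assert [(g.gene_id, g.start, g.end, g.strand) for g in genes2] == [
            (g.gene_id, g.start, g.end, g.strand) for g in genes
        ]
        by_id = {t.sample_id: t for t in tracks2}
        for tr in tracks:
            back = by_id[tr.sample_id]
            assert back.spike_count == tr.spike_count
            for key, arr in tr.counts.items():
                got = back.counts.get(key, np.zeros(0))
                n = max(arr.size, got.size)
                assert np.array_equal(np.pad(got, (0, n - got.size)),
                                      np.pad(arr, (0, n - arr.size)))

    def test_empty_track_list_gives_header_only_sheet(self, tmp_path):
        genes, truth, _ = self._cohort()
        pw.write_fixture(tmp_path / "fx", genes, truth, [])
        lines = (tmp_path / "fx" / "samples.tsv").read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("sample\t")

    def test_fixture_checksum_stable_across_runs(self, tmp_path):
        digests = []
        for run in ("a", "b"):
            genes, truth, tracks = self._cohort()
            out = pw.write_fixture(tmp_path / run, genes, truth, tracks)
            h = hashlib.sha256()
            for p in sorted(out.rglob("*")):
                if p.is_file():
                    h.update(p.relative_to(out).as_posix().encode())
                    h.update(p.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]
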