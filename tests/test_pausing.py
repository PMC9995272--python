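import itertools

import numpy as np
import pytest

from polwave.errors import ComparisonError
from polwave.models import GeneModel, OccupancyTrack
from polwave.pausing import (
    PausingRecord,
    compare_index_distributions,
    pausing_index,
    pausing_index_table,
)


def _track_from(values, strand="+", sid="s"):
    arr = np.asarray(values, dtype=float)
    counts = {("chrS", strand): arr if strand == "+" else arr[::-1].copy()}
    tr = OccupancyTrack(sid, counts=counts)
    tr.recompute_library_size()
    return tr


def _gene(n, strand="+"):
    return GeneModel("g", "chrS", 100, 100 + n, strand)


def _shift(vals):
    # place gene at 100 so the -50 promoter offset stays on the contig
    return np.concatenate([np.zeros(100), vals])


class TestPausingIndex:
    def test_ratio_of_densities(self):
        vals = np.zeros(2000)
        vals[:300] = 10.0
        vals[300:] = 2.0
        rec = pausing_index(_track_from(_shift(vals)), _gene(2000),
                            promoter_window=(0, 300))
        assert rec.pausing_index == pytest.approx(5.0)

    def test_uniform_track_gives_index_one(self):
        rec = pausing_index(_track_from(_shift(np.full(5000, 3.0))), _gene(5000),
                            promoter_window=(0, 300))
        assert rec.pausing_index == pytest.approx(1.0)

    def test_zero_body_flagged_undefined(self):
        vals = np.zeros(2000)
        vals[:300] = 4.0
        rec = pausing_index(_track_from(_shift(vals)), _gene(2000))
        assert not rec.defined and np.isnan(rec.pausing_index)

    def test_short_gene_skipped_not_raised(self):
        rec = pausing_index(_track_from(_shift(np.ones(200))), _gene(200))
        assert rec.skipped and not rec.defined

    def test_equals_bruteforce_and_scale_invariance(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(1000, 3000))
            vals = rng.integers(0, 12, n).astype(float)
            strand = rng.choice(["+", "-"])
            if strand == "+":
                contig = np.concatenate([np.zeros(100), vals])
                gene = GeneModel("g", "chrS", 100, 100 + n, "+")
            else:
                contig = np.concatenate([vals[::-1], np.zeros(100)])
                gene = GeneModel("g", "chrS", 0, n, "-")
            tr = OccupancyTrack("s", counts={("chrS", strand): contig})
            rec = pausing_index(tr, gene, promoter_window=(0, 300))
            prom = sum(vals[:300]) / 300
            body = sum(vals[300:]) / (n - 300)
            assert rec.promoter_density == prom
            assert rec.body_density == body
            if body > 0:
                assert rec.pausing_index == prom / body
                tr3 = _track_from(_shift(vals * 3.7), strand)
                rec3 = pausing_index(tr3, gene, promoter_window=(0, 300))
                assert rec3.pausing_index == pytest.approx(rec.pausing_index, rel=1e-12)


class TestTable:
    def test_ecdf_steps(self):
        genes, arrays = [], {}
        contig = np.zeros(100 + 3 * 3000)
        for i, idx in enumerate([1, 2, 4]):
            start = 100 + i * 3000
            contig[start:start + 300] = idx * 2.0
            contig[start + 300:start + 2000] = 2.0
            genes.append(GeneModel(f"g{i}", "chrS", start, start + 2000, "+"))
        tr = _track_from(contig)
        records, (vals, cdf) = pausing_index_table(tr, genes, promoter_window=(0, 300))
        np.testing.assert_allclose(10 ** vals, [1, 2, 4])
        np.testing.assert_allclose(cdf, [1 / 3, 2 / 3, 1.0])
        records2, _ = pausing_index_table(tr, genes, promoter_window=(0, 300))
        assert [r.pausing_index for r in records] == [r.pausing_index for r in records2]

    def test_doubling_promoter_amplitude_doubles_every_index(self):
        rng = np.random.default_rng(5)
        n = 4000
        base = rng.integers(1, 10, n).astype(float)
        doubled = base.copy()
        doubled[:300] *= 2
        gene = _gene(n)
        r1 = pausing_index(_track_from(_shift(base)), gene, promoter_window=(0, 300))
        r2 = pausing_index(_track_from(_shift(doubled)), gene, promoter_window=(0, 300))
        assert r2.pausing_index == pytest.approx(2 * r1.pausing_index, rel=1e-12)


def _records(indices, sid="a"):
    return [
        PausingRecord(f"g{i}", sid, np.nan, np.nan, x, defined=True)
        for i, x in enumerate(indices)
    ]


class TestComparison:
    def test_identical_sets_give_p_one(self):
        idx = np.linspace(1, 5, 40)
        stat, p = compare_index_distributions(_records(idx), _records(idx, "b"))
        assert p == 1.0

    def test_large_shift_gives_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(0, 0.3, 100)
        stat, p = compare_index_distributions(_records(a), _records(a * 100, "b"))
        assert p < 1e-10

    def test_small_sample_matches_rank_enumeration(self):
        """n=2 vs n=2 exact p equals brute-force enumeration of rank splits."""
        a, b = [1.0, 2.0], [3.0, 4.0]
        _stat, p = compare_index_distributions(_records(a), _records(b, "b"))
        # enumerate all assignments of ranks {1..4} to group a
        pooled = np.log(np.array(a + b))
        obs = pooled[:2].sum()
        sums = [sum(pooled[list(c)]) for c in itertools.combinations(range(4), 2)]
        obs_rank = sum(np.sort(pooled)[:2])  # most extreme low sum
        more_extreme = sum(
            1 for s in sums
            if abs(s - np.mean(sums)) >= abs(obs - np.mean(sums)) - 1e-12
        )
        assert p == pytest.approx(more_extreme / len(sums))

    def test_disjoint_universes_error(self):
        with pytest.raises(ComparisonError):
            compare_index_distributions(_records([1, 2]), _records([1, 2], "b")[2:])


class TestOnSimulatedTimecourse:
    def test_median_index_non_increasing_as_pause_decays(self, tiny_cohort):
        """When only the promoter pool decays after the initiation block, the
        median pausing index can only fall with time."""
        _cfg, genes, _truth, tracks = tiny_cohort
        medians = []
        for t in (0.0, 10.0, 40.0):
            tr = next(x for x in tracks if x.timepoint_min == t and x.replicate == 1)
            records, _ = pausing_index_table(tr, genes)
            medians.append(np.median([r.pausing_index for r in records if r.defined]))
        assert medians[0] >= medians[1] >= medians[2]
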