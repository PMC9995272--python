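import numpy as np
import pytest

import polwave as pw
from polwave import halflife as hl


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small noisy triptolide cohort for unit-level checks."""
    cfg = pw.SimConfig(n_genes=24, gene_length_range=(5_000, 12_000), seed=3)
    genes, truth = pw.simulate_genome(cfg)
    tracks = pw.simulate_triptolide_timecourse(genes, truth, cfg)
    pw.apply_scale_factors(tracks, pw.spikein_scale_factors(tracks, tracks[0].sample_id))
    return cfg, genes, truth, tracks


@pytest.fixture(scope="session")
def halflife_cohort():
    """Study-scale triptolide cohort: 300 genes, 2 replicates, ~100 expected
    promoter counts at t=0, NB dispersion 0.1."""
    cfg = pw.SimConfig(n_genes=300, gene_length_range=(10_000, 40_000), seed=0)
    genes, truth = pw.simulate_genome(cfg)
    tracks = pw.simulate_triptolide_timecourse(genes, truth, cfg)
    pw.apply_scale_factors(tracks, pw.spikein_scale_factors(tracks, tracks[0].sample_id))
    fits = hl.fit_cohort(tracks, genes)
    return genes, truth, fits


@pytest.fixture(scope="session")
def drb_cohort():
    """Study-scale release cohort: 200 genes 60-300 kb, velocities uniform in
    [1, 4] kb/min, release sampled at 0/10/20/30 min, front sd 2 kb."""
    cfg = pw.SimConfig(n_genes=200, seed=0)
    genes, truth = pw.simulate_genome(cfg)
    tracks = pw.simulate_drb_release(genes, truth, cfg)
    pw.apply_scale_factors(tracks, pw.spikein_scale_factors(tracks, tracks[0].sample_id))
    res = pw.wave_rate_analysis(tracks, genes)
    return genes, truth, res


def make_timecourse(times, dens, gene_id="g", rpkm0=10.0, condition="control"):
    return hl.TimeCourse(gene_id, np.asarray(times, float), np.asarray(dens, float),
                         rpkm0, condition)
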