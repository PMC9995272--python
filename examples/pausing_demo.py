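"""Pausing-index distributions and their comparison between conditions.

The pausing index is promoter-window density over gene-body density; the
demo doubles every gene's promoter amplitude to mimic a global pausing
increase and compares the two index distributions with a two-sided
rank-sum test.
"""

import numpy as np

import polwave as pw
from polwave.pausing import compare_index_distributions, pausing_index_table

cfg = pw.SimConfig(n_genes=80, gene_length_range=(8_000, 20_000), seed=42,
                   timepoints_triptolide=(0.0,), replicates=1,
                   replicate_jitter_sd=0.0)
genes, truth = pw.simulate_genome(cfg)
(track,) = pw.simulate_triptolide_timecourse(genes, truth, cfg)

more_paused = pw.uniform_truth(truth, pause_amplitude=2 * truth["pause_amplitude"])
cfg2 = pw.SimConfig(**{**cfg.__dict__, "seed": 43})
(track2,) = pw.simulate_triptolide_timecourse(genes, more_paused, cfg2)

rec_a, (vals_a, _) = pausing_index_table(track, genes)
rec_b, (vals_b, _) = pausing_index_table(track2, genes)
med_a = np.median([r.pausing_index for r in rec_a if r.defined])
med_b = np.median([r.pausing_index for r in rec_b if r.defined])
stat, p = compare_index_distributions(rec_a, rec_b)
print(f"median pausing index: baseline {med_a:.2f}, doubled-promoter {med_b:.2f}")
print(f"rank-sum statistic {stat:.2f}, two-sided p = {p:.3g}")
print("Doubling promoter occupancy should roughly double the median index; a tiny "
      "p-value says the two index distributions differ far beyond sampling noise.")
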