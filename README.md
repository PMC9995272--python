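# polwave

Kinetics of RNA polymerase II (RNAPII) promoter-proximal pausing and
elongation, estimated from strand-specific nascent-transcription coverage
tracks. The package is aimed at genomics analysts working with
mNET-seq-style single-nucleotide 3′-end tracks and TT-seq-style labeled-RNA
coverage from perturbation time courses, and at method developers who need a
fully synthetic benchmark with known ground truth.

## What it computes

- **Pausing index.** For a gene with promoter-proximal density
  `d_p` (strand-aware TSS offsets, default [−50, +300)) and gene-body
  density `d_b` (default [+300, TES)), the index is `PI = d_p / d_b`.
  Distributions are compared between conditions with a two-sided Wilcoxon
  rank-sum test on log indices over a shared gene universe.
- **Paused-RNAPII half-life.** After blocking transcription initiation
  (triptolide-style time course, default 0/5/10/20/40 min), the promoter
  window density decays as `N(t) = N₀·e^(−kt)`; nonlinear least squares
  gives `k` and the half-life `t½ = ln2 / k`. Genes enter cohort summaries
  only if transcript RPKM > 1 at t = 0, the 0-min density is the strict
  maximum, and replicate variability σ < 0.05 (σ computed on t=0-normalized
  densities).
- **Elongation rate.** After release from a reversible CDK9 inhibitor
  (DRB-style, default 0/10/20/30 min with a 10-min 4SU label), labeled
  coverage advances as a wave. Trimmed-mean metagenes (and per-gene
  profiles) are smoothed with a cubic smoothing spline; wave peaks are
  called at the spline maximum with the requirement that peaks advance with
  time; the slope of peak position (kb) vs time (min) is the rate in
  kb/min. Per-gene rates additionally require > 100 rpm expression, a t=0
  peak within 10 kb of the pause region, and strictly monotone peak
  advance.
- **Velocity proxy.** The per-bin ratio of labeled-RNA synthesis to
  polymerase occupancy (TT/mNET) — RNA made per polymerase — as a relative
  elongation velocity.
- **Synthetic data.** `polwave.sim` generates gene models, ground-truth
  kinetics and negative-binomial read noise (with replicates and spike-in
  counts) for both experimental designs, so every stage is testable without
  any external data.

Inputs are BED12/GTF gene models, per-strand bedGraph coverage, and a TSV
sample sheet (sample, assay, condition, timepoint, replicate, spike-in).
Samples are made comparable by spike-in scale factors
`f(s) = spike(ref) / spike(s)`.

## Worked example

`examples/` holds one short script per capability. For instance,

```
python examples/halflife_demo.py
```

simulates a 100-gene initiation-block cohort and prints

```
condition  n  mean_half_life_min  median_half_life_min
  control 74            5.484728              4.471953
median |estimate - truth| / truth over 74 passing genes: 7.0%
```

74 genes survive the three cohort filters; their fitted half-lives average
5.5 min and match the simulator's per-gene truth to a 7% median error.
Similarly `python examples/wave_demo.py` tracks the release wave and prints,
among other lines,

```
worked fit on peaks 22/44/66 kb at 10/20/30 min: 2.2 kb/min, r2=1
```

— a wave advancing 22 kb every 10 min is a 2.2 kb/min elongation rate.

The same analyses run from the shell through a thin CLI
(`polwave all -c run.yaml`, or `polwave validate run.yaml` to check a
configuration); a run writes TSV outputs plus a manifest with the resolved
parameters and output checksums, and identical config + seed reproduce the
manifest byte for byte.

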