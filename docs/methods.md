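# Methods

## Coordinate conventions

Files use the BED/bedGraph dialect (0-based, half-open). Internally every
window is a strand-aware offset from the TSS: offset 0 is the TSS base and
offsets increase in the direction of transcription, so "a 300-bp window
downstream of the TSS" is unambiguously offsets [0, 300) on either strand.
Gene models are transcription units — one interval per gene (GTF input is
unioned over exon records per `gene_id`).

## Normalization

Between-sample comparability comes from exogenous spike-in totals:
`factor(s) = spike(reference) / spike(s)`, with the untreated / 0-min sample
as reference (the choice only rescales all outputs jointly). RPKM (used for
the expression filter) deliberately uses the sample's own library size, not
spike factors, matching the filter's standard definition; spike scaling is
applied to per-base densities everywhere else.

## Pausing index

`PI = mean density over promoter offsets [−50, +300) / mean density over
[+300, gene end)`. The promoter/body windows are configurable and recorded
in output metadata; defaults follow common practice since the exact windows
behind published indices vary. Zero-body genes are flagged undefined and
dropped from both sides of a comparison (keeping a paired universe); indices
are summarized on the log scale. The rank-sum comparison uses the exact
null distribution for small untied samples and the asymptotic normal
approximation otherwise (which reports exactly p = 1 for identical inputs).
ChIP-seq-based and mNET-seq-based indices share one code path; the sample
sheet's assay column only selects the input track.

## Half-life from initiation-block time courses

Replicate promoter-window densities are averaged per timepoint, normalized
to 1 at t = 0, and fitted to `N(t) = n0·exp(−k t)` by bounded nonlinear
least squares (`n0 ≥ 0`, `k ∈ [1e−6, 100] /min`), initialized from a
log-linear pre-fit so the procedure is deterministic. `t½ = ln2/k`. A pure
single exponential is used — with five timepoints a plateau term is not
identifiable. Courses that never drop below their 0-min level drive `k` to
its lower bound and are flagged degenerate rather than reported.

Cohort filters (all strict inequalities, evaluated independently):
transcript RPKM > 1 at t = 0; 0-min replicate-mean density strictly maximal
over the course; replicate σ < 0.05, where σ is the mean over timepoints of
the across-replicate standard deviation of densities normalized to the
replicate-mean 0-min level — dimensionless, so the threshold is
depth-independent. A single-replicate course has undefined σ and passes
with a logged caveat. Fitting the replicate mean (rather than all
replicates jointly) is the default; σ is carried as a quality metric.

## Elongation rate from release time courses

Gene selection: protein-coding, length strictly between 60 and 300 kb, no
genomic overlap with any other gene on either strand.

The metagene is a symmetric trimmed mean (default 10% per side) of
spike-scaled, strand-projected coverage per offset bin (default 100 bp),
with replicate tracks pooled after scaling. The metagene is computed over
the genes that span the whole profile region; letting shorter genes drop
out mid-profile changes the gene composition along the x-axis and skews the
apparent wave position.

Smoothing is a cubic smoothing spline. For a single profile the penalty is
chosen by generalized cross-validation (overridable). For per-gene batches
one shared penalty is used, obtained by matching GCV choices on a spread of
sample profiles — per-profile GCV re-optimization at cohort scale costs
~40× a fixed-penalty fit and adds nothing, since the profiles share one
noise regime.

Wave peaks are the spline maxima subject to the advance-with-time rule. Two
search modes exist: the progressive mode starts each timepoint's search
beyond the previous peak plus an exclusion margin (default 2 kb) and is
used for the metagene; the anchored mode always searches beyond the t=0
pausing peak plus the margin, so a stalled or regressing wave is observable
and the series is flagged non-advancing instead of being forced forward.
The anchored mode feeds the per-gene monotone-advance filter (peaks must
strictly increase across 0 < 10 < 20 < 30 min), which would be vacuous
under progressive search. There is no interactive review step; the
advance/anchoring flags replace it.

The rate is the OLS slope of peak position (kb) on time (min). The t=0 wave
peak — the pausing peak, the origin the wave advances from — is included in
the fit by default: the unreleased sample's peak is a genuine point on the
wave trajectory, and anchoring the line there suppresses a systematic
inflation that otherwise arises because the trailing edge of the label
window drags late metagene peaks outward (`include_zero=False` restores a
post-release-only fit). Per-gene outputs also report the mean of
`peak / t` over post-release timepoints, an alternative per-gene rate
definition; summaries use the OLS slope. Per-gene eligibility: > 100 rpm
(whole-gene reads per million, strict) in the 0-min control, t=0 peak
within 10.3 kb of the TSS (10 kb beyond the 300-bp pause window,
configurable), and strictly monotone peak advance.

## Velocity proxy

Gene bodies (offset 300 bp to the TES) are split into 100 equal
strand-aware bins; the per-bin ratio is
`(TT density + ε_t) / (mNET density + ε_m)` with pseudocounts defaulting to
the 5th percentile of that assay's nonzero bin densities. Ratios are
computed per gene first (matching per-gene heat-map semantics — a metagene
of ratios equals the ratio of metagenes only for uniform signal); the
genewise velocity is the median bin ratio. The proxy is relative: only
between-condition comparisons are meaningful.

## Synthetic data generator

One synthetic contig carries non-overlapping genes (alternating strands,
≥10 kb apart). Ground truth per gene: half-life log-uniform 2–15 min,
velocity uniform 1–4 kb/min, promoter amplitude set so the expected
pause-window count at t=0 is ~100 (log-normal gene-to-gene spread), body
level ~0.05 counts/base (log-normal spread). Counts are negative binomial
per base (`var = μ + αμ²`, default dispersion α = 0.1; α = 0 falls back to
Poisson; `noise="none"` emits expected values for exact oracles). A 2%
log-normal per-sample depth wobble is mirrored in the spike-in totals so
normalization can undo it.

Initiation-block tracks: a Gaussian pause peak at TSS+50 (sd 30 bp,
truncated to the 300-bp window — the quantified window is known, the peak
shape is not, and any unimodal shape inside it behaves identically) decays
as `exp(−ln2·t/t½)`; the block is assumed instant and complete, and the
gene-body level is held constant since only the promoter window is fitted.
Half-life cohorts use 10–40 kb genes (a typical protein-coding span; the
60–300 kb regime is only needed for wave analysis, and promoter kinetics do
not depend on gene length).

Release tracks: the labeled interval spans `[v·(t−d), v·t]` kb from the TSS
(label duration d = 10 min), edges smoothed by a Gaussian of sd 2 kb. Two
features beyond the bare labeled boxcar make the simulated waves behave
like the assay's: a released-pause pulse (default 2× body level) rides the
leading edge — the paused polymerases released at washout travel as a
cohort and produce the characteristic wave peak, without which "peak of the
spline" is ill-posed on a flat plateau — and the front broadens with time
as `sqrt(front_sd² + (σ_v·t)²)` with σ_v = 1 kb/min, representing
cell-to-cell velocity spread within a gene (live-imaging estimates of
elongation variability are ~30–50% of the mean). Both default to zero-able
parameters, and the exact front-position invariant (steepest coverage drop
at `v·t`) is tested in the bare-boxcar limit. A residual TSS peak is present
at every timepoint (polymerases initiating during the label window).

What the generator does *not* emulate: upstream antisense/PROMPT
transcription, enhancer RNAs, termination, splicing-coupled coverage
structure, read-level artifacts (mappability, PCR duplicates), or
transcription units with isoform heterogeneity. Passing tests therefore
demonstrate correctness of the estimators under the modeled signal and
noise structure, not robustness to every artifact of real libraries.

## Problem sizes and numerical choices

The validation cohorts are 300 genes × 5 timepoints × 2 replicates for
half-life recovery and 200 genes × 4 timepoints × 2 replicates for rate
recovery — large enough that median recovery errors are stable (~6–10%)
while a full run stays interactive. Ties in the pause-window argmax cannot
occur with continuous splines on distinct bins; ties in rank tests are
handled by the asymptotic method. Degenerate inputs (empty gene lists,
constant profiles, single replicates, genes shorter than the body offset)
return flagged records or empty outputs rather than raising, except where a
computation is genuinely impossible (zero t=0 density, zero spike counts,
incomplete time courses), which raise typed errors naming the offender.

## Known limitations

- The decay model ignores initiation re-entry and premature termination;
  estimated half-lives are effective pause residence times.
- Wave-peak rates are biased low for genes whose wave runs off the gene end
  within the time course (fast genes near the 60-kb floor); such genes
  usually fail the monotone-advance filter and drop out.
- The velocity proxy has no absolute calibration to kb/min.
- Antisense-bias and cross-contamination corrections for labeled-RNA
  protocols are out of scope; spike scaling is the only between-sample
  correction.
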