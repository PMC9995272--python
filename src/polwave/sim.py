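"""Synthetic nascent-transcription data with known kinetic ground truth.

Two perturbation designs are emulated on one synthetic contig:

* **Initiation-block time course** (triptolide-like): mNET-seq-style
  single-nucleotide 3'-end tracks in which the promoter-proximal pause peak
  decays exponentially, ``amplitude * exp(-ln2 * t / half_life)``, while the
  gene-body signal stays constant.  This is the signal the half-life module
  fits.

* **CDK9-inhibitor release** (DRB-like): TT-seq-style labeled-RNA coverage
  advancing as a wave.  At release time ``t`` with label duration ``d`` the
  labeled interval spans ``[v*(t-d), v*t]`` kb from the TSS.  On top of the
  labeled plateau rides a released-pause pulse at the wave front, and the
  front broadens with time (within-gene, cell-to-cell velocity spread), which
  is what gives real release profiles their clear, widening wave peaks.

Counts are drawn per base from a negative-binomial with a single dispersion
(``var = mu + dispersion * mu**2``); dispersion 0 falls back to Poisson and
``noise="none"`` emits the expected values themselves (useful for exact
oracles).  Per-sample depth wobble (default 2 % log-normal) is mirrored in
the spike-in totals so spike normalization can undo it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import ConfigError, DataError
from .models import GeneModel, OccupancyTrack

# Pause-peak shape: Gaussian at TSS+50, sd 30 bp, truncated to the 300-bp
# quantification window.  Any unimodal shape inside the window would do; this
# one puts the summit where engaged polymerases typically sit.
PAUSE_CENTER = 50
PAUSE_SD = 30
PAUSE_WINDOW = 300

TRUTH_COLUMNS = [
    "gene_id",
    "half_life_min",
    "velocity_kb_min",
    "pause_amplitude",
    "body_level",
    "dispersion",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror the perturbation designs the analyses expect: initiation
    block sampled at 0/5/10/20/40 min, release sampled at 0/10/20/30 min with
    a 10-min label, two replicates, and gene lengths in the 60-300 kb regime
    used for wave-peak analysis.
    """

    n_genes: int = 300
    gene_length_range: tuple[int, int] = (60_000, 300_000)
    intergenic_gap: int = 10_000
    timepoints_triptolide: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 40.0)
    timepoints_drb: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0)
    label_duration: float = 10.0
    replicates: int = 2
    read_depth: float | None = None
    seed: int = 0

    # ground-truth distributions
    half_life_range: tuple[float, float] = (2.0, 15.0)  # log-uniform, minutes
    velocity_range: tuple[float, float] = (1.0, 4.0)  # uniform, kb/min
    promoter_counts: float = 100.0  # expected pause-window counts at t=0
    body_level: float = 0.05  # expected counts per base in the gene body

    # noise structure
    dispersion: float = 0.1
    noise: str = "nb"  # {"nb", "poisson", "none"}
    replicate_jitter_sd: float = 0.02
    spike_mean: float = 50_000.0

    # wave-front geometry
    front_sd: float = 2.0  # kb; Gaussian smoothing of the labeled edges
    front_pulse: float = 2.0  # released-pause pulse height, x body_level
    velocity_sd_within: float = 1.0  # kb/min; cell-to-cell spread -> front broadening
    drb_pause_amplitude: float = 5.0  # residual TSS peak height, x body_level

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo < hi):
            raise ConfigError(f"invalid gene_length_range {self.gene_length_range}")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        for name, tps in (
            ("timepoints_triptolide", self.timepoints_triptolide),
            ("timepoints_drb", self.timepoints_drb),
        ):
            t = list(tps)
            if t != sorted(t) or len(set(t)) != len(t):
                raise ConfigError(f"{name} must be strictly ascending")
            if not t or t[0] != 0:
                raise ConfigError(f"{name} must start at 0")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.noise not in ("nb", "poisson", "none"):
            raise ConfigError(f"unknown noise model {self.noise!r}")
        if not (0 < self.half_life_range[0] < self.half_life_range[1]):
            raise ConfigError("half_life_range must be positive and increasing")
        if not (0 < self.velocity_range[0] <= self.velocity_range[1]):
            raise ConfigError("velocity_range must be positive")


def validate_truth(truth: pd.DataFrame) -> None:
    """Check the SimTruth invariants: unique gene ids, positive kinetics."""
    if truth.empty:
        return
    if truth["gene_id"].duplicated().any():
        raise DataError("duplicate gene_id in truth table")
    for col in ("half_life_min", "velocity_kb_min"):
        if (truth[col] <= 0).any():
            raise DataError(f"truth column {col} must be strictly positive")
    for col in ("pause_amplitude", "body_level", "dispersion"):
        if (truth[col] < 0).any():
            raise DataError(f"truth column {col} must be non-negative")


def simulate_genome(config: SimConfig) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place non-overlapping genes on one synthetic contig and draw truth.

    Genes alternate strands, are separated by at least ``intergenic_gap`` and
    have lengths uniform in ``gene_length_range``.  Half-lives are log-uniform
    and velocities uniform over their configured ranges.  Deterministic for a
    given seed.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    lo, hi = config.gene_length_range
    genes: list[GeneModel] = []
    rows = []
    cursor = config.intergenic_gap
    width = max(4, len(str(max(config.n_genes, 1))))
    for i in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        strand = "+" if i % 2 == 0 else "-"
        gid = f"G{i + 1:0{width}d}"
        genes.append(GeneModel(gid, "chrS", cursor, cursor + length, strand))
        cursor += length + config.intergenic_gap
        h = np.exp(rng.uniform(np.log(config.half_life_range[0]), np.log(config.half_life_range[1])))
        v = rng.uniform(config.velocity_range[0], config.velocity_range[1])
        amp_scale = np.exp(rng.normal(0.0, 0.25))
        body = config.body_level * np.exp(rng.normal(0.0, 0.4))
        # pause_amplitude is the expected count at the pause summit; scale so
        # the 300-bp window sum matches promoter_counts on average.
        unit_sum = _pause_unit().sum()
        amp = config.promoter_counts * amp_scale / unit_sum
        rows.append((gid, h, v, amp, body, config.dispersion))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    validate_truth(truth)
    return genes, truth


def contig_length(genes: list[GeneModel], gap: int = 10_000) -> int:
    return (max((g.end for g in genes), default=0)) + gap


def _pause_unit(window: int = PAUSE_WINDOW, center: int = PAUSE_CENTER, sd: int = PAUSE_SD) -> np.ndarray:
    off = np.arange(window, dtype=float)
    return np.exp(-0.5 * ((off - center) / sd) ** 2)


def _sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float, noise: str) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    if noise == "none":
        return mean
    if noise == "poisson" or dispersion <= 0:
        return rng.poisson(mean).astype(np.float64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p).astype(np.float64)


def _write_segment(arr: np.ndarray, gene: GeneModel, offset_start: int, vals: np.ndarray) -> None:
    """Add ``vals`` (in transcription order, starting at ``offset_start``) to
    the per-base array."""
    n = vals.size
    if gene.strand == "+":
        a = gene.tss + offset_start
        arr[a:a + n] += vals
    else:
        a = gene.tss - offset_start - n + 1
        arr[a:a + n + 0] += vals[::-1]


def _truth_map(genes: list[GeneModel], truth: pd.DataFrame) -> dict[str, pd.Series]:
    by_id = {row.gene_id: row for row in truth.itertuples(index=False)}
    for g in genes:
        if g.gene_id not in by_id:
            raise DataError(f"no truth record for gene {g.gene_id}")
    return by_id


def _new_track_arrays(genes: list[GeneModel], gap: int) -> dict[tuple[str, str], np.ndarray]:
    n = contig_length(genes, gap)
    return {("chrS", "+"): np.zeros(n), ("chrS", "-"): np.zeros(n)}


def simulate_triptolide_timecourse(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: SimConfig,
    condition: str = "control",
) -> list[OccupancyTrack]:
    """3'-end tracks for an initiation-block time course.

    The promoter pause peak decays as ``exp(-ln2 * t / half_life)``; the gene
    body is held constant (only the promoter window is modeled kinetically,
    since only that window is fitted downstream).
    """
    config.validate()
    by_id = _truth_map(genes, truth)
    rng = np.random.default_rng([config.seed, 23])
    unit = _pause_unit()
    tracks = []
    for t in config.timepoints_triptolide:
        for rep in range(1, config.replicates + 1):
            jitter = float(np.exp(rng.normal(0.0, config.replicate_jitter_sd)))
            arrays = _new_track_arrays(genes, config.intergenic_gap)
            segments = []
            for g in genes:
                tr = by_id[g.gene_id]
                decay = np.exp(-np.log(2.0) * t / tr.half_life_min)
                prom = tr.pause_amplitude * decay * unit
                segments.append((g, 0, prom))
                body_len = g.length - PAUSE_WINDOW
                if body_len > 0:
                    segments.append((g, PAUSE_WINDOW, np.full(body_len, tr.body_level)))
            depth_scale = jitter
            if config.read_depth is not None:
                total = sum(seg.sum() for _, _, seg in segments)
                if total > 0:
                    depth_scale *= config.read_depth / total
            for g, off, seg in segments:
                tr = by_id[g.gene_id]
                counts = _sample(rng, seg * depth_scale, tr.dispersion, config.noise)
                _write_segment(arrays[(g.chrom, g.strand)], g, off, counts)
            track = OccupancyTrack(
                sample_id=f"{condition}_mnet_t{t:g}_r{rep}",
                assay="mnet",
                condition=condition,
                timepoint_min=float(t),
                replicate=rep,
                counts=arrays,
                spike_count=float(max(1, rng.poisson(config.spike_mean * jitter))),
            )
            track.recompute_library_size()
            tracks.append(track)
    return tracks


def simulate_drb_release(
    genes: list[GeneModel],
    truth: pd.DataFrame,
    config: SimConfig,
    condition: str = "control",
) -> list[OccupancyTrack]:
    """Labeled-coverage tracks for a release time course.

    For release time ``t`` and label duration ``d`` the expected coverage of a
    gene with velocity ``v`` is

    * a labeled plateau ``body_level`` over ``[v*(t-d), v*t]`` kb from the TSS
      with edges smoothed by a Gaussian of sd ``front_sd`` kb,
    * a released-pause pulse of height ``front_pulse * body_level`` centred on
      the front at ``v*t``, with sd growing as
      ``sqrt(front_sd**2 + (velocity_sd_within * t)**2)`` (fronts broaden as
      cell-to-cell velocity differences accumulate), and
    * a residual TSS pause peak (present at every timepoint; dominant at t=0,
      when no elapsed transcription has occurred).
    """
    config.validate()
    if config.label_duration <= 0:
        raise ConfigError("label_duration must be > 0")
    by_id = _truth_map(genes, truth)
    rng = np.random.default_rng([config.seed, 37])
    tracks = []
    s0 = config.front_sd * 1000.0
    for t in config.timepoints_drb:
        for rep in range(1, config.replicates + 1):
            jitter = float(np.exp(rng.normal(0.0, config.replicate_jitter_sd)))
            arrays = _new_track_arrays(genes, config.intergenic_gap)
            segments: list[tuple[GeneModel, int, np.ndarray]] = []
            for g in genes:
                tr = by_id[g.gene_id]
                # residual pause peak near the TSS
                pwin = min(600, g.length)
                off = np.arange(pwin, dtype=float)
                pause = (
                    config.drb_pause_amplitude
                    * tr.body_level
                    * np.exp(-0.5 * ((off - PAUSE_CENTER) / 100.0) ** 2)
                )
                segments.append((g, 0, pause))
                if t <= 0:
                    continue
                v_bp = tr.velocity_kb_min * 1000.0
                lo = v_bp * max(0.0, t - config.label_duration)
                hi = v_bp * t
                sp = np.hypot(s0, config.velocity_sd_within * 1000.0 * t)
                a = int(max(0, np.floor(lo - 4 * max(s0, sp))))
                b = int(min(g.length, np.ceil(hi + 4 * max(s0, sp))))
                if b <= a:
                    continue
                x = np.arange(a, b, dtype=float)
                plateau = tr.body_level * (ndtr((hi - x) / s0) - ndtr((lo - x) / s0))
                pulse = (
                    config.front_pulse
                    * tr.body_level
                    * np.exp(-0.5 * ((x - hi) / sp) ** 2)
                )
                segments.append((g, a, plateau + pulse))
            depth_scale = jitter
            if config.read_depth is not None:
                total = sum(seg.sum() for _, _, seg in segments)
                if total > 0:
                    depth_scale *= config.read_depth / total
            for g, off_start, seg in segments:
                tr = by_id[g.gene_id]
                counts = _sample(rng, seg * depth_scale, tr.dispersion, config.noise)
                _write_segment(arrays[(g.chrom, g.strand)], g, off_start, counts)
            track = OccupancyTrack(
                sample_id=f"{condition}_ttseq_t{t:g}_r{rep}",
                assay="ttseq",
                condition=condition,
                timepoint_min=float(t),
                replicate=rep,
                counts=arrays,
                spike_count=float(max(1, rng.poisson(config.spike_mean * jitter))),
            )
            track.recompute_library_size()
            tracks.append(track)
    return tracks


def expected_promoter_decay(t: float, half_life_min: float) -> float:
    """Closed-form expected promoter-density ratio relative to t=0."""
    return float(np.exp(-np.log(2.0) * t / half_life_min))


def write_fixture(outdir, genes: list[GeneModel], truth: pd.DataFrame, tracks: list[OccupancyTrack]):
    """Persist a simulated data set as BED12 + bedGraph pairs + TSVs.

    Layout: ``genes.bed``, ``truth.tsv``, ``samples.tsv`` and
    ``tracks/<sample>.{plus,minus}.bedGraph``.  Files round-trip losslessly
    through the readers in :mod:`polwave.io`.
    """
    from pathlib import Path

    from . import io as gio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_bed12(genes, outdir / "genes.bed")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    rows = []
    for tr in tracks:
        gio.write_bedgraph(tr, trackdir)
        rows.append(
            dict(
                sample=tr.sample_id,
                assay=tr.assay,
                condition=tr.condition,
                timepoint_min=tr.timepoint_min,
                replicate=tr.replicate,
                spike_count=tr.spike_count,
                library_size=tr.library_size,
            )
        )
    sheet = pd.DataFrame(
        rows,
        columns=[
            "sample",
            "assay",
            "condition",
            "timepoint_min",
            "replicate",
            "spike_count",
            "library_size",
        ],
    )
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    return outdir


def uniform_truth(truth: pd.DataFrame, **overrides) -> pd.DataFrame:
    """Return a copy of a truth table with selected columns set to constants
    (e.g. ``half_life_min=5.3``) — handy for cohorts generated at one value."""
    out = truth.copy()
    for col, val in overrides.items():
        if col not in TRUTH_COLUMNS:
            raise ConfigError(f"unknown truth column {col!r}")
        out[col] = val
    return out
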