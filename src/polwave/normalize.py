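"""Spike-in scale factors and the density units shared by every stage.

Samples are made comparable by scaling each one so its exogenous spike-in
total matches the reference sample's: ``factor(s) = spike(ref) / spike(s)``.
The reference is conventionally the untreated / 0-min sample; the choice only
rescales all outputs jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import BoundsError, NormalizationError
from .models import GeneModel, OccupancyTrack


@dataclass(frozen=True)
class ScaleFactorSet:
    factors: dict[str, float]
    reference_sample: str

    def __post_init__(self):
        if self.reference_sample not in self.factors:
            raise NormalizationError(
                f"reference sample {self.reference_sample!r} not among factors"
            )
        if abs(self.factors[self.reference_sample] - 1.0) > 1e-12:
            raise NormalizationError("reference sample factor must be 1")
        for sid, f in self.factors.items():
            if not f > 0:
                raise NormalizationError(f"non-positive factor for sample {sid!r}")

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]


def spikein_scale_factors(tracks: list[OccupancyTrack], reference: str) -> ScaleFactorSet:
    """Per-sample multipliers that equalize spike-in totals across samples."""
    spikes = {}
    for tr in tracks:
        if tr.spike_count is None or tr.spike_count <= 0:
            raise NormalizationError(
                f"sample {tr.sample_id!r} has zero or missing spike_count"
            )
        spikes[tr.sample_id] = tr.spike_count
    if reference not in spikes:
        raise NormalizationError(f"reference sample {reference!r} not in track set")
    ref = spikes[reference]
    return ScaleFactorSet(
        factors={sid: ref / s for sid, s in spikes.items()},
        reference_sample=reference,
    )


def apply_scale_factors(tracks: list[OccupancyTrack], factors: ScaleFactorSet) -> None:
    """Record each sample's factor on its track (``track.scale``), in place."""
    for tr in tracks:
        tr.scale = factors[tr.sample_id]


def window_density(
    track: OccupancyTrack,
    gene: GeneModel,
    offset_start: int,
    offset_end: int,
    unit: str = "per_base",
) -> float:
    """Density over a strand-aware TSS-offset window.

    ``per_base``: spike-scaled count sum divided by window length.
    ``rpkm``: raw count sum per kilobase of window per million library reads
    (the sample's own depth — spike scaling cancels in this unit).
    """
    vals = track.window_values(gene, offset_start, offset_end)
    total = float(vals.sum())
    length = offset_end - offset_start
    if unit == "per_base":
        return track.scale * total / length
    if unit == "rpkm":
        if track.library_size <= 0:
            raise NormalizationError(
                f"sample {track.sample_id!r} has no library_size; cannot compute rpkm"
            )
        return total / ((length / 1000.0) * (track.library_size / 1e6))
    raise BoundsError(f"unknown density unit {unit!r}")


def gene_rpm(track: OccupancyTrack, gene: GeneModel) -> float:
    """Reads per million mapped reads over the whole transcription unit."""
    if track.library_size <= 0:
        raise NormalizationError(
            f"sample {track.sample_id!r} has no library_size; cannot compute rpm"
        )
    vals = track.window_values(gene, 0, gene.length)
    return float(vals.sum()) / (track.library_size / 1e6)
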