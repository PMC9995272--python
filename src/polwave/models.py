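"""Core in-memory containers: gene models and per-base occupancy tracks.

Coordinate conventions
----------------------
Genomic intervals are stored 0-based, half-open (the BED/bedGraph dialect).
All analysis windows are expressed as *strand-aware offsets from the TSS*:
offset 0 is the TSS base itself and offsets increase in the direction of
transcription.  On the plus strand the TSS is ``start``; on the minus strand
it is ``end - 1`` and offsets run leftward along the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BoundsError, DataError

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit (union of isoforms) with strand-aware anchors."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.start >= self.end:
            raise DataError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in STRANDS:
            raise DataError(f"gene {self.gene_id}: unknown strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site (base coordinate)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (base coordinate, opposite terminus)."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def offset_interval(self, offset_start: int, offset_end: int) -> tuple[int, int]:
        """Project strand-aware TSS offsets ``[offset_start, offset_end)`` onto
        genomic coordinates, returned as a half-open interval ``(lo, hi)``.

        For minus-strand genes the interval covers the mirrored range; callers
        that need values in transcription order must reverse the slice.
        """
        if offset_start >= offset_end:
            raise BoundsError(
                f"empty offset window [{offset_start}, {offset_end}) for {self.gene_id}"
            )
        if self.strand == "+":
            lo = self.tss + offset_start
            hi = self.tss + offset_end
        else:
            lo = self.tss - offset_end + 1
            hi = self.tss - offset_start + 1
        return lo, hi


def check_unique_ids(genes: list[GeneModel]) -> None:
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise DataError(f"duplicate gene_id {g.gene_id!r} in gene set")
        seen.add(g.gene_id)


@dataclass
class OccupancyTrack:
    """Strand-specific per-base counts for one sequenced sample.

    ``counts`` maps ``(contig, strand)`` to a per-base array.  mNET-seq-like
    tracks hold single-nucleotide 3'-end counts (the polymerase active site);
    TT-seq-like tracks hold plain labeled-RNA coverage.  The file format does
    not distinguish the two — the sample sheet's ``assay`` column does.
    """

    sample_id: str
    assay: str = "mnet"
    condition: str = "control"
    timepoint_min: float = 0.0
    replicate: int = 1
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    library_size: float = 0.0
    spike_count: float = 0.0
    scale: float = 1.0

    def recompute_library_size(self) -> float:
        self.library_size = float(sum(arr.sum() for arr in self.counts.values()))
        return self.library_size

    def window_values(self, gene: GeneModel, offset_start: int, offset_end: int) -> np.ndarray:
        """Raw (unscaled) per-base counts over a strand-aware TSS-offset window,
        returned in transcription order.  Positions past the stored array are
        zero (bedGraph sparsity); positions before the contig start are an error.
        """
        lo, hi = gene.offset_interval(offset_start, offset_end)
        if lo < 0:
            raise BoundsError(
                f"window [{offset_start}, {offset_end}) of {gene.gene_id} "
                f"extends before the start of {gene.chrom}"
            )
        arr = self.counts.get((gene.chrom, gene.strand))
        n = hi - lo
        if arr is None:
            vals = np.zeros(n)
        elif lo >= arr.size:
            vals = np.zeros(n)
        else:
            vals = np.asarray(arr[lo:min(hi, arr.size)], dtype=float)
            if vals.size < n:
                vals = np.concatenate([vals, np.zeros(n - vals.size)])
        if gene.strand == "-":
            vals = vals[::-1]
        return vals
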