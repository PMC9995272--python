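"""Readers and writers for gene models and coverage tracks.

Storage is 0-based half-open (BED/bedGraph dialect); :mod:`polwave.models`
owns the strand-aware internal conventions.  Parsers report the offending
line number on malformed input.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, ParseError
from .models import GeneModel, OccupancyTrack, check_unique_ids

SAMPLE_SHEET_COLUMNS = [
    "sample",
    "assay",
    "condition",
    "timepoint_min",
    "replicate",
    "spike_count",
    "library_size",
]


# ---------------------------------------------------------------- gene models

def read_gene_models(path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 (one record per gene) or GTF (exon spans
    unioned per ``gene_id``).  Coordinates are normalized to the internal
    0-based half-open convention; strand-aware TSS/TES derive from them."""
    if format == "bed12":
        return _read_bed(path)
    if format == "gtf":
        return _read_gtf(path)
    raise ParseError(f"unknown gene-model format {format!r}", str(path))


def _read_bed(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"BED line has {len(fields)} fields, need at least 6",
                    str(path), ln,
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError("non-integer coordinates", str(path), ln) from None
            if strand not in ("+", "-"):
                raise ParseError(f"unknown strand {strand!r}", str(path), ln)
            if start_i >= end_i:
                raise ParseError(f"start {start_i} >= end {end_i}", str(path), ln)
            biotype = fields[12] if len(fields) > 12 else "protein_coding"
            genes.append(GeneModel(name, chrom, start_i, end_i, strand, biotype))
    check_unique_ids(genes)
    return genes


def _read_gtf(path) -> list[GeneModel]:
    spans: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"GTF line has {len(fields)} fields, need 9", str(path), ln)
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "gene", "transcript"):
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)  # GTF is 1-based inclusive
            except ValueError:
                raise ParseError("non-integer coordinates", str(path), ln) from None
            if strand not in ("+", "-"):
                raise ParseError(f"unknown strand {strand!r}", str(path), ln)
            gid = _gtf_attr(attrs, "gene_id")
            if gid is None:
                raise ParseError("missing gene_id attribute", str(path), ln)
            biotype = (
                _gtf_attr(attrs, "gene_biotype")
                or _gtf_attr(attrs, "gene_type")
                or "protein_coding"
            )
            rec = spans.setdefault(gid, [chrom, start_i, end_i, strand, biotype, feature])
            if rec[0] != chrom or rec[3] != strand:
                raise ParseError(
                    f"gene {gid} spans multiple contigs/strands", str(path), ln
                )
            # prefer exon records for the union once any exist
            if feature == "exon" and rec[5] != "exon":
                rec[1], rec[2], rec[5] = start_i, end_i, "exon"
            elif feature == rec[5] or feature == "exon":
                rec[1] = min(rec[1], start_i)
                rec[2] = max(rec[2], end_i)
    genes = [
        GeneModel(gid, chrom, s, e, strand, biotype)
        for gid, (chrom, s, e, strand, biotype, _f) in spans.items()
    ]
    check_unique_ids(genes)
    return genes


def _gtf_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            return part.split(None, 1)[1].strip().strip('"')
    return None


def write_bed12(genes: list[GeneModel], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            block = f"{g.length}"
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.start), str(g.end), g.gene_id, "0", g.strand,
                        str(g.start), str(g.end), "0", "1", f"{block},", "0,",
                        g.biotype,
                    ]
                )
                + "\n"
            )
    return path


# ------------------------------------------------------------------ bedGraph

def _read_bedgraph_strand(path) -> dict[str, np.ndarray]:
    """Expand one bedGraph file into per-contig per-base arrays."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(
                    f"bedGraph line has {len(fields)} fields, need 4", str(path), ln
                )
            chrom, start, end, value = fields[:4]
            try:
                s, e, v = int(start), int(end), float(value)
            except ValueError:
                raise ParseError("malformed interval", str(path), ln) from None
            if s >= e:
                raise ParseError(f"start {s} >= end {e}", str(path), ln)
            if v < 0:
                raise ParseError(f"negative value {v}", str(path), ln)
            intervals.setdefault(chrom, []).append((s, e, v))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in intervals.items():
        ivs.sort()
        n = max(e for _s, e, _v in ivs)
        arr = np.zeros(n)
        prev_end = 0
        prev_val = None
        for s, e, v in ivs:
            if s < prev_end and v != prev_val:
                raise ParseError(
                    f"overlapping intervals with conflicting values on {chrom} at {s}",
                    str(path),
                )
            arr[s:e] = v
            prev_end, prev_val = max(prev_end, e), v
        out[chrom] = arr
    return out


def read_bedgraph(path_plus, path_minus, sample_meta: dict | None = None) -> OccupancyTrack:
    """Read a plus/minus bedGraph pair into one occupancy track.

    Missing positions are zero; ``library_size`` is recomputed from the
    expanded counts.  ``sample_meta`` supplies sample sheet fields
    (sample, assay, condition, timepoint_min, replicate, spike_count).
    """
    meta = dict(sample_meta or {})
    counts: dict[tuple[str, str], np.ndarray] = {}
    for strand, path in (("+", path_plus), ("-", path_minus)):
        for chrom, arr in _read_bedgraph_strand(path).items():
            counts[(chrom, strand)] = arr
    track = OccupancyTrack(
        sample_id=str(meta.get("sample", Path(str(path_plus)).stem)),
        assay=str(meta.get("assay", "mnet")),
        condition=str(meta.get("condition", "control")),
        timepoint_min=float(meta.get("timepoint_min", 0.0)),
        replicate=int(meta.get("replicate", 1)),
        counts=counts,
        spike_count=float(meta.get("spike_count", 0.0)),
    )
    track.recompute_library_size()
    return track


def _rle_intervals(arr: np.ndarray):
    """Yield (start, end, value) runs of non-zero values."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [arr.size]])
    for s, e in zip(starts, ends):
        v = arr[s]
        if v != 0:
            yield int(s), int(e), float(v)


def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_bedgraph(track: OccupancyTrack, outdir) -> tuple[Path, Path]:
    """Write one run-length-encoded bedGraph file per strand (zero runs
    omitted), named ``<sample>.plus.bedGraph`` / ``<sample>.minus.bedGraph``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = outdir / f"{track.sample_id}.{tag}.bedGraph"
        with open(path, "w") as fh:
            for (chrom, s), arr in sorted(track.counts.items()):
                if s != strand:
                    continue
                for a, b, v in _rle_intervals(arr):
                    fh.write(f"{chrom}\t{a}\t{b}\t{_fmt_value(v)}\n")
        paths.append(path)
    return tuple(paths)


# -------------------------------------------------------------- sample sheets

def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS[:6] if c not in sheet.columns]
    if missing:
        raise ParseError(f"sample sheet missing columns: {missing}", str(path))
    if sheet["sample"].duplicated().any():
        raise DataError(f"duplicate sample ids in {path}")
    return sheet


def read_tracks(sheet_path, tracks_dir) -> list[OccupancyTrack]:
    """Load every sample named in a sample sheet from its bedGraph pair."""
    sheet = read_sample_sheet(sheet_path)
    tracks_dir = Path(tracks_dir)
    tracks = []
    for row in sheet.to_dict("records"):
        sid = row["sample"]
        tracks.append(
            read_bedgraph(
                tracks_dir / f"{sid}.plus.bedGraph",
                tracks_dir / f"{sid}.minus.bedGraph",
                row,
            )
        )
    return tracks


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_fixture(fixture_dir):
    """Load a fixture directory written by :func:`polwave.sim.write_fixture`.

    Returns ``(genes, truth, tracks)``.
    """
    fixture_dir = Path(fixture_dir)
    genes = read_gene_models(fixture_dir / "genes.bed", "bed12")
    truth_path = fixture_dir / "truth.tsv"
    truth = read_truth(truth_path) if truth_path.exists() else None
    tracks = read_tracks(fixture_dir / "samples.tsv", fixture_dir / "tracks")
    return genes, truth, tracks
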