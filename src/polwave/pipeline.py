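"""Run-configuration handling and stage orchestration.

A single declarative YAML file drives simulate -> normalize ->
pausing/halflife/wave/velocity.  Every parameter has a default mirroring the
analysis settings used throughout the package (300-bp promoter window,
thresholds 1 RPKM / sigma 0.05 / 100 rpm / 10 kb anchoring, timepoints
0/5/10/20/40 and 0/10/20/30 min).  A run writes a manifest recording the
fully resolved parameters and SHA-256 checksums of every output, so a run is
regenerable from the manifest alone and two runs with the same config and
seed produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import halflife as hl
from . import io as gio
from . import pausing as pz
from . import sim
from . import velocity as vel
from . import wavefront as wf
from .errors import ConfigError, DataError, FitError, ParseError, PolwaveError
from .normalize import apply_scale_factors, spikein_scale_factors

__version__ = "0.1.0"


class StageError(PolwaveError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


_SIM_FIELDS = {f.name for f in dataclasses.fields(sim.SimConfig)}

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "polwave_run",
    "stages": ["simulate", "pausing", "halflife", "wave", "velocity"],
    "genes": None,
    "samples": None,
    "tracks_dir": None,
    "log_level": "INFO",
    "simulate": {},  # SimConfig overrides
    "pausing": {"promoter_window": [-50, 300], "body_offset": 300},
    "halflife": {"window": [0, 300], "rpkm_min": 1.0, "sigma_max": 0.05},
    "wave": {
        "region_kb": 150.0, "grid_bp": 100, "trim_fraction": 0.1,
        "exclusion_kb": 2.0, "rpm_min": 100.0, "anchor_kb": 10.3,
        "min_len": 60_000, "max_len": 300_000,
    },
    "velocity": {"n_bins": 100, "body_offset": 300},
}

_KNOWN_STAGES = ("simulate", "pausing", "halflife", "wave", "velocity")


def _merge(defaults, given, warnings, prefix=""):
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key in ("simulate", "pausing", "halflife", "wave", "velocity"):
            sub = given.get(key, {}) or {}
            if not isinstance(sub, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            if key == "simulate":
                unknown = set(sub) - _SIM_FIELDS
            else:
                unknown = set(sub) - set(dval)
            for u in sorted(unknown):
                warnings.append(f"unknown key {prefix}{key}.{u} (ignored)")
            out[key] = {**dval, **{k: v for k, v in sub.items() if k not in unknown}}
        else:
            out[key] = given.get(key, dval)
    for key in given:
        if key not in defaults:
            warnings.append(f"unknown key {prefix}{key} (ignored)")
    return out


def resolve_config(config: dict) -> tuple[dict, list[str], list[str]]:
    """Materialize defaults; return (resolved, warnings, errors)."""
    warnings: list[str] = []
    errors: list[str] = []
    resolved = _merge(DEFAULTS, config or {}, warnings)
    for stage in resolved["stages"]:
        if stage not in _KNOWN_STAGES:
            errors.append(f"unknown stage {stage!r}")
    wavec = resolved["wave"]
    if not 0 <= wavec["trim_fraction"] < 0.5:
        errors.append(f"wave.trim_fraction {wavec['trim_fraction']} out of range [0, 0.5)")
    if resolved["halflife"]["sigma_max"] <= 0:
        errors.append("halflife.sigma_max must be > 0")
    if resolved["velocity"]["n_bins"] < 1:
        errors.append("velocity.n_bins must be >= 1")
    try:
        _sim_config(resolved).validate()
    except ConfigError as exc:
        errors.append(str(exc))
    if "simulate" not in resolved["stages"]:
        for key in ("genes", "samples"):
            if not resolved[key]:
                errors.append(f"{key!r} path required when not simulating")
            elif not Path(resolved[key]).exists():
                errors.append(f"{key} path {resolved[key]!r} does not exist")
    return resolved, warnings, errors


def validate_config(path) -> dict:
    """Parse and validate a config file; returns a report with the resolved
    parameter set, warnings (e.g. unknown keys) and errors."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise ParseError(f"unparseable YAML: {exc}", str(path)) from exc
    if not isinstance(raw, dict):
        raise ParseError("config must be a mapping", str(path))
    resolved, warnings, errors = resolve_config(raw)
    return {"resolved": resolved, "warnings": warnings, "errors": errors, "valid": not errors}


def _sim_config(resolved: dict) -> sim.SimConfig:
    kwargs = dict(resolved["simulate"])
    kwargs.setdefault("seed", resolved["seed"])
    for key in ("gene_length_range", "timepoints_triptolide", "timepoints_drb"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return sim.SimConfig(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_completeness(tracks, assay: str) -> None:
    by_cond: dict[str, list] = {}
    for tr in tracks:
        if tr.assay == assay:
            by_cond.setdefault(tr.condition, []).append(tr)
    if not by_cond:
        raise DataError(f"no {assay!r} tracks in sample sheet")
    for cond, pool in by_cond.items():
        times = sorted({t.timepoint_min for t in pool})
        reps = sorted({t.replicate for t in pool})
        have = {(t.timepoint_min, t.replicate) for t in pool}
        gaps = [(tp, r) for tp in times for r in reps if (tp, r) not in have]
        if gaps:
            raise DataError(
                f"condition {cond!r} ({assay}): missing (timepoint, replicate): {gaps}"
            )


def run_pipeline(config: dict | str | Path) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Stage failures raise :class:`StageError` naming the failing stage; the
    manifest is only written when every requested stage completed.
    """
    if isinstance(config, (str, Path)):
        report = validate_config(config)
        if not report["valid"]:
            raise ConfigError("; ".join(report["errors"]))
        resolved = report["resolved"]
    else:
        resolved, _w, errors = resolve_config(config)
        if errors:
            raise ConfigError("; ".join(errors))

    outdir = Path(resolved["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(resolved["stages"])
    outputs: dict[str, Path] = {}
    results: dict = {}

    if "simulate" in stages:
        try:
            cfg = _sim_config(resolved)
            genes, truth = sim.simulate_genome(cfg)
            tracks = []
            if any(s in stages for s in ("pausing", "halflife", "velocity")) or stages == ["simulate"]:
                tracks += sim.simulate_triptolide_timecourse(genes, truth, cfg)
            if any(s in stages for s in ("wave", "velocity")) or stages == ["simulate"]:
                tracks += sim.simulate_drb_release(genes, truth, cfg)
            fixture = sim.write_fixture(outdir / "fixture", genes, truth, tracks)
        except PolwaveError as exc:
            raise StageError("simulate", exc) from exc
        genes_path = fixture / "genes.bed"
        samples_path = fixture / "samples.tsv"
        tracks_dir = fixture / "tracks"
        for p in sorted(fixture.rglob("*")):
            if p.is_file():
                outputs[str(p.relative_to(outdir))] = p
    else:
        genes_path = Path(resolved["genes"])
        samples_path = Path(resolved["samples"])
        tracks_dir = Path(resolved["tracks_dir"] or Path(samples_path).parent / "tracks")

    analysis_stages = [s for s in stages if s != "simulate"]
    if analysis_stages:
        genes = gio.read_gene_models(genes_path, "bed12")
        tracks = gio.read_tracks(samples_path, tracks_dir)
        for assay in ("mnet", "ttseq"):
            pool = [t for t in tracks if t.assay == assay]
            if not pool:
                continue
            ref = min(pool, key=lambda t: (t.condition, t.timepoint_min, t.replicate))
            apply_scale_factors(pool, spikein_scale_factors(pool, ref.sample_id))
        mnet = [t for t in tracks if t.assay == "mnet"]
        ttseq = [t for t in tracks if t.assay == "ttseq"]

    if "pausing" in analysis_stages:
        try:
            pcfg = resolved["pausing"]
            frames = []
            for tr in mnet:
                if tr.timepoint_min == 0:
                    records, _ecdf = pz.pausing_index_table(
                        tr, genes, tuple(pcfg["promoter_window"]), pcfg["body_offset"]
                    )
                    frames.append(pz.records_to_frame(records))
            if not frames:
                raise DataError("no t=0 mnet tracks for pausing analysis")
            import pandas as pd

            path = outdir / "pausing.tsv"
            pd.concat(frames).to_csv(path, sep="\t", index=False)
            outputs["pausing.tsv"] = path
        except PolwaveError as exc:
            raise StageError("pausing", exc) from exc

    if "halflife" in analysis_stages:
        try:
            hcfg = resolved["halflife"]
            _check_completeness(tracks, "mnet")
            conditions = sorted({t.condition for t in mnet})
            fits_by_cond = {
                cond: hl.fit_cohort(
                    [t for t in mnet if t.condition == cond], genes,
                    tuple(hcfg["window"]), hcfg["rpkm_min"], hcfg["sigma_max"],
                )
                for cond in conditions
            }
            import pandas as pd

            all_fits = pd.concat([hl.fits_to_frame(f) for f in fits_by_cond.values()])
            path = outdir / "halflife_fits.tsv"
            all_fits.to_csv(path, sep="\t", index=False)
            outputs["halflife_fits.tsv"] = path
            try:
                summary, _kde, paired = hl.halflife_summary(fits_by_cond)
            except FitError:
                # small cohorts may leave no filter-passing genes; record the
                # empty outcome rather than aborting the run
                results["halflife_summary"] = []
            else:
                results["halflife_summary"] = summary.to_dict("records")
                spath = outdir / "halflife_paired.tsv"
                paired.to_csv(spath, sep="\t", index=False)
                outputs["halflife_paired.tsv"] = spath
        except PolwaveError as exc:
            raise StageError("halflife", exc) from exc

    if "wave" in analysis_stages:
        try:
            wcfg = resolved["wave"]
            _check_completeness(tracks, "ttseq")
            res = wf.wave_rate_analysis(
                ttseq, genes, region_kb=wcfg["region_kb"], grid_bp=wcfg["grid_bp"],
                trim_fraction=wcfg["trim_fraction"], exclusion_kb=wcfg["exclusion_kb"],
                rpm_min=wcfg["rpm_min"], anchor_kb=wcfg["anchor_kb"],
                min_len=wcfg["min_len"], max_len=wcfg["max_len"],
            )
            import pandas as pd

            path = outdir / "wave_per_gene.tsv"
            res["per_gene"].to_csv(path, sep="\t", index=False)
            outputs["wave_per_gene.tsv"] = path
            prof_rows = []
            for prof in res["metagene_profiles"]:
                for off, raw, smooth in zip(prof.offsets, prof.raw, prof.smooth):
                    prof_rows.append(
                        dict(timepoint_min=prof.timepoint_min, offset_bp=off,
                             raw=raw, smooth=smooth)
                    )
            mpath = outdir / "wave_metagene.tsv"
            pd.DataFrame(prof_rows).to_csv(mpath, sep="\t", index=False)
            outputs["wave_metagene.tsv"] = mpath
            fit = res["metagene_fit"]
            results["wave"] = dict(
                metagene_rate_kb_min=fit.rate_kb_min if fit else None,
                metagene_r2=fit.r2 if fit else None,
                metagene_peaks=res["metagene_series"].entries,
                n_selected=len(res["selected_genes"]),
                n_eligible=int(res["per_gene"]["eligible"].sum()),
            )
        except PolwaveError as exc:
            raise StageError("wave", exc) from exc

    if "velocity" in analysis_stages:
        try:
            vcfg = resolved["velocity"]
            pairs = {}
            for cond in sorted({t.condition for t in tracks}):
                tt0 = [t for t in ttseq if t.condition == cond and t.timepoint_min == 0]
                mn0 = [t for t in mnet if t.condition == cond and t.timepoint_min == 0]
                if tt0 and mn0:
                    pairs[cond] = (tt0[0], mn0[0])
            if not pairs:
                raise DataError("velocity stage needs t=0 ttseq and mnet tracks")
            import pandas as pd

            tables = []
            for cond, (tt, mn) in pairs.items():
                table, _matrix = vel.velocity_table(
                    tt, mn, genes, vcfg["n_bins"], body_offset=vcfg["body_offset"]
                )
                tables.append(table)
            path = outdir / "velocity.tsv"
            pd.concat(tables).to_csv(path, sep="\t", index=False)
            outputs["velocity.tsv"] = path
        except PolwaveError as exc:
            raise StageError("velocity", exc) from exc

    manifest = {
        "tool": "polwave",
        "version": __version__,
        "config": _jsonable(resolved),
        "results": _jsonable(results),
        "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
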