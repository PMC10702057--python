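"""End-to-end pipeline: simulate → phenotype → filter → scan → markers.

One :class:`RunConfig` holds every stage parameter (defaults are the
study-anchored values: 10-SNP windows, dAF threshold 0.5, run of 5,
pools of 20/16, 50 bp flanks, 65% GC, per-contig quotas).  A run writes
all stage outputs plus a JSON manifest with the serialized config and a
SHA-256 digest of every output file, so identical config + seed means
identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pyfaidx

from beetmbs import daf_scan, marker_design, phenotyping, simpop, variant_filtering
from beetmbs.genmap import beet_like_map
from beetmbs.variants import write_vcf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "read_config", "write_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """All stage parameters with study-anchored defaults."""

    seed: int = 0
    # genetic map / simulation shape
    n_chromosomes: int = 9
    variants_per_chromosome: int = 225
    chrom_length_bp: int = 1_000_000
    chrom_length_cm: float = 80.0
    n_lines: int = 406
    plants_per_line: int = 10
    causal_chrom: str = "chr5"
    causal_cm: float = 10.0
    effect: float = 30.0
    baseline_mean: float = 85.0
    dispersion: float = 5.0
    coverage: float = 20.0
    error_rate: float = 0.002
    block_size: int = 120
    block_sd: float = 0.5
    decoy_fraction: float = 0.1
    # phenotype stage
    k_tol: int = 20
    k_sus: int = 16
    cv_max: float = 0.3
    # filter stage
    min_parent_depth: int = 5
    min_qual: float = 30.0
    # scan stage
    window_size: int = 10
    threshold: float = 0.5
    run_min: int = 5
    min_depth: int = 10
    # marker stage
    flank_bp: int = 50
    max_gc: float = 0.65
    max_per_chrom: int = 1000
    max_per_unplaced: int = 4
    k_per_chrom: int = 21


def write_config(config: RunConfig, path: str) -> None:
    """Canonical key=value serialization (field order; round-trips bytewise)."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {getattr(config, f.name)!r}\n")


def read_config(path: str) -> RunConfig:
    """Parse a key=value config, applying defaults for absent keys."""
    types = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    defaults = RunConfig()
    values: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                values[key] = raw in ("True", "true", "1")
            elif isinstance(current, int):
                values[key] = int(raw)
            elif isinstance(current, float):
                values[key] = float(raw)
            else:
                values[key] = raw.strip("'\"")
    for f in dataclasses.fields(RunConfig):
        if f.name not in values:
            logger.info("config: %s not set, default %r", f.name, getattr(defaults, f.name))
    return RunConfig(**values)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _resolve_causal(gmap, config: RunConfig) -> tuple[str, int]:
    c = gmap.chromosome(config.causal_chrom)
    i = int((abs(c.cm - config.causal_cm)).argmin())
    return (c.name, int(c.positions[i]))


def run_pipeline(config: RunConfig, outdir: str, simulate: bool = True,
                 vcf: str | None = None, fasta: str | None = None,
                 phenotypes: str | None = None) -> dict:
    """Execute all stages and return the manifest dict.

    With ``simulate=True`` (the default) the synthetic generator provides
    the inputs; otherwise ``vcf``/``fasta``/``phenotypes`` paths must
    point at real data with the conventional sample names.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest: dict = {"config": dataclasses.asdict(config), "stages": []}

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path)

    stage = "simulate"
    try:
        if simulate:
            gmap = beet_like_map(
                config.n_chromosomes,
                config.variants_per_chromosome,
                config.chrom_length_bp,
                config.chrom_length_cm,
                seed=config.seed,
            )
            causal = _resolve_causal(gmap, config) if config.effect > 0 else None
            sim = simpop.SimConfig(
                n_lines=config.n_lines,
                plants_per_line=config.plants_per_line,
                causal=causal,
                effect=config.effect,
                baseline_mean=config.baseline_mean,
                dispersion=config.dispersion,
                coverage=config.coverage,
                error_rate=config.error_rate,
                seed=config.seed,
                block_size=config.block_size,
                block_sd=config.block_sd,
                decoy_fraction=config.decoy_fraction,
            )
            genotypes = simpop.simulate_f2(gmap, sim)
            pheno = simpop.simulate_phenotypes(genotypes, sim)
            pheno_path = out / "phenotypes.tsv"
            pheno.to_csv(pheno_path, sep="\t", index=False)
            emit("phenotypes", pheno_path)
            truth = simpop.site_truth(gmap, sim)
            truth_path = out / "truth.tsv"
            simpop.write_truth(truth, sim, str(truth_path))
            emit("truth", truth_path)
            fasta_path = out / "reference.fa"
            simpop.write_reference_fasta(gmap, config.seed, str(fasta_path))
            emit("reference", fasta_path)
            manifest["stages"].append("simulate")
        else:
            pheno = pd.read_csv(phenotypes, sep="\t")
        stage = "phenotype"
        summary, plants = phenotyping.adjusted_means(pheno)
        pools = phenotyping.select_extremes(
            summary, config.k_tol, config.k_sus, config.cv_max
        )
        summary_path = out / "line_summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
        emit("line_summary", summary_path)
        pools_df = pd.DataFrame(
            [("tolerant", l) for l in pools.tolerant]
            + [("susceptible", l) for l in pools.susceptible],
            columns=["pool", "line_id"],
        )
        pools_path = out / "pools.tsv"
        pools_df.to_csv(pools_path, sep="\t", index=False)
        emit("pools", pools_path)
        manifest["stages"].append("phenotype")

        stage = "simulate_reads"
        if simulate:
            table = simpop.simulate_pool_reads(
                genotypes, (list(pools.tolerant), list(pools.susceptible)), sim, truth
            )
            vcf_path = out / "mbs_raw.vcf"
            write_vcf(table, str(vcf_path))
            emit("raw_vcf", vcf_path)
            vcf_in, fasta_in = str(vcf_path), str(fasta_path)
        else:
            vcf_in, fasta_in = vcf, fasta

        stage = "filter"
        required = [simpop.PARENT_SUS, simpop.PARENT_TOL, simpop.F1,
                    simpop.POOL_SUS, simpop.POOL_TOL]
        lenient, ingest_report = variant_filtering.ingest_vcf(vcf_in, required)
        filtered, report = variant_filtering.high_confidence_filter(
            lenient,
            parent_sus=simpop.PARENT_SUS,
            parent_tol=simpop.PARENT_TOL,
            f1=simpop.F1,
            min_parent_depth=config.min_parent_depth,
            min_qual=config.min_qual,
        )
        filtered_path = out / "filtered.vcf"
        write_vcf(filtered, str(filtered_path))
        emit("filtered_vcf", filtered_path)
        report_path = out / "filter_report.tsv"
        report.to_frame().to_csv(report_path, sep="\t", index=False)
        emit("filter_report", report_path)
        manifest["stages"].append("filter")
        manifest["filter"] = {"ingest": ingest_report, "records_out": report.records_out}

        stage = "scan"
        dafs = daf_scan.per_variant_daf(
            filtered, [simpop.POOL_TOL], [simpop.POOL_SUS], config.min_depth
        )
        windows = daf_scan.window_scan(dafs, config.window_size)
        intervals = daf_scan.detect_intervals(windows, config.threshold, config.run_min)
        summary_scan = daf_scan.scan_report(windows, intervals)
        windows_path = out / "windows.tsv"
        windows.to_csv(windows_path, sep="\t", index=False)
        emit("windows", windows_path)
        track_path = out / "daf_track.tsv"
        summary_scan["track"].to_csv(track_path, sep="\t", index=False)
        emit("daf_track", track_path)
        intervals_path = out / "intervals.tsv"
        intervals.to_csv(intervals_path, sep="\t", index=False)
        emit("intervals", intervals_path)
        bed_path = out / "intervals.bed"
        daf_scan.write_intervals_bed(intervals, str(bed_path))
        emit("intervals_bed", bed_path)
        manifest["stages"].append("scan")
        manifest["scan"] = {
            "n_intervals": summary_scan["n_intervals"],
            "global_mean_daf": summary_scan["global_mean_daf"],
            "global_sd_daf": summary_scan["global_sd_daf"],
            "intervals": intervals.to_dict("records"),
        }
        if simulate and causal is not None:
            hit = any(
                r["chrom"] == causal[0] and r["start_pos"] <= causal[1] <= r["end_pos"]
                for r in manifest["scan"]["intervals"]
            )
            manifest["scan"]["causal"] = {"chrom": causal[0], "pos": causal[1], "in_interval": hit}

        stage = "markers"
        ref = pyfaidx.Fasta(fasta_in)
        candidates, panel = marker_design.design_markers(
            filtered,
            lenient,
            ref,
            flank_bp=config.flank_bp,
            max_gc=config.max_gc,
            max_per_chrom=config.max_per_chrom,
            max_per_unplaced=config.max_per_unplaced,
            k_per_chrom=config.k_per_chrom,
        )
        cand_path = out / "marker_candidates.tsv"
        candidates.to_csv(cand_path, sep="\t", index=False)
        emit("marker_candidates", cand_path)
        panel = panel.copy()
        if len(panel):
            panel["kasp"] = [marker_design.kasp_format(r) for r in panel.itertuples()]
        panel_path = out / "marker_panel.tsv"
        panel.to_csv(panel_path, sep="\t", index=False)
        emit("marker_panel", panel_path)
        manifest["stages"].append("markers")
        manifest["markers"] = {
            "candidates_accepted": int((candidates["status"] == "accepted").sum()),
            "panel_size": int(len(panel)),
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 — name the failing stage, keep partial outputs
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outputs, out)
        raise StageError(stage, e) from e

    config_path = out / "run_config.txt"
    write_config(config, str(config_path))
    emit("config", config_path)
    _write_manifest(manifest, outputs, out)
    return manifest


def _write_manifest(manifest: dict, outputs: dict[str, str], out: Path) -> None:
    manifest["outputs"] = {
        name: {"path": path, "sha256": _sha256(Path(path))}
        for name, path in outputs.items()
        if Path(path).exists()
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
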