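"""Stage runners tying the modules into reproducible, manifest-writing runs.

Each ``run_*`` function reads inputs, executes one stage, writes its outputs
plus a ``manifest.json`` (parameters, seed, output checksums) into the
output directory, and returns the manifest. :func:`run_pipeline` dispatches
on a :class:`RunConfig` — the programmatic equivalent of the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import io as pio
from .amplicon_quant import AmpliconTarget, quantify_conversions, quantify_indels
from .reporter_pam import ReporterDesign, discover, pam_table
from .synthetic_screen import (
    PamActivityModel,
    ScreenSimConfig,
    simulate_amplicon_reads,
    simulate_library,
    simulate_sorted_reads,
)
from .target_finder import SpacerQuery, IupacPattern, expected_pam_density, find_offtargets, hits_to_frame

logger = logging.getLogger("pamprofiler")


@dataclass
class RunConfig:
    """One pipeline invocation: a stage name, its parameters, and the
    reproducibility plumbing (seed, output directory, overwrite policy)."""

    subcommand: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Optional[Path] = None
    force: bool = False
    log_level: str = "INFO"


def design_from_dict(cfg: Mapping) -> ReporterDesign:
    fields = {k: cfg[k] for k in ("upstream_anchor", "downstream_anchor", "target", "fixer", "random_length") if k in cfg}
    return ReporterDesign(**fields)


def run_simulate_screen(
    outdir: Path,
    model: PamActivityModel,
    config: ScreenSimConfig,
    force: bool = False,
) -> dict:
    """Simulate the reporter screen; write sorted_reads.fastq + truth.tsv."""
    outdir = pio.prepare_outdir(outdir, force)
    library = simulate_library(config)
    records, truth = simulate_sorted_reads(library, model, config)
    fastq = outdir / "sorted_reads.fastq"
    truth_path = outdir / "truth.tsv"
    pio.write_fastq(fastq, records)
    pio.write_tsv(truth_path, truth)
    logger.info("simulated %d sorted reads from %d constructs", len(records), config.n_constructs)
    return pio.write_manifest(
        outdir, "simulate-screen",
        params={"n_constructs": config.n_constructs, "reads_per_construct": config.reads_per_construct,
                "sequencing_error_rate": config.sequencing_error_rate,
                "editable_fraction": model.editable_fraction,
                "n_weighted_patterns": len(model.pattern_weights)},
        seed=config.seed, outputs=[fastq, truth_path],
    )


def run_simulate_amplicon(
    outdir: Path,
    target: AmpliconTarget,
    indel_fraction: float,
    conversion_profile: Mapping[int, float],
    n_reads: int,
    error_rate: float,
    seed: int,
    force: bool = False,
) -> dict:
    outdir = pio.prepare_outdir(outdir, force)
    records, truth = simulate_amplicon_reads(target, indel_fraction, conversion_profile, n_reads, error_rate, seed)
    fastq = outdir / "amplicon_reads.fastq"
    truth_path = outdir / "truth.tsv"
    pio.write_fastq(fastq, records)
    pio.write_tsv(truth_path, truth)
    return pio.write_manifest(
        outdir, "simulate-amplicon",
        params={"target": target.name, "indel_fraction": indel_fraction,
                "conversion_profile": {str(k): v for k, v in conversion_profile.items()},
                "n_reads": n_reads, "error_rate": error_rate},
        seed=seed, outputs=[fastq, truth_path],
    )


def run_discover(
    outdir: Path,
    fastq: Path,
    design: Optional[ReporterDesign] = None,
    k: int = 4,
    seed: Optional[int] = None,
    force: bool = False,
    plot: bool = False,
    **discover_kwargs,
) -> dict:
    """PAM discovery on a FASTQ of sorted reporter reads."""
    outdir = pio.prepare_outdir(outdir, force)
    reads = [r.sequence for r in pio.read_fastq(fastq)]
    result = discover(reads, design=design, k=k, **discover_kwargs)
    counts_path = outdir / "pam_counts.tsv"
    pio.write_tsv(counts_path, pam_table(result.counts))
    profile = result.profile.frequencies.copy()
    profile.insert(0, "position", profile.index)
    profile["information_content_bits"] = result.ic
    profile_path = outdir / "pam_profile.tsv"
    pio.write_tsv(profile_path, profile)
    wheel_path = outdir / "pam_wheel.json"
    pio.write_json(wheel_path, result.wheel.to_dict())
    summary_path = outdir / "summary.json"
    pio.write_json(summary_path, {
        "n_reads": result.n_reads,
        "n_anchored": result.n_anchored,
        "n_in_frame": result.n_in_frame,
        "consensus": result.consensus,
        "class_counts": dict(result.class_counts),
        "k": k,
    })
    outputs = [counts_path, profile_path, wheel_path, summary_path]
    if plot:
        from .plotting import plot_logo, plot_pam_wheel
        logo_path = outdir / "pam_logo.png"
        wheel_png = outdir / "pam_wheel.png"
        plot_logo(result.profile, result.ic).savefig(logo_path, dpi=150)
        plot_pam_wheel(result.wheel).savefig(wheel_png, dpi=150)
        outputs += [logo_path, wheel_png]
    logger.info("discover: consensus %s from %d in-frame reads", result.consensus, result.counts.total)
    return pio.write_manifest(outdir, "discover", params={"k": k}, seed=seed, inputs=[fastq], outputs=outputs)


def load_targets(targets_tsv: Path, amplicons: Mapping[str, str]) -> list[AmpliconTarget]:
    """Targets TSV (name, amplicon, protospacer, pam, strand) -> located targets."""
    frame = pio.read_tsv(targets_tsv)
    required = {"name", "amplicon", "protospacer", "pam"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{targets_tsv}: missing columns {sorted(missing)}")
    targets = []
    for row in frame.itertuples(index=False):
        strand = getattr(row, "strand", None)
        strand = None if strand in (None, "", ".") or (isinstance(strand, float) and pd.isna(strand)) else strand
        targets.append(AmpliconTarget.locate(row.name, amplicons[row.amplicon], row.protospacer, row.pam, strand))
    return targets


def run_quantify(
    outdir: Path,
    fastq: Path,
    targets: list[AmpliconTarget],
    mode: str = "indel",
    seed: Optional[int] = None,
    force: bool = False,
) -> dict:
    """Indel or base-edit quantification of amplicon reads at each target."""
    if mode not in ("indel", "cbe", "abe"):
        raise ValueError(f"mode must be indel, cbe or abe, got {mode!r}")
    outdir = pio.prepare_outdir(outdir, force)
    reads = [r.sequence for r in pio.read_fastq(fastq)]
    outputs = []
    summary_rows = []
    for target in targets:
        if mode == "indel":
            report = quantify_indels(reads, target)
            hist = pd.DataFrame(
                sorted(report.indel_length_histogram.items()), columns=["net_indel", "n_reads"],
            )
            path = outdir / f"{target.name}.indels.tsv"
            pio.write_tsv(path, hist)
            summary_rows.append({
                "target": target.name, "mode": mode, "n_reads": report.n_reads,
                "n_dropped": report.n_dropped, "n_indel": report.n_indel,
                "indel_pct": report.indel_pct,
            })
        else:
            from_base, to_base = ("C", "T") if mode == "cbe" else ("A", "G")
            table = quantify_conversions(reads, target, from_base, to_base)
            path = outdir / f"{target.name}.conversions.tsv"
            pio.write_tsv(path, table.table)
            for row in table.table.itertuples(index=False):
                summary_rows.append({
                    "target": target.name, "mode": mode, "label": row.label,
                    "n_reads": row.n_reads, "conversion_pct": row.conversion_pct,
                })
        outputs.append(path)
    summary_path = outdir / "summary.tsv"
    pio.write_tsv(summary_path, pd.DataFrame(summary_rows))
    outputs.append(summary_path)
    return pio.write_manifest(
        outdir, "quantify", params={"mode": mode, "targets": [t.name for t in targets]},
        seed=seed, inputs=[fastq], outputs=outputs,
    )


def run_offtargets(
    outdir: Path,
    genome: Mapping[str, str],
    query: SpacerQuery,
    seed: Optional[int] = None,
    force: bool = False,
) -> dict:
    outdir = pio.prepare_outdir(outdir, force)
    hits = find_offtargets(genome, query)
    path = outdir / "offtargets.tsv"
    pio.write_tsv(path, hits_to_frame(hits))
    return pio.write_manifest(
        outdir, "offtargets",
        params={"spacer": query.spacer, "pam": query.pam.pattern, "max_mismatches": query.max_mismatches},
        seed=seed, outputs=[path],
    )


def run_pipeline(config: RunConfig) -> dict:
    """Dispatch a RunConfig to its stage runner; failures carry the stage name."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    dispatch = {
        "simulate-screen": _run_simulate_screen_cfg,
        "simulate-amplicon": _run_simulate_amplicon_cfg,
        "discover": _run_discover_cfg,
        "density": _run_density_cfg,
    }
    if config.subcommand not in dispatch:
        raise ValueError(f"unknown subcommand {config.subcommand!r}")
    try:
        return dispatch[config.subcommand](config)
    except Exception as exc:
        raise RuntimeError(f"stage {config.subcommand!r} failed: {exc}") from exc


def _run_simulate_screen_cfg(config: RunConfig) -> dict:
    p = config.params
    design = design_from_dict(p.get("design", {}))
    model = PamActivityModel(
        pattern_weights=p.get("pattern_weights", {}),
        default_weight=p.get("default_weight", 0.0),
        editable_fraction=p.get("editable_fraction", 1.0 / 3.0),
    )
    sim = ScreenSimConfig(
        design=design,
        n_constructs=p.get("n_constructs", 16384),
        reads_per_construct=p.get("reads_per_construct", 10),
        sequencing_error_rate=p.get("sequencing_error_rate", 0.001),
        seed=config.seed,
        enumerate_pams=p.get("enumerate_pams", False),
    )
    return run_simulate_screen(config.outdir, model, sim, force=config.force)


def _run_simulate_amplicon_cfg(config: RunConfig) -> dict:
    p = config.params
    target = AmpliconTarget.locate(
        p["name"], p["amplicon"], p["protospacer"], p["pam"], p.get("strand"),
    )
    return run_simulate_amplicon(
        config.outdir, target,
        indel_fraction=p.get("indel_fraction", 0.0),
        conversion_profile={int(k): v for k, v in p.get("conversion_profile", {}).items()},
        n_reads=p.get("n_reads", 1000),
        error_rate=p.get("error_rate", 0.0),
        seed=config.seed,
        force=config.force,
    )


def _run_discover_cfg(config: RunConfig) -> dict:
    p = config.params
    design = design_from_dict(p.get("design", {}))
    return run_discover(
        config.outdir, Path(p["fastq"]), design=design, k=p.get("k", 4),
        seed=config.seed, force=config.force, plot=p.get("plot", False),
    )


def _run_density_cfg(config: RunConfig) -> dict:
    p = config.params
    density = expected_pam_density(
        IupacPattern(p["pam"]), p.get("base_composition"), p.get("both_strands", True),
    )
    payload = {"pam": p["pam"], "both_strands": p.get("both_strands", True),
               "density_per_position": density,
               "positions_per_site": (1.0 / density) if density else None}
    if config.outdir is not None:
        outdir = pio.prepare_outdir(config.outdir, config.force)
        pio.write_json(outdir / "density.json", payload)
    return payload
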