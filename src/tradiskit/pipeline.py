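"""End-to-end orchestration: simulate -> subsample -> trim -> map -> call.

One :class:`RunConfig` drives a fully deterministic run: a single global seed
is fanned out to per-stage seeds (seed + stage ordinal), every stage writes
its intermediate files under the output directory, and a :class:`RunReport`
collects the stage statistics.  Input is either a simulation config (the
synthetic library) or pre-existing FASTQ + reference files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import junctions as jx
from . import mapper as mp
from . import seqio, simlib
from . import trimmer as tr

__all__ = ["InputPaths", "RunConfig", "RunReport", "ConfigError", "load_config", "run_pipeline"]

logger = logging.getLogger("tradiskit")

# stage ordinals for seed fan-out
_STAGE_SIM, _STAGE_SUBSAMPLE = 0, 1


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


@dataclass(frozen=True, slots=True)
class InputPaths:
    fastq_r1: str
    fastq_r2: str
    genome_fasta: str
    truth_tsv: str | None = None


@dataclass(slots=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    sim: simlib.SimConfig | None = None
    inputs: InputPaths | None = None
    trim: tr.TrimPolicy = field(default_factory=tr.TrimPolicy)
    map: mp.MapPolicy = field(default_factory=mp.MapPolicy)
    cpm_min: float = 1.0
    subsample_n: int | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'sim' and 'inputs' must be given")
        self.outdir = Path(self.outdir)


@dataclass(slots=True)
class RunReport:
    """Per-stage statistics of one pipeline run; counts never increase downstream."""

    n_pairs_in: int = 0
    n_pairs_after_subsample: int = 0
    trim: dict = field(default_factory=dict)
    n_mapped: int = 0
    n_putative: int = 0
    uis_count: int = 0
    recovery: dict | None = None
    stage_seconds: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build_dataclass(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad value in {where}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Top-level keys: ``outdir`` (required), ``seed``, ``cpm_min``,
    ``subsample_n``, and exactly one of ``sim`` (simulation parameters) or
    ``inputs`` (paths to existing files); optional ``trim`` and ``map``
    sections override policy defaults.  Unknown keys are rejected by name.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {"outdir", "seed", "cpm_min", "subsample_n", "sim", "inputs", "trim", "map"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in config: {', '.join(sorted(unknown))}")
    if "outdir" not in raw:
        raise ConfigError("config requires 'outdir'")
    kwargs: dict = {
        "outdir": Path(raw["outdir"]),
        "seed": int(raw.get("seed", 0)),
        "cpm_min": float(raw.get("cpm_min", 1.0)),
        "subsample_n": None if raw.get("subsample_n") is None else int(raw["subsample_n"]),
    }
    if "sim" in raw and raw["sim"] is not None:
        sim_data = dict(raw["sim"])
        if "fragment_len_range" in sim_data:
            sim_data["fragment_len_range"] = tuple(sim_data["fragment_len_range"])
        sim_data.setdefault("seed", kwargs["seed"] + _STAGE_SIM)
        kwargs["sim"] = _build_dataclass(simlib.SimConfig, sim_data, "sim")
    if "inputs" in raw and raw["inputs"] is not None:
        kwargs["inputs"] = _build_dataclass(InputPaths, dict(raw["inputs"]), "inputs")
    if "trim" in raw and raw["trim"] is not None:
        trim_data = dict(raw["trim"])
        if "error_model" in trim_data:
            trim_data["error_model"] = tr.ErrorModel(trim_data["error_model"])
        kwargs["trim"] = _build_dataclass(tr.TrimPolicy, trim_data, "trim")
    if "map" in raw and raw["map"] is not None:
        kwargs["map"] = _build_dataclass(mp.MapPolicy, dict(raw["map"]), "map")
    try:
        return RunConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML (round-trips through load_config)."""
    raw: dict = {
        "outdir": str(config.outdir),
        "seed": config.seed,
        "cpm_min": config.cpm_min,
        "subsample_n": config.subsample_n,
    }
    if config.sim is not None:
        sim = dataclasses.asdict(config.sim)
        sim["fragment_len_range"] = list(sim["fragment_len_range"])
        raw["sim"] = sim
    if config.inputs is not None:
        raw["inputs"] = dataclasses.asdict(config.inputs)
    trim = dataclasses.asdict(config.trim)
    trim["error_model"] = config.trim.error_model.value
    raw["trim"] = trim
    raw["map"] = dataclasses.asdict(config.map)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def _write_alignment_tsv(alignments, path: Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("query_id\tref_entry\tpos\tmismatches\tmapped_len\n")
        for a in alignments:
            fh.write(f"{a.query_id}\t{a.ref_id}\t{a.pos}\t{a.mismatches}\t{a.mapped_len}\n")
            n += 1
    return n


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow and return the stage report.

    Stages: (optional) simulate, (optional) subsample to fixed depth, trim
    Read 1 in two rounds, map kept reads against the dual-orientation
    reference, de-duplicate to putative junctions and apply the CPM filter.
    When truth is available (simulated input or a truth TSV), recovery
    metrics are added.  All intermediates and a ``report.json`` land in
    ``config.outdir``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    t0 = time.perf_counter()

    # --- stage: acquire input -------------------------------------------------
    truth: simlib.InsertionTruth | None = None
    if config.sim is not None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.sim.seed)
        genome = simlib.simulate_genome(
            sim_cfg.genome_len, sim_cfg.n_chromosomes, seed=sim_cfg.seed
        )
        truth = simlib.sample_truth(
            genome, sim_cfg.n_insertions, sim_cfg.abundance_sigma,
            seed=sim_cfg.seed, read_len=sim_cfg.read_len,
        )
        sim_out = simlib.simulate_reads(sim_cfg, genome, truth, out / "sim")
        r1_path, r2_path = sim_out.fastq_r1, sim_out.fastq_r2
        report.n_pairs_in = sim_out.manifest["n_read_pairs"]
        logger.info("simulate: %d pairs, %d truth sites", report.n_pairs_in, len(truth))
    else:
        genome = seqio.read_fasta(config.inputs.genome_fasta)
        r1_path, r2_path = Path(config.inputs.fastq_r1), Path(config.inputs.fastq_r2)
        if config.inputs.truth_tsv:
            truth = simlib.InsertionTruth.from_tsv(config.inputs.truth_tsv)
        report.n_pairs_in = sum(1 for _ in seqio.read_fastq(r1_path))
        logger.info("input: %d pairs from %s", report.n_pairs_in, r1_path)
    report.stage_seconds["input"] = round(time.perf_counter() - t0, 3)

    # --- stage: subsample -----------------------------------------------------
    t0 = time.perf_counter()
    if config.subsample_n is not None:
        sub = jx.subsample_pairs(
            seqio.read_fastq_pairs(r1_path, r2_path),
            n_target=config.subsample_n,
            seed=config.seed + _STAGE_SUBSAMPLE,
        )
        sub_r1, sub_r2 = out / "subsampled_R1.fastq", out / "subsampled_R2.fastq"
        report.n_pairs_after_subsample = seqio.write_fastq_pairs(sub, sub_r1, sub_r2)
        r1_path, r2_path = sub_r1, sub_r2
        logger.info("subsample: kept %d pairs", report.n_pairs_after_subsample)
    else:
        report.n_pairs_after_subsample = report.n_pairs_in
    report.stage_seconds["subsample"] = round(time.perf_counter() - t0, 3)

    # --- stage: trim ----------------------------------------------------------
    t0 = time.perf_counter()
    kept, stats = tr.filter_pairs(seqio.read_fastq_pairs(r1_path, r2_path), config.trim)
    trimmed_r1, kept_r2 = out / "trimmed_R1.fastq", out / "kept_R2.fastq"
    seqio.write_fastq_pairs(kept, trimmed_r1, kept_r2)
    report.trim = stats.as_dict()
    with open(out / "trim_stats.json", "w") as fh:
        json.dump(report.trim, fh, indent=2)
    logger.info(
        "trim: %d/%d kept (usable fraction %.4f)",
        stats.n_kept, stats.n_input, stats.usable_fraction,
    )
    report.stage_seconds["trim"] = round(time.perf_counter() - t0, 3)

    # --- stage: map -----------------------------------------------------------
    t0 = time.perf_counter()
    index = mp.build_index(genome, config.map)
    alignments = mp.map_reads(seqio.read_fastq(trimmed_r1), index, config.map)
    aln_path = out / "alignments.tsv"
    report.n_mapped = _write_alignment_tsv(alignments, aln_path)
    logger.info("map: %d reads placed", report.n_mapped)
    report.stage_seconds["map"] = round(time.perf_counter() - t0, 3)

    # --- stage: call ----------------------------------------------------------
    t0 = time.perf_counter()
    records = (
        seqio.AlignmentRecord(
            query_id=q, ref_id=r, orientation=(
                seqio.Orientation.RC if r.endswith("_rc") else seqio.Orientation.FWD
            ), pos=int(p), mismatches=int(nm), mapped_len=int(ml),
        )
        for q, r, p, nm, ml in _iter_alignment_tsv(aln_path)
    )
    table = jx.classify_true(jx.putative_junctions(records), cpm_min=config.cpm_min)
    report.n_putative = len(table)
    report.uis_count = table.uis_count
    seqio.write_junction_table(table, out / "junctions.tsv", "tsv")
    seqio.write_junction_table(table, out / "junctions.bed", "bed")
    logger.info("call: %d putative, %d true junctions", report.n_putative, report.uis_count)
    report.stage_seconds["call"] = round(time.perf_counter() - t0, 3)

    if truth is not None:
        report.recovery = jx.recovery_metrics(table, truth, genome)
        logger.info(
            "recovery: precision %.4f recall %.4f",
            report.recovery["precision"], report.recovery["recall"],
        )

    report.manifest = {
        "seed": config.seed,
        "cpm_min": config.cpm_min,
        "subsample_n": config.subsample_n,
        "trim": {**dataclasses.asdict(config.trim), "error_model": config.trim.error_model.value},
        "map": dataclasses.asdict(config.map),
    }
    if report.n_mapped > report.trim["n_kept"]:
        raise RuntimeError("stage accounting error: more mapped reads than kept reads")
    with open(out / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    return report


def _iter_alignment_tsv(path: Path):
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            yield line.rstrip("\n").split("\t")
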