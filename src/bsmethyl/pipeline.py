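"""End-to-end pipeline orchestration with persisted intermediates.

Stage order mirrors the analysis recipe: (optional) simulation →
non-conversion estimation → per-sample site calls → in-silico unmethylated
control → DMR finding → region weighted levels → metaplot. Every run writes
a JSON manifest recording the subcommand, full parameter set, seeds and all
input/output paths; per-stage record counts go to the log (stderr by
default).

Configuration is a plain nested dict (parsed from TOML by the CLI, with
command-line flags taking precedence):

``[simulate]``
    generator parameters (omit the section to run on existing files);
``[input]``
    ``fasta``, ``control_contig``, ``dialect`` and a ``samples`` table of
    name → count-table path;
``[calling]``
    ``alpha``, ``min_cov``;
``[dmr]``
    ``max_gap``, ``min_dms``, ``control_coverage``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import calling, dmr as dmrmod, regionstats, simulate as simmod
from .counts import CountTable
from .fileio import RunManifest, write_regions_bed
from .genome import ReferenceGenome
from .models import DifferentialMethylationModel

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                logger.info("stage %s: done", name)
                return out
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


@_stage("simulate")
def _run_simulate(sim_cfg: dict, outdir: Path):
    known = {f.name for f in dataclasses.fields(simmod.SimulationConfig)}
    unknown = set(sim_cfg) - known
    if unknown:
        raise ValueError(f"unknown simulate options {sorted(unknown)}")
    cfg = simmod.SimulationConfig(**{k: v for k, v in sim_cfg.items() if k in known})
    genome, truth = simmod.generate_genome(cfg)
    fasta = outdir / "genome.fa"
    genome.to_fasta(fasta)
    truth.to_bed(outdir / "truth_regions.bed")
    samples: dict[str, CountTable] = {}
    for i in range(cfg.n_replicates):
        table = simmod.simulate_count_table(
            truth, cfg.coverage_lambda, cfg.nonconversion_rate, cfg.seed + 1 + i
        )
        name = f"rep_{i + 1}"
        table.write_allc(outdir / f"{name}.allc.tsv")
        samples[name] = table
        logger.info("stage simulate: %s -> %d cytosine records", name, len(table))
    return genome, truth, samples


@_stage("input")
def _load_inputs(input_cfg: dict):
    genome = ReferenceGenome.from_fasta(
        input_cfg["fasta"], control_contig=input_cfg.get("control_contig")
    )
    dialect = input_cfg.get("dialect", "allc")
    samples = {
        name: CountTable.read(path, dialect=dialect)
        for name, path in input_cfg["samples"].items()
    }
    for name, tab in samples.items():
        logger.info("stage input: %s -> %d cytosine records", name, len(tab))
    return genome, None, samples


@_stage("nonconversion")
def _run_nonconversion(samples, control_contig):
    if not control_contig:
        raise ValueError("no control contig configured")
    out = {}
    for name, table in samples.items():
        est = calling.estimate_nonconversion(table, control_contig)
        logger.info(
            "stage nonconversion: %s r=%.6f over %d sites", name, est.rate, est.n_sites
        )
        out[name] = est
    return out

@_stage("call_sites")
def _run_call_sites(samples, estimates, alpha, min_cov, outdir: Path):
    out = {}
    for name, table in samples.items():
        calls = calling.call_sites(table, estimates[name], alpha=alpha, min_cov=min_cov)
        calls.write_tsv(outdir / f"{name}.calls.tsv")
        logger.info(
            "stage call_sites: %s tested=%d methylated=%d",
            name, calls.n_tested, calls.n_methylated,
        )
        out[name] = calls
    return out


@_stage("dmr")
def _run_dmr(samples, genome, calling_cfg, dmr_cfg, outdir: Path):
    model = DifferentialMethylationModel.against_unmethylated(
        samples,
        genome,
        control_coverage=dmr_cfg.get("control_coverage", dmrmod.DEFAULT_CONTROL_COVERAGE),
        alpha=calling_cfg.get("alpha", calling.DEFAULT_ALPHA),
        min_cov=calling_cfg.get("min_cov", calling.DEFAULT_MIN_COV),
        max_gap=dmr_cfg.get("max_gap", dmrmod.DEFAULT_MAX_GAP),
        min_dms=dmr_cfg.get("min_dms", dmrmod.DEFAULT_MIN_DMS),
    )
    result = model.fit()
    write_regions_bed(result.regions, outdir / "dmrs.bed")
    logger.info("stage dmr: %d DMSs -> %d DMRs", result.n_dms, result.n_dmrs)
    return result


@_stage("region_levels")
def _run_region_levels(result, outdir: Path):
    levels = result.region_levels()
    levels.to_csv(outdir / "region_levels.tsv", sep="\t", index=False)
    logger.info("stage region_levels: %d region-sample cells", len(levels))
    return levels


@_stage("metaplot")
def _run_metaplot(result, outdir: Path):
    profile = result.metaplot()
    profile.write_tsv(outdir / "metaplot.tsv")
    logger.info("stage metaplot: %d regions profiled", profile.n_regions)
    return profile


def run_pipeline(config: dict, outdir) -> dict:
    """Run the full analysis; returns a dict of in-memory stage products.

    Intermediates are persisted under ``outdir`` and a ``manifest.json``
    records the run. Raises :class:`PipelineError` naming the failing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calling_cfg = config.get("calling", {})
    dmr_cfg = config.get("dmr", {})
    if "simulate" in config:
        genome, truth, samples = _run_simulate(config["simulate"], outdir)
        control_contig = genome.control_contig
    elif "input" in config:
        genome, truth, samples = _load_inputs(config["input"])
        control_contig = genome.control_contig
    else:
        raise PipelineError("config", ValueError("need a [simulate] or [input] section"))
    estimates = _run_nonconversion(samples, control_contig)
    alpha = calling_cfg.get("alpha", calling.DEFAULT_ALPHA)
    min_cov = calling_cfg.get("min_cov", calling.DEFAULT_MIN_COV)
    site_calls = _run_call_sites(samples, estimates, alpha, min_cov, outdir)
    result = _run_dmr(samples, genome, calling_cfg, dmr_cfg, outdir)
    levels = _run_region_levels(result, outdir)
    profile = _run_metaplot(result, outdir) if result.regions else None
    manifest = RunManifest(
        subcommand="run",
        parameters={
            "calling": {"alpha": alpha, "min_cov": min_cov},
            "dmr": {
                "max_gap": dmr_cfg.get("max_gap", dmrmod.DEFAULT_MAX_GAP),
                "min_dms": dmr_cfg.get("min_dms", dmrmod.DEFAULT_MIN_DMS),
                "control_coverage": dmr_cfg.get(
                    "control_coverage", dmrmod.DEFAULT_CONTROL_COVERAGE
                ),
            },
            "simulate": config.get("simulate", {}),
        },
        inputs=config.get("input", {}),
        outputs={
            "dmrs": str(outdir / "dmrs.bed"),
            "region_levels": str(outdir / "region_levels.tsv"),
            "metaplot": str(outdir / "metaplot.tsv") if profile else None,
            "manifest": str(outdir / "manifest.json"),
        },
        seed=config.get("simulate", {}).get("seed"),
    )
    manifest.write(outdir / "manifest.json")
    return {
        "genome": genome,
        "truth": truth,
        "samples": samples,
        "nonconversion": estimates,
        "site_calls": site_calls,
        "dmr_results": result,
        "region_levels": levels,
        "metaplot": profile,
        "manifest": manifest,
    }
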