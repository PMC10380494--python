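"""Run configuration and end-to-end orchestration.

A run loads (or simulates) a cohort, filters SNPs, computes diversity
reports, pairwise Fst matrices at both levels, windowed pi/Fst/pi-ratio
tracks and a sweep scan for every region pair, and optionally validates a
contig junction.  Every artifact lands under one output directory with a
JSON manifest (inputs, parameters, seed, package version, stage list) so
a rerun with the same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from ._version import __version__ as _version
from .differentiation import fst_site_components, fst_windowed, pairwise_fst
from .diversity import population_diversity, windowed_pi
from .junction import JunctionScenario, validate_junction
from .simulate import CohortDesign, simulate_structured_cohort
from .sweep import pi_ratio_track, sweep_scan
from .variantio import filter_variants, read_population_map, read_vcf

logger = logging.getLogger("popsweep")


@dataclass
class RunConfig:
    """Everything one reproducible scan needs."""

    outdir: str = "popsweep_run"
    vcf: str | None = None
    population_map: str | None = None
    simulate: dict | None = None
    maf_min: float = 0.05
    missing_max: float = 0.10
    hwe_alpha: float = 0.001
    window: int = 100_000
    step: int = 10_000
    min_snps: int = 10
    sweep_q: float = 0.05
    junction: dict | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.vcf is not None or self.population_map is not None
        if has_files and self.simulate is not None:
            raise ValueError("supply either input paths or a simulation design, not both")
        if not has_files and self.simulate is None:
            raise ValueError("supply input paths (vcf + population_map) or a simulation design")
        if has_files and (self.vcf is None or self.population_map is None):
            raise ValueError("both vcf and population_map are required")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in dc_fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return RunConfig(**raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    data = {f.name: getattr(config, f.name) for f in dc_fields(RunConfig)}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def run_scan(config: RunConfig) -> dict:
    """Execute filter -> diversity -> Fst -> sweep [-> junction]; return manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "parameters": {
            "maf_min": config.maf_min,
            "missing_max": config.missing_max,
            "hwe_alpha": config.hwe_alpha,
            "window": config.window,
            "step": config.step,
            "min_snps": config.min_snps,
            "sweep_q": config.sweep_q,
        },
        "stages": [],
        "outputs": {},
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    def record(key: str, path: Path):
        manifest["outputs"][key] = str(path.relative_to(outdir))

    try:
        # -- input ---------------------------------------------------------
        if config.simulate is not None:
            stage("simulate")
            design_kwargs = dict(config.simulate)
            design_kwargs.setdefault("seed", config.seed)
            design = CohortDesign(**design_kwargs)
            gm, pmap, _ = simulate_structured_cohort(design)
            manifest["input"] = {"simulated": design_kwargs}
        else:
            gm = read_vcf(config.vcf)
            pmap = read_population_map(config.population_map)
            manifest["input"] = {"vcf": config.vcf, "population_map": config.population_map}
        pmap.require_samples(gm)

        # -- filter --------------------------------------------------------
        stage("filter")
        gm, report = filter_variants(
            gm,
            maf_min=config.maf_min,
            missing_max=config.missing_max,
            hwe_alpha=config.hwe_alpha,
        )
        p = outdir / "filter_report.tsv"
        report.to_tsv(p)
        record("filter_report", p)
        manifest["filter"] = {
            "input": report.input_count,
            "retained": report.retained_count,
            "removed": report.removed,
        }

        # -- diversity -----------------------------------------------------
        stage("diversity")
        div = population_diversity(gm, pmap)
        p = outdir / "diversity.tsv"
        div.to_csv(p, sep="\t", index=False, float_format="%.6g")
        record("diversity", p)

        # -- differentiation ----------------------------------------------
        stage("fst")
        for level in ("population", "region"):
            if len(pmap.groups(level)) >= 2:
                mat = pairwise_fst(gm, pmap, level=level)
                p = outdir / f"fst_matrix_{level}.tsv"
                mat.to_csv(p, sep="\t", float_format="%.6g")
                record(f"fst_matrix_{level}", p)

        # -- sweep scans per region pair ------------------------------------
        stage("sweep")
        regions = pmap.regions
        sweep_summaries = {}
        pi_cache: dict[str, object] = {}
        for i, ra in enumerate(regions):
            for rb in regions[i + 1 :]:
                pair = f"{ra}_vs_{rb}"
                for r in (ra, rb):
                    if r not in pi_cache:
                        pi_cache[r] = windowed_pi(
                            gm, pmap, r, config.window, config.step, config.min_snps
                        )
                        p = outdir / f"pi_{r.replace(' ', '')}.tsv"
                        pi_cache[r].to_bed(p)
                        record(f"pi_{r}", p)
                comp = fst_site_components(
                    gm, pmap.samples_in(ra), pmap.samples_in(rb)
                )
                comp.labels = (ra, rb)
                fst_track = fst_windowed(
                    comp, config.window, config.step, config.min_snps
                )
                p = outdir / f"fst_{pair}.tsv"
                fst_track.to_bed(p)
                record(f"fst_{pair}", p)
                ratio = pi_ratio_track(pi_cache[ra], pi_cache[rb])
                result = sweep_scan(fst_track, ratio, q=config.sweep_q)
                p = outdir / f"sweep_candidates_{pair}.tsv"
                result.candidates.to_csv(p, sep="\t", index=False, float_format="%.6g")
                record(f"sweep_candidates_{pair}", p)
                sweep_summaries[pair] = result.summary()
        p = outdir / "sweep_summary.json"
        _write_json(p, sweep_summaries)
        record("sweep_summary", p)
        manifest["sweep"] = sweep_summaries

        # -- junction (optional) --------------------------------------------
        if config.junction is not None:
            stage("junction")
            scenario = JunctionScenario(**config.junction)
            decision = validate_junction(gm, scenario)
            payload = {
                "scenario": config.junction,
                "scores": decision.scores,
                "pair_counts": decision.pair_counts,
                "chosen": decision.chosen,
                "score_ratio": decision.score_ratio,
            }
            p = outdir / "junction_decision.json"
            _write_json(p, payload)
            record("junction_decision", p)
            manifest["junction"] = payload
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "input"
        manifest["failed_stage"] = failed
        _write_json(outdir / "manifest.json", manifest)
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    _write_json(outdir / "manifest.json", manifest)
    return manifest
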