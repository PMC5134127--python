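"""End-to-end pipeline: simulate/read -> homology -> distances -> tests -> tracking.

A :class:`PipelineConfig` names either a simulation configuration or an
existing cohort on disk, plus the analysis parameters. :func:`run_pipeline`
executes every stage, writes each stage's files under the output directory,
and records a manifest (parameters, seed, sha256 checksums) that fully
determines reproduction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, read_cohort, write_cohort
from .distance import (
    bray_curtis_matrix,
    household_distance_comparison,
    pcoa,
    sorensen_matrix,
    write_ordination,
)
from .homology import HomologyParams, all_pairs_hit_flags
from .permutation import (
    PermutationParams,
    household_overlap_test,
    results_to_dataframe,
    subject_overlap_test,
)
from .simulate import SimulationConfig, simulate_cohort, write_truth
from .tracking import (
    ClusterParams,
    calls_to_dataframe,
    call_transmissions,
    cluster_global_viruses,
    directionality_summary,
    household_sharing,
    persistence_summary,
    presence_dataframe,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs: one input source plus analysis parameters."""

    simulation: SimulationConfig | None = None
    input_metadata: Path | None = None
    input_fasta_dir: Path | None = None
    body_sites: tuple[str, ...] | None = None
    homology: HomologyParams = field(default_factory=HomologyParams)
    permutation: PermutationParams = field(default_factory=PermutationParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    seed: int = 0

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_input = self.input_metadata is not None
        if has_sim == has_input:
            raise ValueError(
                "exactly one of a simulation block or an input cohort must be supplied"
            )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline configuration (versioned schema)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"pipeline config not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported schema_version {version}; expected {SCHEMA_VERSION}")
    simulation = None
    if "simulate" in raw and "input" in raw:
        raise ValueError("config may not contain both 'simulate' and 'input' blocks")
    if "simulate" in raw:
        block = dict(raw["simulate"] or {})
        for key in ("body_sites", "genome_length_range"):
            if key in block:
                block[key] = tuple(block[key])
        simulation = SimulationConfig(**block)
    input_metadata = Path(raw["input"]["metadata"]) if "input" in raw else None
    input_fasta_dir = (
        Path(raw["input"]["fasta_dir"])
        if "input" in raw and raw["input"].get("fasta_dir")
        else None
    )
    return PipelineConfig(
        simulation=simulation,
        input_metadata=input_metadata,
        input_fasta_dir=input_fasta_dir,
        body_sites=tuple(raw["body_sites"]) if raw.get("body_sites") else None,
        homology=HomologyParams(**raw.get("homology", {})),
        permutation=PermutationParams(**raw.get("permutation", {})),
        cluster=ClusterParams(**raw.get("cluster", {})),
        seed=int(raw.get("seed", 0)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    echo: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "homology": dataclasses.asdict(config.homology),
        "permutation": dataclasses.asdict(config.permutation),
        "cluster": dataclasses.asdict(config.cluster),
    }
    if config.simulation is not None:
        sim = dataclasses.asdict(config.simulation)
        sim["body_sites"] = list(sim["body_sites"])
        sim["genome_length_range"] = list(sim["genome_length_range"])
        echo["simulate"] = sim
    else:
        echo["input"] = {
            "metadata": str(config.input_metadata),
            "fasta_dir": str(config.input_fasta_dir) if config.input_fasta_dir else None,
        }
    if config.body_sites:
        echo["body_sites"] = list(config.body_sites)
    return echo


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and return the manifest (also written as manifest.json)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stages: list[str] = []

    def emit(name: str, path: Path) -> None:
        outputs[name] = path

    def stage(name: str) -> None:
        logger.info("stage: %s", name)
        stages.append(name)

    # -- stage 1: cohort --------------------------------------------------
    stage("cohort")
    try:
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort, truth = simulate_cohort(sim_cfg)
            cohort_dir = out_dir / "cohort"
            for name, path in write_cohort(cohort, cohort_dir, overwrite=True).items():
                emit(f"cohort_{name}", path)
            emit("truth", write_truth(truth, out_dir / "truth.json"))
            echo_path = out_dir / "config.yaml"
            echo_path.write_text(yaml.safe_dump(_config_echo(config), sort_keys=True))
            emit("config_echo", echo_path)
        else:
            cohort = read_cohort(config.input_metadata, config.input_fasta_dir)
            truth = None
    except Exception as exc:
        raise RuntimeError(f"stage 'cohort' failed: {exc}") from exc

    sites = sorted({k.body_site for k in cohort.viromes})
    if config.body_sites:
        sites = [s for s in sites if s in config.body_sites]
    perm = dataclasses.replace(config.permutation, seed=config.seed)

    for site in sites:
        # -- stage 2: all-pairs homology ----------------------------------
        stage(f"homology[{site}]")
        try:
            flags = all_pairs_hit_flags(cohort, site, config.homology)
            table = flags.to_shared_fraction_table()
            path = out_dir / f"shared_fractions_{site}.tsv"
            table.to_dataframe().to_csv(path, sep="\t", index=False)
            emit(f"shared_fractions_{site}", path)
            path = out_dir / f"hit_flags_{site}.tsv"
            flags.to_dataframe().to_csv(path, sep="\t", index=False)
            emit(f"hit_flags_{site}", path)
        except Exception as exc:
            raise RuntimeError(f"stage 'homology[{site}]' failed: {exc}") from exc

        # -- stage 3: distances, ordination, household comparison ---------
        stage(f"distance[{site}]")
        try:
            sim_matrix = sorensen_matrix(table)
            path = out_dir / f"sorensen_{site}.tsv"
            sim_matrix.to_dataframe().to_csv(path, sep="\t")
            emit(f"sorensen_{site}", path)
            bray = bray_curtis_matrix(table)
            path = out_dir / f"bray_curtis_{site}.tsv"
            bray.to_dataframe().to_csv(path, sep="\t")
            emit(f"bray_curtis_{site}", path)
            ordination = pcoa(bray, n_axes=min(3, len(bray.keys) - 1))
            coords = out_dir / f"pcoa_{site}_coordinates.tsv"
            eig = out_dir / f"pcoa_{site}_eigen.json"
            write_ordination(ordination, coords, eig)
            emit(f"pcoa_{site}_coordinates", coords)
            emit(f"pcoa_{site}_eigen", eig)
            if cohort.two_person_households():
                comparison = household_distance_comparison(sim_matrix)
                path = out_dir / f"household_comparison_{site}.json"
                path.write_text(json.dumps(comparison, indent=1))
                emit(f"household_comparison_{site}", path)
        except Exception as exc:
            raise RuntimeError(f"stage 'distance[{site}]' failed: {exc}") from exc

        # -- stage 4: permutation tests -----------------------------------
        stage(f"permutation[{site}]")
        try:
            subject_results = []
            for subject in cohort.subjects():
                n_tps = sum(1 for k in flags.keys if k.subject_id == subject)
                if n_tps >= 2:
                    subject_results.append(subject_overlap_test(subject, flags, perm))
            path = out_dir / f"permutation_subjects_{site}.tsv"
            results_to_dataframe(subject_results).to_csv(path, sep="\t", index=False)
            emit(f"permutation_subjects_{site}", path)

            household_results = []
            if len(cohort.two_person_households()) >= 2:
                for household in sorted(cohort.two_person_households()):
                    members = {
                        k.subject_id for k in flags.keys if k.household_id == household
                    }
                    if len(members) == 2:
                        household_results.append(
                            household_overlap_test(household, flags, perm)
                        )
            path = out_dir / f"permutation_households_{site}.tsv"
            results_to_dataframe(household_results).to_csv(path, sep="\t", index=False)
            emit(f"permutation_households_{site}", path)
        except Exception as exc:
            raise RuntimeError(f"stage 'permutation[{site}]' failed: {exc}") from exc

        # -- stage 5: per-subject global viruses and persistence ----------
        stage(f"persistence[{site}]")
        try:
            per_subject = {}
            pooled_spans: list[int] = []
            for subject in cohort.subjects():
                viromes = cohort.subject_viromes(subject, site)
                if len(viromes) < 2:
                    continue
                clusters = cluster_global_viruses(viromes, "subject", config.cluster)
                summary = persistence_summary(clusters)
                per_subject[subject] = summary
                pooled_spans.extend(
                    s for s, c in summary["span_histogram"].items() for _ in range(c)
                )
            pooled = {
                "n_viruses": len(pooled_spans),
                "fraction_ge_4_days": (
                    sum(1 for s in pooled_spans if s >= 4) / len(pooled_spans)
                    if pooled_spans
                    else float("nan")
                ),
                "fraction_ge_150_days": (
                    sum(1 for s in pooled_spans if s >= 150) / len(pooled_spans)
                    if pooled_spans
                    else float("nan")
                ),
            }
            path = out_dir / f"persistence_{site}.json"
            path.write_text(
                json.dumps({"per_subject": per_subject, "pooled": pooled}, indent=1)
            )
            emit(f"persistence_{site}", path)
        except Exception as exc:
            raise RuntimeError(f"stage 'persistence[{site}]' failed: {exc}") from exc

        # -- stages 6-7: household sharing, transmissions, directionality -
        stage(f"transmission[{site}]")
        try:
            summaries = []
            all_calls = []
            presence_frames = []
            for household in sorted(cohort.two_person_households()):
                viromes = [
                    cohort.viromes[k]
                    for k in cohort.sample_keys()
                    if k.household_id == household and k.body_site == site
                ]
                members = {v.key.subject_id for v in viromes}
                if len(members) != 2:
                    continue
                clusters = cluster_global_viruses(viromes, "household", config.cluster)
                summaries.append(household_sharing(clusters))
                all_calls.extend(call_transmissions(clusters, cohort))
                frame = presence_dataframe(clusters)
                frame.insert(0, "household", household)
                presence_frames.append(frame)
            if summaries:
                path = out_dir / f"household_presence_{site}.tsv"
                pd.concat(presence_frames).fillna(0).to_csv(path, sep="\t")
                emit(f"household_presence_{site}", path)
                path = out_dir / f"transmissions_{site}.tsv"
                calls_to_dataframe(all_calls).to_csv(path, sep="\t", index=False)
                emit(f"transmissions_{site}", path)
                summary = directionality_summary(all_calls, summaries)
                per_household = summary.pop("per_household")
                summary["per_household"] = per_household.to_dict(orient="records")
                summary["sharing"] = [
                    {
                        "household": s.household_id,
                        "n_viruses_total": s.n_viruses_total,
                        "n_shared": s.n_shared,
                        "n_unique_to_placebo": s.n_unique_to_placebo,
                        "n_unique_to_antibiotic": s.n_unique_to_antibiotic,
                    }
                    for s in summaries
                ]
                path = out_dir / f"directionality_{site}.json"
                path.write_text(json.dumps(summary, indent=1))
                emit(f"directionality_{site}", path)
        except Exception as exc:
            raise RuntimeError(f"stage 'transmission[{site}]' failed: {exc}") from exc

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
        "stages": stages,
        "outputs": {
            name: {"path": str(path.relative_to(out_dir)), "sha256": _sha256(path)}
            for name, path in sorted(outputs.items())
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
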