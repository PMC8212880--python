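"""Configuration-driven end-to-end pipeline runner.

Stages, in order: static filtering (median normalization → ANOVA/FDR →
bipartition into control- and lesion-predominant clusters), kinetic clustering
(fractional profiles → Gaussian-mixture EM → phase labels → vein-graft-only
early/late sets), pathway-network enrichment and centrality ranking for each
of the four protein sets, consensus central-protein target calls within the
top-ranked pathways, and the module-proximity matrix over the four proteomic
modules plus any user-supplied disease modules.  A run manifest (config
snapshot, software version, per-output sha256 checksums, collected warnings)
is written last; at a fixed seed the whole output directory is byte-stable
across reruns.

Stage seeds are derived from the single global seed by fixed offsets, so
changing one stage's parameters never shifts another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import build_pathway_graph, hypergeom_enrich, node_centralities, top_central_pathways
from .errors import ConfigError, DataError, GraftNetError, ParameterError
from .filtering import anova_filter, bipartition_proteins, normalize_median
from .io import read_abundance_table, read_edge_list, read_gmt, write_results
from .kinetics import classify_phase, condition_filter, fit_kinetic_clusters, profiles_from_table
from .proximity import matrix_pivot, proximity_matrix
from .targets import consensus_central_protein, pathway_protein_subgraph, protein_centralities

_SEED_OFFSET_KINETICS = 101
_SEED_OFFSET_PROXIMITY = 202

_PATH_KEYS = (
    "static_abundance",
    "static_annotations",
    "kinetic_abundance",
    "kinetic_annotations",
    "pathways",
    "interactome",
)


@dataclass
class PipelineConfig:
    """Validated parameters and input paths for one pipeline run."""

    static_abundance: str = ""
    static_annotations: str = ""
    kinetic_abundance: str = ""
    kinetic_annotations: str = ""
    pathways: str = ""
    interactome: str = ""
    disease_modules: str = ""  # optional GMT
    out_dir: str = "results"
    fdr_static: float = 0.05
    fdr_network: float = 0.001
    K: int = 30
    restarts: int = 8
    early_timepoints: tuple = ("D1", "D3")
    late_timepoints: tuple = ("W2", "W4")
    flat_range: float = 0.10
    top_k: int = 3
    n_rand: int = 1000
    min_bin_size: int | None = None
    measure: str = "closest"
    control_condition: str = "IVC"
    keep_condition: str = "VG"
    seed: int = 0


def validate_config(config) -> PipelineConfig:
    """Fill defaults, check ranges and confirm referenced paths exist."""
    if isinstance(config, PipelineConfig):
        cfg = config
    else:
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = sorted(set(config) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        cfg = PipelineConfig(**config)
    for key in ("fdr_static", "fdr_network"):
        v = getattr(cfg, key)
        if not 0 < float(v) <= 1:
            raise ConfigError(f"{key} must lie in (0, 1], got {v}")
    if int(cfg.K) < 2:
        raise ConfigError(f"K must be >= 2, got {cfg.K}")
    if int(cfg.n_rand) < 1:
        raise ConfigError(f"n_rand must be >= 1, got {cfg.n_rand}")
    if int(cfg.top_k) < 1:
        raise ConfigError(f"top_k must be >= 1, got {cfg.top_k}")
    if not 0 < float(cfg.flat_range) <= 1:
        raise ConfigError(f"flat_range must lie in (0, 1], got {cfg.flat_range}")
    if cfg.measure not in ("closest", "separation"):
        raise ConfigError(f"measure must be 'closest' or 'separation', got {cfg.measure!r}")
    cfg.early_timepoints = tuple(cfg.early_timepoints)
    cfg.late_timepoints = tuple(cfg.late_timepoints)
    for key in _PATH_KEYS:
        path = getattr(cfg, key)
        if not path:
            raise ConfigError(f"config key {key} is required")
        if not Path(path).exists():
            raise ConfigError(f"config key {key}: path {path} does not exist")
    if cfg.disease_modules and not Path(cfg.disease_modules).exists():
        raise ConfigError(f"config key disease_modules: path {cfg.disease_modules} does not exist")
    return cfg


def load_config(path) -> PipelineConfig:
    """Load a flat YAML mapping; relative paths resolve against the file's directory."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat key-value mapping")
    for key in (*_PATH_KEYS, "disease_modules"):
        if raw.get(key):
            raw[key] = str((path.parent / raw[key]).resolve())
    if raw.get("out_dir"):
        raw["out_dir"] = str((path.parent / raw["out_dir"]).resolve())
    return validate_config(raw)


@dataclass
class PipelineResult:
    manifest: dict
    differential: pd.DataFrame
    modules: dict
    networks: dict
    targets: pd.DataFrame
    primary_target: str | None
    proximity: pd.DataFrame


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _StageLog:
    """Collects warnings per stage for the manifest."""

    def __init__(self):
        self.warnings: dict[str, list[str]] = {}

    def run(self, name, fn, *args, **kwargs):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                out = fn(*args, **kwargs)
            except GraftNetError as exc:
                raise GraftNetError(f"stage {name!r} failed: {exc}") from exc
            finally:
                self.warnings.setdefault(name, []).extend(
                    sorted(str(w.message) for w in caught)
                )
        return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write tabular outputs plus a run manifest."""
    cfg = validate_config(config)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _StageLog()
    written: list[Path] = []

    def emit(name, records, columns=None):
        path = write_results(records, out / name, columns=columns)
        written.append(path)
        return path

    # ---- inputs
    static = read_abundance_table(cfg.static_abundance, cfg.static_annotations)
    kinetic = read_abundance_table(cfg.kinetic_abundance, cfg.kinetic_annotations)
    pathways = read_gmt(cfg.pathways)
    interactome = read_edge_list(cfg.interactome)
    disease = read_gmt(cfg.disease_modules) if cfg.disease_modules else None

    # ---- static stage
    static_norm = log.run("normalize_static", normalize_median, static)
    differential, retained = log.run(
        "anova_filter", anova_filter, static_norm, None, cfg.fdr_static
    )
    emit("differential.tsv", differential)
    clusters = log.run(
        "bipartition", bipartition_proteins, static_norm, retained, cfg.control_condition
    )
    emit(
        "predominance_clusters.tsv",
        pd.DataFrame(
            [(p, "control_predominant") for p in sorted(clusters.cluster1)]
            + [(p, "lesion_predominant") for p in sorted(clusters.cluster2)],
            columns=["protein_id", "cluster"],
        ),
    )

    # ---- kinetic stage
    kin_norm = log.run("normalize_kinetic", normalize_median, kinetic)
    profiles, timepoints = log.run("profiles", profiles_from_table, kin_norm)
    model = log.run(
        "kinetic_clusters",
        fit_kinetic_clusters,
        profiles,
        int(cfg.K),
        (cfg.seed + _SEED_OFFSET_KINETICS) % (2**31),
        int(cfg.restarts),
    )
    model = log.run(
        "classify_phase",
        classify_phase,
        model,
        cfg.early_timepoints,
        cfg.late_timepoints,
        cfg.flat_range,
    )
    phase_sets = log.run("condition_filter", condition_filter, model, cfg.keep_condition)
    assignments = model.assignments.copy()
    assignments["phase"] = [model.phases[c] for c in assignments["cluster"]]
    emit("kinetic_clusters.tsv", assignments)
    emit(
        "kinetic_centroids.tsv",
        pd.DataFrame(model.centroids, columns=list(timepoints)).assign(
            cluster=range(model.n_clusters), phase=list(model.phases)
        )[["cluster", "phase", *timepoints]],
    )

    # ---- pathway networks and targets
    module_sets = {
        "CONTROL": set(clusters.cluster1),
        "LESION": set(clusters.cluster2),
        "EARLY": set(phase_sets["early"]),
        "LATE": set(phase_sets["late"]),
    }
    emit(
        "protein_modules.tsv",
        pd.DataFrame(
            [(m, p) for m in sorted(module_sets) for p in sorted(module_sets[m])],
            columns=["module", "protein_id"],
        ),
    )
    static_universe = set(static.proteins)
    kinetic_universe = set(kinetic.proteins)
    universes = {
        "CONTROL": static_universe,
        "LESION": static_universe,
        "EARLY": kinetic_universe,
        "LATE": kinetic_universe,
    }
    networks = {}
    target_rows = []
    primary_target = None
    for name in ("LESION", "CONTROL", "EARLY", "LATE"):
        query = module_sets[name]
        if not query:
            warnings.warn(f"module {name} is empty; no network built")
            continue
        records = log.run(
            f"enrich_{name}", hypergeom_enrich, query, pathways, universes[name], cfg.fdr_network
        )
        emit(f"enrichment_{name}.tsv", records)
        graph = log.run(f"pathway_graph_{name}", build_pathway_graph, records)
        cents = node_centralities(graph) if graph.number_of_nodes() else pd.DataFrame()
        if len(cents):
            emit(f"pathway_centrality_{name}.tsv", cents.reset_index())
        top = top_central_pathways(graph, int(cfg.top_k), cents if len(cents) else None) if graph.number_of_nodes() else []
        networks[name] = {"records": records, "graph": graph, "centralities": cents, "top": top}
        for rank, set_id in enumerate(top, start=1):
            members = graph.nodes[set_id]["overlap"]
            try:
                sub = log.run(
                    f"subgraph_{name}_{set_id}", pathway_protein_subgraph, interactome, members
                )
            except GraftNetError as exc:
                warnings.warn(f"target call skipped for {name}/{set_id}: {exc}")
                continue
            triplets = protein_centralities(sub)
            call = consensus_central_protein(triplets, pathway_id=set_id)
            target_rows.append(
                {
                    "network": name,
                    "rank": rank,
                    "pathway_id": set_id,
                    "protein_id": call.protein_id,
                    "borda_score": call.borda_score,
                    "betweenness": call.betweenness,
                    "closeness": call.closeness,
                    "degree": call.degree,
                    "tied": call.tied,
                }
            )
            if name == "LESION" and rank == 1:
                primary_target = call.protein_id
    targets = pd.DataFrame(
        target_rows,
        columns=[
            "network",
            "rank",
            "pathway_id",
            "protein_id",
            "borda_score",
            "betweenness",
            "closeness",
            "degree",
            "tied",
        ],
    )
    emit("targets.tsv", targets)

    # ---- proximity stage
    prox_modules = {k: v for k, v in module_sets.items() if len(v) >= 2}
    if disease is not None:
        for sid in sorted(disease):
            prox_modules[sid] = set(disease.members(sid))
    proximity = log.run(
        "proximity",
        proximity_matrix,
        interactome,
        prox_modules,
        int(cfg.n_rand),
        (cfg.seed + _SEED_OFFSET_PROXIMITY) % (2**31),
        cfg.measure,
        cfg.min_bin_size,
    )
    emit("proximity.tsv", proximity)
    pivot = matrix_pivot(proximity, "p_emp")
    pivot.to_csv(out / "proximity_p_matrix.tsv", sep="\t", na_rep="NA")
    written.append(out / "proximity_p_matrix.tsv")
    matrix_pivot(proximity, "q").to_csv(out / "proximity_q_matrix.tsv", sep="\t", na_rep="NA")
    written.append(out / "proximity_q_matrix.tsv")

    # ---- manifest (config snapshot uses basenames so reruns into different
    # directories stay byte-identical)
    snapshot = dataclasses.asdict(cfg)
    snapshot.pop("out_dir")
    for key in (*_PATH_KEYS, "disease_modules"):
        if snapshot.get(key):
            snapshot[key] = Path(snapshot[key]).name
    snapshot["early_timepoints"] = list(cfg.early_timepoints)
    snapshot["late_timepoints"] = list(cfg.late_timepoints)
    manifest = {
        "version": __version__,
        "config": snapshot,
        "outputs": {p.name: _sha256(p) for p in sorted(written)},
        "warnings": {k: v for k, v in sorted(log.warnings.items()) if v},
        "primary_target": primary_target,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        manifest=manifest,
        differential=differential,
        modules=module_sets,
        networks=networks,
        targets=targets,
        primary_target=primary_target,
        proximity=proximity,
    )
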