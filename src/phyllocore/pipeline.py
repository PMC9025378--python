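"""End-to-end orchestration: from an OTU table to a report bundle.

A single configured run reproduces every analysis surface of the
pipeline on one dataset: composition summaries, ordination and
dispersion testing, the integer similarity-network sweep with its
critical network and modularity partition, per-group co-occurrence
networks, the hierarchical strict-core extraction with the antagonism
screen, trophic-mode profiles, and Venn partitions of the core sets.
All stochastic stages take explicit seeds and every TSV output is
byte-reproducible under a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import cooccurrence_core as cc
from . import diversity as dv
from . import guilds_sets as gs
from . import similarity_network as sn
from .io_model import (
    AbundanceTable,
    GuildDatabase,
    SampleMetadata,
    read_abundance_table,
    read_guild_db,
    read_metadata,
)


class PipelineValidationError(ValueError):
    """Configuration problem detected before any computation."""


@dataclass
class PipelineConfig:
    table_path: str
    metadata_path: str
    guild_db_path: str
    outdir: str
    occupancy_cutoff: float = 1.0
    min_count: int = 1
    representation: str = "raw"  # Bray-Curtis input: raw | hellinger
    rounding: str = "half_up"
    distance_method: str = "component"
    modularity_algorithm: str = "greedy"
    modularity_seed: int | None = None
    permdisp_n_perm: int = 999
    permdisp_seed: int | None = None
    spearman_top_k: int = 100
    spearman_alpha: float = 0.01
    spearman_adjust: str = "none"
    summary_rank: str = "phylum"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def validate(self) -> None:
        for label in ("table_path", "metadata_path", "guild_db_path"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise PipelineValidationError(f"{label} does not exist: {p}")
        if self.permdisp_seed is None:
            raise PipelineValidationError("permdisp_seed is required")
        if self.modularity_seed is None:
            raise PipelineValidationError("modularity_seed is required")
        if not 0 < self.occupancy_cutoff <= 1:
            raise PipelineValidationError("occupancy_cutoff must lie in (0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class ReportBundle:
    outdir: Path
    composition: dict[str, pd.DataFrame]
    dispersion: dict[str, dv.DispersionTest]
    critical_threshold: int
    critical_degenerate: bool
    partition: sn.Partition
    core_hierarchy: cc.CoreHierarchy
    antagonisms: dv.CorrelationResult
    trophic_profile: pd.DataFrame
    venn: gs.VennSummary
    files: list[str] = field(default_factory=list)


def summarize_composition(
    table: AbundanceTable,
    metadata: SampleMetadata,
    rank: str = "phylum",
    group_by: str = "stage",
) -> dict[str, pd.DataFrame]:
    """Per-group taxon/read/incidence shares at a taxonomic rank.

    For every group, returns a frame indexed by rank names (plus
    'unknown' for unresolved taxa) with three columns: the share of
    distinct taxa, of reads, and of incidence (presence events), each
    summing to one.
    """
    metadata.require_covers(table.sample_ids)
    rank_of = pd.Series(
        {
            t: (t if rank == "otu" else (table.taxonomy[t].get(rank) or "unknown"))
            for t in table.taxon_ids
        }
    )
    groups = sorted(set(metadata.frame.loc[table.sample_ids, group_by]))
    out = {}
    for grp in groups:
        samples = [
            s
            for s in table.sample_ids
            if metadata.frame.at[s, group_by] == grp
        ]
        sub = table.counts[samples]
        present = sub.sum(axis=1) > 0
        taxa_share = (
            present.astype(float).groupby(rank_of).sum() / max(present.sum(), 1)
        )
        reads = sub.sum(axis=1).astype(float)
        read_share = reads.groupby(rank_of).sum() / reads.sum()
        incidence = (sub > 0).sum(axis=1).astype(float)
        inc_share = incidence.groupby(rank_of).sum() / incidence.sum()
        frame = pd.DataFrame(
            {
                "taxon_share": taxa_share,
                "read_share": read_share,
                "incidence_share": inc_share,
            }
        ).fillna(0.0)
        out[grp] = frame.sort_index()
    return out


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(
    config: PipelineConfig,
    hierarchy: dict[str, cc.HierarchyNode] | None = None,
) -> ReportBundle:
    """Execute every stage on the configured inputs and write the bundle.

    ``hierarchy`` defaults to the standard nested grouping derived from
    the metadata (all > stages > site-stages > focal-tree leaves).
    """
    config.validate()
    table = read_abundance_table(config.table_path)
    metadata = read_metadata(config.metadata_path)
    guild_db = read_guild_db(config.guild_db_path)
    metadata.require_covers(table.sample_ids)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[str] = []

    def record(name: str) -> Path:
        files.append(name)
        return outdir / name

    # --- composition summaries -------------------------------------------
    composition = summarize_composition(table, metadata, config.summary_rank)
    for grp, frame in composition.items():
        _write_tsv(frame, record(f"composition_{config.summary_rank}_{grp}.tsv"))

    # --- Hellinger + ordination + dispersion -----------------------------
    hellinger = dv.hellinger_transform(table)
    jsd = dv.jensen_shannon_matrix(table)
    jsd.write_tsv(record("jsd_distances.tsv"))
    ordination = dv.pcoa(jsd)
    _write_tsv(ordination.coordinates, record("pcoa_coordinates.tsv"))
    dispersion: dict[str, dv.DispersionTest] = {}
    for factor in ("stage", "site"):
        labels = metadata.frame.loc[jsd.labels, factor]
        counts = labels.value_counts()
        if len(counts) >= 2 and counts.min() >= 2:
            dispersion[factor] = dv.permdisp(
                jsd,
                list(labels),
                n_perm=config.permdisp_n_perm,
                seed=config.permdisp_seed,
            )
    _write_tsv(
        pd.DataFrame(
            {
                "factor": list(dispersion),
                "F": [d.F for d in dispersion.values()],
                "p_perm": [d.p_perm for d in dispersion.values()],
                "n_perm": [d.n_perm for d in dispersion.values()],
                "seed": [d.seed for d in dispersion.values()],
            }
        ),
        record("permdisp.tsv"),
        index=False,
    )

    # --- similarity network sweep ----------------------------------------
    bc = dv.bray_curtis_matrix(table, representation=config.representation)
    sim = sn.to_similarity_matrix(bc, rounding=config.rounding)
    sweep = sn.sweep_thresholds(sim)
    curve = sn.network_distance_curve(sweep, method=config.distance_method)
    t_star, critical, degenerate = sn.find_critical_network(
        sweep, method=config.distance_method
    )
    curve_frame = pd.DataFrame(
        {"threshold": range(len(curve)), "distance": curve}
    )
    curve_frame["critical"] = curve_frame["threshold"] == t_star
    _write_tsv(curve_frame, record("network_distance_curve.tsv"), index=False)
    partition = sn.modularity_partition(
        critical, algorithm=config.modularity_algorithm, seed=config.modularity_seed
    )
    sn.export_graph(critical, record("critical_network.graphml"), partition)
    sn.export_graph(
        critical, record("critical_network_edges.tsv"), partition,
        format="edgelist_tsv",
    )

    # --- co-occurrence networks per group --------------------------------
    inc = cc.to_incidence(table, min_count=config.min_count)
    hierarchy = hierarchy or _default_hierarchy(metadata)
    for name, node in hierarchy.items():
        if node.parent is None:
            continue
        graph = cc.cooccurrence_graph(inc, node.samples)
        sn.export_graph(graph, record(f"cooccurrence_{name}.graphml"))

    # --- hierarchical strict cores + antagonism screen -------------------
    core_h = cc.hierarchical_cores(inc, hierarchy, config.occupancy_cutoff)
    core_h.write_tsv(record("core_hierarchy.tsv"))
    candidates = sorted(
        set().union(*(c.members for c in core_h.cores.values())) or set()
    )
    if len(candidates) >= 2:
        antagonisms = cc.antagonism_screen(
            hellinger, candidates, alpha=config.spearman_alpha,
            adjust=config.spearman_adjust,
        )
    else:
        antagonisms = dv.CorrelationResult(
            pd.DataFrame(
                columns=["taxon_a", "taxon_b", "rho", "p_raw", "p_adjusted", "significant"]
            ),
            config.spearman_alpha,
        )
    antagonisms.write_tsv(record("antagonisms.tsv"))
    screen = dv.spearman_screen(
        hellinger, top_k=config.spearman_top_k, alpha=config.spearman_alpha,
        adjust=config.spearman_adjust,
    )
    screen.write_tsv(record("spearman_screen.tsv"))

    # --- guilds + Venn ----------------------------------------------------
    assignments = gs.assign_guilds(table, guild_db)
    groups = {
        name: node.samples for name, node in hierarchy.items() if node.parent is not None
    } or {"all": table.sample_ids}
    profile = gs.trophic_mode_profile(assignments, table, groups, weight="taxa")
    _write_tsv(profile, record("trophic_profile.tsv"))
    leaf_nodes = {
        name: set(core_h.cores[name].members)
        for name, node in hierarchy.items()
        if not any(n.parent == name for n in hierarchy.values())
    }
    venn_sets = dict(list(leaf_nodes.items())[:5])
    if len(venn_sets) < 2:
        venn_sets = {
            "core": set(core_h.cores[next(iter(hierarchy))].members),
            "all_taxa": set(table.taxon_ids),
        }
    venn = gs.venn_partition(venn_sets)
    venn.write_tsv(record("core_venn.tsv"))

    # --- run log ----------------------------------------------------------
    log = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "critical_threshold": int(t_star),
        "critical_degenerate": bool(degenerate),
        "modularity_Q": partition.Q,
        "n_modules": len(set(partition.assignment.values())),
        "files": files,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))

    return ReportBundle(
        outdir=outdir,
        composition=composition,
        dispersion=dispersion,
        critical_threshold=int(t_star),
        critical_degenerate=degenerate,
        partition=partition,
        core_hierarchy=core_h,
        antagonisms=antagonisms,
        trophic_profile=profile,
        venn=venn,
        files=files,
    )


def _default_hierarchy(metadata: SampleMetadata):
    from .synthetic_data import default_hierarchy

    return default_hierarchy(metadata)
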