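"""Presence/absence analysis: co-occurrence networks and strict cores.

A taxon is *present* in a sample when it has at least ``min_count``
reads (one read by default).  Two taxa co-occur when some sample holds
both; the co-occurrence network of a sample group is the union, over
its samples, of the complete graphs on each sample's present taxa.  A
group's core mycobiome is the set of taxa whose occupancy — the
fraction of group samples where present — reaches a cutoff; the
strictest core uses a cutoff of 1.0 (present in every sample).  Nested
sample groups therefore carry nested strict cores: the core of a larger
group is always contained in the core of any of its subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .diversity import CorrelationResult, spearman_screen
from .io_model import AbundanceTable


@dataclass
class IncidenceTable:
    """Boolean presence matrix derived from read counts."""

    presence: pd.DataFrame  # taxa x samples, bool
    min_count: int

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.columns)


@dataclass
class CoreSet:
    group_samples: list[str]
    occupancy_cutoff: float
    members: set[str]
    occupancy: pd.Series  # per taxon, fraction of group samples occupied


@dataclass
class HierarchyNode:
    name: str
    samples: list[str]
    parent: str | None = None


@dataclass
class CoreHierarchy:
    nodes: dict[str, HierarchyNode]
    cores: dict[str, CoreSet]
    nesting_report: list[str] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for name in self.nodes:
            core = self.cores[name]
            for taxon in sorted(core.members):
                rows.append(
                    {
                        "group": name,
                        "taxon": taxon,
                        "occupancy": core.occupancy[taxon],
                    }
                )
        pd.DataFrame(rows, columns=["group", "taxon", "occupancy"]).to_csv(
            path, sep="\t", index=False
        )


def to_incidence(table: AbundanceTable, min_count: int = 1) -> IncidenceTable:
    """Binarize read counts: present iff count >= min_count."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return IncidenceTable(table.counts >= min_count, min_count)


def aggregate_samples(
    inc: IncidenceTable, groups: Mapping[str, Sequence[str]]
) -> IncidenceTable:
    """Pool samples (logical OR of presence) into named units.

    Used to collapse the individually sequenced leaves of one tree into a
    single tree-level sampling unit before core extraction.
    """
    cols = {}
    for name, members in groups.items():
        missing = [s for s in members if s not in inc.presence.columns]
        if missing:
            raise KeyError(f"unknown samples in group {name!r}: {missing}")
        cols[name] = inc.presence[list(members)].any(axis=1)
    return IncidenceTable(pd.DataFrame(cols), inc.min_count)


def cooccurrence_graph(inc: IncidenceTable, samples: Iterable[str]) -> nx.Graph:
    """Co-occurrence network of the taxa present in the selected samples.

    Nodes are taxa present in at least one selected sample; an edge joins
    two taxa iff some selected sample holds both, and the edge attribute
    ``witnesses`` lists every such sample.
    """
    selected = list(samples)
    if not selected:
        raise ValueError("empty sample selection")
    missing = [s for s in selected if s not in inc.presence.columns]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    sub = inc.presence[selected]
    g = nx.Graph()
    present_any = sub.any(axis=1)
    g.add_nodes_from(sub.index[present_any])
    witnesses: dict[tuple, list[str]] = {}
    for sample in selected:
        taxa = list(sub.index[sub[sample]])
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                key = (taxa[i], taxa[j]) if taxa[i] <= taxa[j] else (taxa[j], taxa[i])
                witnesses.setdefault(key, []).append(sample)
    g.add_edges_from((a, b, {"witnesses": w}) for (a, b), w in witnesses.items())
    return g


def core_taxa(
    inc: IncidenceTable,
    group_samples: Iterable[str],
    occupancy_cutoff: float = 1.0,
) -> CoreSet:
    """Occupancy-defined core of a sample group.

    A taxon belongs to the core when the fraction of group samples where
    it is present is at least ``occupancy_cutoff``; the default 1.0 is
    the strict core (present in all samples of the group).
    """
    selected = list(group_samples)
    if not selected:
        raise ValueError("empty sample group")
    if not 0 < occupancy_cutoff <= 1:
        raise ValueError("occupancy_cutoff must lie in (0, 1]")
    missing = [s for s in selected if s not in inc.presence.columns]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    occupancy = inc.presence[selected].mean(axis=1)
    members = set(occupancy.index[occupancy >= occupancy_cutoff])
    return CoreSet(selected, occupancy_cutoff, members, occupancy)


def hierarchical_cores(
    inc: IncidenceTable,
    hierarchy: Mapping[str, HierarchyNode] | Iterable[HierarchyNode],
    occupancy_cutoff: float = 1.0,
) -> CoreHierarchy:
    """Core sets over a nested family of sample groups.

    Every child node's samples must be a subset of its parent's.  At
    cutoff 1.0 the core of a parent group is mathematically guaranteed to
    be a subset of each child's core; ``nesting_report`` records any
    violation (which would indicate an implementation bug) and must
    therefore come back empty.
    """
    if not isinstance(hierarchy, Mapping):
        hierarchy = {node.name: node for node in hierarchy}
    nodes = dict(hierarchy)
    for name, node in nodes.items():
        if node.parent is not None:
            if node.parent not in nodes:
                raise ValueError(f"node {name!r} has unknown parent {node.parent!r}")
            extra = set(node.samples) - set(nodes[node.parent].samples)
            if extra:
                raise ValueError(
                    f"node {name!r} is not nested in parent "
                    f"{node.parent!r}: extra samples {sorted(extra)}"
                )
    cores = {
        name: core_taxa(inc, node.samples, occupancy_cutoff)
        for name, node in nodes.items()
    }
    report = []
    if occupancy_cutoff == 1.0:
        for name, node in nodes.items():
            if node.parent is None:
                continue
            stray = cores[node.parent].members - cores[name].members
            if stray:
                report.append(
                    f"core({node.parent}) not within core({name}): {sorted(stray)}"
                )
    return CoreHierarchy(nodes, cores, report)


def antagonism_screen(
    hellinger: pd.DataFrame,
    candidates: Iterable[str],
    alpha: float = 0.01,
    adjust: str = "none",
) -> CorrelationResult:
    """Negative Spearman correlations among candidate (e.g. core) taxa.

    Screens every pair among the candidates on the supplied
    Hellinger-transformed abundances and returns only the pairs with
    rho < 0 and p < alpha, sorted most-negative first — the signature of
    a putative antagonistic interaction between co-occurring taxa.
    """
    wanted = sorted(set(candidates))
    missing = [t for t in wanted if t not in hellinger.index]
    if missing:
        raise KeyError(f"candidates not in table: {missing}")
    result = spearman_screen(
        hellinger.loc[wanted], top_k=len(wanted), alpha=alpha, adjust=adjust
    )
    pairs = result.pairs
    keep = (pairs["rho"] < 0) & pairs["significant"]
    pairs = pairs[keep].sort_values("rho", kind="mergesort").reset_index(drop=True)
    return CorrelationResult(pairs, alpha, result.diagnostics)
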