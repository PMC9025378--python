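"""Trophic-mode/guild assignment and shared/unique set algebra.

Fungal taxa are classified into trophic modes (saprotroph, pathotroph,
symbiotroph, or combinations) by matching their taxonomy against a local
guild lookup table at the most specific rank available, in the style of
the FunGuild annotation tool.  Venn-type comparisons between named taxon
collections are computed as exact region partitions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io_model import AbundanceTable, GuildDatabase, TaxonomyRecord

# match order: most specific rank first
_MATCH_RANKS = ("species", "genus", "family", "order", "class", "phylum")


@dataclass(frozen=True)
class GuildAssignment:
    taxon_id: str
    matched_name: str | None
    matched_rank: str | None
    trophic_modes: frozenset[str]  # empty <=> unassigned
    guild: str
    confidence: str

    @property
    def assigned(self) -> bool:
        return bool(self.trophic_modes)

    @property
    def mode_label(self) -> str:
        """Canonical category label, e.g. 'pathotroph+saprotroph'."""
        if not self.trophic_modes:
            return "unassigned"
        return "+".join(sorted(self.trophic_modes))


def assign_guild(
    taxon_id: str, tax: TaxonomyRecord, db: GuildDatabase
) -> GuildAssignment:
    """Match one taxon against the guild database, deepest rank first.

    A species-level record beats a genus-level one, and so on up to
    phylum.  A taxon with no match at any rank is returned as
    'unassigned' — a value, not an error.
    """
    if len(db) == 0:
        raise ValueError("guild database is empty")
    for rank in _MATCH_RANKS:
        name = tax.get(rank)
        if name is None:
            continue
        rec = db.lookup(name, rank)
        if rec is not None:
            return GuildAssignment(
                taxon_id=taxon_id,
                matched_name=name,
                matched_rank=rank,
                trophic_modes=rec.trophic_modes,
                guild=rec.guild,
                confidence=rec.confidence,
            )
    return GuildAssignment(taxon_id, None, None, frozenset(), "unassigned", "unassigned")


def assign_guilds(table: AbundanceTable, db: GuildDatabase) -> dict[str, GuildAssignment]:
    return {t: assign_guild(t, table.taxonomy[t], db) for t in table.taxon_ids}


def trophic_mode_profile(
    assignments: Mapping[str, GuildAssignment],
    table: AbundanceTable,
    groups: Mapping[str, Sequence[str]],
    weight: str = "taxa",
) -> pd.DataFrame:
    """Per-group proportions over trophic-mode combinations.

    ``weight='taxa'`` counts each taxon present in the group once;
    ``weight='reads'`` weights by read counts.  Categories include every
    observed mode combination plus 'unassigned'; each group's proportions
    sum to one.
    """
    if weight not in ("taxa", "reads"):
        raise ValueError("weight must be 'taxa' or 'reads'")
    missing = [t for t in table.taxon_ids if t not in assignments]
    if missing:
        raise ValueError(f"assignments missing for taxa: {missing}")
    labels = pd.Series({t: assignments[t].mode_label for t in table.taxon_ids})
    out = {}
    for name, samples in groups.items():
        sub = table.counts[list(samples)]
        if weight == "taxa":
            weights = (sub.sum(axis=1) > 0).astype(float)
        else:
            weights = sub.sum(axis=1).astype(float)
        total = weights.sum()
        if total == 0:
            raise ValueError(f"group {name!r} has no data")
        out[name] = weights.groupby(labels).sum() / total
    frame = pd.DataFrame(out).fillna(0.0)
    return frame.sort_index()


@dataclass
class VennSummary:
    set_names: list[str]
    regions: dict[frozenset, set]  # included-names combination -> members

    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.regions.items()}

    def region(self, *names: str) -> set:
        """Members exactly in the given sets and in no other."""
        return set(self.regions.get(frozenset(names), set()))

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for combo in sorted(self.regions, key=lambda c: (len(c), sorted(c))):
            mask = "".join("1" if n in combo else "0" for n in self.set_names)
            members = sorted(self.regions[combo])
            rows.append(
                {
                    "sets": "&".join(sorted(combo)),
                    "mask": mask,
                    "count": len(members),
                    "members": ";".join(str(m) for m in members),
                }
            )
        pd.DataFrame(rows, columns=["sets", "mask", "count", "members"]).to_csv(
            path, sep="\t", index=False
        )


def venn_partition(
    sets: Mapping[str, Iterable],
    normalizer: Callable | None = None,
) -> VennSummary:
    """Exact region partition of 2-5 named sets.

    Every non-empty inclusion/exclusion combination of the sets is
    enumerated with its exact membership; regions are disjoint and cover
    the union.  The default normalizer strips surrounding whitespace and
    preserves case.
    """
    names = list(sets)
    if not 2 <= len(names) <= 5:
        raise ValueError("venn_partition takes between two and five sets")
    if normalizer is None:
        normalizer = lambda x: x.strip() if isinstance(x, str) else x
    cleaned = {name: {normalizer(m) for m in members} for name, members in sets.items()}
    regions: dict[frozenset, set] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(cleaned[n] for n in combo))
            for other in names:
                if other not in combo:
                    inside -= cleaned[other]
            regions[frozenset(combo)] = inside
    return VennSummary(names, regions)
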