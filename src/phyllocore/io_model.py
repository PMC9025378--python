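"""Tabular input/output and the shared data model.

The universal input of the pipeline is an OTU abundance table: a taxa x
samples matrix of non-negative integer read counts, with one taxonomy
string per taxon.  Files are plain TSV (UTF-8, header row, no quoting):
first column holds taxon identifiers, one column holds the taxonomy
string, and every remaining column is a sample of integer counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_UNITE_PREFIX = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


class TableFormatError(ValueError):
    """Raised when an input file violates the tabular schema."""


@dataclass(frozen=True)
class TaxonomyRecord:
    """Parsed taxonomy of one OTU.

    ``ranks`` maps each of the seven canonical ranks to a name; ranks the
    source string does not resolve are absent.  ``source`` preserves the
    raw label verbatim so placeholder names such as ``Ascomycota sp. 52-1``
    survive a round trip untouched.
    """

    ranks: Mapping[str, str]
    source: str

    def __post_init__(self) -> None:
        bad = set(self.ranks) - set(RANKS)
        if bad:
            raise ValueError(f"unknown taxonomy ranks: {sorted(bad)}")
        for rank, name in self.ranks.items():
            if not name:
                raise ValueError(f"empty name for rank {rank!r}")

    def get(self, rank: str) -> str | None:
        return self.ranks.get(rank)


def parse_taxonomy(source: str) -> TaxonomyRecord:
    """Parse a taxonomy label into a :class:`TaxonomyRecord`.

    Three dialects are recognised:

    * UNITE-style ``k__Fungi;p__Basidiomycota;...;g__Meira`` — every
      non-empty ``X__name`` token fills the matching rank;
    * plain binomial ``Genus species`` — fills genus and species;
    * a single capitalised word — fills genus only.

    Anything else (e.g. placeholder OTU labels like ``Ascomycota sp.
    52-1``) is kept opaque: no rank is filled, the source string is
    preserved.
    """
    if not source or not source.strip():
        raise ValueError("empty taxonomy string")
    text = source.strip()
    ranks: dict[str, str] = {}
    if "__" in text:
        for token in text.split(";"):
            token = token.strip()
            if not token:
                continue
            m = re.fullmatch(r"([kpcofgs])__(.*)", token)
            if m is None:
                continue  # unparseable token -> rank stays unknown
            name = m.group(2).replace("_", " ").strip()
            if name:
                ranks[_UNITE_PREFIX[m.group(1)]] = name
        return TaxonomyRecord(ranks=ranks, source=source)
    words = text.split()
    if len(words) == 2 and re.fullmatch(r"[A-Z][a-z-]+", words[0]) and re.fullmatch(
        r"[a-z-]+", words[1]
    ):
        return TaxonomyRecord(
            ranks={"genus": words[0], "species": f"{words[0]} {words[1]}"},
            source=source,
        )
    if len(words) == 1 and re.fullmatch(r"[A-Z][a-z-]+", words[0]):
        return TaxonomyRecord(ranks={"genus": words[0]}, source=source)
    return TaxonomyRecord(ranks={}, source=source)


@dataclass
class AbundanceTable:
    """Taxa x samples integer read-count matrix with per-taxon taxonomy."""

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonomyRecord]

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise TableFormatError(f"duplicate taxon ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise TableFormatError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            raise TableFormatError("counts must be integers (no relative abundances)")
        if values.size and values.min() < 0:
            r, c = np.unravel_index(int(np.argmin(values)), values.shape)
            raise TableFormatError(
                f"negative count at taxon {idx[r]!r}, sample {cols[c]!r}"
            )
        missing = [t for t in idx if t not in self.taxonomy]
        if missing:
            raise TableFormatError(f"taxa without taxonomy entry: {missing}")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        wanted = list(sample_ids)
        missing = [s for s in wanted if s not in self.counts.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return AbundanceTable(self.counts[wanted].copy(), dict(self.taxonomy))


def filter_taxa_by_total(table: AbundanceTable, min_total_reads: int) -> AbundanceTable:
    """Keep taxa whose total read count is strictly greater than the cutoff.

    Mirrors the common display filter "taxa with more than N reads"; the
    inequality is strict, so a taxon with exactly ``min_total_reads`` reads
    is dropped.  The sample set is unchanged.  Idempotent and monotone in
    the cutoff.
    """
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    keep = table.taxon_totals() > min_total_reads
    counts = table.counts.loc[keep].copy()
    taxonomy = {t: table.taxonomy[t] for t in counts.index}
    return AbundanceTable(counts, taxonomy)


@dataclass
class SampleMetadata:
    """Per-sample design variables: site, developmental stage, tree, leaf."""

    frame: pd.DataFrame  # indexed by sample id

    STAGES = ("adult", "plantlet")

    def __post_init__(self) -> None:
        required = {"site", "stage", "tree"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TableFormatError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dups = sorted(self.frame.index[self.frame.index.duplicated()].unique())
            raise TableFormatError(f"duplicate sample ids in metadata: {dups}")
        bad_stage = sorted(set(self.frame["stage"]) - set(self.STAGES))
        if bad_stage:
            raise TableFormatError(
                f"stage must be one of {self.STAGES}; got {bad_stage}"
            )
        if "leaf" in self.frame.columns:
            pairs = list(zip(self.frame["tree"], self.frame["leaf"]))
            seen: set[tuple] = set()
            for p in pairs:
                if p in seen:
                    raise TableFormatError(f"duplicate (tree, leaf) pair: {p}")
                seen.add(p)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching every column == value condition."""
        mask = pd.Series(True, index=self.frame.index)
        for col, value in conditions.items():
            mask &= self.frame[col] == value
        return list(self.frame.index[mask])

    def require_covers(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise TableFormatError(f"metadata missing samples: {missing}")


@dataclass(frozen=True)
class GuildRecord:
    taxon: str
    rank: str
    trophic_modes: frozenset[str]
    guild: str
    confidence: str


TROPHIC_MODES = ("saprotroph", "pathotroph", "symbiotroph")


@dataclass
class GuildDatabase:
    """Local lookup table of trophic modes/guilds keyed by (taxon name, rank)."""

    records: list[GuildRecord]
    _index: dict[tuple[str, str], GuildRecord] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for rec in self.records:
            if rec.rank not in RANKS:
                raise TableFormatError(f"guild record with unknown rank {rec.rank!r}")
            if not rec.trophic_modes:
                raise TableFormatError(
                    f"guild record for {rec.taxon!r} has empty trophic modes"
                )
            bad = set(rec.trophic_modes) - set(TROPHIC_MODES)
            if bad:
                raise TableFormatError(
                    f"unknown trophic modes {sorted(bad)} for {rec.taxon!r}"
                )
            key = (rec.taxon, rec.rank)
            if key in self._index:
                raise TableFormatError(f"duplicate guild record for {key}")
            self._index[key] = rec

    def lookup(self, taxon: str, rank: str) -> GuildRecord | None:
        return self._index.get((taxon, rank))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(
    path: str | Path,
    taxonomy_col: str = "taxonomy",
    samples_as_rows: bool = False,
) -> AbundanceTable:
    """Read a TSV OTU table (taxa as rows by default) into an AbundanceTable.

    Row and column order of the file are preserved.  Count cells must be
    non-negative integers; offending cells are reported by taxon and sample.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    dups = sorted({c for c in header[1:] if c in seen or seen.add(c)})
    if dups:  # pandas silently renames duplicate headers, so check raw line
        raise TableFormatError(f"{path.name}: duplicate sample columns: {dups}")
    frame = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if samples_as_rows:
        frame = frame.T
    if taxonomy_col not in frame.columns:
        raise TableFormatError(
            f"{path.name}: taxonomy column {taxonomy_col!r} not found"
        )
    tax_strings = frame[taxonomy_col]
    count_frame = frame.drop(columns=[taxonomy_col])
    if count_frame.columns.has_duplicates:
        dups = sorted(count_frame.columns[count_frame.columns.duplicated()].unique())
        raise TableFormatError(f"{path.name}: duplicate sample columns: {dups}")
    counts = pd.DataFrame(index=count_frame.index)
    for col in count_frame.columns:
        parsed = pd.to_numeric(count_frame[col], errors="coerce")
        bad = parsed.isna() | (parsed != parsed.round()) | (parsed < 0)
        if bad.any():
            row = bad.idxmax()
            raise TableFormatError(
                f"{path.name}: non-integer or negative count at "
                f"taxon {row!r}, sample {col!r}: {count_frame.at[row, col]!r}"
            )
        counts[col] = parsed.astype(np.int64)
    taxonomy = {t: parse_taxonomy(s) for t, s in tax_strings.items()}
    return AbundanceTable(counts, taxonomy)


def write_table(
    table: AbundanceTable, path: str | Path, taxonomy_col: str = "taxonomy"
) -> None:
    """Write an AbundanceTable as TSV; inverse of :func:`read_abundance_table`."""
    out = table.counts.copy()
    out.insert(0, taxonomy_col, [table.taxonomy[t].source for t in out.index])
    out.index.name = out.index.name or "otu_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def read_guild_db(path: str | Path) -> GuildDatabase:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"taxon", "rank", "trophic_mode", "guild", "confidence"}
    missing = required - set(frame.columns)
    if missing:
        raise TableFormatError(f"guild DB missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        modes = frozenset(m for m in row["trophic_mode"].split(";") if m)
        records.append(
            GuildRecord(
                taxon=row["taxon"],
                rank=row["rank"],
                trophic_modes=modes,
                guild=row["guild"],
                confidence=row["confidence"],
            )
        )
    return GuildDatabase(records)


def write_guild_db(db: GuildDatabase, path: str | Path) -> None:
    rows = [
        {
            "taxon": r.taxon,
            "rank": r.rank,
            "trophic_mode": ";".join(sorted(r.trophic_modes)),
            "guild": r.guild,
            "confidence": r.confidence,
        }
        for r in db.records
    ]
    pd.DataFrame(rows, columns=["taxon", "rank", "trophic_mode", "guild", "confidence"]).to_csv(
        path, sep="\t", index=False
    )
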