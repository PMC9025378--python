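"""Synthetic phyllosphere metabarcoding communities with planted truth.

The generator emulates a two-site, two-stage leaf-sampling design: five
adult trees per site, one focal tree with individually sequenced leaves
(the intra-individual scale), and a set of plantlets at one site.  Reads
are drawn per sample by multinomial sampling at a fixed depth from
log-normal relative-abundance vectors perturbed by group effects.  Four
kinds of structure are planted and recorded in a :class:`SyntheticTruth`
so every downstream stage can be scored against ground truth:

* a nested family of strict core taxa, present in every sample of their
  hierarchy node by construction (and in *only* those nodes: any other
  taxon that comes out ubiquitous in a node is knocked out of one of its
  samples, so the strict core of each node equals the planted set);
* one antagonist taxon pair coupled through a shared latent factor with
  opposite signs, calibrated to a target Spearman correlation;
* a stage dominance shift: one taxon order is fold-enriched in
  plantlets, mirroring the adult/plantlet contrast in real communities;
* per-genus trophic modes drawn at configured fractions, emitted as a
  matching guild-database fixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cooccurrence_core import HierarchyNode
from .io_model import (
    AbundanceTable,
    GuildDatabase,
    GuildRecord,
    SampleMetadata,
    parse_taxonomy,
)
from .similarity_network import SimilarityMatrix

#: plantlet-enriched taxon order (the stage-shift group)
STAGE_SHIFT_ORDER = "Exobasidiales"

# latent-factor exponent calibrated by pilot simulation so the planted
# antagonist pair lands near the target Spearman rho at default noise
_ANTAGONIST_COUPLING = {-0.6: 1.5, -0.5: 1.05}


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator."""

    sites: tuple[str, str] = ("CNF", "TNF")
    trees_per_site: int = 5
    focal_tree_leaves: int = 5  # leaves of the first TNF tree, sequenced singly
    n_plantlets: int = 5  # at the second site
    n_satellite_taxa: int = 80
    depth: int = 50_000
    overdispersion: float = 0.8  # per-sample log-normal noise (sd of log)
    site_effect: float = 0.2  # per-taxon, per-site log-normal effect (sd)
    stage_shift_fold: float = 8.0  # plantlet enrichment of STAGE_SHIFT_ORDER
    antagonist_target_rho: float = -0.6
    mode_fractions: dict = field(
        default_factory=lambda: {
            "saprotroph": 0.55,
            "pathotroph": 0.10,
            "symbiotroph": 0.02,
        }
    )

    def validate(self) -> None:
        if self.trees_per_site < 2 or self.n_plantlets < 2:
            raise ValueError("need at least two trees per site and two plantlets")
        if self.focal_tree_leaves < 1:
            raise ValueError("focal_tree_leaves must be >= 1")
        if self.depth < 100:
            raise ValueError("sequencing depth unrealistically low")
        if sum(self.mode_fractions.values()) > 1 + 1e-9:
            raise ValueError("mode fractions must sum to at most 1")
        if self.antagonist_target_rho not in _ANTAGONIST_COUPLING:
            raise ValueError(
                f"antagonist_target_rho must be one of "
                f"{sorted(_ANTAGONIST_COUPLING)}"
            )


@dataclass
class SyntheticTruth:
    """Planted structure of one generated dataset."""

    planted_core: dict[str, list[str]]  # hierarchy node -> core taxon ids
    antagonist_pairs: list[tuple[str, str, float]]
    stage_shift: tuple[str, float]  # (taxon order, fold)
    block_structure: dict[str, str]  # sample -> block id (stage)
    mode_fractions: dict[str, float]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["planted_core"] = {
            k: sorted(v) for k, v in self.planted_core.items()
        }
        payload["antagonist_pairs"] = [list(p) for p in self.antagonist_pairs]
        payload["stage_shift"] = list(self.stage_shift)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted_core={k: list(v) for k, v in payload["planted_core"].items()},
            antagonist_pairs=[
                (a, b, float(r)) for a, b, r in payload["antagonist_pairs"]
            ],
            stage_shift=(payload["stage_shift"][0], float(payload["stage_shift"][1])),
            block_structure=dict(payload["block_structure"]),
            mode_fractions=dict(payload["mode_fractions"]),
            seed=int(payload["seed"]),
        )


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

def _design(config: SyntheticConfig) -> pd.DataFrame:
    """Sample sheet: one row per sequenced unit (leaf pool or single leaf)."""
    site_a, site_b = config.sites
    rows = []
    for i in range(1, config.trees_per_site + 1):
        rows.append((f"{site_a}_C{i}", site_a, "adult", f"C{i}", ""))
    for i in range(1, config.trees_per_site + 1):
        tree = f"T{i}"
        if i == 1:
            for leaf in range(1, config.focal_tree_leaves + 1):
                rows.append(
                    (f"{site_b}_T1_L{leaf}", site_b, "adult", tree, f"L{leaf}")
                )
        else:
            rows.append((f"{site_b}_{tree}", site_b, "adult", tree, ""))
    for i in range(1, config.n_plantlets + 1):
        rows.append((f"{site_b}_P{i}", site_b, "plantlet", f"P{i}", ""))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "site", "stage", "tree", "leaf"]
    ).set_index("sample_id")
    return frame


def default_hierarchy(metadata: SampleMetadata) -> dict[str, HierarchyNode]:
    """The nested grouping family: all > stages > site-stages > focal leaves."""
    frame = metadata.frame
    site_a, site_b = sorted(set(frame["site"]))
    all_samples = list(frame.index)
    adults = list(frame.index[frame["stage"] == "adult"])
    plantlets = list(frame.index[frame["stage"] == "plantlet"])
    a_adults = list(frame.index[(frame["stage"] == "adult") & (frame["site"] == site_a)])
    b_adults = list(frame.index[(frame["stage"] == "adult") & (frame["site"] == site_b)])
    focal = list(frame.index[(frame["tree"] == "T1") & (frame["leaf"] != "")])
    nodes = {
        "all": HierarchyNode("all", all_samples, None),
        "adults": HierarchyNode("adults", adults, "all"),
        "plantlets": HierarchyNode("plantlets", plantlets, "all"),
        f"{site_a}_adults": HierarchyNode(f"{site_a}_adults", a_adults, "adults"),
        f"{site_b}_adults": HierarchyNode(f"{site_b}_adults", b_adults, "adults"),
    }
    if focal:
        nodes["T1_leaves"] = HierarchyNode("T1_leaves", focal, f"{site_b}_adults")
    return nodes


# ---------------------------------------------------------------------------
# taxon panel
# ---------------------------------------------------------------------------

_UNITE = "k__Fungi;p__{phylum};c__{cls};o__{order};f__{family};g__{genus}"

_CORE_PANEL = [
    # (otu id, hierarchy node, taxonomy string, base weight)
    ("otu1", "all", "Ascomycota sp. 52-1", 260.0),
    (
        "otu2",
        "all",
        _UNITE.format(
            phylum="Basidiomycota", cls="Exobasidiomycetes", order="Exobasidiales",
            family="Brachybasidiaceae", genus="Meira",
        ) + ";s__Meira_argovae",
        220.0,
    ),
    (
        "otu3",
        "all",
        _UNITE.format(
            phylum="Basidiomycota", cls="Exobasidiomycetes", order="Exobasidiales",
            family="Brachybasidiaceae", genus="Meira",
        ) + ";s__Meira_nashicola",
        150.0,
    ),
    (
        "otu4",
        "adults",
        _UNITE.format(
            phylum="Basidiomycota", cls="Exobasidiomycetes", order="Microstromatales",
            family="Microstromataceae", genus="Sympodiomycopsis",
        ),
        120.0,
    ),
    (
        "otu5",
        "adults",
        _UNITE.format(
            phylum="Basidiomycota", cls="Exobasidiomycetes", order="Exobasidiales",
            family="Brachybasidiaceae", genus="Meira",
        ) + ";s__Meira_geulakonigii",
        100.0,
    ),
    ("otu6", "plantlets", "Ascomycota sp. 26", 90.0),
    (
        "otu7",
        "CNF_adults",
        _UNITE.format(
            phylum="Ascomycota", cls="Saccharomycetes", order="Saccharomycetales",
            family="Debaryomycetaceae", genus="Meyerozyma",
        ),
        80.0,
    ),
    ("otu8", "TNF_adults", "Ascomycota sp. 24", 85.0),
    (
        "otu9",
        "TNF_adults",
        _UNITE.format(
            phylum="Basidiomycota", cls="Agaricomycetes", order="Polyporales",
            family="Meripilaceae", genus="Physisporinus",
        ),
        70.0,
    ),
    ("otu10", "T1_leaves", "Dothideomycetes sp. 1-2", 75.0),
]

_SATELLITE_ORDERS = [
    ("Basidiomycota", "Agaricomycetes", "Agaricales"),
    ("Ascomycota", "Eurotiomycetes", "Chaetothyriales"),
    ("Basidiomycota", "Agaricomycetes", "Polyporales"),
    ("Basidiomycota", "Exobasidiomycetes", "Exobasidiales"),
    ("Ascomycota", "Dothideomycetes", "Pleosporales"),
    ("Ascomycota", "Sordariomycetes", "Hypocreales"),
]
_SATELLITE_ORDER_WEIGHTS = [0.30, 0.20, 0.15, 0.12, 0.13, 0.10]


def _taxon_panel(config: SyntheticConfig, rng: np.random.Generator):
    """(ids, taxonomy strings, base weights, order labels, planted map)."""
    ids, tax, weights, orders = [], [], [], []
    planted: dict[str, list[str]] = {}
    for otu, node, taxonomy, weight in _CORE_PANEL:
        ids.append(otu)
        tax.append(taxonomy)
        weights.append(weight)
        orders.append("Exobasidiales" if "Exobasidiales" in taxonomy else
                      ("Microstromatales" if "Microstromatales" in taxonomy else "other"))
        planted.setdefault(node, []).append(otu)
    order_idx = rng.choice(
        len(_SATELLITE_ORDERS), size=config.n_satellite_taxa,
        p=_SATELLITE_ORDER_WEIGHTS,
    )
    sat_weights = np.exp(rng.normal(np.log(0.02), 2.0, size=config.n_satellite_taxa))
    for k in range(config.n_satellite_taxa):
        phylum, cls, order = _SATELLITE_ORDERS[order_idx[k]]
        genus = f"Fungigenus{k + 1}"
        ids.append(f"otu{len(_CORE_PANEL) + k + 1}")
        tax.append(
            _UNITE.format(phylum=phylum, cls=cls, order=order,
                          family=f"{order}_fam", genus=genus)
        )
        weights.append(float(sat_weights[k]))
        orders.append(order)
    return ids, tax, np.array(weights), orders, planted


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def _draw_counts(
    config: SyntheticConfig,
    rng: np.random.Generator,
    design: pd.DataFrame,
    base_weights: np.ndarray,
    orders: Sequence[str],
    antagonists: Sequence[tuple[int, int, float]] = (),
    group_effects: bool = True,
) -> np.ndarray:
    """Multinomial read counts, taxa x samples."""
    n_taxa = base_weights.shape[0]
    samples = list(design.index)
    shift_mask = np.array([o == STAGE_SHIFT_ORDER for o in orders])
    site_names = sorted(set(design["site"]))
    site_factors = {
        s: np.exp(rng.normal(0.0, config.site_effect, size=n_taxa))
        for s in site_names
    }
    counts = np.zeros((n_taxa, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        w = base_weights * np.exp(
            rng.normal(0.0, config.overdispersion, size=n_taxa)
        )
        if group_effects:
            w = w * site_factors[design.at[sample, "site"]]
            if design.at[sample, "stage"] == "plantlet":
                w = w * np.where(shift_mask, config.stage_shift_fold, 1.0)
        for ia, ib, _ in antagonists:
            u = rng.uniform()
            g = _ANTAGONIST_COUPLING[config.antagonist_target_rho]
            w[ia] *= u**g
            w[ib] *= (1.0 - u) ** g
        counts[:, j] = rng.multinomial(config.depth, w / w.sum())
    return counts


def _force_core_presence(
    counts: np.ndarray,
    required: dict[int, set[int]],  # taxon index -> sample indices required
) -> None:
    """Guarantee planted core presence, conserving each sample's depth.

    A missing required taxon receives one read moved from the sample's
    most abundant taxon (a deterministic repair; misses are rare because
    planted cores are abundant).
    """
    for t, samples in required.items():
        for s in samples:
            if counts[t, s] == 0:
                donor = int(np.argmax(counts[:, s]))
                counts[donor, s] -= 1
                counts[t, s] += 1


def _knock_out_accidental_cores(
    counts: np.ndarray,
    rng: np.random.Generator,
    nodes: dict[str, HierarchyNode],
    sample_pos: dict[str, int],
    planted_full: dict[str, set[int]],
    required_samples: dict[int, set[int]],
) -> None:
    """Remove non-planted taxa from one sample of any node they saturate.

    Ensures the strict core of every hierarchy node equals exactly its
    planted set.  Reads removed are transferred to the sample's most
    abundant taxon so the column sum (sequencing depth) is conserved.
    """
    changed = True
    while changed:
        changed = False
        for name, node in nodes.items():
            cols = [sample_pos[s] for s in node.samples]
            present = counts[:, cols] > 0
            ubiquitous = np.nonzero(present.all(axis=1))[0]
            for t in ubiquitous:
                if t in planted_full[name]:
                    continue
                candidates = sorted(
                    c for c in cols if c not in required_samples.get(t, set())
                )
                if not candidates:  # planted in every child branch: impossible
                    raise RuntimeError("cannot clear accidental core taxon")
                victim = int(rng.choice(candidates))
                donor = int(np.argmax(counts[:, victim]))
                if donor == t:
                    order = np.argsort(counts[:, victim])[::-1]
                    donor = int(order[1])
                counts[donor, victim] += counts[t, victim]
                counts[t, victim] = 0
                changed = True


def _planted_full(
    nodes: dict[str, HierarchyNode], planted: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Per-node full core: taxa planted for the node or any ancestor."""
    full = {}
    for name in nodes:
        chain, cur = [], name
        while cur is not None:
            chain.append(cur)
            cur = nodes[cur].parent
        full[name] = sorted(
            {t for anc in chain for t in planted.get(anc, [])},
            key=lambda t: int(t[3:]),
        )
    return full


def _guild_fixture(
    config: SyntheticConfig, rng: np.random.Generator, taxonomy_strings: list[str]
) -> GuildDatabase:
    guild_text = {
        "saprotroph": ("Undefined Saprotroph", "Wood Saprotroph"),
        "pathotroph": ("Plant Pathogen", "Animal Pathogen"),
        "symbiotroph": ("Ectomycorrhizal", "Lichenized"),
    }
    genera = []
    seen = set()
    for s in taxonomy_strings:
        genus = parse_taxonomy(s).get("genus")
        if genus and genus not in seen:
            seen.add(genus)
            genera.append(genus)
    labels = list(config.mode_fractions)
    probs = [config.mode_fractions[m] for m in labels]
    probs.append(max(0.0, 1.0 - sum(probs)))  # unassigned
    labels.append(None)
    records = []
    for genus in genera:
        mode = labels[rng.choice(len(labels), p=np.array(probs) / sum(probs))]
        if mode is None:
            continue
        first = mode.split("+")[0]
        guild = guild_text[first][rng.integers(len(guild_text[first]))]
        records.append(
            GuildRecord(
                taxon=genus,
                rank="genus",
                trophic_modes=frozenset(mode.split("+")),
                guild=guild,
                confidence="Probable",
            )
        )
    return GuildDatabase(records)


def generate_dataset(
    seed: int, config: SyntheticConfig | None = None
) -> tuple[AbundanceTable, SampleMetadata, GuildDatabase, SyntheticTruth]:
    """Generate one synthetic community dataset with its truth record."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    design = _design(config)
    ids, tax_strings, weights, orders, planted = _taxon_panel(config, rng)
    nodes = default_hierarchy(SampleMetadata(design))
    planted = {k: v for k, v in planted.items() if k in nodes}
    planted_full = _planted_full(nodes, planted)
    taxon_pos = {t: i for i, t in enumerate(ids)}
    sample_pos = {s: j for j, s in enumerate(design.index)}
    pf_idx = {n: {taxon_pos[t] for t in full} for n, full in planted_full.items()}
    required: dict[int, set[int]] = {}
    for name, node in nodes.items():
        for t in pf_idx[name]:
            required.setdefault(t, set()).update(sample_pos[s] for s in node.samples)

    antagonists = [
        (taxon_pos["otu1"], taxon_pos["otu2"], config.antagonist_target_rho)
    ]
    counts = _draw_counts(
        config, rng, design, weights, orders, antagonists, group_effects=True
    )
    _force_core_presence(counts, required)
    _knock_out_accidental_cores(counts, rng, nodes, sample_pos, pf_idx, required)

    frame = pd.DataFrame(counts, index=ids, columns=list(design.index))
    table = AbundanceTable(frame, {t: parse_taxonomy(s) for t, s in zip(ids, tax_strings)})
    metadata = SampleMetadata(design)
    guild_db = _guild_fixture(config, rng, tax_strings)
    truth = SyntheticTruth(
        planted_core={n: list(full) for n, full in planted_full.items()},
        antagonist_pairs=[("otu1", "otu2", config.antagonist_target_rho)],
        stage_shift=(STAGE_SHIFT_ORDER, config.stage_shift_fold),
        block_structure={s: design.at[s, "stage"] for s in design.index},
        mode_fractions=dict(config.mode_fractions),
        seed=seed,
    )
    return table, metadata, guild_db, truth


def null_dataset(
    seed: int, config: SyntheticConfig | None = None
) -> tuple[AbundanceTable, SampleMetadata]:
    """Exchangeable-sample dataset: no group effects, no planted structure.

    The null for permutation-test and correlation-screen calibration.
    Two deliberate departures from :func:`generate_dataset` keep the
    screened taxa as close to independent as relative-abundance data
    allow: counts are drawn per taxon as independent Poisson variables
    around the expected depth (fixing the column sum multinomially
    couples every taxon pair through closure), and the base-weight panel
    is flat (log-normal sd 0.5, no dominant planted cores) so that no
    taxon holds a large enough share for the closure of the relative
    transform to induce visible negative correlation.  Column totals
    therefore fluctuate around ``config.depth``.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    design = _design(config)
    ids, tax_strings, _, orders, _ = _taxon_panel(config, rng)
    n_taxa = len(ids)
    base = np.exp(rng.normal(0.0, 0.5, size=n_taxa))
    base = base / base.sum()
    counts = np.zeros((n_taxa, len(design.index)), dtype=np.int64)
    for j in range(len(design.index)):
        w = base * np.exp(rng.normal(0.0, config.overdispersion, size=n_taxa))
        counts[:, j] = rng.poisson(config.depth * w)
    frame = pd.DataFrame(counts, index=ids, columns=list(design.index))
    table = AbundanceTable(frame, {t: parse_taxonomy(s) for t, s in zip(ids, tax_strings)})
    return table, SampleMetadata(design)


def generate_block_similarity(
    n_nodes: int,
    blocks: int | Sequence[int],
    within_range: tuple[int, int],
    between_range: tuple[int, int],
    seed: int,
) -> SimilarityMatrix:
    """Planted-block integer similarity matrix for critical-network tests.

    Same-block pairs draw uniformly from ``within_range`` and cross-block
    pairs from ``between_range`` (both inclusive); the ranges must not
    overlap.  Node labels encode their block (``b<k>_n<i>``) so planted
    membership can be read back from any derived graph.
    """
    if isinstance(blocks, int):
        if blocks < 1:
            raise ValueError("need at least one block")
        assignment = [i * blocks // n_nodes for i in range(n_nodes)]
    else:
        assignment = list(blocks)
        if len(assignment) != n_nodes:
            raise ValueError("block assignment length must equal n_nodes")
    lo_w, hi_w = within_range
    lo_b, hi_b = between_range
    for lo, hi in ((lo_w, hi_w), (lo_b, hi_b)):
        if not (0 <= lo <= hi <= 100):
            raise ValueError("ranges must be within [0, 100]")
    if max(lo_w, lo_b) <= min(hi_w, hi_b):
        raise ValueError("within and between ranges must not overlap")
    rng = np.random.default_rng(seed)
    labels = [f"b{assignment[i]}_n{i}" for i in range(n_nodes)]
    values = np.full((n_nodes, n_nodes), 100, dtype=np.int64)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if assignment[i] == assignment[j]:
                v = rng.integers(lo_w, hi_w + 1)
            else:
                v = rng.integers(lo_b, hi_b + 1)
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(labels, values)
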