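"""Transformations, dissimilarities, ordination and dispersion testing.

All pairwise measures operate column-wise on a taxa x samples table:
Hellinger transformation (square root of relative abundance), Bray-Curtis
dissimilarity, Jensen-Shannon divergence, classical-scaling ordination
(PCoA), the PERMDISP permutation test of multivariate dispersion, and a
Spearman correlation screen over the most abundant taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import AbundanceTable


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise sample dissimilarities."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite values")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if self.values.size and self.values.min() < 0:
            raise ValueError("distances must be non-negative")
        # enforce exact symmetry / hollowness after the tolerance checks
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "sample_id"
        frame.to_csv(path, sep="\t")


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all axes, decreasing (may include negatives)
    proportion_explained: np.ndarray  # positive axes only


@dataclass
class DispersionTest:
    F: float
    p_perm: float
    n_perm: int
    group_distances: pd.Series  # per-sample distance to own group centroid
    seed: int


@dataclass
class CorrelationResult:
    pairs: pd.DataFrame  # taxon_a, taxon_b, rho, p_raw, p_adjusted, significant
    alpha: float
    diagnostics: list[str] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# column-wise transforms
# ---------------------------------------------------------------------------

def _count_frame(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, AbundanceTable):
        return table.counts
    return table


def relative_abundance(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to one."""
    counts = _count_frame(table)
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total reads: {list(zero)}")
    return counts / totals


def hellinger_transform(table: AbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Square root of relative abundance; columns have unit Euclidean norm."""
    return np.sqrt(relative_abundance(table))


# ---------------------------------------------------------------------------
# dissimilarities
# ---------------------------------------------------------------------------

def bray_curtis_matrix(
    table: AbundanceTable | pd.DataFrame, representation: str = "raw"
) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity BC(i,j) = sum|x-y| / sum(x+y).

    ``representation`` selects the matrix the index is computed on: raw
    read counts (default) or Hellinger-transformed abundances.
    """
    counts = _count_frame(table)
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    if representation == "raw":
        data = counts.to_numpy(dtype=float)
    elif representation == "hellinger":
        data = hellinger_transform(counts).to_numpy()
    else:
        raise ValueError(f"unknown representation {representation!r}")
    totals = data.sum(axis=0)
    if np.count_nonzero(totals == 0) >= 2:
        empty = [c for c, t in zip(counts.columns, totals) if t == 0]
        raise ValueError(f"Bray-Curtis undefined for all-zero sample pair: {empty}")
    # sum|x-y| = sum(x+y) - 2*sum(min); denominators via column totals
    n = data.shape[1]
    values = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(data[:, i : i + 1] - data[:, i + 1 :]).sum(axis=0)
        denom = totals[i] + totals[i + 1 :]
        values[i, i + 1 :] = diff / denom
    values += values.T
    return DistanceMatrix(list(counts.columns), values)


def _shannon(p: np.ndarray, log) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * log(p), 0.0)
    return -terms.sum(axis=0)


def jensen_shannon_matrix(
    table: AbundanceTable | pd.DataFrame, log_base: float = 2
) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence between relative-abundance profiles.

    JSD(P,Q) = H(M) - (H(P)+H(Q))/2 with M the mixture (P+Q)/2 and the
    convention 0*log 0 = 0.  With base-2 logarithms values lie in [0, 1].
    """
    if log_base == 2:
        log = np.log2
    elif log_base in (np.e, "e"):
        log = np.log
    else:
        raise ValueError("log_base must be 2 or e")
    rel = relative_abundance(table).to_numpy()
    labels = list(_count_frame(table).columns)
    n = rel.shape[1]
    H = _shannon(rel, log)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = (rel[:, i] + rel[:, j]) / 2.0
            d = _shannon(m[:, None], log)[0] - (H[i] + H[j]) / 2.0
            values[i, j] = values[j, i] = max(d, 0.0)
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def _classical_scaling(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the double-centred -D^2/2 matrix.

    Returns (eigenvalues, eigenvectors) sorted by decreasing eigenvalue;
    negative eigenvalues (non-Euclidean distances) are retained.
    """
    d2 = dist.values**2
    n = dist.n
    centered = -0.5 * d2
    row_mean = centered.mean(axis=1, keepdims=True)
    col_mean = centered.mean(axis=0, keepdims=True)
    b = centered - row_mean - col_mean + centered.mean()
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    return eigvals[order], eigvecs[:, order]


def pcoa(dist: DistanceMatrix, eig_tolerance: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis (classical scaling).

    Coordinates are returned only for axes with eigenvalue above the
    tolerance (relative to the largest eigenvalue); negative eigenvalues
    are reported in ``eigenvalues`` but contribute no coordinate axis.
    """
    if dist.n < 2:
        raise ValueError("PCoA needs at least two samples")
    eigvals, eigvecs = _classical_scaling(dist)
    scale = max(abs(eigvals[0]), 1.0)
    keep = eigvals > eig_tolerance * scale
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    pos_sum = eigvals[keep].sum()
    proportion = eigvals[keep] / pos_sum if pos_sum > 0 else eigvals[keep]
    frame = pd.DataFrame(
        coords,
        index=dist.labels,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigvals, proportion)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

def _dispersion_embedding(
    dist: DistanceMatrix, eig_tolerance: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Real and imaginary PCoA axes for centroid distances.

    Axes with positive eigenvalue carry real coordinates; axes with
    negative eigenvalue carry 'imaginary' coordinates whose squared
    contribution is subtracted, following the standard correction for
    non-Euclidean dissimilarities.
    """
    eigvals, eigvecs = _classical_scaling(dist)
    scale = max(np.abs(eigvals).max(), 1.0)
    pos = eigvals > eig_tolerance * scale
    neg = eigvals < -eig_tolerance * scale
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    return real, imag


def _centroid_distances(
    real: np.ndarray, imag: np.ndarray, codes: np.ndarray, n_groups: int
) -> np.ndarray:
    d2 = np.empty(codes.shape[0])
    for g in range(n_groups):
        mask = codes == g
        r = real[mask] - real[mask].mean(axis=0)
        sq = (r**2).sum(axis=1)
        if imag.shape[1]:
            im = imag[mask] - imag[mask].mean(axis=0)
            sq = sq - (im**2).sum(axis=1)
        d2[mask] = np.maximum(sq, 0.0)
    return np.sqrt(d2)


def _anova_f(d: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d.shape[0]
    if d.max() - d.min() <= 1e-12 * max(1.0, d.max()):
        return 0.0  # constant centroid distances: no dispersion signal
    grand = d.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        vals = d[codes == g]
        ss_between += vals.shape[0] * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 1e-300 or df_w == 0:
        return 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permdisp(
    dist: DistanceMatrix,
    groups: Sequence[str] | dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> DispersionTest:
    """PERMDISP: permutation test of homogeneity of multivariate dispersions.

    Samples are embedded by PCoA (negative-eigenvalue axes retained with
    the imaginary correction), each sample's distance to its group
    centroid is computed, and the observed one-way ANOVA F statistic on
    those distances is compared against ``n_perm`` random permutations of
    the group labels, recomputing centroids each time.  The p-value is
    (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    if isinstance(groups, dict):
        labels = [groups[s] for s in dist.labels]
    else:
        labels = list(groups)
        if len(labels) != dist.n:
            raise ValueError("group labels do not match distance matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    codes = np.searchsorted(np.unique(labels), labels)
    n_groups = len(np.unique(codes))
    counts = np.bincount(codes)
    if n_groups < 2:
        raise ValueError("PERMDISP needs at least two groups")
    if counts.min() < 2:
        small = [str(np.unique(labels)[i]) for i in np.where(counts < 2)[0]]
        raise ValueError(f"groups with fewer than two samples: {small}")
    real, imag = _dispersion_embedding(dist)
    d_obs = _centroid_distances(real, imag, codes, n_groups)
    f_obs = _anova_f(d_obs, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        d_p = _centroid_distances(real, imag, perm, n_groups)
        if _anova_f(d_p, perm, n_groups) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return DispersionTest(
        F=float(f_obs),
        p_perm=float(p),
        n_perm=n_perm,
        group_distances=pd.Series(d_obs, index=dist.labels),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Spearman screen
# ---------------------------------------------------------------------------

def _spearman_pair_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided t-approximation p for all row pairs."""
    ranks = np.apply_along_axis(stats.rankdata, 1, values)
    rho = np.corrcoef(ranks)
    n = values.shape[1]
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    exact = np.abs(rho) >= 1 - 1e-15
    p[exact] = 0.0
    return rho, p


def spearman_screen(
    matrix: pd.DataFrame,
    top_k: int = 100,
    alpha: float = 0.01,
    adjust: str = "none",
) -> CorrelationResult:
    """All-pairs Spearman correlation among the ``top_k`` most abundant taxa.

    Taxa are ranked by total abundance (ties broken by taxon id); ties in
    sample values use average ranks; two-sided p-values use the
    t-approximation t = rho*sqrt((n-2)/(1-rho^2)).  Constant taxa are
    excluded and reported in ``diagnostics``.  ``adjust='bh'`` applies
    Benjamini-Hochberg across the screened pairs.
    """
    if matrix.shape[1] < 4:
        raise ValueError("need at least four samples for the Spearman screen")
    if top_k < 2:
        raise ValueError("top_k must be >= 2")
    if adjust not in ("none", "bh"):
        raise ValueError("adjust must be 'none' or 'bh'")
    totals = matrix.sum(axis=1)
    order = sorted(matrix.index, key=lambda t: (-totals[t], str(t)))
    chosen = order[: int(top_k)]
    sub = matrix.loc[chosen]
    values = sub.to_numpy(dtype=float)
    diagnostics = []
    constant = values.std(axis=1) == 0
    for taxon in sub.index[constant]:
        diagnostics.append(f"constant vector: {taxon}")
    sub = sub.loc[~constant]
    if sub.shape[0] < 2:
        empty = pd.DataFrame(
            columns=["taxon_a", "taxon_b", "rho", "p_raw", "p_adjusted", "significant"]
        )
        return CorrelationResult(empty, alpha, diagnostics)
    rho, p = _spearman_pair_matrix(sub.to_numpy(dtype=float))
    taxa = list(sub.index)
    ii, jj = np.triu_indices(len(taxa), k=1)
    frame = pd.DataFrame(
        {
            "taxon_a": [taxa[i] for i in ii],
            "taxon_b": [taxa[j] for j in jj],
            "rho": rho[ii, jj],
            "p_raw": p[ii, jj],
        }
    )
    if adjust == "bh":
        frame["p_adjusted"] = _benjamini_hochberg(frame["p_raw"].to_numpy())
        frame["significant"] = frame["p_adjusted"] < alpha
    else:
        frame["p_adjusted"] = frame["p_raw"]
        frame["significant"] = frame["p_raw"] < alpha
    return CorrelationResult(frame, alpha, diagnostics)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
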