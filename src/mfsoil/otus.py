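"""OTU table processing: equalization, filtering, transforms and diversity.

Operates on a samples × OTUs integer count table (pandas DataFrame) with an
optional taxonomy string per OTU (semicolon-separated lineage, phylum to
family). The operations mirror a standard 16S rRNA amplicon workflow after
OTU picking: subsample every library to a common depth, drop OTUs below a
fractional read threshold, Hellinger-transform for Euclidean-space
ordination, and compute alpha (Shannon, ACE) and beta (multivariate
dispersion) diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "equalize_libraries",
    "filter_rare_otus",
    "hellinger_transform",
    "shannon_index",
    "ace_estimator",
    "chao1_estimator",
    "multivariate_dispersion",
    "summarize_taxonomy",
    "ubiquitous_otus",
]

TAXONOMY_RANKS = ("phylum", "class", "order", "family")


@dataclass
class OtuTable:
    """Samples × OTUs counts with optional per-OTU taxonomy.

    ``counts``: non-negative integer DataFrame, index = sample ids, columns =
    OTU ids (both unique). ``taxonomy``: optional Series indexed like the
    columns, semicolon-separated lineage strings.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("sample and OTU identifiers must be unique")
        if self.taxonomy is not None:
            missing = self.counts.columns.difference(self.taxonomy.index)
            if len(missing):
                raise ValueError(f"taxonomy missing for OTUs: {list(missing)[:5]}")
            self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def with_counts(self, counts: pd.DataFrame) -> "OtuTable":
        tax = None
        if self.taxonomy is not None:
            tax = self.taxonomy.reindex(counts.columns)
        return OtuTable(counts=counts, taxonomy=tax)


def _as_counts(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    return table.counts if isinstance(table, OtuTable) else table


def _wrap_like(table: OtuTable | pd.DataFrame, counts: pd.DataFrame):
    return table.with_counts(counts) if isinstance(table, OtuTable) else counts


def equalize_libraries(
    table: OtuTable | pd.DataFrame,
    depth: int | str = "min",
    seed: int = 0,
    *,
    drop_shallow: bool = False,
):
    """Rarefy every library to a common depth without replacement.

    ``depth="min"`` uses the smallest library. Subsampling is an exact
    multivariate hypergeometric draw (all reads equally likely, no
    replacement), one draw per seed. Libraries shallower than ``depth`` raise
    unless ``drop_shallow`` removes them.
    """
    counts = _as_counts(table)
    sizes = counts.sum(axis=1)
    if depth == "min":
        depth = int(sizes.min())
    depth = int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    shallow = sizes.index[sizes < depth]
    if len(shallow):
        if not drop_shallow:
            raise ValueError(
                f"libraries below depth {depth}: {list(shallow)}; "
                "pass drop_shallow=True to remove them"
            )
        counts = counts.drop(index=shallow)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7,)))
    out = np.empty_like(counts.to_numpy())
    for i, row in enumerate(counts.to_numpy()):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    result = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return _wrap_like(table, result)


def filter_rare_otus(
    table: OtuTable | pd.DataFrame,
    min_fraction: float = 0.00005,
    *,
    rule: str = "any-sample",
):
    """Drop OTUs under a fractional read threshold of the (uniform) library size.

    The threshold is floor(min_fraction * library size); with the default
    fraction (0.005%) and a 166 040-read library that is 8 reads. Requires an
    equalized table. ``rule="any-sample"`` (default) keeps an OTU reaching the
    threshold in at least one library; ``rule="table-total"`` applies the
    threshold to the OTU's summed count instead — the fractional phrasing is
    ambiguous between the two readings, so both are supported.
    """
    counts = _as_counts(table)
    sizes = counts.sum(axis=1)
    if min_fraction < 0:
        raise ValueError("min_fraction must be >= 0")
    if min_fraction == 0:
        return _wrap_like(table, counts.copy())
    if sizes.nunique() != 1:
        raise ValueError(
            "library sizes are not uniform; equalize libraries before filtering"
        )
    threshold = int(np.floor(min_fraction * sizes.iloc[0]))
    if rule == "any-sample":
        keep = (counts >= threshold).any(axis=0)
    elif rule == "table-total":
        keep = counts.sum(axis=0) >= threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return _wrap_like(table, counts.loc[:, keep])


def hellinger_transform(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Square root of relative abundances per sample.

    y'_ij = sqrt(y_ij / y_i+); each row then has unit sum of squares, making
    Euclidean distance on the rows appropriate for count data.
    """
    counts = _as_counts(table)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {empty}")
    return np.sqrt(counts.div(totals, axis=0))


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) for one sample."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an empty sample")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1_estimator(counts) -> float:
    """Chao1 richness: S_obs + F1^2 / (2 F2) (bias-corrected form when F2=0)."""
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    s_obs = arr.size
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def ace_estimator(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness for one sample.

    S_ACE = S_abund + S_rare / C_ACE + (F1 / C_ACE) * gamma^2 with
    C_ACE = 1 - F1 / N_rare and
    gamma^2 = max(S_rare * sum i(i-1) F_i / (C_ACE N_rare (N_rare - 1)) - 1, 0),
    where the rare group holds OTUs with abundance <= rare_cutoff. When every
    rare read is a singleton (C_ACE = 0) the estimator is undefined and Chao1
    is returned with a warning.
    """
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("ACE undefined for an empty sample")
    rare = arr[arr <= rare_cutoff]
    s_abund = int((arr > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(arr.size)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "all rare reads are singletons; ACE undefined, falling back to Chao1",
            stacklevel=2,
        )
        return chao1_estimator(counts)
    i_vals = np.arange(1, rare_cutoff + 1)
    f_i = np.array([(rare == i).sum() for i in i_vals])
    sum_term = float((i_vals * (i_vals - 1) * f_i).sum())
    if n_rare > 1:
        gamma2 = max(s_rare * sum_term / (c_ace * n_rare * (n_rare - 1)) - 1.0, 0.0)
    else:
        gamma2 = 0.0
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def multivariate_dispersion(
    dist: np.ndarray | pd.DataFrame, groups
) -> tuple[pd.Series, pd.Series]:
    """Distance-to-group-centroid beta diversity (multivariate dispersion).

    Embeds the distance matrix by principal coordinates (keeping negative
    eigenvalues), computes each sample's distance to its group centroid with
    the standard sign correction (squared distances on negative axes are
    subtracted), and averages within groups. Returns (per-sample distances,
    group mean dispersion).
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        labels = list(range(d.shape[0]))
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("dist must be square, symmetric, with zero diagonal")
    groups = pd.Series(np.asarray(groups), index=labels)
    if len(groups) != n:
        raise ValueError("one group label per sample required")
    # Gower-centred double-centering of -D^2/2, full eigendecomposition
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    eigval, eigvec = np.linalg.eigh(g)
    keep = np.abs(eigval) > 1e-10 * max(np.abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))  # axes for both signs
    signs = np.sign(eigval)
    dists = np.zeros(n)
    for grp in groups.unique():
        idx = np.flatnonzero((groups == grp).to_numpy())
        if idx.size == 1:
            warnings.warn(f"group {grp!r} has a single sample; dispersion 0",
                          stacklevel=2)
            dists[idx] = 0.0
            continue
        centroid = coords[idx].mean(axis=0)
        sq = ((coords[idx] - centroid) ** 2 * signs).sum(axis=1)
        dists[idx] = np.sqrt(np.clip(sq, 0.0, None))
    per_sample = pd.Series(dists, index=labels, name="dist_to_centroid")
    group_means = per_sample.groupby(groups).mean()
    group_means.name = "mean_dispersion"
    return per_sample, group_means


def _rank_index(level: str) -> int:
    try:
        return TAXONOMY_RANKS.index(level)
    except ValueError:
        raise ValueError(
            f"unknown taxonomic level {level!r}; expected one of {TAXONOMY_RANKS}"
        ) from None


def summarize_taxonomy(table: OtuTable, level: str = "phylum") -> pd.DataFrame:
    """Per-sample relative abundance (%) pooled at a taxonomic rank.

    Lineage strings are split on ';'; OTUs whose lineage lacks the requested
    rank (or have no taxonomy entry) pool into ``unclassified``. An ``overall``
    row gives the table-wide summary. Rows sum to 100%.
    """
    if table.taxonomy is None:
        raise ValueError("OTU table has no taxonomy")
    pos = _rank_index(level)
    taxa = []
    for otu in table.counts.columns:
        lineage = table.taxonomy.loc[otu]
        if not isinstance(lineage, str) or not lineage.strip():
            taxa.append("unclassified")
            continue
        parts = [p.strip() for p in lineage.split(";")]
        taxa.append(parts[pos] if pos < len(parts) and parts[pos] else "unclassified")
    grouped = table.counts.T.groupby(pd.Index(taxa, name=level)).sum().T
    overall = grouped.sum(axis=0).to_frame().T
    overall.index = pd.Index(["overall"])
    grouped = pd.concat([grouped, overall])
    rel = grouped.div(grouped.sum(axis=1), axis=0) * 100.0
    return rel


def ubiquitous_otus(table: OtuTable | pd.DataFrame) -> set[str]:
    """OTUs detected (count > 0) in every sample."""
    counts = _as_counts(table)
    if counts.empty:
        raise ValueError("empty OTU table")
    present = (counts > 0).all(axis=0)
    return set(counts.columns[present])
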