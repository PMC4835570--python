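"""Multifunctional soil classification.

The classifier takes a composites × variables biogeochemical table (carbon,
nitrogen, pH, texture, trace-gas exchange rates, bacterial abundance),
standardizes each variable, clusters the samples by UPGMA on Euclidean
distances, and delineates *multifunctional classes* as the maximal subtrees
within which a similarity-profile permutation test (SIMPROF) finds no
structure. Classes are then ranked by the Euclidean distance of their
centroid from the reference (unlogged-forest) centroid in standardized
space. A correlation PCA with Kaiser–Guttman axis retention and the
equilibrium circle of descriptors screens which variables shape the reduced
space; one-way ANOVA and correlation utilities reproduce the univariate
screens.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "TreeNode",
    "ClassifiedDendrogram",
    "PcaResult",
    "standardize_variables",
    "euclidean_distances",
    "upgma",
    "simprof",
    "delineate_classes",
    "rank_classes",
    "pca",
    "correlate_variables",
    "anova_screen",
    "roman",
]


# ---------------------------------------------------------------- UPGMA tree

@dataclass(frozen=True)
class TreeNode:
    """Node of an UPGMA merge tree.

    ``height`` is the average between-cluster distance at the merge (0 for
    leaves); ``leaves`` the sorted tuple of leaf indices under the node.
    """

    node_id: int
    height: float
    leaves: tuple[int, ...]
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children


def upgma(dist: np.ndarray | pd.DataFrame) -> TreeNode:
    """Average-linkage agglomerative clustering of a distance matrix.

    At each step the two clusters at minimal average inter-cluster distance
    merge at a node whose height is that distance. Ties are broken by the
    smallest (lexicographically ordered) pair of minimum leaf indices, making
    the topology reproducible. Returns the root :class:`TreeNode`.
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 2:
        raise ValueError("need a square distance matrix over >= 2 samples")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(node_id=i, height=0.0, leaves=(i,)) for i in range(n)
    }
    # average inter-cluster distances between active clusters
    dd: dict[tuple[int, int], float] = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        dmin = min(dd[key] for key in dd)
        candidates = [key for key, val in dd.items() if val == dmin]
        # deterministic tie-break on sorted minimum leaf indices of the pair
        def tiekey(key: tuple[int, int]) -> tuple[int, int]:
            a, b = key
            return tuple(sorted((min(nodes[a].leaves), min(nodes[b].leaves))))
        i, j = min(candidates, key=tiekey)
        ni, nj = nodes[i], nodes[j]
        merged = TreeNode(
            node_id=next_id,
            height=dmin,
            leaves=tuple(sorted(ni.leaves + nj.leaves)),
            children=(ni, nj) if min(ni.leaves) < min(nj.leaves) else (nj, ni),
        )
        size_i, size_j = len(ni.leaves), len(nj.leaves)
        active -= {i, j}
        for k in active:
            a, b = (i, k) if i < k else (k, i)
            c, e = (j, k) if j < k else (k, j)
            dk = (size_i * dd[(a, b)] + size_j * dd[(c, e)]) / (size_i + size_j)
            dd[(k, next_id)] = dk
        dd = {key: val for key, val in dd.items() if i not in key and j not in key}
        nodes[next_id] = merged
        active.add(next_id)
        next_id += 1
    return nodes[next_id - 1]


# ----------------------------------------------------------- preprocessing

def standardize_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Center each variable to mean 0 and scale to sample SD 1 (n-1)."""
    values = table.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=1)
    constant = [str(c) for c, s in zip(table.columns, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        raise ValueError(f"constant variables cannot be standardized: {constant}")
    z = (values - values.mean(axis=0)) / sd
    return pd.DataFrame(z, index=table.index, columns=table.columns)


def euclidean_distances(z: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Euclidean distance matrix between rows."""
    if isinstance(z, pd.DataFrame):
        labels = z.index
        arr = z.to_numpy(dtype=float)
    else:
        arr = np.asarray(z, dtype=float)
        labels = pd.RangeIndex(arr.shape[0])
    d = squareform(pdist(arr, metric="euclidean"))
    return pd.DataFrame(d, index=labels, columns=labels)


# ----------------------------------------------------------------- SIMPROF

def _null_profiles(z: np.ndarray, n_profiles: int, rng: np.random.Generator) -> np.ndarray:
    """Sorted pairwise-distance profiles of column-wise permuted copies of z."""
    m, p = z.shape
    idx = rng.random((n_profiles, m, p)).argsort(axis=1)
    perm = np.take_along_axis(np.broadcast_to(z, (n_profiles, m, p)), idx, axis=1)
    sq = np.einsum("bip,bip->bi", perm, perm)
    gram = np.einsum("bip,bjp->bij", perm, perm)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * gram
    iu = np.triu_indices(m, 1)
    profiles = np.sqrt(np.clip(d2[:, iu[0], iu[1]], 0.0, None))
    profiles.sort(axis=1)
    return profiles


def simprof(
    z: np.ndarray | pd.DataFrame,
    n_perm_expected: int = 999,
    n_perm_null: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Similarity-profile test for internal structure among samples.

    The observed profile is the sorted vector of pairwise Euclidean distances.
    Null profiles permute each variable independently across the samples; the
    expected profile is the pointwise mean of ``n_perm_expected`` null
    profiles, the statistic pi the summed absolute departure of a profile from
    it, and p the fraction of an independent batch of ``n_perm_null`` null
    statistics at least as large as the observed one (+1 on both counts).
    Fewer than 3 samples are untestable: (nan, 1.0) by convention.
    """
    del alpha  # the decision threshold belongs to the caller
    arr = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, dtype=float)
    m = arr.shape[0]
    if m < 3:
        return (float("nan"), 1.0)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    profiles = _null_profiles(arr, n_perm_expected + n_perm_null, rng)
    expected = profiles[:n_perm_expected].mean(axis=0)
    observed = np.sort(pdist(arr, metric="euclidean"))
    pi_obs = float(np.abs(observed - expected).sum())
    null_pis = np.abs(profiles[n_perm_expected:] - expected).sum(axis=1)
    p = (1.0 + int((null_pis >= pi_obs).sum())) / (1.0 + n_perm_null)
    return (pi_obs, float(p))


# --------------------------------------------------------- class delineation

def roman(k: int) -> str:
    """1-based Roman numeral (class labels follow dendrogram leaf order)."""
    numerals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
                (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
                (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for value, sym in numerals:
        while k >= value:
            out.append(sym)
            k -= value
    return "".join(out)


@dataclass
class ClassifiedDendrogram:
    """UPGMA tree annotated with SIMPROF tests and the resulting partition."""

    root: TreeNode
    leaf_names: tuple[str, ...]
    node_tests: dict[int, tuple[float, float]]   # node_id -> (pi, p)
    labels: pd.Series = field(default_factory=pd.Series)  # sample -> class label

    @property
    def classes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, label in self.labels.items():
            out.setdefault(label, []).append(sample)
        return out

    def leaf_order(self) -> list[str]:
        order: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                order.append(self.leaf_names[node.leaves[0]])
                return
            for child in node.children:
                walk(child)

        walk(self.root)
        return order


def delineate_classes(
    tree: TreeNode,
    z: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> ClassifiedDendrogram:
    """Top-down SIMPROF delineation of multifunctional classes.

    Starting at the root, each node with >= 3 samples is tested; a rejected
    node (p <= alpha) is split and its children tested in turn, while a node
    that fails to reject — or is too small to test — becomes one class. Class
    labels are Roman numerals in dendrogram leaf order. Each node's test uses
    a child seed derived from (seed, node_id), so the whole delineation is
    reproducible.
    """
    arr = z.to_numpy(dtype=float)
    leaf_names = tuple(str(i) for i in z.index)
    node_tests: dict[int, tuple[float, float]] = {}
    class_nodes: list[TreeNode] = []

    def visit(node: TreeNode) -> None:
        if len(node.leaves) < 3:
            class_nodes.append(node)
            return
        node_seed = int(
            np.random.SeedSequence(entropy=seed, spawn_key=(node.node_id,)).generate_state(1)[0]
            % (2**31)
        )
        pi, p = simprof(arr[list(node.leaves)], n_perm, n_perm, alpha, seed=node_seed)
        node_tests[node.node_id] = (pi, p)
        if p <= alpha:
            for child in node.children:
                visit(child)
        else:
            class_nodes.append(node)

    visit(tree)
    # label classes in dendrogram leaf order
    order: dict[int, int] = {}

    def first_leaf_position(node: TreeNode, pos: dict[int, int]) -> int:
        return min(pos[leaf] for leaf in node.leaves)

    positions: dict[int, int] = {}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            positions[node.leaves[0]] = len(positions)
            return
        for child in node.children:
            walk(child)

    walk(tree)
    class_nodes.sort(key=lambda nd: first_leaf_position(nd, positions))
    labels = {}
    for k, node in enumerate(class_nodes, start=1):
        for leaf in node.leaves:
            labels[leaf_names[leaf]] = roman(k)
    series = pd.Series({name: labels[name] for name in z.index.astype(str)},
                       name="class")
    series.index = z.index
    return ClassifiedDendrogram(
        root=tree, leaf_names=leaf_names, node_tests=node_tests, labels=series
    )


def rank_classes(
    labels: pd.Series, z: pd.DataFrame, reference: pd.Series | list[bool]
) -> pd.DataFrame:
    """Rank classes by centroid distance from the reference-sample centroid.

    ``reference`` flags the baseline samples (e.g. unlogged forest). Returns
    one row per class with its size, Euclidean distance between the class
    centroid and the reference centroid in standardized space, and the
    disturbance rank (1 = closest to baseline).
    """
    ref = np.asarray(reference, dtype=bool)
    if ref.shape[0] != z.shape[0]:
        raise ValueError("reference flags must align with z rows")
    if not ref.any():
        raise ValueError("no reference samples flagged")
    ref_centroid = z.to_numpy(dtype=float)[ref].mean(axis=0)
    rows = []
    for label in labels.unique():
        members = labels.index[labels == label]
        centroid = z.loc[members].to_numpy(dtype=float).mean(axis=0)
        rows.append({
            "class": label,
            "n_samples": len(members),
            "members": ",".join(map(str, members)),
            "distance_to_reference": float(np.linalg.norm(centroid - ref_centroid)),
        })
    report = pd.DataFrame(rows).set_index("class")
    report["disturbance_rank"] = (
        report["distance_to_reference"].rank(method="min").astype(int)
    )
    return report.sort_values("distance_to_reference")


# --------------------------------------------------------------------- PCA

@dataclass
class PcaResult:
    """Correlation PCA with Kaiser–Guttman retention and equilibrium circle."""

    eigenvalues: np.ndarray          # variance units; sum = p for standardized z
    scores: pd.DataFrame             # site scores (rows = samples)
    loadings: pd.DataFrame           # scaling-1 descriptor coordinates (eigenvectors)
    correlation_loadings: pd.DataFrame  # scaling-2: eigenvectors * sqrt(eigenvalue)
    retained: np.ndarray             # Kaiser–Guttman flags (eigenvalue > mean)
    equilibrium_radius: float
    contributing: pd.Series          # descriptor length in d-space > radius


def pca(z: pd.DataFrame, d: int = 2, *, sqrt_radius: bool = True) -> PcaResult:
    """PCA of a standardized table with descriptor screening.

    Eigen-decomposition of the covariance of z (correlation PCA, since z is
    standardized); axes with eigenvalue above the mean eigenvalue are
    retained (Kaiser–Guttman). The equilibrium circle has radius sqrt(d/p)
    (``sqrt_radius=False`` gives the plain ratio d/p); descriptors whose
    scaling-1 loading vector over the first ``d`` axes is longer than the
    radius contribute more than average to the displayed plane.
    """
    n, p = z.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    arr = z.to_numpy(dtype=float)
    arr = arr - arr.mean(axis=0)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    axes = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=z.index, columns=axes)
    loadings = pd.DataFrame(vt.T, index=z.columns, columns=axes)
    corr_loadings = pd.DataFrame(vt.T * np.sqrt(eigenvalues), index=z.columns,
                                 columns=axes)
    retained = eigenvalues > eigenvalues.mean()
    d_eff = min(d, len(s))
    radius = math.sqrt(d_eff / p) if sqrt_radius else d_eff / p
    lengths = np.linalg.norm(loadings.to_numpy()[:, :d_eff], axis=1)
    contributing = pd.Series(lengths > radius, index=z.columns, name="contributing")
    return PcaResult(
        eigenvalues=eigenvalues,
        scores=scores,
        loadings=loadings,
        correlation_loadings=corr_loadings,
        retained=retained,
        equilibrium_radius=radius,
        contributing=contributing,
    )


# ----------------------------------------------------- univariate screens

#: Default normalizing transforms for the univariate analyses: gas exchange
#: rates are log-transformed, bacterial abundance square-root-transformed.
DEFAULT_TRANSFORMS = {
    "h2_uptake": "log",
    "co_uptake": "log",
    "co2_production": "log",
    "bacterial_abundance": "sqrt",
}


def _apply_transform(values: np.ndarray, how: str | None, name: str) -> np.ndarray:
    if how is None:
        return values
    if how == "log":
        if np.any(values <= 0):
            raise ValueError(f"log transform of non-positive values in {name!r}")
        return np.log(values)
    if how == "sqrt":
        if np.any(values < 0):
            raise ValueError(f"sqrt transform of negative values in {name!r}")
        return np.sqrt(values)
    raise ValueError(f"unknown transform {how!r} for {name!r}")


def correlate_variables(
    table: pd.DataFrame, transforms: dict[str, str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations after normalizing transforms.

    Returns one row per unordered variable pair with r, two-sided p, and the
    Shapiro–Wilk normality p of each transformed variable.
    """
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    cols = {}
    shapiro_p = {}
    for name in table.columns:
        vals = _apply_transform(table[name].to_numpy(dtype=float),
                                transforms.get(name), str(name))
        if np.std(vals) == 0:
            raise ValueError(f"variable {name!r} is constant; correlation undefined")
        cols[name] = vals
        shapiro_p[name] = float(stats.shapiro(vals).pvalue)
    rows = []
    for a, b in itertools.combinations(table.columns, 2):
        r, p = stats.pearsonr(cols[a], cols[b])
        rows.append({
            "var_a": a, "var_b": b, "pearson_r": float(r), "p_value": float(p),
            "shapiro_p_a": shapiro_p[a], "shapiro_p_b": shapiro_p[b],
        })
    return pd.DataFrame(rows)


def anova_screen(
    table: pd.DataFrame,
    groups,
    transforms: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """One-way ANOVA per variable with Bonferroni post-hoc t-tests.

    Returns (summary, posthoc): summary has per-variable F, p, Shapiro–Wilk p
    (on the pooled transformed values) and a significance flag; posthoc maps
    each variable to a symmetric matrix of Bonferroni-corrected pairwise
    t-test p-values.
    """
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    groups = pd.Series(np.asarray(groups), index=table.index)
    levels = list(dict.fromkeys(groups))
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two groups")
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 samples: {list(small.index)}")
    n_pairs = len(levels) * (len(levels) - 1) // 2
    summary_rows = []
    posthoc: dict[str, pd.DataFrame] = {}
    for name in table.columns:
        vals = _apply_transform(table[name].to_numpy(dtype=float),
                                transforms.get(name), str(name))
        by_group = [vals[(groups == g).to_numpy()] for g in levels]
        if all(np.ptp(v) == 0 for v in by_group) and len({v[0] for v in by_group}) == 1:
            f_stat, p_val = 0.0, 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f_stat, p_val = stats.f_oneway(*by_group)
            if not np.isfinite(f_stat):
                f_stat, p_val = 0.0, 1.0
        sw_p = float(stats.shapiro(vals).pvalue)
        summary_rows.append({
            "variable": name, "F": float(f_stat), "p_value": float(p_val),
            "shapiro_p": sw_p, "significant": bool(p_val <= alpha),
        })
        mat = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels,
                           columns=levels)
        for a, b in itertools.combinations(range(len(levels)), 2):
            va, vb = by_group[a], by_group[b]
            if np.ptp(np.concatenate([va, vb])) == 0:
                p_ab = 1.0
            else:
                p_ab = float(stats.ttest_ind(va, vb).pvalue)
            p_corr = min(1.0, p_ab * n_pairs)
            mat.iloc[a, b] = mat.iloc[b, a] = p_corr
        posthoc[str(name)] = mat
    return pd.DataFrame(summary_rows).set_index("variable"), posthoc
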