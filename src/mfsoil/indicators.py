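"""Indicator OTU analysis (IndVal) for multifunctional soil classes.

For each OTU and class, specificity A (how concentrated the OTU's mean
abundance is in that class) and fidelity B (in what fraction of the class's
samples it occurs) combine into the indicator value; significance comes from
permuting class labels across samples. Representative indicators — the most
abundant significant indicator per class — are then correlated (Spearman)
with the environmental variables to check that their distribution tracks the
biogeochemistry that defined the classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IndicatorResult",
    "indval",
    "select_representatives",
    "correlate_indicators",
]

logger = logging.getLogger(__name__)


@dataclass
class IndicatorResult:
    """Per-OTU indicator statistics against a class partition."""

    otu: str
    best_class: str
    a: float          # specificity in [0, 1]
    b: float          # fidelity in [0, 1]
    stat: float       # sqrt(A*B) (group-equalized) or A*B (classic)
    p: float
    significant: bool
    testable: bool    # singleton classes give ~no permutation power
    representative: bool = False
    total_count: int = 0


def _components(counts: np.ndarray, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class A and B matrices (classes × OTUs).

    ``membership`` is a classes × samples 0/1 matrix. A uses class mean
    abundances (so unequal class sizes do not bias specificity); B is the
    within-class prevalence.
    """
    sizes = membership.sum(axis=1, keepdims=True)
    means = (membership @ counts) / sizes
    col_tot = means.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(col_tot > 0, means / col_tot, 0.0)
    b = (membership @ (counts > 0)) / sizes
    return a, b


def _stat(a: np.ndarray, b: np.ndarray, mode: str) -> np.ndarray:
    if mode == "group_equalized":
        return np.sqrt(a * b)
    if mode == "classic":
        return a * b
    raise ValueError(f"unknown mode {mode!r}")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def indval(
    table: pd.DataFrame,
    classes: pd.Series | dict,
    mode: str = "group_equalized",
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
    fdr: bool = False,
) -> list[IndicatorResult]:
    """Indicator value analysis of an OTU count table against a partition.

    ``table``: samples × OTUs counts (equalized/filtered counts, not
    Hellinger). ``classes``: class label per sample. The statistic for an OTU
    is the maximum over classes of sqrt(A*B) (default, group-equalized) or
    A*B (classic); its p-value is the +1-corrected fraction of ``n_perm``
    label permutations reaching at least the observed statistic. OTUs whose
    best class is a singleton are flagged untestable (permutation power ~0 at
    the usual alpha) but still reported. ``fdr=True`` flags significance on
    Benjamini–Hochberg-adjusted p-values across the table's OTUs instead of
    the raw ones (raw p-values are reported either way).
    """
    if isinstance(classes, dict):
        classes = pd.Series(classes)
    classes = classes.reindex(table.index)
    if classes.isna().any():
        raise ValueError("every sample needs a class label")
    labels = list(dict.fromkeys(classes))
    if len(labels) < 2:
        raise ValueError("IndVal needs at least two classes")
    counts = table.to_numpy(dtype=float)
    n, n_otus = counts.shape
    membership = np.stack([(classes == lab).to_numpy(dtype=float) for lab in labels])
    if (membership.sum(axis=1) == 0).any():
        raise ValueError("empty class in partition")
    a, b = _components(counts, membership)
    stat_mat = _stat(a, b, mode)
    best_idx = stat_mat.argmax(axis=0)
    obs = stat_mat[best_idx, np.arange(n_otus)]

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(19,)))
    exceed = np.zeros(n_otus, dtype=np.int64)
    # permute labels by permuting the membership columns
    for _ in range(n_perm):
        perm = rng.permutation(n)
        a_p, b_p = _components(counts, membership[:, perm])
        exceed += _stat(a_p, b_p, mode).max(axis=0) >= obs
    p_vals = (1.0 + exceed) / (1.0 + n_perm)
    decision_p = _benjamini_hochberg(p_vals) if fdr else p_vals

    class_sizes = membership.sum(axis=1)
    results = []
    for j, otu in enumerate(table.columns):
        k = best_idx[j]
        testable = class_sizes[k] > 1
        results.append(IndicatorResult(
            otu=str(otu),
            best_class=str(labels[k]),
            a=float(a[k, j]),
            b=float(b[k, j]),
            stat=float(obs[j]),
            p=float(p_vals[j]),
            significant=bool(decision_p[j] <= alpha),
            testable=bool(testable),
            total_count=int(counts[:, j].sum()),
        ))
    return results


def select_representatives(
    results: list[IndicatorResult], table: pd.DataFrame | None = None
) -> list[IndicatorResult]:
    """Flag, per class, the significant indicator with the highest abundance.

    Abundance is the OTU's total read count (recomputed from ``table`` when
    given, else the stored totals); ties resolve in identifier order. Classes
    with no significant indicator are logged and left without a flag.
    """
    totals = {r.otu: r.total_count for r in results}
    if table is not None:
        for otu in table.columns:
            totals[str(otu)] = int(table[otu].sum())
    for r in results:
        r.representative = False
    by_class: dict[str, list[IndicatorResult]] = {}
    for r in results:
        by_class.setdefault(r.best_class, []).append(r)
    for cls, members in sorted(by_class.items()):
        significant = [r for r in members if r.significant]
        if not significant:
            logger.info("class %s has no significant indicator", cls)
            continue
        winner = min(significant, key=lambda r: (-totals.get(r.otu, 0), r.otu))
        winner.representative = True
    return results


def correlate_indicators(
    results: list[IndicatorResult],
    table: pd.DataFrame,
    env: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations of representative-indicator abundances with
    environmental variables.

    Returns a long-format table (indicator, class, variable, rho, p,
    significant). Samples are aligned on the shared index of ``table`` and
    ``env``; a constant abundance vector yields missing rho with a warning.
    """
    shared = table.index.intersection(env.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples to correlate")
    reps = [r for r in results if r.representative]
    rows = []
    for r in reps:
        abund = table.loc[shared, r.otu].to_numpy(dtype=float)
        for var in env.columns:
            vals = env.loc[shared, var].to_numpy(dtype=float)
            if np.ptp(abund) == 0 or np.ptp(vals) == 0:
                warnings.warn(
                    f"constant vector for {r.otu} vs {var}; correlation undefined",
                    stacklevel=2,
                )
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(abund, vals)
            rows.append({
                "indicator": r.otu, "class": r.best_class, "variable": var,
                "rho": float(rho) if np.isfinite(rho) else np.nan,
                "p_value": float(p) if np.isfinite(p) else np.nan,
                "significant": bool(np.isfinite(p) and p <= alpha),
            })
    return pd.DataFrame(rows)
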