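"""Constrained ordination of community profiles on environmental variables.

Redundancy analysis (RDA) regresses the (Hellinger-transformed, centered)
community matrix Y on standardized explanatory variables X and extracts the
principal axes of the fitted values; significance comes from a permutation
test on the pseudo-F statistic, collinearity is screened with variance
inflation factors, and the parsimonious model is built by forward selection
under the double-stopping rule (marginal permutation p <= alpha AND the
cumulative adjusted R2 may not exceed the global model's adjusted R2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RdaResult",
    "rda",
    "permutation_test_rda",
    "vif",
    "forward_select",
    "extreme_otus",
]


@dataclass
class RdaResult:
    """Eigenstructure and fit summary of one RDA."""

    canonical_eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    r2: float
    adj_r2: float
    site_scores: pd.DataFrame         # sample coordinates on canonical axes
    species_scores: pd.DataFrame      # OTU coordinates (scaling 2)
    biplot_scores: pd.DataFrame       # explanatory-variable arrows
    vif: pd.Series
    p_value: float | None = None
    selected: list[str] = field(default_factory=list)
    selection_history: pd.DataFrame | None = None

    @property
    def total_variance(self) -> float:
        return float(self.canonical_eigenvalues.sum()
                     + self.residual_eigenvalues.sum())


def _prep(Y, X) -> tuple[np.ndarray, np.ndarray, list, list, list]:
    y_df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, dtype=float))
    x_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    if y_df.shape[0] != x_df.shape[0]:
        raise ValueError("Y and X must have aligned rows")
    yc = y_df.to_numpy(dtype=float)
    yc = yc - yc.mean(axis=0)
    xc = x_df.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    return yc, xc, list(y_df.index), list(y_df.columns), list(x_df.columns)


def _fit(yc: np.ndarray, xc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares fitted values and residuals of Y on X (centered)."""
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ beta
    return fitted, yc - fitted


def vif(X: pd.DataFrame | np.ndarray) -> pd.Series:
    """Variance inflation factor 1/(1-R2_j) per explanatory variable.

    Perfectly collinear columns are flagged with +inf rather than raising.
    """
    x_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    n, m = x_df.shape
    if n <= m:
        raise ValueError("VIF needs more samples than variables")
    xc = x_df.to_numpy(dtype=float)
    xc = xc - xc.mean(axis=0)
    out = {}
    for j, name in enumerate(x_df.columns):
        if m == 1:
            out[name] = 1.0
            continue
        target = xc[:, j]
        others = np.delete(xc, j, axis=1)
        ss_tot = float((target**2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        _, resid = _fit(target[:, None], others)
        r2_j = 1.0 - float((resid**2).sum()) / ss_tot
        out[name] = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
    return pd.Series(out, name="vif")


def rda(Y: pd.DataFrame | np.ndarray, X: pd.DataFrame | np.ndarray) -> RdaResult:
    """Redundancy analysis of Y constrained by X.

    Y is column-centered; fitted values from the multivariate least-squares
    regression of Y on X yield the canonical axes (their principal axes), the
    residual matrix the unconstrained axes. Eigenvalues carry the usual
    variance normalization (SS/(n-1)) so canonical + residual eigenvalues sum
    to the total variance of Y. Scores use a correlation-style scaling 2
    (species scores weighted by sqrt(eigenvalue)).
    """
    yc, xc, samples, otus, varnames = _prep(Y, X)
    n, m = xc.shape
    if n <= m:
        raise ValueError("RDA needs more samples than explanatory variables")
    rank_x = np.linalg.matrix_rank(xc)
    if rank_x < m:
        raise ValueError(
            "explanatory matrix is collinear to machine precision; "
            "screen variables with vif() first"
        )
    fitted, resid = _fit(yc, xc)
    denom = n - 1
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    can_rank = min(m, int((s > 1e-10 * max(s[0], 1.0)).sum()) if s.size else 0)
    s = s[:can_rank]
    u = u[:, :can_rank]
    vt = vt[:can_rank]
    canonical = s**2 / denom
    _, s_res, _ = np.linalg.svd(resid, full_matrices=False)
    residual = s_res[s_res > 1e-10]**2 / denom
    ss_tot = float((yc**2).sum())
    r2 = float((fitted**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1) if n - m - 1 > 0 else np.nan
    axes = [f"RDA{i + 1}" for i in range(can_rank)]
    # scaling 2: species scores stretched by sqrt(lambda), sites contracted
    species = pd.DataFrame(vt.T * (s / np.sqrt(denom)), index=otus, columns=axes)
    sites = pd.DataFrame(u, index=samples, columns=axes)
    # biplot arrows: correlations of X with the canonical site axes
    biplot = np.zeros((m, can_rank))
    for j in range(m):
        xj = xc[:, j]
        for a in range(can_rank):
            sd_x, sd_u = xj.std(), u[:, a].std()
            biplot[j, a] = (
                np.corrcoef(xj, u[:, a])[0, 1] if sd_x > 0 and sd_u > 0 else 0.0
            )
    biplot_df = pd.DataFrame(biplot, index=varnames, columns=axes)
    vifs = vif(pd.DataFrame(xc, columns=varnames)) if m > 1 else pd.Series(
        {varnames[0]: 1.0}, name="vif")
    return RdaResult(
        canonical_eigenvalues=canonical,
        residual_eigenvalues=residual,
        r2=r2,
        adj_r2=adj,
        site_scores=sites,
        species_scores=species,
        biplot_scores=biplot_df,
        vif=vifs,
    )


def _pseudo_f(yc: np.ndarray, xc: np.ndarray) -> float:
    n, m = xc.shape
    fitted, resid = _fit(yc, xc)
    ss_fit = float((fitted**2).sum())
    ss_res = float((resid**2).sum())
    df_res = n - m - 1
    if df_res <= 0 or ss_res <= 0:
        return np.inf
    return (ss_fit / m) / (ss_res / df_res)


def permutation_test_rda(
    Y, X, n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value of the RDA pseudo-F (free permutation of Y rows)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yc, xc, *_ = _prep(Y, X)
    f_obs = _pseudo_f(yc, xc)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(13,)))
    n = yc.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _pseudo_f(yc[perm], xc) >= f_obs:
            count += 1
    return (1.0 + count) / (1.0 + n_perm)


def _residualize(mat: np.ndarray, on: np.ndarray | None) -> np.ndarray:
    if on is None or on.shape[1] == 0:
        return mat - mat.mean(axis=0)
    centered = mat - mat.mean(axis=0)
    _, resid = _fit(centered, on - on.mean(axis=0))
    return resid


def forward_select(
    Y: pd.DataFrame | np.ndarray,
    X: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> RdaResult:
    """Forward selection of explanatory variables with double stopping.

    The global model (all candidates) must first reject at ``alpha``. At each
    step the candidate adding the most R2 is admitted only if its marginal
    permutation test — a partial RDA conditioning on the already-selected
    variables by residualizing both Y and the candidate — gives p <= alpha
    and the cumulative adjusted R2 stays at or below the global adjusted R2.
    Returns the RDA of the selected set (empty selection yields a degenerate
    result with r2 = 0 and the global p attached).
    """
    if not isinstance(X, pd.DataFrame) or X.shape[1] == 0:
        raise ValueError("candidate set must be a non-empty DataFrame")
    yc, xc_all, samples, otus, names = _prep(Y, X)
    n = yc.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))

    global_model = rda(Y, X)
    global_p = permutation_test_rda(
        Y, X, n_perm=n_perm, seed=int(rng.integers(2**31)))
    history: list[dict] = []
    selected: list[str] = []
    if global_p > alpha:
        result = _empty_result(yc, samples, otus)
        result.p_value = global_p
        result.selection_history = pd.DataFrame(history)
        return result

    remaining = list(names)
    ss_tot = float((yc**2).sum())
    while remaining:
        best_name, best_r2 = None, -np.inf
        for name in remaining:
            cols = selected + [name]
            fitted, _ = _fit(yc, xc_all[:, [names.index(c) for c in cols]])
            r2_c = float((fitted**2).sum()) / ss_tot
            if r2_c > best_r2:
                best_name, best_r2 = name, r2_c
        m_new = len(selected) + 1
        adj_new = 1.0 - (1.0 - best_r2) * (n - 1) / (n - m_new - 1)
        if adj_new > global_model.adj_r2 + 1e-12:
            history.append({"variable": best_name, "added_r2": best_r2,
                            "p": np.nan, "admitted": False,
                            "reason": "adjusted R2 exceeds global model"})
            break
        # marginal test conditioned on the selected set
        sel_idx = [names.index(c) for c in selected]
        cond = xc_all[:, sel_idx] if sel_idx else None
        y_res = _residualize(yc, cond)
        x_res = _residualize(xc_all[:, [names.index(best_name)]], cond)
        p_marg = permutation_test_rda(
            y_res, x_res, n_perm=n_perm, seed=int(rng.integers(2**31)))
        admitted = p_marg <= alpha
        history.append({"variable": best_name, "added_r2": best_r2, "p": p_marg,
                        "admitted": admitted, "reason": "" if admitted else
                        "marginal test not significant"})
        if not admitted:
            break
        selected.append(best_name)
        remaining.remove(best_name)

    if not selected:
        result = _empty_result(yc, samples, otus)
        result.p_value = global_p
        result.selection_history = pd.DataFrame(history)
        return result
    final = rda(Y, X[selected])
    final.p_value = permutation_test_rda(
        Y, X[selected], n_perm=n_perm, seed=int(rng.integers(2**31)))
    final.selected = selected
    final.selection_history = pd.DataFrame(history)
    return final


def _empty_result(yc: np.ndarray, samples, otus) -> RdaResult:
    _, s_res, _ = np.linalg.svd(yc - yc.mean(axis=0), full_matrices=False)
    residual = s_res[s_res > 1e-10]**2 / (yc.shape[0] - 1)
    return RdaResult(
        canonical_eigenvalues=np.array([]),
        residual_eigenvalues=residual,
        r2=0.0,
        adj_r2=0.0,
        site_scores=pd.DataFrame(index=samples),
        species_scores=pd.DataFrame(index=otus),
        biplot_scores=pd.DataFrame(),
        vif=pd.Series(dtype=float),
    )


def extreme_otus(result: RdaResult, k: int = 14, d: int = 2) -> list[str]:
    """The k OTUs with the longest score vectors in the retained canonical plane.

    Deterministic top-k by Euclidean norm over the first ``d`` canonical axes;
    ties resolve in identifier order.
    """
    scores = result.species_scores
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds the {scores.shape[0]} available OTUs")
    arr = scores.to_numpy(dtype=float)[:, : min(d, scores.shape[1])]
    norms = np.linalg.norm(arr, axis=1)
    order = sorted(range(len(norms)), key=lambda i: (-norms[i], str(scores.index[i])))
    return [str(scores.index[i]) for i in order[:k]]
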