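"""Benthic community-change analysis between two labelled periods.

From-scratch SIMPER: Bray–Curtis contribution decomposition over all
between-period sample pairs, consistency ratios, ranked cumulative
contributions, percentage change of period means, and permutation
p-values with an add-one correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ImputationError, InferenceError, ValidationError

META_COLUMNS = ("site", "date", "transect", "period")

__all__ = [
    "META_COLUMNS",
    "bray_curtis",
    "percentage_change",
    "impute_missing",
    "simper",
    "SimperResult",
]


def split_matrix(matrix: pd.DataFrame):
    """Separate metadata columns from variable columns."""
    meta_cols = [c for c in META_COLUMNS if c in matrix.columns]
    var_cols = [c for c in matrix.columns if c not in meta_cols]
    if not var_cols:
        raise ValidationError("community matrix has no variable columns")
    return matrix[meta_cols], matrix[var_cols]


def bray_curtis(a, b):
    """Bray–Curtis dissimilarity and its per-variable contributions.

    contribution_j = |a_j − b_j| / Σ_k (a_k + b_k); the dissimilarity is
    the sum of contributions.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("vectors must be nonnegative")
    denom = (a + b).sum()
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined: both vectors are all-zero")
    contrib = np.abs(a - b) / denom
    return float(contrib.sum()), contrib


def percentage_change(before: float, after: float) -> float:
    """100 × (after − before) / before; NaN (flag) when before is 0."""
    if before < 0 or after < 0:
        raise ValidationError("proportions must be nonnegative")
    if before == 0:
        return math.nan
    return 100.0 * (after - before) / before


def impute_missing(matrix: pd.DataFrame):
    """Fill missing cells with the (site, period) mean of the variable,
    falling back to the variable's global mean.

    Returns ``(imputed matrix, number of cells imputed)``.
    """
    meta, vars_ = split_matrix(matrix)
    all_missing = [c for c in vars_.columns if vars_[c].isna().all()]
    if all_missing:
        raise ImputationError(f"variable(s) entirely missing: {all_missing}")
    n_missing = int(vars_.isna().to_numpy().sum())
    if n_missing == 0:
        return matrix.copy(), 0
    if not {"site", "period"}.issubset(meta.columns):
        raise ValidationError("imputation needs 'site' and 'period' columns")
    filled = vars_.copy()
    group_means = filled.groupby(
        [meta["site"].to_numpy(), meta["period"].to_numpy()]
    ).transform("mean")
    filled = filled.fillna(group_means)
    filled = filled.fillna(filled.mean())
    out = pd.concat([meta, filled], axis=1)[matrix.columns]
    return out, n_missing


@dataclass(frozen=True)
class SimperResult:
    """Ranked per-variable decomposition of between-period dissimilarity.

    ``table`` columns: average_contribution, consistency_ratio,
    mean_before, mean_after, cumulative_contribution, percent_change,
    p_value — one row per variable, ranked by average contribution.
    """

    table: pd.DataFrame
    mean_dissimilarity: float
    periods: tuple
    n_permutations: int
    seed: int


def _pairwise_contributions(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Per-variable Bray–Curtis contributions for every (a, b) pair.

    Returns an array of shape (len(A)*len(B), n_vars).
    """
    diffs = np.abs(A[:, None, :] - B[None, :, :])
    denom = (A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :])
    if (denom == 0).any():
        raise ValidationError("Bray-Curtis undefined: an all-zero sample pair")
    contrib = diffs / denom[:, :, None]
    return contrib.reshape(-1, A.shape[1])


def simper(
    matrix: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
    periods: tuple | None = None,
) -> SimperResult:
    """SIMPER decomposition with permutation inference.

    The test statistic per variable is its average between-period
    contribution; period labels are permuted across all samples and
    p = (1 + #{permuted ≥ observed}) / (1 + n_permutations), so the floor
    with 100 permutations is 1/101 ≈ 0.0099.
    """
    meta, vars_ = split_matrix(matrix)
    if "period" not in meta.columns:
        raise ValidationError("community matrix needs a 'period' column")
    if vars_.isna().any().any():
        raise ValidationError("missing values present; run impute_missing first")
    labels = meta["period"].to_numpy()
    uniq = sorted(pd.unique(labels))
    if periods is None:
        periods = tuple(uniq)
    if len(periods) != 2 or set(periods) != set(uniq):
        raise InferenceError(
            f"exactly two period labels required, got {uniq} vs requested {periods}"
        )
    X = vars_.to_numpy(dtype=float)
    mask_a = labels == periods[0]
    mask_b = labels == periods[1]
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise InferenceError("each period needs at least 2 samples")

    contrib = _pairwise_contributions(X[mask_a], X[mask_b])
    avg = contrib.mean(axis=0)
    sd = contrib.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, avg / sd, np.inf)

    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(avg)
    n = len(labels)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        pm_a = np.zeros(n, dtype=bool)
        pm_a[perm[: mask_a.sum()]] = True
        perm_avg = _pairwise_contributions(X[pm_a], X[~pm_a]).mean(axis=0)
        exceed += perm_avg >= avg
    p_values = (1.0 + exceed) / (1.0 + n_permutations)

    mean_before = X[mask_a].mean(axis=0)
    mean_after = X[mask_b].mean(axis=0)
    pct = np.array(
        [percentage_change(b, a) for b, a in zip(mean_before, mean_after)]
    )
    table = pd.DataFrame(
        {
            "average_contribution": avg,
            "consistency_ratio": ratio,
            "mean_before": mean_before,
            "mean_after": mean_after,
            "percent_change": pct,
            "p_value": p_values,
        },
        index=pd.Index(vars_.columns, name="variable"),
    )
    # rank by contribution; stable sort after a name sort breaks ties deterministically
    table = table.sort_index().sort_values(
        "average_contribution", ascending=False, kind="stable"
    )
    total = table["average_contribution"].sum()
    table["cumulative_contribution"] = (
        table["average_contribution"].cumsum() / total if total > 0 else 0.0
    )
    table = table[
        [
            "average_contribution",
            "consistency_ratio",
            "mean_before",
            "mean_after",
            "cumulative_contribution",
            "percent_change",
            "p_value",
        ]
    ]
    return SimperResult(
        table=table,
        mean_dissimilarity=float(avg.sum()),
        periods=tuple(periods),
        n_permutations=n_permutations,
        seed=seed,
    )


def simper_by_site(
    matrix: pd.DataFrame,
    n_permutations: int = 100,
    seed: int = 0,
    periods: tuple | None = None,
) -> dict:
    """Run SIMPER separately within each site (labels permuted within site)."""
    results = {}
    for i, (site, sub) in enumerate(matrix.groupby("site", sort=True)):
        results[site] = simper(
            sub.reset_index(drop=True),
            n_permutations=n_permutations,
            seed=seed + i,
            periods=periods,
        )
    return results
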