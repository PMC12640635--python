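"""Ecological Recovery Feasibility Index (ERFI).

Site-level composite score: PCA on six standardized benthic indicators,
loading-magnitude weights L_j = |l_j1| + |l_j2| + |l_j3|, signed expert
direction weights D_j, composite weights C_j = L_j × D_j, raw score
ERFI_i = Σ_j C_j z_ij, and a [0, 1] min–max normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import DEFAULT_BLEACHED_STATES, diversity_table, prevalence_table
from .errors import DecompositionError, ValidationError

logger = logging.getLogger(__name__)

ERFI_VARIABLES = ("coral", "cca", "turf", "cyanobacteria", "bleaching", "diversity")

#: expert direction weights: positive = favours recovery
DEFAULT_DIRECTION_WEIGHTS = {
    "coral": 4,
    "cca": 2,
    "diversity": 2,
    "cyanobacteria": -2,
    "bleaching": -2,
    "turf": -3,
}

__all__ = [
    "ERFI_VARIABLES",
    "DEFAULT_DIRECTION_WEIGHTS",
    "ErfiWeights",
    "ErfiScores",
    "standardize",
    "pca_loadings",
    "combine_weights",
    "erfi_scores",
    "run_erfi",
]


@dataclass(frozen=True)
class ErfiWeights:
    """Per-variable loadings (columns l1..lk), L, D and C = L × D."""

    loadings: pd.DataFrame  # variables × components, signed
    L: pd.Series
    D: pd.Series
    C: pd.Series
    explained_variance_ratio: np.ndarray
    n_components: int


@dataclass(frozen=True)
class ErfiScores:
    raw: pd.Series  # indexed by site
    normalized: pd.Series
    ranking: list  # site names, best first
    degenerate: bool = False


def standardize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scores; zero-variance columns are dropped with a notice.

    ``ddof=1`` (sample SD) mirrors mainstream statistical software; pass
    ``ddof=0`` for the population convention.
    """
    X = matrix.astype(float)
    if len(X) < 2:
        raise DecompositionError("standardization needs at least 2 sites")
    sd = X.std(ddof=ddof)
    dropped = list(sd.index[(sd == 0) | sd.isna()])
    if dropped:
        logger.warning("dropping zero-variance column(s): %s", dropped)
        X = X.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    if X.shape[1] == 0:
        raise DecompositionError("all columns have zero variance")
    return (X - X.mean()) / sd


def pca_loadings(z_matrix: pd.DataFrame, n_components: int = 3):
    """PCA of a standardized matrix via SVD; returns (loadings, evr).

    Loadings are the orthonormal right singular vectors (one column per
    component), ordered by decreasing explained variance. Component signs
    are arbitrary; downstream weights use absolute values.
    """
    Z = z_matrix.to_numpy(dtype=float)
    n_sites, n_vars = Z.shape
    if n_sites < 2:
        raise DecompositionError("PCA needs at least 2 sites")
    available = min(n_sites - 1, n_vars)
    k = min(n_components, available)
    if k < n_components:
        logger.warning(
            "only %d component(s) retrievable (requested %d)", k, n_components
        )
    centered = Z - Z.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    evr = (var / var.sum())[:available]
    loadings = pd.DataFrame(
        vt[:k].T,
        index=z_matrix.columns,
        columns=[f"l{i + 1}" for i in range(k)],
    )
    return loadings, evr


def combine_weights(
    loadings: pd.DataFrame,
    direction_weights: dict = None,
    explained_variance_ratio: np.ndarray | None = None,
) -> ErfiWeights:
    """L_j = Σ_k |l_jk| over the retained components; C_j = L_j × D_j."""
    dw = dict(DEFAULT_DIRECTION_WEIGHTS if direction_weights is None else direction_weights)
    missing = set(loadings.index) - set(dw)
    if missing:
        raise ValidationError(f"no direction weight for variable(s): {sorted(missing)}")
    L = loadings.abs().sum(axis=1)
    D = pd.Series({v: dw[v] for v in loadings.index}, name="D")
    C = L * D
    return ErfiWeights(
        loadings=loadings,
        L=L.rename("L"),
        D=D,
        C=C.rename("C"),
        explained_variance_ratio=(
            np.asarray(explained_variance_ratio)
            if explained_variance_ratio is not None
            else np.array([])
        ),
        n_components=loadings.shape[1],
    )


def erfi_scores(z_matrix: pd.DataFrame, weights: ErfiWeights) -> ErfiScores:
    """Weighted z-score composite per site with min–max normalization."""
    missing = set(z_matrix.columns) - set(weights.C.index)
    if missing:
        raise ValidationError(f"weights missing for column(s): {sorted(missing)}")
    raw = z_matrix.mul(weights.C.reindex(z_matrix.columns), axis=1).sum(axis=1)
    raw.name = "raw"
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("degenerate normalization: all raw ERFI scores equal")
        normalized = pd.Series(0.5, index=raw.index, name="normalized")
        degenerate = True
    else:
        normalized = ((raw - lo) / (hi - lo)).rename("normalized")
        degenerate = False
    ranking = list(raw.sort_values(ascending=False).index)
    return ErfiScores(raw=raw, normalized=normalized, ranking=ranking, degenerate=degenerate)


@dataclass(frozen=True)
class ErfiReport:
    scores: ErfiScores
    weights: ErfiWeights
    site_matrix: pd.DataFrame
    z_matrix: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def build_site_matrix(
    benthic: pd.DataFrame,
    belt: pd.DataFrame,
    window: tuple,
    bleached_states=DEFAULT_BLEACHED_STATES,
) -> pd.DataFrame:
    """Assemble the six-variable site matrix from survey tables.

    Cover variables (coral, cca, turf, cyanobacteria) are unweighted means
    of transect proportions inside the date window; bleaching is the mean
    belt-transect prevalence; diversity the mean Shannon H. Sites with no
    benthic survey in the window are excluded with a warning.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    b = benthic.copy()
    b["date"] = pd.to_datetime(b["date"])
    b = b[(b["date"] >= start) & (b["date"] <= end)]
    if b.empty:
        raise ValidationError("no benthic surveys inside the ERFI window")
    cover = (
        b.groupby(["site", "category"])["proportion"].mean().unstack(fill_value=0.0)
    )
    out = pd.DataFrame(index=cover.index)
    for var in ("coral", "cca", "turf", "cyanobacteria"):
        out[var] = cover[var] if var in cover.columns else 0.0

    bt = belt.copy()
    bt["date"] = pd.to_datetime(bt["date"])
    bt = bt[(bt["date"] >= start) & (bt["date"] <= end)]
    if not bt.empty:
        prev = prevalence_table(bt, bleached_states).groupby("site")["prevalence"].mean()
        div = diversity_table(bt).groupby("site")["shannon_h"].mean()
    else:
        prev = pd.Series(dtype=float)
        div = pd.Series(dtype=float)
    out["bleaching"] = prev.reindex(out.index).fillna(0.0)
    out["diversity"] = div.reindex(out.index).fillna(0.0)

    all_sites = set(benthic["site"]) | set(belt["site"])
    excluded = sorted(all_sites - set(out.index))
    if excluded:
        logger.warning("site(s) without benthic surveys in window excluded: %s", excluded)
    out.index.name = "site"
    return out[list(ERFI_VARIABLES)]


def run_erfi(
    benthic: pd.DataFrame,
    belt: pd.DataFrame,
    window: tuple,
    direction_weights: dict = None,
    bleached_states=DEFAULT_BLEACHED_STATES,
    n_components: int = 3,
    ddof: int = 1,
) -> ErfiReport:
    """Full pipeline: site matrix → standardize → PCA weights → scores."""
    site_matrix = build_site_matrix(benthic, belt, window, bleached_states)
    z = standardize(site_matrix, ddof=ddof)
    loadings, evr = pca_loadings(z, n_components=n_components)
    weights = combine_weights(loadings, direction_weights, evr)
    scores = erfi_scores(z, weights)
    provenance = {
        "window": [str(pd.Timestamp(window[0]).date()), str(pd.Timestamp(window[1]).date())],
        "direction_weights": {
            k: int(v)
            for k, v in (direction_weights or DEFAULT_DIRECTION_WEIGHTS).items()
        },
        "bleached_states": sorted(bleached_states),
        "n_components": int(weights.n_components),
        "sd_ddof": int(ddof),
        "aggregation": "unweighted mean over transects and dates",
        "deterministic": True,
    }
    return ErfiReport(
        scores=scores, weights=weights, site_matrix=site_matrix, z_matrix=z,
        provenance=provenance,
    )
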