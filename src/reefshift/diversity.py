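"""Shannon diversity, bleaching prevalence and proportion utilities."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit, logit as _logit

from .errors import DiversityError, ValidationError

HEALTH_STATES = ("healthy", "pale", "partially_bleached", "mostly_bleached", "bleached")

#: every non-healthy pigmentation state counts as bleached by default;
#: the subset is configurable because survey protocols differ on "pale".
DEFAULT_BLEACHED_STATES = frozenset(HEALTH_STATES[1:])

PROPORTION_FLOOR = 1e-4
PROPORTION_CEIL = 1 - 1e-4

__all__ = [
    "HEALTH_STATES",
    "DEFAULT_BLEACHED_STATES",
    "shannon_index",
    "diversity_table",
    "bleaching_prevalence",
    "prevalence_table",
    "inv_logit",
    "logit",
    "bound_proportions",
]


def shannon_index(counts) -> float:
    """Shannon entropy H = −Σ p ln p (nats) of a count vector."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValidationError("counts must be nonnegative")
    total = counts.sum()
    if total == 0:
        raise DiversityError("Shannon index undefined for an empty transect")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(belt: pd.DataFrame) -> pd.DataFrame:
    """Per-transect Shannon H, richness and total abundance.

    ``belt`` is long format: site, date, transect, taxon, health_state,
    count. Colony counts are pooled over health states within a taxon
    before computing H.
    """
    _check_belt(belt)
    taxa = belt.groupby(["site", "date", "transect", "taxon"], sort=True)["count"].sum()
    rows = []
    for (site, date, transect), grp in taxa.groupby(level=[0, 1, 2]):
        counts = grp.to_numpy()
        rows.append(
            {
                "site": site,
                "date": date,
                "transect": transect,
                "shannon_h": shannon_index(counts),
                "richness": int((counts > 0).sum()),
                "total_abundance": int(counts.sum()),
            }
        )
    return pd.DataFrame(rows)


def bleaching_prevalence(counts_by_state: dict, bleached_states=DEFAULT_BLEACHED_STATES) -> float:
    """Fraction of colonies whose health state is in ``bleached_states``."""
    unknown = set(counts_by_state) - set(HEALTH_STATES)
    if unknown:
        raise ValidationError(f"unknown health state(s): {sorted(unknown)}")
    total = sum(counts_by_state.values())
    if total == 0:
        return float("nan")  # undefined-prevalence flag
    hit = sum(v for k, v in counts_by_state.items() if k in bleached_states)
    return hit / total


def prevalence_table(belt: pd.DataFrame, bleached_states=DEFAULT_BLEACHED_STATES) -> pd.DataFrame:
    """Per-transect bleaching prevalence across all taxa."""
    _check_belt(belt)
    out = []
    for (site, date, transect), grp in belt.groupby(["site", "date", "transect"], sort=True):
        counts = grp.groupby("health_state")["count"].sum().to_dict()
        n = int(sum(counts.values()))
        out.append(
            {
                "site": site,
                "date": date,
                "transect": transect,
                "prevalence": bleaching_prevalence(counts, bleached_states),
                "n_colonies": n,
            }
        )
    return pd.DataFrame(out)


def _check_belt(belt: pd.DataFrame):
    required = {"site", "date", "transect", "taxon", "health_state", "count"}
    missing = required - set(belt.columns)
    if missing:
        raise ValidationError(f"belt table missing column(s) {sorted(missing)}")
    if (belt["count"] < 0).any():
        raise ValidationError("belt counts must be nonnegative")
    bad = set(belt["health_state"]) - set(HEALTH_STATES)
    if bad:
        raise ValidationError(f"unknown health state(s): {sorted(bad)}")


def inv_logit(x):
    """Inverse logit 1 / (1 + exp(−x))."""
    return expit(x)


def logit(p):
    """Log-odds of a proportion in (0, 1)."""
    p = np.asarray(p, dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValidationError("logit requires values strictly inside (0, 1)")
    return _logit(p)


def bound_proportions(values):
    """Clip proportions to [0.0001, 0.9999] to avoid boundary issues."""
    arr = np.asarray(values, dtype=float)
    if ((arr < 0) | (arr > 1)).any() or not np.isfinite(arr).all():
        raise ValidationError("proportions must lie in [0, 1]")
    clipped = np.clip(arr, PROPORTION_FLOOR, PROPORTION_CEIL)
    return clipped if arr.ndim else float(clipped)
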