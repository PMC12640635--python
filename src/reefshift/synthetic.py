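"""Synthetic reef-monitoring data with the structure the analysis assumes.

Generates (a) a multi-decadal daily SST series with seasonal cycle, linear
warming trend, stationary AR(1) noise and episodic half-sine warm
anomalies, and (b) benthic-cover and belt-transect survey tables spanning
a coral→turf compositional shift between two periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import HEALTH_STATES
from .errors import ConfigurationError

DAYS_PER_YEAR = 365.25

__all__ = ["SstSimConfig", "SurveySimConfig", "simulate_sst", "simulate_surveys"]


@dataclass(frozen=True)
class SstSimConfig:
    start_date: str = "1985-01-01"
    end_date: str = "2025-04-30"
    base_mean: float = 28.0
    seasonal_amplitude: float = 1.0
    trend: float = 0.23          # °C per decade
    ar1_coef: float = 0.8
    noise_sd: float = 0.3        # marginal SD of the AR(1) noise
    #: list of (start_date, duration_days, peak_magnitude °C)
    anomaly_events: tuple = ()
    peak_day_of_year: int = 105  # seasonal maximum (mid-April, boreal spring ETP)
    seed: int = 0

    def __post_init__(self):
        start, end = pd.Timestamp(self.start_date), pd.Timestamp(self.end_date)
        if end <= start:
            raise ConfigurationError("end_date must be after start_date")
        if (end - start).days < 2 * 365:
            raise ConfigurationError("simulated series must span at least 2 years")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not abs(self.ar1_coef) < 1:
            raise ConfigurationError("|ar1_coef| must be < 1")


def simulate_sst(config: SstSimConfig) -> pd.Series:
    """Daily SST = base + seasonal sinusoid + trend + AR(1) + anomaly bumps."""
    dates = pd.date_range(config.start_date, config.end_date, freq="D")
    n = len(dates)
    t_days = np.arange(n, dtype=float)

    # calendar-locked annual cycle: per-year period avoids phase drift over
    # leap years, which would otherwise alias into the fitted trend
    doy = dates.day_of_year.to_numpy(dtype=float)
    year_len = np.where(dates.is_leap_year, 366.0, 365.0)
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_day_of_year) / year_len
    )
    trend = config.trend / (10 * DAYS_PER_YEAR) * t_days

    rng = np.random.default_rng(config.seed)
    noise = np.zeros(n)
    if config.noise_sd > 0:
        phi = config.ar1_coef
        innov_sd = config.noise_sd * np.sqrt(1 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        # start at the stationary marginal distribution: no burn-in needed
        noise[0] = rng.normal(0.0, config.noise_sd)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]

    bumps = np.zeros(n)
    for ev_start, duration, peak in config.anomaly_events:
        offset = (pd.Timestamp(ev_start) - dates[0]).days
        if duration <= 0:
            raise ConfigurationError("anomaly duration must be positive")
        idx = np.arange(max(offset, 0), min(offset + duration, n))
        if idx.size:
            bumps[idx] += peak * np.sin(np.pi * (idx - offset) / duration)

    values = config.base_mean + seasonal + trend + noise + bumps
    return pd.Series(values, index=dates, name="sst_c")


@dataclass(frozen=True)
class SurveySimConfig:
    sites: tuple = ("A", "B", "C")
    transects_per_survey: int = 3
    survey_dates: tuple = ("2024-04-15", "2024-07-15", "2025-01-15")
    period_breakpoint: str = "2024-10-01"
    #: Dirichlet concentration weights per benthic category
    baseline_concentration: dict = field(
        default_factory=lambda: {
            "coral": 4.0, "turf": 4.0, "cca": 2.0, "macroalgae": 1.0,
            "cyanobacteria": 0.5, "bleached": 2.0, "dead_coral": 1.5,
        }
    )
    shift_concentration: dict = field(
        default_factory=lambda: {
            "coral": 2.0, "turf": 8.0, "cca": 2.0, "macroalgae": 0.7,
            "cyanobacteria": 0.2, "bleached": 3.0, "dead_coral": 0.3,
        }
    )
    taxa_pool: tuple = (
        "Pocillopora", "Porites_lobata", "Pavona_clavus", "Pavona_gigantea",
        "Pavona_varians", "Pavona_maldiviensis", "Pavona_chiriquiensis",
        "Pavona_frondifera", "Psammocora_stellata", "Psammocora_profundacella",
        "Tubastraea_coccinea", "Gardineroseris_planulata",
    )
    #: effective number of (equally abundant) taxa per site
    site_diversity: dict = field(default_factory=lambda: {"A": 6, "B": 3, "C": 1})
    site_bleaching_logit_mean: float = -1.2
    site_bleaching_logit_sd: float = 0.5
    colonies_per_transect_mean: float = 40.0
    seed: int = 0

    def __post_init__(self):
        if set(self.baseline_concentration) != set(self.shift_concentration):
            raise ConfigurationError(
                "baseline and shift concentrations must share category names"
            )
        for name, conc in (
            ("baseline_concentration", self.baseline_concentration),
            ("shift_concentration", self.shift_concentration),
        ):
            if any(v <= 0 for v in conc.values()):
                raise ConfigurationError(f"{name} weights must be strictly positive")
        unknown = set(self.site_diversity) - set(self.sites)
        if unknown:
            raise ConfigurationError(f"site_diversity for unknown site(s): {sorted(unknown)}")
        if self.transects_per_survey < 1:
            raise ConfigurationError("transects_per_survey must be >= 1")
        if self.colonies_per_transect_mean <= 0:
            raise ConfigurationError("colonies_per_transect_mean must be positive")


def _taxon_probs(effective_taxa: float, n_taxa: int) -> np.ndarray:
    """Equal mass on the first round(effective_taxa) taxa of the pool."""
    k = int(np.clip(round(effective_taxa), 1, n_taxa))
    p = np.zeros(n_taxa)
    p[:k] = 1.0 / k
    return p


def simulate_surveys(config: SurveySimConfig):
    """Return (benthic table, belt table) as long-format DataFrames.

    Benthic rows: site, date, transect, category, proportion (per-transect
    Dirichlet draw summing to 1; post-breakpoint draws use the shift
    concentration). Belt rows: site, date, transect, taxon, health_state,
    count, with a site-level logit-normal bleached fraction.
    """
    rng = np.random.default_rng(config.seed)
    categories = sorted(config.baseline_concentration)
    base_alpha = np.array([config.baseline_concentration[c] for c in categories])
    shift_alpha = np.array([config.shift_concentration[c] for c in categories])
    breakpoint = pd.Timestamp(config.period_breakpoint)
    non_healthy = [s for s in HEALTH_STATES if s != "healthy"]

    site_logits = {
        site: rng.normal(config.site_bleaching_logit_mean, config.site_bleaching_logit_sd)
        for site in config.sites
    }

    benthic_rows, belt_rows = [], []
    for site in config.sites:
        eff = config.site_diversity.get(site, len(config.taxa_pool))
        taxon_p = _taxon_probs(eff, len(config.taxa_pool))
        bleach_frac = 1.0 / (1.0 + np.exp(-site_logits[site]))
        for date in config.survey_dates:
            ts = pd.Timestamp(date)
            alpha = shift_alpha if ts >= breakpoint else base_alpha
            for transect in range(1, config.transects_per_survey + 1):
                props = rng.dirichlet(alpha)
                benthic_rows.extend(
                    {
                        "site": site,
                        "date": ts.date().isoformat(),
                        "transect": transect,
                        "category": cat,
                        "proportion": p,
                    }
                    for cat, p in zip(categories, props)
                )
                n_colonies = rng.poisson(config.colonies_per_transect_mean)
                taxa_counts = rng.multinomial(n_colonies, taxon_p)
                for taxon, count in zip(config.taxa_pool, taxa_counts):
                    if count == 0:
                        continue
                    n_bleached = rng.binomial(count, bleach_frac)
                    states = {"healthy": count - n_bleached}
                    if n_bleached:
                        sub = rng.multinomial(
                            n_bleached, np.full(len(non_healthy), 1 / len(non_healthy))
                        )
                        for state, c in zip(non_healthy, sub):
                            states[state] = c
                    belt_rows.extend(
                        {
                            "site": site,
                            "date": ts.date().isoformat(),
                            "transect": transect,
                            "taxon": taxon,
                            "health_state": state,
                            "count": int(c),
                        }
                        for state, c in states.items()
                        if c > 0
                    )
    benthic = pd.DataFrame(benthic_rows)
    belt = pd.DataFrame(
        belt_rows,
        columns=["site", "date", "transect", "taxon", "health_state", "count"],
    )
    return benthic, belt
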