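"""Reservation and tree-survey tables consistent with a truth surface."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import SyntheticLandscape
from .visitation import VisitationTruth

RESERVATION_COLUMNS = ("property_id", "date", "day_stratum", "party_size", "checkin_hour")


def generate_reservations(
    truth: VisitationTruth, seed: int, max_party: int = 6
) -> pd.DataFrame:
    """One row per reservation party; daily totals equal the truth exactly.

    Each day's true visitor count is split into parties of 1..max_party
    and every party gets a check-in hour in 9–18.
    """
    rng = np.random.default_rng(seed)
    rows = []
    daily = truth.daily_visitors.sort_values(
        ["property_id", "date"], kind="mergesort"
    )
    for row in daily.itertuples():
        remaining = int(row.visitors)
        while remaining > 0:
            size = int(min(rng.integers(1, max_party + 1), remaining))
            hour = int(rng.integers(9, 19))  # inclusive 9..18
            rows.append((row.property_id, row.date, row.day_stratum, size, hour))
            remaining -= size
    return pd.DataFrame(rows, columns=list(RESERVATION_COLUMNS))


@dataclass
class SpeciesResponse:
    """Log-linear species response to standardized property activity.

    ``loadings`` maps species name -> slope on the z-scored property
    activity; ``year_loading`` (settable to 0) adds a shared trend on
    the z-scored survey year; basal areas are
    exp(intercept + loading*z_activity + year_loading*z_year + noise).
    """

    loadings: dict[str, float]
    years: tuple[int, ...] = (2018, 2019)
    intercepts: dict[str, float] = field(default_factory=dict)
    year_loading: float = 0.0
    noise_sd: float = 0.0

    def validate(self) -> None:
        if len(self.loadings) < 2:
            raise ValueError("ordination needs at least 2 species")
        if len(self.years) < 2:
            raise ValueError("need at least 2 survey years")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def standardized_property_activity(truth: VisitationTruth) -> pd.Series:
    """Z-score of the base (road-free) activity total per property."""
    s = pd.Series(truth.property_activity, dtype=float).sort_index()
    sd = s.std(ddof=0)
    if sd == 0:
        return s * 0.0
    return (s - s.mean()) / sd


def generate_tree_surveys(
    landscape: SyntheticLandscape,
    truth: VisitationTruth,
    effect: SpeciesResponse,
    seed: int,
) -> pd.DataFrame:
    """Site × year mean basal area table (m²/ha) per species.

    Rows are a (site_id, year) MultiIndex over all properties and survey
    years; columns are species.
    """
    effect.validate()
    if len(landscape.green_spaces) < 2:
        raise ValueError("ordination needs at least 2 sites")
    rng = np.random.default_rng(seed)
    z_activity = standardized_property_activity(truth)
    years = np.asarray(effect.years, dtype=float)
    year_sd = years.std()
    z_years = (years - years.mean()) / year_sd if year_sd > 0 else years * 0.0

    species = sorted(effect.loadings)
    index = pd.MultiIndex.from_product(
        [sorted(z_activity.index), list(effect.years)], names=["site_id", "year"]
    )
    data = np.zeros((len(index), len(species)))
    for i, (site, year) in enumerate(index):
        zy = z_years[list(effect.years).index(year)]
        for j, sp in enumerate(species):
            mu = (
                effect.intercepts.get(sp, 0.0)
                + effect.loadings[sp] * z_activity[site]
                + effect.year_loading * zy
            )
            noise = rng.normal(0.0, effect.noise_sd) if effect.noise_sd > 0 else 0.0
            data[i, j] = np.exp(mu + noise)
    return pd.DataFrame(data, index=index, columns=species)
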