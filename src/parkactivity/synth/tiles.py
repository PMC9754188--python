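"""Forward model of the anonymization pipeline applied to truth surfaces.

Per (cell, month, stratum, window) slot the emitted index is

    max(true_intensity + noise, 0) / normalization_baseline

with zero-mean Gaussian noise truncated at zero and applied before
thresholding.  Slots whose pre-normalization value falls below the
threshold are omitted entirely — suppressed records are absent, never
zero — and zero-intensity slots never produce records at all.  The
baseline is a single scalar stand-in for the provider's January-mean
country normalization, keeping the index unitless and relative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..geo import ActivityCell
from .visitation import VisitationTruth


@dataclass
class AnonymizationParams:
    threshold: float = 0.0
    noise_sd: float = 0.0
    normalization_baseline: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not self.normalization_baseline > 0:
            raise ValueError("normalization_baseline must be positive")


def render_activity_tiles(
    truth: VisitationTruth, anon: AnonymizationParams
) -> list[ActivityCell]:
    """Emit anonymized tile records from a truth surface (deterministic per seed)."""
    anon.validate()
    df = truth.intensity.sort_values(
        ["cell_id", "month", "day_stratum", "window_start_hour"], kind="mergesort"
    ).reset_index(drop=True)
    values = df["intensity"].to_numpy(dtype=float)
    if anon.noise_sd > 0:
        rng = np.random.default_rng(anon.seed)
        values = np.maximum(values + rng.normal(0.0, anon.noise_sd, values.size), 0.0)
    keep = (values >= anon.threshold) & (values > 0)
    cells: list[ActivityCell] = []
    for value, row in zip(values[keep], df.loc[keep].itertuples()):
        cells.append(
            ActivityCell(
                cell_id=row.cell_id,
                geometry=truth.cell_geometry[row.cell_id],
                activity_index=value / anon.normalization_baseline,
                month=row.month,
                day_stratum=row.day_stratum,
                window_start_hour=int(row.window_start_hour),
            )
        )
    return cells
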