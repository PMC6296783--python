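"""Deterministic conversions from raw soil assays to function values.

Four laboratory measurements feed the function table:

* **Basal respiration** — hourly O2-consumption readings of unamended soil
  on a micro-compensation respirometer; the rate is the mean over a late,
  quasi-stationary window (hours 14-24 by default).
* **MIRR** (maximum initial respiratory response) — after glucose
  amendment, the mean of the three lowest hourly readings within the first
  10 h, i.e. between the disturbance peak and the microbial growth peak.
* **Microbial biomass C** — substrate-induced-respiration conversion,
  ``biomass = 38 x MIRR`` (ug C per g dry soil when MIRR is in
  ul O2 g^-1 h^-1).
* **%WSA** — fraction of water-stable aggregates from wet sieving of a
  4.0 g dry sample, corrected for coarse matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateSampleError,
    IncompleteSeriesError,
    InvalidInputError,
    NegativeFractionError,
)

#: Substrate-induced-respiration conversion factor (ug C per ul O2).
SIR_FACTOR: float = 38.0

#: Dry-soil mass placed on the sieve, grams.
WSA_INITIAL_MASS_G: float = 4.0

#: Basal-respiration averaging window, 1-based hours, both ends inclusive.
BASAL_WINDOW: tuple[int, int] = (14, 24)

#: MIRR search window, 1-based hours, both ends inclusive.
MIRR_WINDOW: tuple[int, int] = (1, 10)

#: Number of lowest readings averaged for MIRR.
MIRR_N_LOWEST: int = 3


@dataclass
class RespirationSeries:
    """Hourly O2-consumption readings (ul O2 h^-1 g^-1 dry soil).

    ``glucose`` marks substrate-induced runs (MIRR input); unamended runs
    (``glucose=False``) feed basal respiration. Hour indexing is 1-based
    from the start of the measurement.
    """

    rates: np.ndarray
    glucose: bool = False
    plot_id: str | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise InvalidInputError("respiration rates must be >= 0")


@dataclass
class SievingMeasurement:
    """One wet-sieving duplicate: water-stable and coarse masses in grams."""

    water_stable_g: float
    coarse_g: float
    initial_g: float = WSA_INITIAL_MASS_G
    duplicate: int = 1

    def __post_init__(self) -> None:
        if self.water_stable_g < 0 or self.coarse_g < 0:
            raise InvalidInputError("sieving masses must be >= 0")
        if self.water_stable_g > self.initial_g:
            raise InvalidInputError(
                f"water-stable fraction {self.water_stable_g} g exceeds "
                f"initial mass {self.initial_g} g"
            )


def basal_respiration(
    series: RespirationSeries, window: tuple[int, int] = BASAL_WINDOW
) -> float:
    """Mean O2-consumption rate over the late measurement window.

    Parameters
    ----------
    series
        Unamended (``glucose=False``) 24-h hourly series.
    window
        1-based (first, last) hour, both inclusive; default hours 14-24.
    """
    if series.glucose:
        raise InvalidInputError("basal respiration requires an unamended series")
    lo, hi = window
    if len(series.rates) < hi:
        raise IncompleteSeriesError(
            f"series has {len(series.rates)} readings; hours {lo}-{hi} required"
        )
    return float(np.mean(series.rates[lo - 1 : hi]))


def compute_mirr(
    series: RespirationSeries,
    window: tuple[int, int] = MIRR_WINDOW,
    n_lowest: int = MIRR_N_LOWEST,
) -> float:
    """Maximum initial respiratory response: mean of the ``n_lowest``
    smallest readings within the first-10-hour window of a glucose run."""
    if not series.glucose:
        raise InvalidInputError("MIRR requires a glucose-amended series")
    lo, hi = window
    if len(series.rates) < hi:
        raise IncompleteSeriesError(
            f"series has {len(series.rates)} readings; hours {lo}-{hi} required"
        )
    values = np.sort(series.rates[lo - 1 : hi])
    if len(values) < n_lowest:
        raise IncompleteSeriesError(
            f"{len(values)} readings in window; {n_lowest} required"
        )
    return float(np.mean(values[:n_lowest]))


def microbial_biomass_c(mirr: float, sir_factor: float = SIR_FACTOR) -> float:
    """Microbial biomass C (ug C g^-1 dry soil) from MIRR via the
    substrate-induced-respiration conversion ``sir_factor x MIRR``."""
    if mirr < 0:
        raise InvalidInputError("MIRR must be >= 0")
    return sir_factor * mirr


def wsa_fraction(measurements: SievingMeasurement | Sequence[SievingMeasurement]) -> float:
    """Water-stable-aggregate fraction of a soil sample.

    Per duplicate, ``(water_stable - coarse) / (initial - coarse)``;
    duplicates are averaged after the per-duplicate fraction is computed,
    which preserves each duplicate's own denominator.
    """
    if isinstance(measurements, SievingMeasurement):
        measurements = [measurements]
    fractions = []
    for m in measurements:
        if m.coarse_g >= m.initial_g:
            raise DegenerateSampleError(
                f"coarse matter {m.coarse_g} g >= initial mass {m.initial_g} g"
            )
        if m.water_stable_g < m.coarse_g:
            raise NegativeFractionError(
                f"water-stable mass {m.water_stable_g} g below coarse matter "
                f"{m.coarse_g} g"
            )
        fractions.append((m.water_stable_g - m.coarse_g) / (m.initial_g - m.coarse_g))
    return float(np.mean(fractions))
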