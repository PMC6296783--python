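"""Taxonomic diversity and evenness indices from plot cover vectors.

All indices operate on relative abundances ``p_i = cover_i / sum(cover)``
and are therefore invariant to the cover scale (percent of ground vs
proportions). Shannon entropy uses natural logarithms by convention of
the biodiversity-experiment literature; the base is configurable.

Monocultures have no defined Shannon evenness (``ln S = 0``); following
the analysis convention of the source experiment, plots whose sown
community went entirely extinct carry *zero* for every diversity index,
while an undefined evenness on a surviving monoculture is reported as NaN
and excluded from evenness analyses.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedCommunityError

__all__ = [
    "realized_richness",
    "shannon_diversity",
    "shannon_evenness",
    "simpson_evenness",
    "diversity_table",
]


def _covers(covers) -> np.ndarray:
    arr = np.asarray(covers, dtype=float)
    if np.any(arr < 0):
        raise InvalidInputError("covers must be >= 0")
    return arr


def realized_richness(covers, detect_threshold: float = 0.0) -> int:
    """Number of species with cover strictly above ``detect_threshold``.

    The threshold is on the same scale as the covers (default 0, i.e.
    any positive cover counts as presence).
    """
    arr = _covers(covers)
    return int(np.sum(arr > detect_threshold))


def _proportions(covers) -> np.ndarray:
    arr = _covers(covers)
    total = arr.sum()
    if total <= 0:
        raise UndefinedCommunityError("all covers are zero")
    return arr / total


def shannon_diversity(covers, base: float = math.e) -> float:
    """Shannon entropy H = -sum p_i log p_i over species with p_i > 0."""
    p = _proportions(covers)
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / math.log(base) + 0.0)  # avoid -0.0


def shannon_evenness(covers, base: float = math.e) -> float:
    """Pielou's J = H / log(realized richness); NaN when richness < 2."""
    s = realized_richness(covers)
    if s < 2:
        return float("nan")
    return shannon_diversity(covers, base=base) / (math.log(s) / math.log(base))


def simpson_evenness(covers) -> float:
    """Inverse-Simpson diversity divided by realized richness.

    ``E = (1 / sum p_i^2) / S``; equals 1 for any perfectly even
    community, including monocultures.
    """
    p = _proportions(covers)
    s = int(np.sum(p > 0))
    return float((1.0 / np.sum(p**2)) / s)


def diversity_table(
    covers: pd.DataFrame, detect_threshold: float = 0.0
) -> pd.DataFrame:
    """Per-plot diversity record from a plot x species cover matrix.

    Parameters
    ----------
    covers
        DataFrame indexed by plot id, one column per species, covers >= 0.
    detect_threshold
        Minimum cover counted as presence.

    Returns
    -------
    DataFrame indexed by plot id with columns ``realized_richness``,
    ``shannon_H``, ``shannon_evenness``, ``simpson_evenness``. Plots with
    zero total cover (all sown species extinct) carry 0 in every column;
    surviving monocultures carry NaN Shannon evenness.
    """
    records = {}
    for plot_id, row in covers.iterrows():
        vec = row.to_numpy(dtype=float)
        if vec.sum() <= 0:
            records[plot_id] = (0, 0.0, 0.0, 0.0)
            continue
        records[plot_id] = (
            realized_richness(vec, detect_threshold),
            shannon_diversity(vec),
            shannon_evenness(vec),
            simpson_evenness(vec),
        )
    out = pd.DataFrame.from_dict(
        records,
        orient="index",
        columns=["realized_richness", "shannon_H", "shannon_evenness", "simpson_evenness"],
    )
    out.index.name = covers.index.name or "plot_id"
    return out
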