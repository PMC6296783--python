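"""Distance-based functional diversity from traits and abundances.

The construction mirrors the classical dbFD-style workflow: Gower
distances over the species x trait table, principal coordinates analysis
(with Cailliez or Lingoes correction when the Gower matrix is not
Euclidean-embeddable), then four abundance-weighted indices in the
ordination space:

* **FRic** — convex-hull volume of the present species, as a fraction of
  the species pool's hull volume on the same axes;
* **FEve** — regularity of the abundance distribution along the minimum
  spanning tree of the present species (Villeger's index);
* **FDiv** — abundance weighting toward the hull extremes (Villeger);
* **FDis** — abundance-weighted mean distance to the abundance-weighted
  centroid (Laliberte-Legendre dispersion), defined for any non-empty
  community, monocultures included (FDis = 0).

FRic, FEve, and FDiv need at least three functionally distinct species;
below that they are undefined and reported as NaN. Plots whose sown
community went entirely extinct carry 0 for every index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    DegenerateTraitError,
    InvalidInputError,
    SchemaError,
    UndefinedCommunityError,
)

__all__ = [
    "FunctionalSpace",
    "gower_distances",
    "pcoa_embed",
    "functional_dispersion",
    "functional_richness",
    "functional_evenness",
    "functional_divergence",
    "community_fd",
]

#: Relative eigenvalue cutoff for axis retention.
EIG_TOL = 1e-9


def gower_distances(traits: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Gower distances between species.

    For quantitative traits, ``d(i,j)`` is the mean over traits of
    ``|x_i - x_j| / range(trait)``; distances lie in [0, 1] and are
    invariant to any affine rescaling of a single trait column.

    Raises
    ------
    DegenerateTraitError
        If a trait has zero range across the pool (names the trait).
    """
    x = traits.to_numpy(dtype=float)
    ranges = x.max(axis=0) - x.min(axis=0)
    for name, r in zip(traits.columns, ranges):
        if r <= 0:
            raise DegenerateTraitError(f"trait {name!r} has zero range")
    scaled = x / ranges
    diff = np.abs(scaled[:, None, :] - scaled[None, :, :])
    d = diff.mean(axis=2)
    return pd.DataFrame(d, index=traits.index, columns=traits.index)


@dataclass
class FunctionalSpace:
    """Species coordinates in a metric embedding of a distance matrix.

    ``coordinates`` rows are species, columns PCoA axes ordered by
    decreasing eigenvalue; ``eigenvalues`` the retained (positive)
    eigenvalues; ``correction`` records which adjustment, if any, was
    applied to make the distances Euclidean-embeddable.
    """

    distances: pd.DataFrame
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    correction: str = "none"

    @property
    def species(self) -> pd.Index:
        return self.coordinates.index

    def plot_coordinates(self, species, n_axes: int | None = None) -> np.ndarray:
        coords = self.coordinates.loc[list(species)].to_numpy()
        return coords if n_axes is None else coords[:, :n_axes]


def _gower_center(a: np.ndarray) -> np.ndarray:
    n = len(a)
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _cailliez_constant(d: np.ndarray) -> float:
    """Smallest constant c such that d + c (off-diagonal) is Euclidean."""
    n = len(d)
    b1 = _gower_center(-0.5 * d**2)
    b2 = _gower_center(-0.5 * d)
    top = np.hstack([np.zeros((n, n)), 2.0 * b1])
    bottom = np.hstack([-np.eye(n), -4.0 * b2])
    eig = np.linalg.eigvals(np.vstack([top, bottom]))
    return float(np.max(eig.real))


def pcoa_embed(distances: pd.DataFrame, correction: str = "cailliez") -> FunctionalSpace:
    """Principal coordinates analysis with optional negative-eigenvalue
    correction.

    Eigendecomposes the doubly centred matrix ``-D^2/2``; when negative
    eigenvalues beyond numerical noise occur, the distances are adjusted
    by the Cailliez (additive, on d) or Lingoes (additive, on d^2)
    constant before the final embedding. Axes with eigenvalue above
    ``EIG_TOL`` times the largest are retained; pairwise Euclidean
    distances among the coordinates reproduce the (corrected) input
    distances to high accuracy.
    """
    if correction not in {"cailliez", "lingoes", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise InvalidInputError("distance matrix must be square and symmetric")
    n = len(d)
    applied = "none"

    def decompose(dmat):
        b = _gower_center(-0.5 * dmat**2)
        vals, vecs = np.linalg.eigh(b)
        return vals[::-1], vecs[:, ::-1]

    vals, vecs = decompose(d)
    tol = EIG_TOL * max(vals.max(), 1.0)
    if correction != "none" and vals.min() < -tol:
        if correction == "cailliez":
            c = _cailliez_constant(d)
            d = d + c
        else:  # lingoes: d'^2 = d^2 + 2c
            c = -float(vals.min())
            d = np.sqrt(d**2 + 2.0 * c)
        np.fill_diagonal(d, 0.0)
        applied = correction
        vals, vecs = decompose(d)
        tol = EIG_TOL * max(vals.max(), 1.0)

    keep = vals > tol
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    axes = [f"axis{i + 1}" for i in range(keep.sum())]
    return FunctionalSpace(
        distances=pd.DataFrame(d, index=distances.index, columns=distances.columns),
        coordinates=pd.DataFrame(coords, index=distances.index, columns=axes),
        eigenvalues=vals[keep],
        correction=applied,
    )


def _weights(abundances) -> np.ndarray:
    w = np.asarray(abundances, dtype=float)
    if np.any(w < 0):
        raise InvalidInputError("abundances must be >= 0")
    total = w.sum()
    if total <= 0:
        raise UndefinedCommunityError("all abundances are zero")
    return w / total


def functional_dispersion(coords: np.ndarray, abundances) -> float:
    """Abundance-weighted mean distance to the weighted centroid."""
    z = np.atleast_2d(np.asarray(coords, dtype=float))
    w = _weights(abundances)
    centroid = w @ z
    return float(np.sum(w * np.linalg.norm(z - centroid, axis=1)))


def _hull_volume(z: np.ndarray) -> float:
    """Convex-hull volume; in 1-D the range, in 2-D the area."""
    z = np.atleast_2d(z)
    if z.shape[1] == 1:
        return float(z.max() - z.min())
    hull = ConvexHull(z)
    return float(hull.volume)


def functional_richness(
    space: FunctionalSpace, present_species, n_axes: int | None = None
) -> float:
    """Convex-hull volume of the present species divided by the pool's.

    Both hulls use the same leading ``n_axes`` PCoA axes (all retained
    axes by default). Returns NaN (undefined) when the present species
    are too few or too degenerate to span a hull in that space.
    """
    present = list(present_species)
    m = space.coordinates.shape[1] if n_axes is None else n_axes
    if len(present) <= m:
        return float("nan")
    try:
        vol = _hull_volume(space.plot_coordinates(present, m))
    except QhullError:
        return float("nan")
    pool_vol = _hull_volume(space.coordinates.to_numpy()[:, :m])
    if pool_vol <= 0:
        raise InvalidInputError("species pool spans no hull volume")
    return vol / pool_vol


def _mst_edges(z: np.ndarray, names) -> list[tuple[int, int, float]]:
    """Kruskal MST with deterministic (weight, name, name) tie-break."""
    n = len(z)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            w = float(np.linalg.norm(z[i] - z[j]))
            lo, hi = sorted((str(names[i]), str(names[j])))
            edges.append((w, lo, hi, i, j))
    edges.sort()
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = []
    for w, _, _, i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((i, j, w))
            if len(tree) == n - 1:
                break
    return tree


def functional_evenness(coords: np.ndarray, abundances, names=None) -> float:
    """Villeger's MST-based functional evenness.

    Each MST branch between species i and j gets a partial weighted
    evenness ``EW = d(i,j) / (w_i + w_j)``; after normalising to
    ``PEW = EW / sum(EW)``,

    ``FEve = (sum min(PEW, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1))``.

    Requires at least three species; undefined (NaN) below that.
    """
    z = np.atleast_2d(np.asarray(coords, dtype=float))
    w = _weights(abundances)
    s = len(w)
    if s < 3:
        return float("nan")
    if names is None:
        names = [f"s{i}" for i in range(s)]
    tree = _mst_edges(z, names)
    ew = np.array([d / (w[i] + w[j]) for i, j, d in tree])
    total = ew.sum()
    if total <= 0:
        return float("nan")
    pew = ew / total
    ref = 1.0 / (s - 1)
    return float((np.minimum(pew, ref).sum() - ref) / (1.0 - ref))


def functional_divergence(coords: np.ndarray, abundances) -> float:
    """Villeger's functional divergence.

    The centre of gravity G of the hull-vertex species defines distances
    ``dG_i``; with ``dbar`` their unweighted mean over present species,
    ``delta_d = sum w_i (dG_i - dbar)`` and
    ``delta_abs = sum w_i |dG_i - dbar|``,

    ``FDiv = (delta_d + dbar) / (delta_abs + dbar)``.

    Requires at least three species and a defined hull; NaN otherwise.
    """
    z = np.atleast_2d(np.asarray(coords, dtype=float))
    w = _weights(abundances)
    if len(w) < 3:
        return float("nan")
    if z.shape[1] == 1:
        vertices = [int(np.argmin(z[:, 0])), int(np.argmax(z[:, 0]))]
    else:
        try:
            vertices = ConvexHull(z).vertices
        except QhullError:
            return float("nan")
    g = z[vertices].mean(axis=0)
    dg = np.linalg.norm(z - g, axis=1)
    dbar = dg.mean()
    delta_d = float(np.sum(w * (dg - dbar)))
    delta_abs = float(np.sum(w * np.abs(dg - dbar)))
    denom = delta_abs + dbar
    if denom <= 0:
        return float("nan")
    return (delta_d + dbar) / denom


def community_fd(
    covers: pd.DataFrame,
    traits: pd.DataFrame,
    correction: str = "cailliez",
) -> pd.DataFrame:
    """Per-plot FRic, FEve, FDiv, FDis from covers and traits.

    Indices are weighted by the relative covers of the present species.
    Hull-based indices (FRic, FDiv) use a common reduced axis count
    ``m = min(retained axes, min qualifying richness - 1)`` so the hull
    is defined for every qualifying plot (the dbFD convention); FEve and
    FDis use all retained axes. Plots with total cover 0 carry 0 for all
    four indices; plots with fewer than three present species carry NaN
    for FRic/FEve/FDiv and a defined FDis.
    """
    missing = covers.columns.difference(traits.index)
    if len(missing):
        raise SchemaError(f"species missing from trait table: {list(missing)}")
    space = pcoa_embed(gower_distances(traits.loc[covers.columns]), correction)

    present_per_plot = {
        pid: covers.columns[row.to_numpy(dtype=float) > 0]
        for pid, row in covers.iterrows()
    }
    qual = [len(p) for p in present_per_plot.values() if len(p) >= 3]
    m_hull = space.coordinates.shape[1]
    if qual:
        m_hull = max(1, min(m_hull, min(qual) - 1))

    rows = {}
    for pid, row in covers.iterrows():
        vec = row.to_numpy(dtype=float)
        present = present_per_plot[pid]
        if vec.sum() <= 0:
            rows[pid] = (0.0, 0.0, 0.0, 0.0)
            continue
        w = vec[vec > 0]
        z_full = space.plot_coordinates(present)
        fdis = functional_dispersion(z_full, w)
        if len(present) >= 3:
            fric = functional_richness(space, present, m_hull)
            feve = functional_evenness(z_full, w, names=list(present))
            fdiv = functional_divergence(z_full[:, :m_hull], w)
        else:
            fric = feve = fdiv = float("nan")
        rows[pid] = (fric, feve, fdiv, fdis)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["FRic", "FEve", "FDiv", "FDis"]
    )
    out.index.name = covers.index.name or "plot_id"
    return out
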