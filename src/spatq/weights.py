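"""Areal neighbor structure (spatial weights).

Every spatial method in this package consumes a :class:`SpatialWeights`:
a sparse, id-ordered matrix ``W`` whose entry ``W[i, j]`` encodes how much
unit *j* counts as a neighbor of unit *i*.  Two constructors are provided —
queen contiguity derived from polygon geometry, and an explicit undirected
adjacency-pair list — plus row-standardization, which is what the
autocorrelation and regression modules expect.

Units with no neighbors ("islands", e.g. an island province that touches
nothing) are kept with an all-zero row, flagged, and reported loudly; they
are never silently bridged to the mainland.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialWeights",
    "queen_contiguity",
    "from_adjacency_pairs",
    "row_standardize",
    "read_geojson_polygons",
    "read_adjacency_file",
    "write_triplets",
]


class IslandError(ValueError):
    """Raised when a weights build yields no contact at all."""


@dataclass(frozen=True)
class SpatialWeights:
    """Dense areal weight matrix with ordered unit ids.

    Attributes
    ----------
    unit_ids : tuple of str
        Lexicographically sorted unit identifiers; every vector aligned
        with this object must follow this order.
    matrix : ndarray of shape (n, n)
        Nonnegative weights with zero diagonal.
    standardized : bool
        True if each nonempty row sums to one.
    islands : tuple of str
        Ids of units whose row (and column, for binary matrices) is all
        zero.
    """

    unit_ids: tuple
    matrix: np.ndarray
    standardized: bool = False
    islands: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.n, self.n):
            raise ValueError(f"matrix shape {m.shape} != ({self.n}, {self.n})")
        if (m < 0).any():
            raise ValueError("negative weights are not allowed")
        if np.abs(np.diag(m)).max(initial=0.0) > 0:
            raise ValueError("diagonal of W must be zero (W_ii = 0)")
        object.__setattr__(self, "matrix", m)

    def index_of(self, unit_id) -> int:
        return self.unit_ids.index(unit_id)

    def degrees(self) -> np.ndarray:
        """Neighbor counts per unit (nonzero entries per row)."""
        return (self.matrix > 0).sum(axis=1)

    def nonisland_mask(self) -> np.ndarray:
        return ~np.isin(np.asarray(self.unit_ids, dtype=object), self.islands)


def _finish(unit_ids, matrix, *, standardized=False, context=""):
    unit_ids = tuple(unit_ids)
    deg = (matrix > 0).sum(axis=1)
    islands = tuple(uid for uid, d in zip(unit_ids, deg) if d == 0)
    if len(islands) == len(unit_ids):
        raise IslandError(
            f"no unit has any neighbor{' in ' + context if context else ''}: "
            f"all {len(unit_ids)} units are islands ({', '.join(map(str, islands))})"
        )
    if islands:
        warnings.warn(
            f"units with no neighbors (islands), excluded from spatial terms: "
            f"{', '.join(map(str, islands))}",
            UserWarning,
            stacklevel=3,
        )
    return SpatialWeights(unit_ids, matrix, standardized=standardized, islands=islands)


def queen_contiguity(polygons: dict, snap: float = 1e-8) -> SpatialWeights:
    """Binary queen-contiguity weights from per-unit polygons.

    Two units are neighbors iff their geometries share at least one
    boundary point (edge *or* single vertex).  Coordinates are snapped to
    a grid of ``snap`` map units first, so sliver mismatches in real
    administrative borders do not break contact detection.

    Parameters
    ----------
    polygons : dict
        Mapping unit id -> shapely Polygon/MultiPolygon.
    snap : float
        Grid size for coordinate snapping before the intersects test.
    """
    import shapely

    if not polygons:
        raise ValueError("empty polygon collection")
    ids = sorted(polygons)
    if len(ids) != len(polygons):  # pragma: no cover - dict cannot duplicate
        raise ValueError("duplicate unit ids")
    geoms = []
    for uid in ids:
        g = polygons[uid]
        if g is None or g.is_empty:
            raise ValueError(f"empty geometry for unit {uid!r}")
        if snap and snap > 0:
            g = shapely.set_precision(g, snap)
        geoms.append(g)

    n = len(ids)
    w = np.zeros((n, n))
    tree = shapely.STRtree(geoms)
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j != i:
                w[i, j] = w[j, i] = 1.0
    return _finish(ids, w, context="queen contiguity")


def from_adjacency_pairs(pairs, unit_ids) -> SpatialWeights:
    """Binary symmetric weights from an undirected pair list."""
    ids = sorted(set(unit_ids))
    if len(ids) != len(list(unit_ids)):
        raise ValueError("duplicate unit ids")
    pos = {uid: k for k, uid in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair ({a!r}, {a!r}) rejected")
        if a not in pos or b not in pos:
            unknown = a if a not in pos else b
            raise ValueError(f"unknown unit id in pair: {unknown!r}")
        w[pos[a], pos[b]] = w[pos[b], pos[a]] = 1.0
    return _finish(ids, w, context="adjacency pairs")


def row_standardize(w: SpatialWeights) -> SpatialWeights:
    """Divide each row by its sum; island rows stay all-zero.

    Idempotent: standardizing an already-standardized matrix returns an
    equal matrix.
    """
    sums = w.matrix.sum(axis=1, keepdims=True)
    out = np.divide(w.matrix, sums, out=np.zeros_like(w.matrix), where=sums > 0)
    return SpatialWeights(w.unit_ids, out, standardized=True, islands=w.islands)


# ---------------------------------------------------------------------------
# io


def read_geojson_polygons(path, id_property: str = "id") -> dict:
    """Read a GeoJSON FeatureCollection into {unit id: shapely geometry}."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        uid = feat.get("properties", {}).get(id_property)
        if uid is None:
            raise ValueError(f"feature missing id property {id_property!r}")
        if uid in out:
            raise ValueError(f"duplicate unit id {uid!r}")
        out[uid] = shape(feat["geometry"])
    return out


def read_adjacency_file(path):
    """Read a two-column 'src,dst' delimited pair file."""
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["src", "dst"]:
        raise ValueError("adjacency file must have header 'src,dst'")
    return list(df.itertuples(index=False, name=None))


def write_triplets(w: SpatialWeights, path) -> None:
    """Export nonzero weights as sparse triplet CSV ('i,j,w') for audit."""
    with open(path, "w") as fh:
        fh.write("i,j,w\n")
        ii, jj = np.nonzero(w.matrix)
        for i, j in zip(ii, jj):
            fh.write(f"{w.unit_ids[i]},{w.unit_ids[j]},{w.matrix[i, j]:.12g}\n")
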