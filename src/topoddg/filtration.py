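"""Filtered simplicial complexes and boundary matrices.

Two constructions are provided, matching how the featurization uses them:

* **Vietoris–Rips** from a distance matrix (dimension-0 features). The
  filtration value of a simplex is its *diameter* — the largest pairwise
  distance among its vertices. Infinite distances (the modified-distance
  rule) simply mean the pair is never connected.
* **Alpha** from 3-D coordinates (dimension 1–2 features). Built on the
  Delaunay triangulation with the standard filtration-value assignment
  (circumradius for Gabriel simplices, smallest coface value otherwise),
  reported on the radius scale in Å. Because the modified-distance rule has
  no distance matrix here, same-group interactions are excluded after the
  fact by :func:`prune_cross_only`.

The two value scales (diameter vs radius) are never mixed inside one
feature block.

Boundary matrices use the orientation fixed by ascending vertex index: the
column of a k-simplex has sign (−1)^i on the face dropping its i-th vertex.
Laplacian spectra do not depend on this choice.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .sites import DistanceMatrix

__all__ = [
    "FiltrationComplex",
    "Snapshot",
    "BoundaryMatrix",
    "build_rips",
    "build_alpha",
    "prune_cross_only",
    "snapshot",
    "boundary_matrix",
    "DEFAULT_GRID_DIM0",
    "DEFAULT_GRID_DIM12",
]

#: Default filtration grids (Å): VR diameters for dimension 0, Alpha radii
#: for dimensions 1–2. Chosen to bracket the default site-subset radii.
DEFAULT_GRID_DIM0 = np.round(np.arange(0.0, 12.0 + 1e-9, 0.25), 6)
DEFAULT_GRID_DIM12 = np.round(np.arange(0.0, 12.0 + 1e-9, 0.5), 6)

Simplex = tuple[int, ...]


@dataclass
class FiltrationComplex:
    """Ordered simplices with filtration values.

    ``simplices`` is sorted by (value, dimension, vertex tuple), so iterating
    reproduces the nested sequence of complexes. Vertex tuples are sorted
    ascending; faces always appear with a value no larger than any coface.
    """

    simplices: list[tuple[Simplex, float]]
    max_dim: int
    source: str  # "rips" | "alpha"
    n_vertices: int

    def __post_init__(self) -> None:
        self.simplices.sort(key=lambda sv: (sv[1], len(sv[0]), sv[0]))

    def validate(self) -> None:
        """Check the closure property; raises AssertionError on violation."""
        value = {s: v for s, v in self.simplices}
        for s, v in self.simplices:
            if list(s) != sorted(s):
                raise AssertionError(f"unsorted vertex tuple {s}")
            if len(s) > 1:
                for face in itertools.combinations(s, len(s) - 1):
                    if face not in value:
                        raise AssertionError(f"missing face {face} of {s}")
                    if value[face] > v + 1e-12:
                        raise AssertionError(f"face {face} born after coface {s}")

    @property
    def max_value(self) -> float:
        return max((v for _, v in self.simplices), default=0.0)


@dataclass
class Snapshot:
    """A single complex of the nested sequence: simplices with value ≤ t."""

    t: float
    by_dim: dict[int, list[Simplex]]
    index: dict[int, dict[Simplex, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {k: {s: i for i, s in enumerate(ss)} for k, ss in self.by_dim.items()}

    def simplices(self, k: int) -> list[Simplex]:
        return self.by_dim.get(k, [])

    def n_simplices(self, k: int) -> int:
        return len(self.by_dim.get(k, []))

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.by_dim.values())

    def contains(self, other: "Snapshot") -> bool:
        return all(
            set(ss) <= set(self.by_dim.get(k, []))
            for k, ss in other.by_dim.items()
        )


@dataclass
class BoundaryMatrix:
    """Signed incidence matrix B_k: rows (k−1)-simplices, columns k-simplices."""

    k: int
    entries: np.ndarray  # integer matrix, coefficients in {-1, 0, +1}
    rows: list[Simplex]
    cols: list[Simplex]


# ---------------------------------------------------------------------------
# Vietoris–Rips


def build_rips(
    dist: DistanceMatrix | np.ndarray,
    max_dim: int = 1,
    max_filtration: float = float(DEFAULT_GRID_DIM0[-1]),
) -> FiltrationComplex:
    """Vietoris–Rips complex from a symmetric distance matrix.

    A subset of points enters as a simplex at its diameter; any pair at
    infinite distance never co-occurs in a simplex.
    """
    d = dist.entries if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("Rips construction needs a square distance matrix")
    finite = d[np.isfinite(d)]
    if finite.size and finite.min() < 0:
        raise ValueError("negative distances")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    simplices: list[tuple[Simplex, float]] = [((i,), 0.0) for i in range(n)]
    # incremental clique expansion: extend (k-1)-simplices by a larger vertex
    frontier: list[tuple[Simplex, float]] = list(simplices)
    for _ in range(max_dim):
        nxt: list[tuple[Simplex, float]] = []
        for s, v in frontier:
            for j in range(s[-1] + 1, n):
                dj = d[list(s), j]
                m = dj.max() if dj.size else 0.0
                if np.isfinite(m) and max(v, m) <= max_filtration:
                    nxt.append((s + (j,), max(v, float(m))))
        simplices.extend(nxt)
        frontier = nxt
        if not frontier:
            break
    return FiltrationComplex(simplices, max_dim, "rips", n)


# ---------------------------------------------------------------------------
# Alpha


def _circumsphere_sq(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Circumcenter and squared circumradius of an affinely independent set."""
    p0 = points[0]
    v = points[1:] - p0
    gram = 2.0 * v @ v.T
    rhs = np.einsum("ij,ij->i", v, v)
    x, *_ = np.linalg.lstsq(gram, rhs, rcond=None)
    offset = x @ v
    return p0 + offset, float(offset @ offset)


def _delaunay_top_simplices(coords: np.ndarray) -> list[Simplex]:
    """Top-dimensional Delaunay cells, joggling degenerate inputs."""
    n = coords.shape[0]
    if n <= 4:
        return [tuple(range(n))]
    try:
        tri = Delaunay(coords)
    except QhullError:
        warnings.warn("degenerate point cloud; joggling input for Delaunay")
        tri = Delaunay(coords, qhull_options="QJ")
    return [tuple(sorted(int(v) for v in cell)) for cell in tri.simplices]


def build_alpha(coords: np.ndarray, max_dim: int = 2) -> FiltrationComplex:
    """Alpha complex of a 3-D point cloud, values on the radius scale (Å).

    Every simplex of the Delaunay triangulation receives the smallest radius
    at which it joins the union-of-balls complex: its circumradius if the
    circumsphere is empty (Gabriel), otherwise the smallest value among its
    cofaces. Simplices above ``max_dim`` are used for value assignment and
    then discarded.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    if n == 0:
        raise ValueError("empty point cloud")
    if n == 1:
        return FiltrationComplex([((0,), 0.0)], max_dim, "alpha", 1)

    cells = _delaunay_top_simplices(coords)
    top_dim = max(len(c) for c in cells) - 1
    by_dim: dict[int, set[Simplex]] = {d: set() for d in range(top_dim + 1)}
    for cell in cells:
        d = len(cell) - 1
        by_dim[d].add(cell)
        for dd in range(d):
            for face in itertools.combinations(cell, dd + 1):
                by_dim[dd].add(face)

    value_sq: dict[Simplex, float] = {}
    for d in range(top_dim, 0, -1):
        for tau in by_dim[d]:
            if tau not in value_sq:
                _, r2 = _circumsphere_sq(coords[list(tau)])
                value_sq[tau] = r2
            for i in range(d + 1):
                sigma = tau[:i] + tau[i + 1:]
                opposite = tau[i]
                if sigma in value_sq:
                    value_sq[sigma] = min(value_sq[sigma], value_sq[tau])
                else:
                    center, r2s = _circumsphere_sq(coords[list(sigma)])
                    gap = float(np.dot(coords[opposite] - center, coords[opposite] - center))
                    if gap < r2s:  # not Gabriel: inherits the coface value
                        value_sq[sigma] = value_sq[tau]
    for d in range(1, top_dim + 1):
        for s in by_dim[d]:
            if s not in value_sq:  # Gabriel simplex never touched from above
                _, r2 = _circumsphere_sq(coords[list(s)])
                value_sq[s] = r2
    # closure pass: no face may appear after any of its cofaces
    for d in range(top_dim, 1, -1):
        for tau in by_dim[d]:
            for i in range(d + 1):
                sigma = tau[:i] + tau[i + 1:]
                value_sq[sigma] = min(value_sq[sigma], value_sq[tau])
    simplices: list[tuple[Simplex, float]] = [((i,), 0.0) for i in range(n)]
    for d in range(1, min(top_dim, max_dim) + 1):
        for s in by_dim[d]:
            simplices.append((s, float(np.sqrt(value_sq[s]))))
    return FiltrationComplex(simplices, max_dim, "alpha", n)


# ---------------------------------------------------------------------------
# same-group pruning, snapshots, boundaries


def prune_cross_only(
    cx: FiltrationComplex,
    grouping: Mapping[int, str] | Callable[[int], str],
) -> FiltrationComplex:
    """Drop every simplex that contains a same-group vertex pair.

    This transplants the modified-distance exclusion rule onto a complex
    built from raw geometry (the Alpha complex): vertices always survive,
    and so do simplices whose vertices pairwise straddle the groups.
    """
    label = grouping if callable(grouping) else grouping.__getitem__
    kept: list[tuple[Simplex, float]] = []
    for s, v in cx.simplices:
        try:
            labels = [label(i) for i in s]
        except KeyError as exc:
            raise ValueError(f"vertex {exc} has no group label") from exc
        if any(lab is None for lab in labels):
            raise ValueError(f"unlabeled vertex in simplex {s}")
        if len(set(labels)) == len(labels) or len(s) == 1:
            kept.append((s, v))
    return FiltrationComplex(kept, cx.max_dim, cx.source, cx.n_vertices)


def snapshot(cx: FiltrationComplex, t: float) -> Snapshot:
    """The complex at filtration value t (simplices with value ≤ t)."""
    if t < 0:
        raise ValueError("filtration value must be non-negative")
    by_dim: dict[int, list[Simplex]] = {}
    for s, v in cx.simplices:
        if v <= t:
            by_dim.setdefault(len(s) - 1, []).append(s)
    if 0 not in by_dim:
        by_dim[0] = []
    return Snapshot(t=t, by_dim=by_dim)


def boundary_matrix(snap: Snapshot, k: int) -> BoundaryMatrix:
    """Signed incidence matrix B_k of a snapshot.

    For k = 0 the boundary operator is the zero map and the matrix has no
    rows; B_k is otherwise (m × n) for m (k−1)-simplices and n k-simplices,
    with column signs alternating as (−1)^i over the sorted vertex tuple.
    """
    if k < 0:
        raise ValueError("dimension must be non-negative")
    cols = snap.simplices(k)
    if k == 0:
        return BoundaryMatrix(0, np.zeros((0, len(cols)), dtype=np.int64), [], list(cols))
    rows = snap.simplices(k - 1)
    row_index = snap.index.get(k - 1, {})
    b = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for j, s in enumerate(cols):
        for i in range(k + 1):
            face = s[:i] + s[i + 1:]
            b[row_index[face], j] = -1 if i % 2 else 1
    return BoundaryMatrix(k, b, list(rows), list(cols))


def serialize_complex(cx: FiltrationComplex) -> str:
    """One simplex per line: ``k v0..vk value``."""
    lines = [f"{len(s) - 1} {' '.join(map(str, s))} {v:.9g}" for s, v in cx.simplices]
    return "\n".join(lines) + "\n"


def deserialize_complex(text: str, source: str = "rips") -> FiltrationComplex:
    simplices = []
    n_vertices = 0
    for line in text.strip().splitlines():
        parts = line.split()
        k = int(parts[0])
        verts = tuple(int(x) for x in parts[1:2 + k])
        simplices.append((verts, float(parts[-1])))
        n_vertices = max(n_vertices, max(verts) + 1)
    max_dim = max(len(s) - 1 for s, _ in simplices)
    return FiltrationComplex(simplices, max_dim, source, n_vertices)
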