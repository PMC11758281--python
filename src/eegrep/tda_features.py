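"""Persistent homology pipelines, vectorized as persistence images.

Two topology-based representations are provided:

* UTS-PH — 0-dimensional persistence of each channel's univariate series
  under the sublevel-set (lower-star) filtration.  A component is born at
  every local minimum and dies when it merges with an older component at a
  local maximum (elder rule), so the diagram records the relative heights of
  the signal's peaks while ignoring their widths — making it invariant to
  expansion/contraction of the time axis and stable under amplitude noise.
  Each channel's diagram becomes a 10 x 10 persistence image; concatenated
  over 64 channels this yields a vector of length 6400.

* FBN-PH — 0- and 1-dimensional persistence of the functional brain network.
  The 64 x 64 correlation-distance matrix is first rank-transformed (each
  off-diagonal entry replaced by its rank), which makes the result invariant
  under any monotone transformation of the distances, then filtered as a
  Vietoris-Rips complex up to 2-simplices.  Both diagrams become 10 x 10
  persistence images, concatenated into a vector of length 200.

The persistence computations are implemented here directly: union-find for
the 0-dimensional sweeps and boundary-matrix reduction over GF(2) (with
bitset columns) for the 1-dimensional bars.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .data_model import Epoch

__all__ = [
    "PersistenceDiagram",
    "PersistenceImage",
    "lower_star_diagram",
    "rank_transform",
    "vr_diagrams",
    "persistence_image",
    "uts_ph_vector",
    "fbn_ph_vector",
    "UTS_PH_BIRTH_RANGE",
    "UTS_PH_PERS_RANGE",
]

#: Fixed persistence-image axes for the UTS-PH pipeline: births span the
#: clipped amplitude range and persistence its full width, so images are
#: comparable across epochs and subjects.
UTS_PH_BIRTH_RANGE: tuple[float, float] = (-50.0, 50.0)
UTS_PH_PERS_RANGE: tuple[float, float] = (0.0, 100.0)


# ---------------------------------------------------------------------------
# Diagrams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersistenceDiagram:
    """A multiset of (birth, death, dim) triples; death may be ``inf``.

    ``points`` is a (k, 2) float array of [birth, death] rows and ``dims``
    the matching homology dimensions.  Essential classes carry death inf.
    """

    points: np.ndarray
    dims: np.ndarray

    def __post_init__(self) -> None:
        points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if points.size == 0:
            points = points.reshape(0, 2)
        dims = np.asarray(self.dims, dtype=int).ravel()
        if points.shape[0] != dims.shape[0]:
            raise ValueError("points and dims length mismatch")
        finite = np.isfinite(points[:, 1])
        if np.any(points[finite, 1] <= points[finite, 0]):
            raise ValueError("every finite point needs death > birth")
        object.__setattr__(self, "points", points)
        object.__setattr__(self, "dims", dims)

    def in_dim(self, dim: int, finite_only: bool = False) -> np.ndarray:
        """The [birth, death] rows of one homology dimension."""
        mask = self.dims == dim
        pts = self.points[mask]
        if finite_only:
            pts = pts[np.isfinite(pts[:, 1])]
        return pts

    def to_csv(self, path: str | Path) -> None:
        """3-column CSV: birth, death ('inf' for essential), dim."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("birth,death,dim\n")
            for (b, d), dim in zip(self.points, self.dims):
                death = "inf" if np.isinf(d) else repr(float(d))
                fh.write(f"{float(b)!r},{death},{int(dim)}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PersistenceDiagram":
        rows = Path(path).read_text(encoding="utf-8").strip().splitlines()[1:]
        points, dims = [], []
        for row in rows:
            b, d, dim = row.split(",")
            points.append([float(b), float(d)])
            dims.append(int(dim))
        return cls(np.array(points).reshape(-1, 2), np.array(dims, dtype=int))


def _diagram(bars0, bars1=(), essential0=(), essential1=()) -> PersistenceDiagram:
    points, dims = [], []
    for b, d in bars0:
        points.append([b, d]); dims.append(0)
    for b in essential0:
        points.append([b, np.inf]); dims.append(0)
    for b, d in bars1:
        points.append([b, d]); dims.append(1)
    for b in essential1:
        points.append([b, np.inf]); dims.append(1)
    return PersistenceDiagram(np.array(points).reshape(-1, 2), np.array(dims, dtype=int))


# ---------------------------------------------------------------------------
# Lower-star (sublevel-set) persistence of a 1-D signal
# ---------------------------------------------------------------------------


def lower_star_diagram(series: np.ndarray) -> PersistenceDiagram:
    """0-dimensional sublevel-set persistence of a univariate signal.

    A component of ``{t : f(t) <= s}`` is born at each local minimum and, at
    a merge, the component with the larger birth value dies (elder rule; ties
    broken toward the earlier minimum surviving).  The component of the
    global minimum never dies and is reported with death ``inf``.  Plateaus
    (runs of equal consecutive values) are collapsed to a single sample
    first, which leaves the sublevel-set topology unchanged.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("series must have at least one sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    # collapse plateaus
    keep = np.concatenate([[True], np.diff(x) != 0.0])
    x = x[keep]
    n = x.size

    order = np.lexsort((np.arange(n), x))  # by value, then index
    parent = np.full(n, -1, dtype=int)  # -1: not yet added
    birth_value = np.empty(n)
    birth_index = np.empty(n, dtype=int)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    bars: list[tuple[float, float]] = []
    for i in order:
        parent[i] = i
        birth_value[i] = x[i]
        birth_index[i] = i
        for j in (i - 1, i + 1):
            if 0 <= j < n and parent[j] != -1:
                ri, rj = find(i), find(j)
                if ri == rj:
                    continue
                # elder rule: smaller birth value survives; tie -> earlier index
                elder, younger = (ri, rj) if (
                    (birth_value[ri], birth_index[ri]) <= (birth_value[rj], birth_index[rj])
                ) else (rj, ri)
                if x[i] > birth_value[younger]:
                    bars.append((float(birth_value[younger]), float(x[i])))
                parent[younger] = elder
    global_min = float(np.min(x))
    return _diagram(bars0=bars, essential0=[global_min])


# ---------------------------------------------------------------------------
# Rank filtration and Vietoris-Rips persistence of a distance matrix
# ---------------------------------------------------------------------------


def rank_transform(dist: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Replace off-diagonal entries by their ascending rank (ties averaged).

    Ranks are computed over the strict upper triangle and mirrored, the
    diagonal stays 0.  The output depends only on the ordering of the
    distances, so any strictly increasing transform of the input yields the
    same matrix.
    """
    from scipy.stats import rankdata

    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=atol):
        raise ValueError("matrix is not symmetric within tolerance")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    out = np.zeros_like(d)
    out[iu] = ranks
    out.T[iu] = ranks
    return out


def vr_diagrams(dist: np.ndarray, max_dim: int = 1) -> PersistenceDiagram:
    """Vietoris-Rips persistence of a distance-like matrix, up to H1.

    All vertices are born at filtration 0; an edge enters at its matrix
    entry and a triangle at the maximum of its three edges.  Dim-0 bars are
    computed by a union-find sweep over the sorted edges (their deaths are
    exactly the minimum-spanning-tree edge weights; one class is essential).
    Dim-1 bars pair cycle-creating edges with the triangles that fill them,
    by boundary-matrix reduction over GF(2) with bitset columns.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    n = d.shape[0]
    if n == 0:
        return _diagram(bars0=[])

    ii, jj = np.triu_indices(n, k=1)
    weights = d[ii, jj]
    edge_order = np.lexsort((jj, ii, weights))
    ev = weights[edge_order]
    ei = ii[edge_order]
    ej = jj[edge_order]
    n_edges = ev.size
    edge_index = {}  # (i, j) -> sorted edge position
    for pos in range(n_edges):
        edge_index[(int(ei[pos]), int(ej[pos]))] = pos

    # --- dim 0: union-find over sorted edges --------------------------------
    parent = np.arange(n)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    bars0: list[tuple[float, float]] = []
    creator = np.zeros(n_edges, dtype=bool)  # edges that create a cycle
    for pos in range(n_edges):
        ra, rb = find(int(ei[pos])), find(int(ej[pos]))
        if ra == rb:
            creator[pos] = True
        else:
            parent[max(ra, rb)] = min(ra, rb)
            if ev[pos] > 0.0:
                bars0.append((0.0, float(ev[pos])))

    bars1: list[tuple[float, float]] = []
    essential1: list[float] = []
    if max_dim >= 1 and n >= 3:
        # --- dim 1: reduce the triangle boundary matrix ---------------------
        tri: list[tuple[float, int, int, int]] = []
        for a in range(n):
            for b in range(a + 1, n):
                dab = d[a, b]
                for c in range(b + 1, n):
                    tri.append((max(dab, d[a, c], d[b, c]), a, b, c))
        tri.sort()
        pivots: dict[int, int] = {}  # lowest edge position -> reduced column bits
        paired: set[int] = set()
        for tval, a, b, c in tri:
            col = (
                (1 << edge_index[(a, b)])
                | (1 << edge_index[(a, c)])
                | (1 << edge_index[(b, c)])
            )
            while col:
                low = col.bit_length() - 1
                other = pivots.get(low)
                if other is None:
                    pivots[low] = col
                    paired.add(low)
                    if tval > ev[low]:
                        bars1.append((float(ev[low]), float(tval)))
                    break
                col ^= other
        for pos in np.flatnonzero(creator):
            if int(pos) not in paired:
                essential1.append(float(ev[pos]))

    return _diagram(bars0=bars0, bars1=bars1, essential0=[0.0], essential1=essential1)


# ---------------------------------------------------------------------------
# Persistence images
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersistenceImage:
    """A Gaussian-smoothed grid embedding of a persistence diagram.

    Each finite diagram point, mapped to (birth, persistence) coordinates,
    contributes an isotropic Gaussian of bandwidth ``sigma`` weighted
    linearly by its persistence; the grid integrates the surface over
    ``resolution x resolution`` cells spanning the fixed axis ranges.
    Essential classes are excluded (their persistence is unbounded).
    """

    grid: np.ndarray
    birth_range: tuple[float, float]
    persistence_range: tuple[float, float]
    sigma: float
    weight: str = "linear"

    def vector(self) -> np.ndarray:
        return self.grid.ravel()


def persistence_image(diagram: PersistenceDiagram,
                      resolution: int = 10,
                      sigma: float | None = None,
                      birth_range: tuple[float, float] = (0.0, 1.0),
                      persistence_range: tuple[float, float] = (0.0, 1.0),
                      dim: int = 0) -> PersistenceImage:
    """Vectorize one homology dimension of a diagram as a persistence image.

    ``sigma`` defaults to one grid-cell width of the birth axis.  An empty
    diagram maps to the zero grid.
    """
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    b0, b1 = birth_range
    p0, p1 = persistence_range
    if not (b1 > b0 and p1 > p0):
        raise ValueError("axis ranges must be non-degenerate")
    if sigma is None:
        sigma = (b1 - b0) / resolution
    grid = np.zeros((resolution, resolution))
    pts = diagram.in_dim(dim, finite_only=True)
    if pts.size:
        births = pts[:, 0]
        pers = pts[:, 1] - pts[:, 0]
        b_edges = np.linspace(b0, b1, resolution + 1)
        p_edges = np.linspace(p0, p1, resolution + 1)
        for b, p in zip(births, pers):
            cdf_b = ndtr((b_edges - b) / sigma)
            cdf_p = ndtr((p_edges - p) / sigma)
            grid += p * np.outer(np.diff(cdf_b), np.diff(cdf_p))
    return PersistenceImage(
        grid=grid, birth_range=birth_range, persistence_range=persistence_range,
        sigma=float(sigma),
    )


# ---------------------------------------------------------------------------
# Feature pipelines
# ---------------------------------------------------------------------------


def uts_ph_vector(epoch: Epoch | np.ndarray,
                  channels: Sequence[int] | None = None,
                  resolution: int = 10) -> np.ndarray:
    """UTS-PH: per-channel lower-star diagram -> dim-0 persistence image ->
    flatten -> concatenate.  Full 64-channel output has length 6400."""
    values = epoch.values if isinstance(epoch, Epoch) else np.atleast_2d(np.asarray(epoch, dtype=float))
    if channels is not None:
        values = values[list(channels)]
    parts = []
    for row in values:
        diagram = lower_star_diagram(row)
        image = persistence_image(
            diagram, resolution=resolution,
            birth_range=UTS_PH_BIRTH_RANGE, persistence_range=UTS_PH_PERS_RANGE,
            dim=0,
        )
        parts.append(image.vector())
    return np.concatenate(parts)


def fbn_ph_vector(dist: np.ndarray, resolution: int = 10) -> np.ndarray:
    """FBN-PH: rank filtration -> Vietoris-Rips persistence -> concatenated
    dim-0 and dim-1 persistence images (length 200 at 10 x 10).

    Image axes span [0, #edges] in rank units, the full possible range, so
    the vector is comparable across epochs and invariant under monotone
    transformations of the input distances."""
    ranked = rank_transform(dist)
    n = ranked.shape[0]
    n_edges = n * (n - 1) // 2
    diagram = vr_diagrams(ranked, max_dim=1)
    hi = float(max(n_edges, 1))
    images = [
        persistence_image(
            diagram, resolution=resolution,
            birth_range=(0.0, hi), persistence_range=(0.0, hi), dim=d,
        ).vector()
        for d in (0, 1)
    ]
    return np.concatenate(images)
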