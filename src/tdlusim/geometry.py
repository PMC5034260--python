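"""Simulated TDLU cross-section geometry.

A terminal duct lobular unit (TDLU) cross-section is modelled on a square
lattice. Each acinus is a disc-shaped lumen wrapped by a one-node ring of
luminal epithelium and a one-node ring of myoepithelium. A polygon (the
convex hull of the epithelium, dilated by a stromal margin) separates the
intralobular from the interlobular stroma. Epithelial rings are built with
the 4-neighbourhood so every lumen node is sealed off from the stroma;
cell-cell contact and immune movement elsewhere in the package use the
Moore (8-)neighbourhood.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Compartment codes (int8)
LUMEN = 0
LUMINAL_EPITHELIUM = 1
MYOEPITHELIUM = 2
INTRALOBULAR_STROMA = 3
INTERLOBULAR_STROMA = 4

COMPARTMENT_LABELS = {
    LUMEN: "LUMEN",
    LUMINAL_EPITHELIUM: "LUMINAL_EPITHELIUM",
    MYOEPITHELIUM: "MYOEPITHELIUM",
    INTRALOBULAR_STROMA: "INTRALOBULAR_STROMA",
    INTERLOBULAR_STROMA: "INTERLOBULAR_STROMA",
}
LABEL_TO_CODE = {v: k for k, v in COMPARTMENT_LABELS.items()}

_MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_VON_NEUMANN = [(-1, 0), (1, 0), (0, -1), (0, 1)]


class GeometryError(ValueError):
    """Raised when a requested TDLU layout is infeasible on the grid."""


@dataclass
class LatticeDomain:
    """A TDLU cross-section lattice with compartment labels and adjacency.

    ``compartment`` is an (height, width) int8 array of compartment codes.
    ``dist_to_epithelium`` holds the Moore (chessboard) BFS distance of every
    non-lumen node to the nearest epithelial node (-1 inside lumina).
    Flat node indices are ``row * width + col``.
    """

    compartment: np.ndarray
    tdlu_polygon: np.ndarray  # (k, 2) float vertices (x, y)
    dist_to_epithelium: np.ndarray = field(default=None, repr=False)
    # neighbour tables, (n_nodes, 8|4) int32, -1-padded
    nbr_moore: np.ndarray = field(default=None, repr=False)
    nbr_vn: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.compartment = np.asarray(self.compartment, dtype=np.int8)
        if self.nbr_moore is None:
            self.nbr_moore = _neighbor_table(self.shape, _MOORE)
        if self.nbr_vn is None:
            self.nbr_vn = _neighbor_table(self.shape, _VON_NEUMANN)
        if self.dist_to_epithelium is None:
            self.dist_to_epithelium = distance_to_epithelium(self)

    # -- basic queries ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.compartment.shape

    @property
    def height(self) -> int:
        return self.compartment.shape[0]

    @property
    def width(self) -> int:
        return self.compartment.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.compartment.size

    @property
    def flat(self) -> np.ndarray:
        return self.compartment.ravel()

    @property
    def lumen_mask(self) -> np.ndarray:
        return self.flat == LUMEN

    @property
    def epithelium_mask(self) -> np.ndarray:
        c = self.flat
        return (c == LUMINAL_EPITHELIUM) | (c == MYOEPITHELIUM)

    @property
    def stroma_mask(self) -> np.ndarray:
        c = self.flat
        return (c == INTRALOBULAR_STROMA) | (c == INTERLOBULAR_STROMA)

    @property
    def n_epithelial(self) -> int:
        return int(self.epithelium_mask.sum())

    def node_xy(self, node: int | np.ndarray):
        """Flat index -> (x, y) = (col, row)."""
        return np.asarray(node) % self.width, np.asarray(node) // self.width

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        ys, xs = np.divmod(np.arange(self.n_nodes), self.width)
        labels = [COMPARTMENT_LABELS[c] for c in self.flat]
        pd.DataFrame({"node_x": xs, "node_y": ys, "compartment": labels}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "LatticeDomain":
        df = pd.read_csv(path, sep="\t")
        w = int(df["node_x"].max()) + 1
        h = int(df["node_y"].max()) + 1
        comp = np.empty((h, w), dtype=np.int8)
        comp[df["node_y"].to_numpy(), df["node_x"].to_numpy()] = [
            LABEL_TO_CODE[s] for s in df["compartment"]
        ]
        epi = np.argwhere(np.isin(comp, (LUMINAL_EPITHELIUM, MYOEPITHELIUM)))
        poly = _hull_polygon(epi[:, ::-1].astype(float)) if len(epi) >= 3 else np.zeros((0, 2))
        return cls(compartment=comp, tdlu_polygon=poly)


def _neighbor_table(shape, offsets) -> np.ndarray:
    h, w = shape
    n = h * w
    tab = np.full((n, len(offsets)), -1, dtype=np.int32)
    rows, cols = np.divmod(np.arange(n), w)
    for k, (dr, dc) in enumerate(offsets):
        rr, cc = rows + dr, cols + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        tab[ok, k] = rr[ok] * w + cc[ok]
    return tab


def _hull_polygon(points_xy: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points_xy)
    return points_xy[hull.vertices]


def _disc(center, radius, shape):
    """Flat indices of nodes within Euclidean ``radius`` of ``center`` (row, col)."""
    h, w = shape
    r0, c0 = center
    rr, cc = np.mgrid[0:h, 0:w]
    return np.flatnonzero(((rr - r0) ** 2 + (cc - c0) ** 2).ravel() <= radius**2)


def _acinus_centers(n_acini, spacing, grid_size, jitter, rng):
    """Jittered square-grid placement of acinus centres around the grid middle."""
    side = int(np.ceil(np.sqrt(n_acini)))
    mid = (grid_size - 1) / 2.0
    pts = []
    for i in range(side):
        for j in range(side):
            pts.append(((i - (side - 1) / 2) * spacing + mid, (j - (side - 1) / 2) * spacing + mid))
    pts = np.array(pts)
    order = np.argsort(((pts - mid) ** 2).sum(axis=1), kind="stable")
    centers = pts[order[:n_acini]]
    if jitter > 0:
        centers = centers + rng.integers(-jitter, jitter + 1, size=centers.shape)
    return np.rint(centers).astype(int)


def build_tdlu(
    n_acini: int,
    lumen_radius: int = 2,
    acinus_spacing: int = 11,
    grid_size: int = 72,
    seed: int = 0,
    stromal_margin: int = 3,
    jitter: int = 1,
    epithelial_band: tuple[int, int] | None = (250, 2500),
) -> LatticeDomain:
    """Build a TDLU cross-section with ``n_acini`` acini on a square grid.

    Each acinus is a lumen disc of the given radius, a luminal ring (the
    4-neighbours of the lumen) and a myoepithelial ring (the 4-neighbours of
    the luminal ring). Acini are placed on a jittered grid; overlapping or
    out-of-bounds acini raise :class:`GeometryError` rather than being
    silently clipped. The total epithelial node count must fall inside
    ``epithelial_band`` (pass ``None`` to skip the check).
    """
    if n_acini < 1:
        raise GeometryError("n_acini must be >= 1")
    if lumen_radius < 1:
        raise GeometryError("lumen_radius must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (grid_size, grid_size)
    comp = np.full(shape, INTERLOBULAR_STROMA, dtype=np.int8)
    flat = comp.ravel()
    vn = _neighbor_table(shape, _VON_NEUMANN)

    centers = _acinus_centers(n_acini, acinus_spacing, grid_size, jitter, rng)
    footprint = lumen_radius + 2  # lumen + two rings
    claimed = np.zeros(flat.size, dtype=bool)
    for r0, c0 in centers:
        if (
            r0 - footprint < 0
            or c0 - footprint < 0
            or r0 + footprint >= grid_size
            or c0 + footprint >= grid_size
        ):
            raise GeometryError(
                f"acinus at ({r0},{c0}) with footprint radius {footprint} crosses the grid boundary"
            )
        lumen = _disc((r0, c0), lumen_radius, shape)
        luminal = _ring_of(lumen, vn, exclude=lumen)
        myo = _ring_of(luminal, vn, exclude=np.concatenate([lumen, luminal]))
        acinus = np.concatenate([lumen, luminal, myo])
        if claimed[acinus].any():
            raise GeometryError(f"acinus at ({r0},{c0}) overlaps a previously placed acinus")
        claimed[acinus] = True
        flat[lumen] = LUMEN
        flat[luminal] = LUMINAL_EPITHELIUM
        flat[myo] = MYOEPITHELIUM

    n_epi = int(np.isin(flat, (LUMINAL_EPITHELIUM, MYOEPITHELIUM)).sum())
    if epithelial_band is not None and not (epithelial_band[0] <= n_epi <= epithelial_band[1]):
        raise GeometryError(
            f"epithelial node count {n_epi} outside the configured band {epithelial_band}"
        )

    # TDLU polygon: convex hull of epithelial nodes dilated by the stromal margin
    epi_rc = np.argwhere(np.isin(comp, (LUMINAL_EPITHELIUM, MYOEPITHELIUM)))
    hull = _hull_polygon(epi_rc[:, ::-1].astype(float))  # (x, y)
    rr, cc = np.mgrid[0:grid_size, 0:grid_size]
    inside = _within_margin(hull, cc.ravel(), rr.ravel(), stromal_margin)
    stroma = flat == INTERLOBULAR_STROMA
    flat[stroma & inside] = INTRALOBULAR_STROMA

    dom = LatticeDomain(compartment=comp, tdlu_polygon=hull)
    _check_invariants(dom)
    return dom


def _ring_of(core: np.ndarray, vn_table: np.ndarray, exclude: np.ndarray) -> np.ndarray:
    nbrs = vn_table[core].ravel()
    nbrs = np.unique(nbrs[nbrs >= 0])
    return np.setdiff1d(nbrs, exclude, assume_unique=False)


def _within_margin(polygon_xy, xs, ys, margin) -> np.ndarray:
    """Nodes inside the polygon or within ``margin`` (Euclidean) of it."""
    import shapely

    poly = shapely.Polygon(polygon_xy).buffer(margin)
    return shapely.contains_xy(poly, np.asarray(xs, float), np.asarray(ys, float))


def _check_invariants(dom: LatticeDomain) -> None:
    flat = dom.flat
    vn = dom.nbr_vn
    moore = dom.nbr_moore
    lumen = np.flatnonzero(flat == LUMEN)
    for node in lumen:
        nb = vn[node]
        nb = nb[nb >= 0]
        if np.isin(flat[nb], (INTRALOBULAR_STROMA, INTERLOBULAR_STROMA)).any():
            raise GeometryError(f"lumen node {node} is adjacent to stroma (ring not sealed)")
    luminal = np.flatnonzero(flat == LUMINAL_EPITHELIUM)
    for node in luminal:
        nb = moore[node]
        nb = nb[nb >= 0]
        if not (flat[nb] == MYOEPITHELIUM).any():
            raise GeometryError(f"luminal node {node} has no myoepithelial neighbour")


def distance_to_epithelium(domain: LatticeDomain) -> np.ndarray:
    """Moore-BFS distance of every non-lumen node to the epithelial node set.

    Returns an (height, width) int32 map; epithelial nodes are 0, lumen
    nodes -1 (undefined: immune cells never occupy lumina).
    """
    flat = domain.flat
    dist = np.full(domain.n_nodes, -1, dtype=np.int32)
    sources = np.flatnonzero((flat == LUMINAL_EPITHELIUM) | (flat == MYOEPITHELIUM))
    dist[sources] = 0
    lumen = flat == LUMEN
    q = deque(sources.tolist())
    moore = domain.nbr_moore
    while q:
        node = q.popleft()
        d = dist[node] + 1
        for nb in moore[node]:
            if nb >= 0 and not lumen[nb] and dist[nb] < 0:
                dist[nb] = d
                q.append(nb)
    return dist.reshape(domain.shape)
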