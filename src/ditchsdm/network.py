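"""Ditch-network graph and the network/distance covariates.

The rasterized ditch network (2 m cells) is modelled as a graph whose nodes
are ditch cells and whose edges connect 8-neighbouring ditch cells, with edge
lengths of one cell size (orthogonal) or sqrt(2) cell sizes (diagonal). A
dendritic network is a tree rooted at the single outlet; loops are tolerated
with a warning, since shortest-path distances remain well defined.

Also here: the per-cell covariate table (the eight explanatory variables),
[0, 1] min-max rescaling so model weights are comparable across variables,
Euclidean distance-to-land-use-class covariates with a 200 m footprint
extension against edge effects, and the Pearson collinearity screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid

__all__ = [
    "COVARIATE_NAMES",
    "LANDUSE_CLASSES",
    "DitchGraph",
    "OccurrenceSet",
    "CovariateTable",
    "build_graph",
    "distance_to_outlet",
    "distance_to_class",
    "rescale_covariates",
    "correlation_screen",
]

#: the eight explanatory variables, in canonical order
COVARIATE_NAMES = ("Doutlet", "Drain", "Mrvbf", "Northness", "Slope", "Solar", "Dnat", "Droad")

#: integer codes used in land-use grids
LANDUSE_CLASSES = {"other": 0, "natural": 1, "road": 2}

Cell = tuple[int, int]


@dataclass
class DitchGraph:
    """Graph over ditch cells with metric edge lengths and a designated outlet."""

    graph: nx.Graph
    outlet: Cell
    cell_size: float = 2.0

    def __post_init__(self) -> None:
        if self.outlet not in self.graph:
            raise ValueError(f"outlet {self.outlet} is not a network cell")

    @property
    def nodes(self) -> list[Cell]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def is_tree(self) -> bool:
        return nx.is_tree(self.graph)

    @property
    def total_length(self) -> float:
        """Summed edge length in metres."""
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def density(self, area_m2: float) -> float:
        """Network density in m/ha for a catchment of ``area_m2``."""
        return self.total_length / (area_m2 / 10_000.0)

    def distances_from(self, sources, cutoff: float | None = None) -> dict[Cell, float]:
        """Shortest network distance (m) from the nearest of ``sources``."""
        return nx.multi_source_dijkstra_path_length(
            self.graph, set(sources), cutoff=cutoff, weight="length"
        )

    def mask(self, template: Grid) -> Grid:
        out = np.zeros(template.shape)
        for r, c in self.graph.nodes:
            out[r, c] = 1.0
        return template.like(out)

    def branch_polylines(self, template: Grid) -> list[np.ndarray]:
        """Split the network into ditch polylines at junctions and endpoints.

        Each returned (n, 2) array of projected (x, y) vertices runs between
        two nodes of degree != 2 (junction, endpoint or outlet), so a
        'ditch' is a homogeneous unbranched stretch of the network.
        """
        g = self.graph
        breakpoints = {n for n in g if g.degree(n) != 2}
        breakpoints.add(self.outlet)
        lines: list[np.ndarray] = []
        visited_edges: set[frozenset] = set()
        for start in sorted(breakpoints):
            for nbr in sorted(g.neighbors(start)):
                edge = frozenset((start, nbr))
                if edge in visited_edges:
                    continue
                chain = [start, nbr]
                visited_edges.add(edge)
                prev, cur = start, nbr
                while cur not in breakpoints:
                    nxts = [n for n in g.neighbors(cur) if n != prev]
                    if not nxts:
                        break
                    nxt = nxts[0]
                    visited_edges.add(frozenset((cur, nxt)))
                    chain.append(nxt)
                    prev, cur = cur, nxt
                lines.append(np.array([template.cell_center(r, c) for r, c in chain]))
        return lines


@dataclass
class OccurrenceSet:
    """Presence and absence cell sets for one species on the network."""

    species: str
    presences: tuple[Cell, ...]
    absences: tuple[Cell, ...]

    def __post_init__(self) -> None:
        self.presences = tuple(sorted(self.presences))
        self.absences = tuple(sorted(self.absences))
        overlap = set(self.presences) & set(self.absences)
        if overlap:
            raise ValueError(f"{len(overlap)} cells are both presence and absence")

    @property
    def cells(self) -> tuple[Cell, ...]:
        return tuple(sorted(self.presences + self.absences))

    @property
    def n_presence(self) -> int:
        return len(self.presences)

    @property
    def n_absence(self) -> int:
        return len(self.absences)

    def labels(self, cells: list[Cell] | None = None) -> np.ndarray:
        cells = list(cells) if cells is not None else list(self.cells)
        pres = set(self.presences)
        return np.array([1 if c in pres else 0 for c in cells], dtype=int)


@dataclass
class CovariateTable:
    """Per-ditch-cell values of the explanatory variables.

    ``df`` is indexed by cell with columns ``row``, ``col`` and one column per
    covariate. ``rescaled`` marks whether values are on the [0, 1] scale;
    ``rescale_bounds`` stores the per-variable (min, max) used, so the same
    affine map can be applied to new data or inverted.
    """

    df: pd.DataFrame
    rescaled: bool = False
    rescale_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("row", "col") if c not in self.df.columns]
        if missing:
            raise ValueError(f"covariate table missing columns {missing}")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("row", "col")]

    @property
    def cells(self) -> list[Cell]:
        return [(int(r), int(c)) for r, c in zip(self.df["row"], self.df["col"])]

    def matrix(self, names: list[str] | None = None) -> np.ndarray:
        return self.df[list(names or self.covariates)].to_numpy(dtype=float)

    def rows_for(self, cells: list[Cell]) -> pd.DataFrame:
        lookup = {cell: i for i, cell in enumerate(self.cells)}
        try:
            pos = [lookup[c] for c in cells]
        except KeyError as err:
            raise KeyError(f"cell {err.args[0]} not in covariate table") from None
        return self.df.iloc[pos]

    def apply_bounds(self, other: "CovariateTable") -> "CovariateTable":
        """Rescale ``other`` (raw) with this table's stored bounds."""
        if not self.rescale_bounds:
            raise ValueError("no stored rescale bounds")
        df = other.df.copy()
        for name, (lo, hi) in self.rescale_bounds.items():
            df[name] = (df[name] - lo) / (hi - lo)
        return CovariateTable(df=df, rescaled=True, rescale_bounds=dict(self.rescale_bounds))

    def to_csv(self, path) -> None:
        df = self.df.copy()
        df["rescaled"] = int(self.rescaled)
        df.to_csv(path, index=False)


def build_graph(network_mask: Grid, outlet: Cell) -> DitchGraph:
    """Ditch graph from a rasterized network mask and its outlet cell.

    Edges join 8-neighbouring masked cells; lengths are ``cell_size`` m
    (orthogonal) or ``cell_size * sqrt(2)`` m (diagonal). Raises on an empty
    or disconnected mask (reporting component count and sizes); warns if the
    network contains loops (non-dendritic) -- distances stay well defined.
    """
    rows, cols = np.nonzero(network_mask.data > 0)
    nodes = [(int(r), int(c)) for r, c in zip(rows, cols)]
    if not nodes:
        raise ValueError("network mask is empty")
    node_set = set(nodes)
    if outlet not in node_set:
        raise ValueError(f"outlet {outlet} is off-network")
    size = network_mask.cell_size
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for r, c in nodes:
        for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):  # undirected: half of 8
            nb = (r + dr, c + dc)
            if nb in node_set:
                length = size * (np.sqrt(2) if dr and dc else 1.0)
                g.add_edge((r, c), nb, length=length)
    if not nx.is_connected(g):
        comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise ValueError(
            f"network has {len(comps)} disconnected components (sizes {comps[:10]})"
        )
    if g.number_of_edges() != g.number_of_nodes() - 1:
        warnings.warn(
            "network contains loops (non-dendritic); shortest-path distances still apply",
            stacklevel=2,
        )
    return DitchGraph(graph=g, outlet=outlet, cell_size=size)


def distance_to_outlet(graph: DitchGraph) -> dict[Cell, float]:
    """Shortest-path network distance (m) from every ditch cell to the outlet."""
    dist = nx.single_source_dijkstra_path_length(graph.graph, graph.outlet, weight="length")
    missing = set(graph.graph.nodes) - set(dist)
    if missing:
        raise ValueError(f"{len(missing)} cells cannot reach the outlet")
    return dist


def distance_to_class(
    cells: list[Cell],
    landuse: Grid,
    class_label: str | int,
    cap: float = 200.0,
    origin_offset: Cell = (0, 0),
) -> tuple[np.ndarray, np.ndarray]:
    """Straight-line distance (m) from ditch cell centres to the nearest cell
    of a land-use class.

    The land-use grid may cover an extended footprint (the scene padded by up
    to ``cap`` metres against edge effects); ``origin_offset`` gives the
    (row, col) of the scene's top-left cell inside it. Cells with no class
    cell within ``cap`` get the cap value and a raised flag.

    Returns ``(distances, capped_flags)`` aligned with ``cells``.
    """
    if isinstance(class_label, str):
        if class_label not in LANDUSE_CLASSES:
            raise ValueError(
                f"unknown land-use class {class_label!r}; expected one of {sorted(LANDUSE_CLASSES)}"
            )
        code = LANDUSE_CLASSES[class_label]
    else:
        code = int(class_label)
    target = landuse.data == code
    flags = np.zeros(len(cells), dtype=bool)
    if not target.any():
        flags[:] = True
        return np.full(len(cells), cap), flags
    # centre-to-centre Euclidean distances via the exact distance transform
    dist_grid = ndimage.distance_transform_edt(~target, sampling=landuse.cell_size)
    dr, dc = origin_offset
    out = np.empty(len(cells))
    for i, (r, c) in enumerate(cells):
        rr, cc = r + dr, c + dc
        if not (0 <= rr < landuse.shape[0] and 0 <= cc < landuse.shape[1]):
            raise IndexError(f"ditch cell {(r, c)} falls outside the land-use footprint")
        out[i] = dist_grid[rr, cc]
    over = out > cap
    out[over] = cap
    flags |= over
    return out, flags


def rescale_covariates(table: CovariateTable) -> CovariateTable:
    """Min-max rescale every covariate to [0, 1] over the table's cells.

    Bounds are stored on the result so the identical affine map can be applied
    to new data (see :meth:`CovariateTable.apply_bounds`). A constant column
    cannot be rescaled and raises, naming the variable.
    """
    if table.rescaled:
        raise ValueError("table is already rescaled")
    df = table.df.copy()
    bounds: dict[str, tuple[float, float]] = {}
    for name in table.covariates:
        col = df[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"covariate {name!r} contains non-finite values")
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            raise ValueError(f"covariate {name!r} is constant (range zero); cannot rescale")
        df[name] = (col - lo) / (hi - lo)
        bounds[name] = (lo, hi)
    return CovariateTable(df=df, rescaled=True, rescale_bounds=bounds)


def correlation_screen(
    table: CovariateTable, threshold: float = 0.6
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlation matrix over covariates, with collinearity flags.

    Pairs with ``|r| >= threshold`` are returned as flags; a model built on
    flagged pairs risks unstable partial regression coefficients.
    """
    if len(table.df) < 3:
        raise ValueError("need at least 3 cells for a correlation screen")
    names = table.covariates
    X = table.matrix(names)
    if np.any(X.std(axis=0) == 0):
        bad = [n for n, s in zip(names, X.std(axis=0)) if s == 0]
        raise ValueError(f"zero-variance covariates: {bad}")
    corr = pd.DataFrame(np.corrcoef(X, rowvar=False), index=names, columns=names)
    flagged = [
        (names[i], names[j], float(corr.iloc[i, j]))
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if abs(corr.iloc[i, j]) >= threshold
    ]
    return corr, flagged
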