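"""Spatial autocorrelation along the ditch network.

Occurrence data collected along a drainage network are autocorrelated over
*network* (stream) distance, not straight-line distance. This module
provides:

* a Moran's I correlogram with half-open network-distance lag rings and
  Z-scores under the randomization assumption;
* the critical distance -- the end of the initial run of significant lags --
  beyond which occurrences can be treated as independent;
* greedy seeded-random thinning that spaces retained cells at least the
  critical distance apart;
* the spatial sorting bias (SSB) diagnostic of a train/test split: the mean
  nearest-training-presence distance of test presences over that of test
  absences (1 = unbiased split, 0 = strongly biased).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Cell, DitchGraph, OccurrenceSet

__all__ = [
    "MoranProfile",
    "SplitDiagnostics",
    "network_moran_profile",
    "critical_distance",
    "thin_by_distance",
    "spatial_sorting_bias",
]


@dataclass
class MoranProfile:
    """Moran's I and Z per network-distance lag ring."""

    lags: np.ndarray  # ring upper bounds, metres, strictly increasing
    I: np.ndarray  # Moran index per ring (nan where the ring has no pair)
    Z: np.ndarray  # randomization Z-score per ring
    n: int  # number of cells
    pair_counts: np.ndarray  # unordered pairs per ring

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"lag_m": self.lags, "I": self.I, "Z": self.Z, "pairs": self.pair_counts})


@dataclass
class SplitDiagnostics:
    """Spatial sorting bias and class counts of one train/test split."""

    ssb: float
    n_test_presence: int
    n_test_absence: int
    n_train_presence: int


def _pairwise_within(graph: DitchGraph, cells: list[Cell], cutoff: float):
    """(i, j, d) for unordered cell pairs with network distance d <= cutoff."""
    index = {c: i for i, c in enumerate(cells)}
    sub = graph.graph
    for c in cells:
        if c not in sub:
            raise KeyError(f"cell {c} is not on the network")
    for c in cells:
        i = index[c]
        dists = nx.single_source_dijkstra_path_length(sub, c, cutoff=cutoff, weight="length")
        for other, d in dists.items():
            j = index.get(other)
            if j is not None and j > i:
                yield i, j, d


def network_moran_profile(
    values: dict[Cell, float] | tuple[list[Cell], np.ndarray],
    graph: DitchGraph,
    lags: np.ndarray | None = None,
) -> MoranProfile:
    """Moran's I correlogram over network-distance lag rings.

    ``values`` maps surveyed cells to a numeric (typically 0/1 presence)
    value. For each ring (d_prev, d]: weights w_ij = 1 iff the network
    distance between cells i and j falls in the ring, and

        I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    Z-scores use the analytical mean -1/(n-1) and variance under the
    randomization assumption. Rings without pairs yield nan.
    """
    if lags is None:
        lags = np.arange(2.0, 102.0, 2.0)
    lags = np.asarray(lags, dtype=float)
    if isinstance(values, dict):
        cells = sorted(values)
        x = np.array([values[c] for c in cells], dtype=float)
    else:
        cells, x = list(values[0]), np.asarray(values[1], dtype=float)
    n = len(cells)
    if n < 3:
        raise ValueError("need at least 3 cells")
    xc = x - x.mean()
    m2 = float(np.sum(xc**2))
    if m2 == 0:
        raise ValueError("values are constant; Moran's I undefined")
    b2 = n * float(np.sum(xc**4)) / m2**2

    edges = np.concatenate([[0.0], lags])
    n_lags = len(lags)
    cross = np.zeros(n_lags)  # sum of w_ij * xc_i * xc_j over unordered pairs
    pair_count = np.zeros(n_lags, dtype=np.int64)
    degree = np.zeros((n_lags, n), dtype=np.int64)
    for i, j, d in _pairwise_within(graph, cells, cutoff=float(lags[-1])):
        if d <= 0:
            continue
        k = int(np.searchsorted(edges, d, side="left")) - 1
        if k < 0 or k >= n_lags:
            continue
        cross[k] += xc[i] * xc[j]
        pair_count[k] += 1
        degree[k, i] += 1
        degree[k, j] += 1

    I = np.full(n_lags, np.nan)
    Z = np.full(n_lags, np.nan)
    e_i = -1.0 / (n - 1)
    for k in range(n_lags):
        if pair_count[k] == 0:
            continue
        s0 = 2.0 * pair_count[k]  # symmetric binary weights
        I[k] = (n / s0) * (2.0 * cross[k]) / m2
        s1 = 2.0 * s0
        s2 = float(np.sum((2.0 * degree[k]) ** 2))
        num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
            (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
        )
        den = (n - 1) * (n - 2) * (n - 3) * s0**2
        var = num / den - e_i**2
        if var > 0:
            Z[k] = (I[k] - e_i) / np.sqrt(var)
    return MoranProfile(lags=lags, I=I, Z=Z, n=n, pair_counts=pair_count)


def critical_distance(profile: MoranProfile, z_crit: float = 1.96) -> float:
    """Largest lag of the initial consecutive run of significant positive Z.

    Returns 0 if the first lag is already non-significant (no thinning
    required). Raises on an empty profile.
    """
    if len(profile.lags) == 0:
        raise ValueError("empty Moran profile")
    d = 0.0
    for lag, z in zip(profile.lags, profile.Z):
        if np.isfinite(z) and z > z_crit:
            d = float(lag)
        else:
            break
    return d


def thin_by_distance(
    occurrences: OccurrenceSet, graph: DitchGraph, d_crit: float, seed: int
) -> OccurrenceSet:
    """Greedy seeded-random thinning to a minimum network spacing.

    Presences and absences are thinned independently with the same
    ``d_crit``: cells are visited in seeded random order and kept only if
    every already-kept cell of the same class is at least ``d_crit`` away in
    network distance. ``d_crit = 0`` returns the input unchanged.
    """
    if d_crit < 0:
        raise ValueError("d_crit must be >= 0")
    if d_crit == 0:
        return occurrences
    rng = np.random.default_rng(seed)

    def thin(cells: tuple[Cell, ...]) -> tuple[Cell, ...]:
        order = list(cells)
        rng.shuffle(order)
        kept: set[Cell] = set()
        for cell in order:
            near = nx.single_source_dijkstra_path_length(
                graph.graph, cell, cutoff=d_crit, weight="length"
            )
            if not any(other in kept and d < d_crit for other, d in near.items()):
                kept.add(cell)
        return tuple(sorted(kept))

    return OccurrenceSet(
        species=occurrences.species,
        presences=thin(occurrences.presences),
        absences=thin(occurrences.absences),
    )


def spatial_sorting_bias(
    train: OccurrenceSet, test: OccurrenceSet, graph: DitchGraph
) -> SplitDiagnostics:
    """Spatial sorting bias of a train/test split (network-distance form).

    ssb = mean over test presences of the network distance to the nearest
    training presence, divided by the same mean over test absences. Values
    near 1 indicate an unbiased split; near 0, test presences sit much closer
    to training presences than test absences do.
    """
    if not train.presences:
        raise ValueError("no training presences")
    if not test.presences or not test.absences:
        raise ValueError("test split needs both presences and absences")
    dist = graph.distances_from(train.presences)
    try:
        num = float(np.mean([dist[c] for c in test.presences]))
        den = float(np.mean([dist[c] for c in test.absences]))
    except KeyError as err:
        raise ValueError(f"cell {err.args[0]} unreachable from training presences") from None
    return SplitDiagnostics(
        ssb=num / den if den > 0 else np.nan,
        n_test_presence=test.n_presence,
        n_test_absence=test.n_absence,
        n_train_presence=train.n_presence,
    )
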