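"""Genetic map construction from a DH genotype matrix.

Two-point analysis first: for every marker pair the recombination fraction
r^ = k/n is the fraction of pairwise-complete individuals whose calls
differ (in a DH population a differing pair IS a recombinant), and the LOD
of linkage is the log10 likelihood ratio of r = r^ against r = 1/2,

    LOD = k*log10(r^) + (n-k)*log10(1-r^) - n*log10(1/2),

taken as n*log10(2) exactly when k = 0 and clamped to 0 when r^ >= 1/2.
Linkage groups are connected components of the LOD >= 5 graph; marker order
within a group minimises the sum of adjacent recombination fractions (SARF)
by a greedy nearest-neighbour chain refined with 2-opt; distances are
Haldane, d = -50*ln(1-2r), accumulated along the order. Markers with
pairwise r^ = 0 co-segregate and collapse into a single bin/position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .genotyping import MISSING

logger = logging.getLogger(__name__)

MIN_LOD = 5.0
LOG10_2 = float(np.log10(2.0))


# ---------------------------------------------------------------- two-point

@dataclass
class PairwiseLinkage:
    """Dense two-point tables over an ordered marker list."""

    markers: list[str]
    n_informative: np.ndarray  # (m, m) int
    k: np.ndarray              # (m, m) int recombinant counts
    r: np.ndarray              # (m, m) float, 0.5 where uninformative
    lod: np.ndarray            # (m, m) float
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {m: i for i, m in enumerate(self.markers)}

    def table(self) -> pd.DataFrame:
        iu, ju = np.triu_indices(len(self.markers), k=1)
        return pd.DataFrame({
            "marker1": np.asarray(self.markers)[iu],
            "marker2": np.asarray(self.markers)[ju],
            "n_informative": self.n_informative[iu, ju],
            "k": self.k[iu, ju],
            "r": self.r[iu, ju],
            "lod": self.lod[iu, ju],
        })


def two_point_lod(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """LOD of linkage from recombinant count k out of n informative."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, k / np.maximum(n, 1), 0.5)
        term_k = np.where(k > 0, k * np.log10(np.where(r > 0, r, 1.0)), 0.0)
        term_nk = np.where(n - k > 0,
                           (n - k) * np.log10(np.where(r < 1, 1.0 - r, 1.0)),
                           0.0)
        lod = term_k + term_nk + n * LOG10_2
    return np.where((r >= 0.5) | (n == 0), 0.0, lod)


def pairwise_rf_lod(matrix: pd.DataFrame) -> PairwiseLinkage:
    """All-pairs recombination fraction and LOD, missing-aware.

    Missing calls make an individual uninformative for that pair only
    (pairwise complete observations). Uninformative pairs get r = 0.5 and
    LOD 0.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two markers")
    a = (matrix == "A").to_numpy(dtype=np.float64)
    b = (matrix == "B").to_numpy(dtype=np.float64)
    k = a @ b.T
    k = k + k.T
    n = (a + b) @ (a + b).T
    with np.errstate(invalid="ignore"):
        r = np.where(n > 0, k / np.maximum(n, 1), 0.5)
    lod = two_point_lod(k, n)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    uninform = n == 0
    if uninform.any():
        logger.debug("%d uninformative marker pairs", int(uninform.sum()) // 2)
    return PairwiseLinkage(list(matrix.index), n.astype(int), k.astype(int),
                           r, lod)


# ----------------------------------------------------------------- grouping

def group_markers(pw: PairwiseLinkage, min_lod: float = MIN_LOD
                  ) -> tuple[list[list[str]], list[str]]:
    """Linkage groups as connected components of the LOD >= min_lod graph.

    An edge additionally requires r^ < 0.5. Markers with no edge at all are
    reported unlinked. A marker bridging two otherwise separate groups
    merges them (connected components); such bridges are logged.
    """
    m = len(pw.markers)
    adj = (pw.lod >= min_lod) & (pw.r < 0.5)
    np.fill_diagonal(adj, False)
    graph = nx.Graph()
    graph.add_nodes_from(range(m))
    graph.add_edges_from(zip(*np.nonzero(np.triu(adj))))
    groups, unlinked = [], []
    for comp in nx.connected_components(graph):
        names = sorted(pw.markers[i] for i in comp)
        if len(comp) == 1:
            unlinked.append(names[0])
        else:
            groups.append(names)
    groups.sort(key=lambda g: g[0])
    return groups, sorted(unlinked)


# ----------------------------------------------------------------- ordering

def _bins(pw: PairwiseLinkage, members: list[int]) -> list[list[int]]:
    """Co-segregation bins: components of the r^ = 0 (informative) graph."""
    graph = nx.Graph()
    graph.add_nodes_from(members)
    arr = np.array(members)
    sub_r = pw.r[np.ix_(arr, arr)]
    sub_n = pw.n_informative[np.ix_(arr, arr)]
    ii, jj = np.nonzero(np.triu((sub_r == 0) & (sub_n > 0), k=1))
    graph.add_edges_from(zip(arr[ii], arr[jj]))
    return [sorted(c) for c in nx.connected_components(graph)]


def sarf(order: list[int], r: np.ndarray) -> float:
    """Sum of adjacent recombination fractions for an order."""
    return float(sum(r[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _two_opt(order: list[int], r: np.ndarray) -> list[int]:
    """Reverse-segment refinement; never increases SARF."""
    order = list(order)
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                left = r[order[i - 1], order[i]] if i > 0 else 0.0
                right = r[order[j], order[j + 1]] if j < m - 1 else 0.0
                new_left = r[order[i - 1], order[j]] if i > 0 else 0.0
                new_right = r[order[i], order[j + 1]] if j < m - 1 else 0.0
                if new_left + new_right < left + right - 1e-12:
                    order[i:j + 1] = reversed(order[i:j + 1])
                    improved = True
    return order


def order_group(group: list[str], pw: PairwiseLinkage) -> list[list[str]]:
    """Order one linkage group; returns a list of co-segregation bins.

    Bins are ordered as units: a greedy nearest-neighbour chain is started
    from one end of the most distal bin pair and refined by 2-opt on the
    SARF criterion. Orientation is fixed deterministically with the
    lexicographically smallest terminal marker first.
    """
    members = [pw.index[m] for m in group]
    if len(members) < 2:
        return [[pw.markers[i] for i in members]]
    bins = _bins(pw, members)
    reps = np.array([b[0] for b in bins])
    # distance between bins: mean r^ over member pairs (0.5 if uninformative)
    nb = len(bins)
    dist = np.zeros((nb, nb))
    for x in range(nb):
        for y in range(x + 1, nb):
            block_r = pw.r[np.ix_(bins[x], bins[y])]
            block_n = pw.n_informative[np.ix_(bins[x], bins[y])]
            vals = np.where(block_n > 0, block_r, 0.5)
            dist[x, y] = dist[y, x] = float(vals.mean())
    if nb == 1:
        order = [0]
    else:
        start = int(np.unravel_index(np.argmax(dist), dist.shape)[0])
        order = [start]
        remaining = set(range(nb)) - {start}
        while remaining:
            last = order[-1]
            nxt = min(remaining, key=lambda y: (dist[last, y], y))
            order.append(nxt)
            remaining.remove(nxt)
        order = _two_opt(order, dist)
    names = [[pw.markers[i] for i in bins[j]] for j in order]
    if names[-1][0] < names[0][0]:
        names.reverse()
    return names


# ------------------------------------------------------------ map distances

def haldane(r: float | np.ndarray) -> float | np.ndarray:
    """Haldane map distance in cM: d = -50*ln(1 - 2r); requires r < 1/2."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must be in [0, 0.5)")
    out = -50.0 * np.log(1.0 - 2.0 * r)
    return float(out) if out.ndim == 0 else out


def haldane_inverse(d: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a Haldane distance in cM (d >= 0)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    out = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------- assembly

def assemble_map(ordered_groups: list[list[list[str]]],
                 pw: PairwiseLinkage,
                 group_names: list[str] | None = None) -> pd.DataFrame:
    """Cumulative Haldane positions along each ordered group.

    ``ordered_groups`` holds, per group, the ordered list of bins from
    :func:`order_group`. Adjacent-bin r^ is measured between bin
    representatives (first member); co-segregating markers share one bin
    id and position. Returns columns marker, group, bin, position_cM.
    """
    rows = []
    for g, bins in enumerate(ordered_groups):
        name = group_names[g] if group_names else f"LG{g + 1}"
        pos = 0.0
        prev_rep = None
        for b, bin_markers in enumerate(bins):
            rep = pw.index[bin_markers[0]]
            if prev_rep is not None:
                r_adj = pw.r[prev_rep, rep]
                if pw.n_informative[prev_rep, rep] == 0:
                    logger.warning("uninformative adjacency in %s; 0 cM used",
                                   name)
                    r_adj = 0.0
                if r_adj >= 0.5:
                    raise ValueError(
                        f"adjacent r >= 0.5 in {name}: order rejected")
                pos += haldane(r_adj)
            for marker in bin_markers:
                rows.append((marker, name, b, pos))
            prev_rep = rep
    return pd.DataFrame(rows, columns=["marker", "group", "bin",
                                       "position_cM"])


def build_map(matrix: pd.DataFrame, min_lod: float = MIN_LOD,
              anchors: pd.DataFrame | None = None
              ) -> tuple[pd.DataFrame, list[str]]:
    """Full map pipeline: two-point -> group -> order -> Haldane positions.

    ``anchors`` (columns marker, chromosome) relabels linkage groups by the
    majority chromosome of any anchor markers they contain. Returns
    (map table, unlinked markers).
    """
    pw = pairwise_rf_lod(matrix)
    groups, unlinked = group_markers(pw, min_lod=min_lod)
    ordered = []
    for g in groups:
        bins = order_group(g, pw)
        try:
            assemble_map([bins], pw)
        except ValueError:
            # adjacent r >= 0.5: re-order from the reversed member list
            logger.warning("order rejected for a group; re-ordering")
            bins = order_group(list(reversed(g)), pw)
        ordered.append(bins)
    names = None
    if anchors is not None:
        lookup = dict(zip(anchors["marker"], anchors["chromosome"]))
        names = []
        for g, bins in enumerate(ordered):
            labels = [lookup[m] for b in bins for m in b if m in lookup]
            names.append(pd.Series(labels).mode().iloc[0] if labels
                         else f"LG{g + 1}")
    gmap = assemble_map(ordered, pw, group_names=names)
    return gmap, unlinked


def group_lengths(gmap: pd.DataFrame) -> pd.Series:
    return gmap.groupby("group")["position_cM"].max()
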