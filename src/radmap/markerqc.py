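"""Marker- and line-level quality control for a DH genotype matrix.

Four procedures used between genotyping and final map construction:

* missing-data filter — markers with >= 15% missing calls are excluded;
* duplicate-line detection — DH production can yield multiple lines from
  one doubled gamete; individuals with zero conflicting calls over a
  sufficient shared-marker overlap are collapsed to one representative;
* segregation distortion — per-marker chi-square against the 1:1 DH
  expectation, reported as a signed profile (-log10 p, signed toward the
  over-represented parent) for plotting along the map;
* singleton recoding — a call that disagrees with both tightly linked
  flanking calls is an apparent double crossover, almost always an error,
  and is recoded missing unless the flanking distances are large enough
  for genuine double recombination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genotyping import MISSING

logger = logging.getLogger(__name__)

MISSING_THRESHOLD = 0.15
MIN_OVERLAP = 50
MAX_FLANK_CM = 10.0


def filter_missing(matrix: pd.DataFrame,
                   threshold: float = MISSING_THRESHOLD
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Exclude markers whose missing fraction is >= threshold.

    The boundary is inclusive, matching "≥ 15% missing data points":
    14/93 missing (15.05%) is excluded, 13/93 (13.98%) retained.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    frac = (matrix == MISSING).mean(axis=1)
    excluded = matrix.index[frac >= threshold].tolist()
    return matrix.drop(index=excluded), excluded


def find_duplicate_lines(matrix: pd.DataFrame, min_overlap: int = MIN_OVERLAP
                         ) -> tuple[list[list[str]], pd.DataFrame]:
    """Detect sets of genetically identical individuals.

    Two individuals are duplicates iff they conflict at zero markers where
    both are called AND share at least ``min_overlap`` non-missing markers.
    Sets are transitive closures; the first member (input order) of each
    set is retained in the reduced matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two individuals")
    if min_overlap > matrix.shape[0]:
        raise ValueError("min_overlap exceeds marker count")
    inds = list(matrix.columns)
    obs = (matrix != MISSING).to_numpy()
    a_calls = (matrix == "A").to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(inds)
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            both = obs[:, i] & obs[:, j]
            if both.sum() < min_overlap:
                continue
            if (a_calls[both, i] == a_calls[both, j]).all():
                graph.add_edge(inds[i], inds[j])
    order = {ind: k for k, ind in enumerate(inds)}
    sets = [sorted(c, key=order.get) for c in nx.connected_components(graph)
            if len(c) > 1]
    sets.sort(key=lambda s: order[s[0]])
    drop = [ind for s in sets for ind in s[1:]]
    return sets, matrix.drop(columns=drop)


@dataclass
class DistortionProfile:
    table: pd.DataFrame  # marker, nA, nB, chi2, p, signed_score, flagged

    @property
    def flagged(self) -> list[str]:
        return self.table.loc[self.table["flagged"], "marker"].tolist()


def segregation_distortion(matrix: pd.DataFrame,
                           alpha: float = 0.05) -> DistortionProfile:
    """Per-marker chi-square (1 df) against 1:1 segregation.

    signed_score = -log10(p) * sign(nA - nB): positive values mean excess
    of parent-A alleles. Markers with no callable individuals are flagged
    uncallable (NaN statistics).
    """
    if matrix.shape[0] < 1:
        raise ValueError("matrix has no markers")
    n_a = (matrix == "A").sum(axis=1).to_numpy(dtype=float)
    n_b = (matrix == "B").sum(axis=1).to_numpy(dtype=float)
    n = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        e = n / 2.0
        chi2 = (n_a - e) ** 2 / e + (n_b - e) ** 2 / e
    p = stats.chi2.sf(chi2, df=1)
    with np.errstate(divide="ignore"):
        score = -np.log10(p) * np.sign(n_a - n_b)
    table = pd.DataFrame({
        "marker": matrix.index,
        "nA": n_a.astype(int),
        "nB": n_b.astype(int),
        "chi2": chi2,
        "p": p,
        "signed_score": score,
        "flagged": (p < alpha) | (n == 0),
        "uncallable": n == 0,
    }).reset_index(drop=True)
    return DistortionProfile(table)


def detect_singletons(matrix: pd.DataFrame, genetic_map: pd.DataFrame,
                      max_flank_cM: float = MAX_FLANK_CM
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Find and recode apparent double crossovers.

    ``genetic_map`` needs columns marker, group, position_cM. Within each
    linkage group (map order) a call is a singleton iff it differs from the
    nearest non-missing call on both sides; it is recoded missing iff both
    flanking distances are < max_flank_cM, else retained as plausible
    recombination. Terminal calls (one flank) are never singletons.

    Returns (report, recoded matrix); report columns are marker,
    individual, action, left_cM, right_cM.
    """
    recoded = matrix.copy()
    rows = []
    on_map = set(genetic_map["marker"])
    for marker in matrix.index:
        if marker not in on_map:
            logger.info("marker %s not on map; skipped for singletons", marker)
    for _, grp in genetic_map.groupby("group", sort=False):
        grp = grp.sort_values("position_cM")
        markers = [m for m in grp["marker"] if m in matrix.index]
        pos = {m: c for m, c in zip(grp["marker"], grp["position_cM"])}
        if len(markers) < 3:
            continue
        sub = matrix.loc[markers]
        for ind in matrix.columns:
            calls = sub[ind].to_numpy()
            known = np.flatnonzero(calls != MISSING)
            for a, b, c in zip(known[:-2], known[1:-1], known[2:]):
                if calls[b] != calls[a] and calls[b] != calls[c]:
                    left = pos[markers[b]] - pos[markers[a]]
                    right = pos[markers[c]] - pos[markers[b]]
                    if left < max_flank_cM and right < max_flank_cM:
                        action = "recoded_missing"
                        recoded.loc[markers[b], ind] = MISSING
                    else:
                        action = "retained"
                    rows.append((markers[b], ind, action, left, right))
    report = pd.DataFrame(rows, columns=["marker", "individual", "action",
                                         "left_cM", "right_cM"])
    return report, recoded


def write_distortion_tsv(profile: DistortionProfile,
                         genetic_map: pd.DataFrame | None,
                         path) -> None:
    """Distortion profile TSV with map coordinates for re-plotting."""
    table = profile.table
    if genetic_map is not None:
        table = table.merge(
            genetic_map.rename(columns={"position_cM": "cM"}),
            on="marker", how="left")
    table.to_csv(path, sep="\t", index=False)
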