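"""Tag clustering and cross-parent SNP marker discovery.

Per-sample tags are collapsed into depth-annotated clusters, depth-filtered
(8x floor against sequencing error, 500x ceiling against high-copy repeats),
and the two parents' surviving clusters are matched across at Hamming
distance <= 2 to build the marker panel: identical tags are monomorphic,
unique pairs at distance 1-2 are codominant SNP markers, unmatched tags are
dominant-style (present in one parent only), and tags with several partners
are ambiguous and excluded as paralog risk.

Matching uses pigeonhole seeding: each 28-mer is split into three segments,
so any pair within distance 2 shares at least one exact segment; candidates
found through a segment index are verified by a full Hamming count, making
the matcher exactly equivalent to the all-pairs scan it replaces.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simdata import TAG_LEN

logger = logging.getLogger(__name__)

MIN_DEPTH = 8
MAX_DEPTH = 500
MAX_MISMATCH = 2

CODOMINANT = "codominant"
MONOMORPHIC = "monomorphic"
DOMINANT_A = "dominant_A"
DOMINANT_B = "dominant_B"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class TagCluster:
    sample_id: str
    tag: str
    depth: int


def cluster_tags(sample_id: str, tags: Counter) -> list[TagCluster]:
    """One cluster per distinct tag string; depth = multiplicity."""
    return [TagCluster(sample_id, tag, depth)
            for tag, depth in sorted(tags.items())]


def filter_clusters(clusters: list[TagCluster],
                    min_depth: int = MIN_DEPTH,
                    max_depth: int = MAX_DEPTH) -> list[TagCluster]:
    """Retain clusters with min_depth <= depth <= max_depth.

    The ceiling is inclusive: depth 500 is kept, "greater than 500" dropped.
    """
    if min_depth <= 0 or max_depth <= 0 or min_depth > max_depth:
        raise ValueError("thresholds must be positive with min <= max")
    return [c for c in clusters if min_depth <= c.depth <= max_depth]


def _segments(tag: str, n_seg: int = MAX_MISMATCH + 1) -> list[tuple[int, str]]:
    """Split into n_seg near-equal segments; pigeonhole over <= 2 mismatches."""
    bounds = [round(i * len(tag) / n_seg) for i in range(n_seg + 1)]
    return [(i, tag[bounds[i]:bounds[i + 1]]) for i in range(n_seg)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("unequal tag lengths")
    return sum(x != y for x, y in zip(a, b))


def _partners(tags_a: list[str], tags_b: list[str],
              max_mismatch: int) -> dict[str, list[str]]:
    """For each A-tag, all B-tags within max_mismatch (exact, via seeding)."""
    index: dict[tuple[int, str], list[str]] = defaultdict(list)
    for tb in tags_b:
        for key in _segments(tb):
            index[key].append(tb)
    out: dict[str, list[str]] = {}
    for ta in tags_a:
        cands: set[str] = set()
        for key in _segments(ta):
            cands.update(index.get(key, ()))
        out[ta] = sorted(tb for tb in cands if hamming(ta, tb) <= max_mismatch)
    return out


def match_parent_clusters(clusters_a: list[TagCluster],
                          clusters_b: list[TagCluster],
                          max_mismatch: int = MAX_MISMATCH) -> pd.DataFrame:
    """Build the marker panel by cross-parent tag matching.

    Returns a DataFrame with columns locus_id, allele_A, allele_B,
    snp_positions (list of 0-based offsets) and marker_class. Pairing must
    be unique in both directions for a marker call; any tag with two or
    more partners within ``max_mismatch`` is classed ambiguous. Locus ids
    are assigned deterministically in lexicographic tag order.
    """
    tags_a = [c.tag for c in clusters_a]
    tags_b = [c.tag for c in clusters_b]
    if len(set(tags_a)) != len(tags_a) or len(set(tags_b)) != len(tags_b):
        raise ValueError("duplicate tags within a parent: clusters must be unique")

    a_to_b = _partners(tags_a, tags_b, max_mismatch)
    b_to_a = _partners(tags_b, tags_a, max_mismatch)

    rows = []
    for ta in tags_a:
        partners = a_to_b[ta]
        if not partners:
            rows.append((ta, "", [], DOMINANT_A))
        elif len(partners) > 1 or len(b_to_a[partners[0]]) > 1:
            rows.append((ta, "", [], AMBIGUOUS))
        else:
            tb = partners[0]
            diffs = [i for i, (x, y) in enumerate(zip(ta, tb)) if x != y]
            cls = MONOMORPHIC if not diffs else CODOMINANT
            rows.append((ta, tb, diffs, cls))
    matched_b = {r[1] for r in rows if r[1]}
    for tb in tags_b:
        if tb in matched_b:
            continue
        if not b_to_a[tb]:
            rows.append(("", tb, [], DOMINANT_B))
        else:
            rows.append(("", tb, [], AMBIGUOUS))

    rows.sort(key=lambda r: (r[0] or r[1]))
    panel = pd.DataFrame(rows, columns=["allele_A", "allele_B",
                                        "snp_positions", "marker_class"])
    panel.insert(0, "locus_id",
                 [f"FGX_SIM{i + 1:05d}" for i in range(len(panel))])
    return panel


def classify_panel(panel: pd.DataFrame) -> tuple[dict[str, int], pd.DataFrame]:
    """Class counts plus the codominant-only subpanel used downstream."""
    counts = panel["marker_class"].value_counts().to_dict()
    sub = panel[panel["marker_class"] == CODOMINANT].reset_index(drop=True)
    if sub.empty:
        warnings.warn("no codominant markers in panel", stacklevel=2)
    return counts, sub


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    out = panel.copy()
    out["snp_positions"] = out["snp_positions"].map(
        lambda v: ",".join(str(x) for x in v))
    out.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    panel = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    panel["snp_positions"] = panel["snp_positions"].map(
        lambda s: [int(x) for x in s.split(",")] if s else [])
    return panel
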