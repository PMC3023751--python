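"""Scoring DH individuals against the codominant marker panel.

Progeny reads are matched to panel alleles at Hamming distance 0 only; a
genotype is called when at least two reads support one allele and none
support the other. Conflicting evidence (reads for both alleles) and
insufficient depth are both coded missing — under this rule a sequencing
error can only cost a call, never flip one, because DH individuals carry no
true heterozygotes. No depth ceiling applies here: the 8x/500x window is a
discovery-phase filter and progeny were intentionally sequenced shallow.

The genotype matrix is written both as CSV and in the JoinMap 4 ``.loc``
format (population type DH, codes a/b/-).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_READS = 2
MISSING = "-"
CODE = {"A": "a", "B": "b", MISSING: MISSING}
DECODE = {v: k for k, v in CODE.items()}


def genotype_sample(tags: Counter, panel: pd.DataFrame,
                    min_reads: int = MIN_READS) -> pd.Series:
    """Call one individual at every panel locus.

    ``tags`` maps 28-nt tag -> read count (from demux/cluster_tags). Per
    locus the reads exactly matching allele_A and allele_B are counted;
    call A iff depth_A >= min_reads and depth_B == 0, B symmetrically;
    any locus with reads for both alleles is a conflict -> missing, and
    anything below the floor is missing too.
    """
    calls = []
    for _, row in panel.iterrows():
        da = tags.get(row["allele_A"], 0)
        db = tags.get(row["allele_B"], 0)
        if da >= 1 and db >= 1:
            calls.append(MISSING)
        elif da >= min_reads:
            calls.append("A")
        elif db >= min_reads:
            calls.append("B")
        else:
            calls.append(MISSING)
    return pd.Series(calls, index=panel["locus_id"].tolist(), dtype=object)


def build_genotype_matrix(sample_tags: dict[str, Counter],
                          panel: pd.DataFrame,
                          min_reads: int = MIN_READS) -> pd.DataFrame:
    """Markers x individuals matrix of calls in {A, B, -}.

    Individuals with 100% missing calls are retained but logged.
    """
    cols = {}
    for sample in sample_tags:
        col = genotype_sample(sample_tags[sample], panel, min_reads=min_reads)
        if (col == MISSING).all() and len(col):
            logger.warning("individual %s has no callable locus", sample)
        cols[sample] = col
    matrix = pd.DataFrame(cols)
    matrix.index.name = "locus_id"
    return matrix


def missing_rates(matrix: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """(per-marker, per-individual) missing fractions."""
    miss = matrix == MISSING
    return miss.mean(axis=1), miss.mean(axis=0)


def write_matrix_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.replace(MISSING, "NA").to_csv(path)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    return matrix.replace("NA", MISSING)


def write_joinmap_loc(matrix: pd.DataFrame, population_name: str,
                      path: str | Path) -> None:
    """JoinMap 4 ``.loc`` writer for a DH population (codes a, b, -)."""
    for marker in matrix.index:
        if re.search(r"\s", str(marker)):
            raise ValueError(f"marker id {marker!r} contains whitespace")
    lines = [
        f"name = {population_name}",
        "popt = DH",
        f"nloc = {len(matrix.index)}",
        f"nind = {len(matrix.columns)}",
        "",
    ]
    for marker, row in matrix.iterrows():
        lines.append(str(marker) + " " + " ".join(CODE[c] for c in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_joinmap_loc(path: str | Path) -> tuple[pd.DataFrame, str]:
    """Inverse of :func:`write_joinmap_loc` (individuals named I1..In)."""
    header: dict[str, str] = {}
    data = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        m = re.match(r"(name|popt|nloc|nind)\s*=\s*(\S+)", line)
        if m:
            header[m.group(1)] = m.group(2)
            continue
        parts = line.split()
        data.append((parts[0], [DECODE[c] for c in parts[1:]]))
    nind = int(header["nind"])
    matrix = pd.DataFrame(
        {f"I{j + 1}": [row[1][j] for row in data] for j in range(nind)},
        index=[row[0] for row in data])
    matrix.index.name = "locus_id"
    assert len(matrix) == int(header["nloc"])
    return matrix, header["name"]
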