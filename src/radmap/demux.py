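"""Barcode demultiplexing and tag trimming.

Raw 36-nt reads carry a 4-nt inline multiplex identifier (MID) followed by
the 6-nt SbfI remnant TGCAGG. A read is assigned to a sample only when its
first four bases exactly match that sample's barcode AND bases 5-10 equal
the remnant; assigned reads contribute bases 5-32 (1-based, inclusive) as
their 28-nt tag. Everything else is counted in a discard category, so
assigned + discarded always equals the input read count.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .simdata import MID_LEN, REMNANT, TAG_LEN

logger = logging.getLogger(__name__)

_TAG_END = MID_LEN + TAG_LEN  # 1-based position 32


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: str | None = None


@dataclass
class SampleTagSet:
    """All 28-nt tags assigned to one sample, as a multiset."""

    sample_id: str
    tags: Counter = field(default_factory=Counter)
    n_discarded_barcode: int = 0
    n_discarded_remnant: int = 0
    n_discarded_ambiguous: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(self.tags.values())


def trim_tag(read: ReadRecord) -> str:
    """Bases 5-32 (1-based, inclusive) of the read: remnant + 22 genomic nt."""
    if len(read.sequence) < _TAG_END:
        raise ValueError(
            f"read {read.read_id} is {len(read.sequence)} nt, need >= {_TAG_END}")
    return read.sequence[MID_LEN:_TAG_END]


def demultiplex(reads: Iterable[ReadRecord],
                barcode_map: dict[str, str]) -> dict[str, SampleTagSet]:
    """Partition reads by exact barcode match and remnant check.

    Returns one :class:`SampleTagSet` per sample plus a pseudo-sample
    ``_unassigned`` holding the discard tallies for reads matching no
    barcode. Reads with N in the barcode or remnant are never assigned.
    """
    seen: dict[str, str] = {}
    for sample, bc in barcode_map.items():
        if bc in seen:
            raise ValueError(
                f"duplicate barcode {bc!r} for {seen[bc]} and {sample}")
        if "N" in bc:
            raise ValueError(f"barcode {bc!r} contains N")
        seen[bc] = sample

    result = {s: SampleTagSet(sample_id=s) for s in barcode_map}
    unassigned = SampleTagSet(sample_id="_unassigned")
    for read in reads:
        seq = read.sequence
        if len(seq) < _TAG_END:
            logger.info("read %s shorter than %d nt; discarded",
                        read.read_id, _TAG_END)
            unassigned.n_discarded_ambiguous += 1
            continue
        sample = seen.get(seq[:MID_LEN])
        if sample is None:
            unassigned.n_discarded_barcode += 1
            continue
        tagset = result[sample]
        if seq[MID_LEN:MID_LEN + len(REMNANT)] != REMNANT:
            tagset.n_discarded_remnant += 1
            continue
        tagset.tags[seq[MID_LEN:_TAG_END]] += 1
    result["_unassigned"] = unassigned
    return result


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (plain or gzip) as :class:`ReadRecord`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield ReadRecord(rec.id, str(rec.seq))


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """2-column TSV ``sample_id<TAB>barcode`` -> dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "barcode"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["barcode"]))


def write_tag_files(tagsets: dict[str, SampleTagSet], out_dir: str | Path) -> Path:
    """One ``<sample>.tags.tsv`` (tag, count) per sample plus a summary TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample, ts in sorted(tagsets.items()):
        if sample != "_unassigned":
            df = pd.DataFrame(sorted(ts.tags.items()), columns=["tag", "count"])
            df.to_csv(out / f"{sample}.tags.tsv", sep="\t", index=False)
        rows.append((sample, ts.n_assigned, ts.n_discarded_barcode,
                     ts.n_discarded_remnant, ts.n_discarded_ambiguous))
    summary = pd.DataFrame(rows, columns=[
        "sample_id", "n_assigned", "n_discarded_barcode",
        "n_discarded_remnant", "n_discarded_other"])
    summary_path = out / "demux_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    return summary_path


def read_tag_file(path: str | Path) -> Counter:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return Counter(dict(zip(df["tag"], df["count"])))
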