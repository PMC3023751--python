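"""End-to-end driver: simulated reads -> demux -> panel -> genotypes -> map."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import demux as demux_mod
from . import discovery, genotyping, linkage, markerqc, simdata


def fastq_records(fastq_text: str) -> list[demux_mod.ReadRecord]:
    lines = fastq_text.splitlines()
    return [demux_mod.ReadRecord(lines[i][1:], lines[i + 1])
            for i in range(0, len(lines), 4)]


@dataclass
class PipelineResult:
    truth: simdata.TrueGenotypes
    tagsets: dict[str, demux_mod.SampleTagSet]
    read_log: pd.DataFrame
    panel: pd.DataFrame
    subpanel: pd.DataFrame
    matrix: pd.DataFrame
    fastq: str


def run_pipeline(config: simdata.SimConfig, pop_seed: int,
                 read_seed: int) -> PipelineResult:
    """Simulate one experiment and run it through discovery + genotyping."""
    truth = simdata.simulate_genome(config)
    truth = simdata.simulate_dh_population(truth, config.n_individuals,
                                           seed=pop_seed)
    fastq, log = simdata.simulate_reads(truth, config, seed=read_seed)
    tagsets = demux_mod.demultiplex(fastq_records(fastq), config.barcodes)
    filtered = [discovery.filter_clusters(
        discovery.cluster_tags(p, tagsets[p].tags)) for p in ("P_A", "P_B")]
    panel = discovery.match_parent_clusters(*filtered)
    _, subpanel = discovery.classify_panel(panel)
    tags = {ind: tagsets[ind].tags for ind in truth.individuals}
    matrix = genotyping.build_genotype_matrix(tags, subpanel)
    return PipelineResult(truth, tagsets, log, panel, subpanel, matrix, fastq)


def wrong_call_stats(result: PipelineResult) -> tuple[int, int]:
    """(wrong calls, total non-missing calls) against the simulation truth."""
    truth = result.truth
    mapped = truth.mapped_loci.reset_index(drop=True)
    by_allele = {(row["alleleA"], row["alleleB"]): j
                 for j, row in mapped.iterrows()}
    wrong = called = 0
    mat = result.matrix
    panel_idx = result.subpanel.set_index("locus_id")
    for lid in mat.index:
        row = panel_idx.loc[lid]
        j = by_allele.get((row["allele_A"], row["allele_B"]))
        if j is None:
            wrong += (mat.loc[lid] != "-").sum()
            called += (mat.loc[lid] != "-").sum()
            continue
        true_calls = pd.Series(
            ["A" if s == 0 else "B" for s in truth.sources[:, j]],
            index=truth.individuals)
        obs = mat.loc[lid]
        mask = obs != "-"
        called += int(mask.sum())
        wrong += int((obs[mask] != true_calls[mask]).sum())
    return wrong, called


def build_qc_map(matrix: pd.DataFrame, min_lod: float = linkage.MIN_LOD
                 ) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Two-pass map construction with the full marker-QC workflow.

    Missing-data filter, initial map, singleton recoding against that map,
    then a rebuild on the cleaned matrix. Returns (map, cleaned matrix,
    unlinked markers of the final pass).
    """
    matrix, _ = markerqc.filter_missing(matrix)
    gmap1, _ = linkage.build_map(matrix, min_lod=min_lod)
    _, recoded = markerqc.detect_singletons(matrix, gmap1)
    gmap2, unlinked = linkage.build_map(recoded, min_lod=min_lod)
    return gmap2, recoded, unlinked


def true_map_lengths(truth: simdata.TrueGenotypes) -> pd.Series:
    """True Haldane length spanned by the polymorphic loci per chromosome."""
    poly = truth.polymorphic_loci
    return poly.groupby("chrom")["cM"].agg(lambda s: s.max() - s.min())
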