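"""Synthetic RAD-seq experiments with known truth.

Emulates a reduced-representation sequencing experiment on a doubled-haploid
(DH) barley-style population: two fully inbred parents differing by SNPs at a
subset of restriction-site tags, DH progeny derived from a single meiosis of
their F1 (1:1 segregation, Haldane recombination, no heterozygotes), 36-nt
single-end reads carrying a 4-nt inline multiplex identifier (MID) followed
by the SbfI remnant TGCAGG, overdispersed per-locus read depth, per-base
substitution errors, high-copy repeat tags, and replicated quantitative
traits controlled by a few additive QTL.

Every generator is deterministic given a seed; the FASTQ writer is
byte-stable so simulated runs are exactly reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

REMNANT = "TGCAGG"
TAG_LEN = 28
MID_LEN = 4
READ_LEN = 36
FILLER_LEN = READ_LEN - MID_LEN - TAG_LEN
BASES = np.array(list("ACGT"))

# copy-number range for high-copy repeat tags
REPEAT_COPY_LOW = 20
REPEAT_COPY_HIGH = 100


def _default_barcodes(n: int) -> dict[str, str]:
    """Assign distinct 4-mers to parents P_A, P_B and DH_001..DH_n."""
    mers = []
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                for d in "ACGT":
                    mers.append(a + b + c + d)
    names = ["P_A", "P_B"] + [f"DH_{i + 1:03d}" for i in range(n)]
    return dict(zip(names, mers))  # truncated if > 254 samples


@dataclass
class SimConfig:
    """Knobs of the simulated experiment.

    Defaults mirror the mapping-population design the pipeline targets:
    7 chromosomes carrying 20 polymorphic SbfI tags each at 5-cM spacing,
    93 DH individuals, 10x mean progeny depth (parents deeper, 40x),
    0.1% per-base substitution error and a handful of high-copy repeats.
    """

    n_chromosomes: int = 7
    loci_per_chromosome: int = 20
    inter_locus_cM: float = 5.0
    snp_fraction: float = 1.0
    n_individuals: int = 93
    mean_depth: float = 10.0
    parent_mean_depth: float = 40.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.001
    n_repeat_loci: int = 5
    barcodes: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "loci_per_chromosome", "n_individuals",
                     "n_repeat_loci"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.snp_fraction <= 1.0:
            raise ValueError("snp_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.mean_depth < 0 or self.parent_mean_depth < 0:
            raise ValueError("depths must be >= 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if not self.barcodes:
            self.barcodes = _default_barcodes(self.n_individuals)
        seen = set()
        for sample, bc in self.barcodes.items():
            if len(bc) != MID_LEN or any(c not in "ACGT" for c in bc):
                raise ValueError(f"barcode {bc!r} for {sample} is not a 4-mer over ACGT")
            if bc in seen:
                raise ValueError(f"duplicate barcode {bc!r}")
            seen.add(bc)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class TrueGenotypes:
    """Ground truth of a simulated experiment.

    loci: one row per tag locus — locus_id, chrom, cM, alleleA, alleleB,
        snp_positions (0-based offsets into the 28-nt tag), copy_number
        (> 1 flags a high-copy repeat; repeats sit off-map with chrom "").
    sources: individuals x mapped loci matrix of parental origin
        (0 = parent A, 1 = parent B); filled by :func:`simulate_dh_population`.
    individuals: row labels of ``sources``.
    """

    loci: pd.DataFrame
    sources: np.ndarray | None = None
    individuals: list[str] | None = None

    @property
    def mapped_loci(self) -> pd.DataFrame:
        return self.loci[self.loci["copy_number"] == 1]

    @property
    def polymorphic_loci(self) -> pd.DataFrame:
        return self.loci[self.loci["snp_positions"].str.len() > 0]


def _random_tags(rng: np.random.Generator, n: int) -> list[str]:
    """Distinct 28-nt tags, each starting with the SbfI remnant."""
    tags: set[str] = set()
    while len(tags) < n:
        body = rng.choice(BASES, size=(n - len(tags), TAG_LEN - len(REMNANT)))
        for row in body:
            tags.add(REMNANT + "".join(row))
    return sorted(tags)[:n]


def simulate_genome(config: SimConfig) -> TrueGenotypes:
    """Draw the parental tag universe and the true genetic map.

    Each mapped locus carries one 28-nt tag per parent beginning with
    TGCAGG; exactly ``round(snp_fraction * n_loci)`` loci are polymorphic,
    differing at 1-2 positions confined to the trailing 22 nt. Repeat loci
    (copy_number in [20, 100]) are monomorphic and off the genetic map.
    """
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_chromosomes * config.loci_per_chromosome
    n_poly = int(round(config.snp_fraction * n_loci))
    if n_loci > 0 and 0 < config.snp_fraction and n_poly < 1:
        warnings.warn("snp_fraction * n_loci < 1: zero polymorphic loci",
                      stacklevel=2)
    tags = _random_tags(rng, n_loci + config.n_repeat_loci)
    rng.shuffle(tags)

    poly_idx = set(rng.choice(n_loci, size=n_poly, replace=False)) if n_poly else set()
    rows = []
    for i in range(n_loci):
        chrom = i // config.loci_per_chromosome + 1
        pos = (i % config.loci_per_chromosome) * config.inter_locus_cM
        allele_a = tags[i]
        if i in poly_idx:
            n_snp = int(rng.integers(1, 3))
            offs = sorted(rng.choice(np.arange(len(REMNANT), TAG_LEN),
                                     size=n_snp, replace=False).tolist())
            b = list(allele_a)
            for off in offs:
                b[off] = str(rng.choice(BASES[BASES != b[off]]))
            allele_b = "".join(b)
        else:
            offs = []
            allele_b = allele_a
        rows.append((f"chr{chrom}", float(pos), allele_a, allele_b, offs, 1))
    for j in range(config.n_repeat_loci):
        tag = tags[n_loci + j]
        copy = int(rng.integers(REPEAT_COPY_LOW, REPEAT_COPY_HIGH + 1))
        rows.append(("", float("nan"), tag, tag, [], copy))

    loci = pd.DataFrame(rows, columns=["chrom", "cM", "alleleA", "alleleB",
                                       "snp_positions", "copy_number"])
    loci.insert(0, "locus_id", [f"SIMLOC{i + 1:05d}" for i in range(len(loci))])
    return TrueGenotypes(loci=loci)


def haldane_r(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Recombination fraction for a Haldane map distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_dh_population(truth: TrueGenotypes, n: int,
                           seed: int | None = None) -> TrueGenotypes:
    """Draw ``n`` DH individuals as mosaics of the two parental haplotypes.

    The starting allele of each chromosome is Bernoulli(1/2); a crossover
    occurs between adjacent loci independently with the Haldane probability
    r = (1 - exp(-2d/100))/2. Individuals are fully homozygous throughout,
    so ``sources`` stores a single parental label per locus.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    mapped = truth.mapped_loci
    cols = []
    for _, grp in mapped.groupby("chrom", sort=False):
        d = np.diff(grp["cM"].to_numpy())
        r = haldane_r(d)
        start = rng.integers(0, 2, size=(n, 1))
        xo = rng.random((n, len(d))) < r
        # cumulative XOR of crossovers along the chromosome
        states = np.concatenate([start, xo], axis=1).cumsum(axis=1) % 2
        cols.append(states)
    sources = np.concatenate(cols, axis=1) if cols else np.zeros((n, 0), int)
    return TrueGenotypes(
        loci=truth.loci,
        sources=sources.astype(np.int8),
        individuals=[f"DH_{i + 1:03d}" for i in range(n)],
    )


def _mutate(rng: np.random.Generator, seqs: np.ndarray, error_rate: float) -> np.ndarray:
    """Substitute each base independently with probability error_rate."""
    if error_rate <= 0:
        return seqs
    hits = rng.random(seqs.shape) < error_rate
    if hits.any():
        # shift by 1-3 positions in the base alphabet: never the same base
        shift = rng.integers(1, 4, size=int(hits.sum()))
        idx = np.searchsorted(BASES, seqs[hits])
        seqs = seqs.copy()
        seqs[hits] = BASES[(idx + shift) % 4]
    return seqs


def _emit_reads(rng: np.random.Generator, out: list[str], sample: str,
                barcode: str, tag_depths: list[tuple[str, int]],
                error_rate: float, counter: list[int],
                truth_log: list[tuple]) -> None:
    tags = [t for t, dep in tag_depths for _ in range(dep)]
    if not tags:
        return
    arr = np.array([list(t) for t in tags], dtype="<U1")
    arr = _mutate(rng, arr, error_rate)
    fillers = rng.choice(BASES, size=(len(tags), FILLER_LEN))
    qual = "I" * READ_LEN
    for i, true_tag in enumerate(tags):
        counter[0] += 1
        rid = f"SIM_{counter[0]:09d}"
        seq = barcode + "".join(arr[i]) + "".join(fillers[i])
        out.append(f"@{rid}\n{seq}\n+\n{qual}\n")
        truth_log.append((rid, sample, true_tag))


def simulate_reads(truth: TrueGenotypes, config: SimConfig,
                   seed: int | None = None) -> tuple[str, pd.DataFrame]:
    """Generate 36-nt barcoded reads for both parents and every individual.

    Returns the FASTQ text (Phred+33, constant quality) and a per-read truth
    log (read_id, sample, true 28-nt tag). Read layout: 4-nt MID + 28-nt tag
    + 4-nt random filler. Per-sample per-locus depths are negative binomial
    with the configured mean and dispersion; repeat loci emit copy_number
    times that depth; each base is substituted independently at error_rate.
    """
    samples = (["P_A", "P_B"]
               + (list(truth.individuals) if truth.sources is not None else []))
    missing = [s for s in samples if s not in config.barcodes]
    if missing:
        raise ValueError(f"no barcode for samples {missing[:3]}...: only "
                         "254 distinct 4-nt MIDs exist")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = truth.loci
    out: list[str] = []
    log: list[tuple] = []
    counter = [0]

    def draw_depths(mean: float, size: int) -> np.ndarray:
        if mean <= 0:
            return np.zeros(size, dtype=int)
        k = config.depth_dispersion
        return rng.negative_binomial(k, k / (k + mean), size=size)

    copy = loci["copy_number"].to_numpy()
    for parent, allele_col in (("P_A", "alleleA"), ("P_B", "alleleB")):
        depths = draw_depths(config.parent_mean_depth, len(loci)) * copy
        pairs = list(zip(loci[allele_col], depths.tolist()))
        _emit_reads(rng, out, parent, config.barcodes[parent], pairs,
                    config.error_rate, counter, log)

    if truth.sources is not None:
        mapped = truth.mapped_loci
        repeats = loci[loci["copy_number"] > 1]
        for i, ind in enumerate(truth.individuals):
            src = truth.sources[i]
            alleles = np.where(src == 0, mapped["alleleA"], mapped["alleleB"])
            depths = draw_depths(config.mean_depth, len(mapped))
            pairs = list(zip(alleles.tolist(), depths.tolist()))
            if len(repeats):
                rdep = draw_depths(config.mean_depth, len(repeats))
                rdep = rdep * repeats["copy_number"].to_numpy()
                pairs += list(zip(repeats["alleleA"], rdep.tolist()))
            _emit_reads(rng, out, ind, config.barcodes[ind], pairs,
                        config.error_rate, counter, log)

    log_df = pd.DataFrame(log, columns=["read_id", "sample", "true_tag"])
    return "".join(out), log_df


def simulate_phenotypes(truth: TrueGenotypes,
                        qtl_spec: list[tuple[str, float]],
                        h2_target: float = 0.9,
                        n_reps: int = 2,
                        seed: int | None = None,
                        trait: str = "TRAIT",
                        polygenic_sd: float = 0.0,
                        residual_sd: float | None = None) -> pd.DataFrame:
    """Replicated trait values controlled by additive QTL.

    Genotypic value of individual i is sum of +a (parent-A allele) or -a
    (parent-B allele) over the QTL in ``qtl_spec`` (locus_id, a), plus an
    unlinked polygenic deviation with SD ``polygenic_sd``. Residual noise is
    scaled so the realized broad-sense heritability H2 = sG2/(sG2 + se2/r)
    matches ``h2_target``; h2_target = 1 means no residual noise at all.
    ``residual_sd`` overrides the heritability scaling with an explicit
    per-replicate noise SD. Output is tidy: individual, trait, replicate,
    value.
    """
    if not 0.0 < h2_target <= 1.0:
        raise ValueError("h2_target must be in (0, 1]")
    if truth.sources is None:
        raise ValueError("population not simulated yet")
    rng = np.random.default_rng(seed)
    mapped = truth.mapped_loci.reset_index(drop=True)
    idx = {lid: j for j, lid in enumerate(mapped["locus_id"])}
    g = np.zeros(len(truth.individuals))
    for locus, a in qtl_spec:
        if locus not in idx:
            raise KeyError(f"QTL locus {locus} not in truth")
        g += np.where(truth.sources[:, idx[locus]] == 0, a, -a)
    if polygenic_sd > 0:
        g = g + rng.normal(0.0, polygenic_sd, size=len(g))
    var_g = float(np.var(g, ddof=1)) if len(g) > 1 else 0.0
    if residual_sd is not None:
        sigma_e = float(residual_sd)
    elif h2_target < 1.0 and var_g > 0:
        sigma_e = float(np.sqrt(n_reps * var_g * (1.0 - h2_target) / h2_target))
    else:
        sigma_e = 0.0
    rows = []
    for i, ind in enumerate(truth.individuals):
        for rep in range(1, n_reps + 1):
            eps = rng.normal(0.0, sigma_e) if sigma_e > 0 else 0.0
            rows.append((ind, trait, rep, g[i] + eps))
    return pd.DataFrame(rows, columns=["individual", "trait", "replicate", "value"])


def true_genotype_matrix(truth: TrueGenotypes,
                         missing_rate: float = 0.0,
                         seed: int | None = None) -> pd.DataFrame:
    """Error-free genotype matrix (markers x individuals) from the truth.

    Bypasses read simulation: calls are the parental source labels of the
    polymorphic mapped loci, optionally masked missing at ``missing_rate``
    to emulate shallow coverage.
    """
    if truth.sources is None:
        raise ValueError("population not simulated yet")
    mapped = truth.mapped_loci.reset_index(drop=True)
    poly = mapped["snp_positions"].str.len() > 0
    calls = np.where(truth.sources.T[poly.to_numpy()], "B", "A").astype(object)
    if missing_rate > 0:
        rng = np.random.default_rng(seed)
        calls[rng.random(calls.shape) < missing_rate] = "-"
    matrix = pd.DataFrame(calls, index=mapped.loc[poly, "locus_id"].tolist(),
                          columns=truth.individuals)
    matrix.index.name = "locus_id"
    return matrix


def write_truth_tables(truth: TrueGenotypes, out_dir: str | Path) -> None:
    """TSV truth tables: locus table and (if present) source-parent matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    loci = truth.loci.copy()
    loci["snp_positions"] = loci["snp_positions"].map(
        lambda v: ",".join(str(x) for x in v))
    loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
    if truth.sources is not None:
        mat = pd.DataFrame(truth.sources,
                           index=truth.individuals,
                           columns=truth.mapped_loci["locus_id"].tolist())
        mat.to_csv(out / "truth_sources.tsv", sep="\t")
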