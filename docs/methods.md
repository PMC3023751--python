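# Methods

`radmap` implements a reduced-representation genotyping-by-sequencing
workflow for doubled-haploid (DH) mapping populations, of the kind used to
build SNP linkage maps in barley from SbfI RAD libraries, together with a
ground-truthed simulator of the whole experiment. This note records the
models, the parameters that matter, and the design choices made where the
procedure was genuinely open.

## Read model and demultiplexing

Reads are 36 nt: a 4-nt inline multiplex identifier (MID), the 6-nt SbfI
remnant `TGCAGG`, and 22 nt of genomic sequence, followed by filler to the
read length. The analysed unit is the 28-nt tag at positions 5–32
(1-based): remnant plus genomic sequence. A read is assigned to a sample
only when its MID matches a barcode exactly *and* the remnant is intact;
there is no 1-mismatch barcode rescue, because rescue would distort the
depth statistics that the downstream filters depend on. Reads failing
either check are counted per discard category, so assigned + discarded
equals input on any input. SNPs can only occur in the trailing 22 nt of a
tag (the remnant is constant by construction).

## SNP discovery

Per sample, identical tags collapse into clusters whose depth is the read
multiplicity. Parental clusters are depth-filtered to 8 ≤ depth ≤ 500
(inclusive at both ends: 8 is kept, 501 is dropped): the floor suppresses
sequencing-error tags, the ceiling removes high-copy repeats. The two
parents' surviving tags are then matched across at Hamming distance ≤ 2.
Matching uses pigeonhole seeding — each 28-mer is split into three
segments, so two tags within distance 2 must share at least one aligned
segment exactly — and every candidate pair is verified by a full Hamming
count, making the matcher provably identical to the all-pairs scan (the
test suite checks this equivalence exhaustively on 1000-tag instances).

Classification: a unique distance-0 pair is monomorphic; a unique pair at
distance 1–2 is a codominant SNP marker; an unmatched tag is
dominant-style (present in one parent only); any tag with two or more
partners within distance 2 is ambiguous and excluded as paralog risk (the
conservative choice; keeping best hits would admit repeat-derived false
markers). Only codominant markers go forward to mapping — dominant
presence/absence markers confound absence with dropout in a sequencing
assay and are deliberately not mapped.

## Genotyping

Progeny are scored against the codominant panel by exact tag match only.
A genotype is called when ≥ 2 reads support one allele and none support
the other; any locus with reads for both alleles, or below the floor, is
missing. Because DH lines carry no true heterozygotes, under this rule a
sequencing error can cost a call but can never flip one: a wrong call
would need ≥ 2 identical error reads converting one allele into the other
with zero true-allele reads observed. The discovery-phase 8×/500× window
is *not* applied to progeny: it is a repeat filter for allele mining, and
progeny are intentionally sequenced shallow (2-read floor instead). The
strict conflict rule (a single opposing read voids the call) is exposed as
`min_reads`; a majority-vote variant was rejected because allele switching
at 1-SNP loci is the dominant error mode it would admit.

The matrix is written as CSV and as a JoinMap 4 `.loc` file (population
type DH, codes `a`/`b`/`-`); writer and reader are exact inverses.

## Marker and line QC

* Missing-data filter: markers with ≥ 15% missing calls are excluded
  (boundary inclusive: 14/93 = 15.05% is dropped, 13/93 kept).
* Duplicate lines: DH production can deliver several lines from one
  doubled gamete. Two individuals are duplicates when they conflict at no
  marker where both are called and share ≥ `min_overlap` (default 50)
  called markers; duplicate sets are transitive closures and one
  representative (first in input order) is kept.
* Segregation distortion: per marker, χ² with 1 df against the 1:1 DH
  expectation, no continuity correction (standard at n ≈ 80–90). The
  profile is reported as −log10(p) signed toward the over-represented
  parent, suitable for plotting along the map.
* Singletons: a call differing from the nearest called neighbours on both
  sides within its linkage group is an apparent double crossover. It is
  recoded missing when both flanking distances are < `max_flank_cM`
  (default 10 cM — at 10 cM flanks a genuine double crossover has
  probability ≈ r² ≈ 0.8%, so recoding is almost always removing an
  error); with wide flanks it is retained as plausible recombination.
  Terminal calls are never singletons. This runs as a second pass after an
  initial map build, and genuine tight double crossovers are knowingly
  sacrificed — the rule's documented cost.

## Linkage mapping

Two-point analysis over pairwise-complete observations: in a DH
population, an individual whose calls differ at two markers *is* a
recombinant, so r̂ = k/n, and the linkage LOD is the log10 likelihood
ratio of r = r̂ against r = 1/2,

    LOD = k·log10(r̂) + (n−k)·log10(1−r̂) − n·log10(1/2),

which is n·log10 2 exactly at k = 0 (the 0·log 0 limit) and 0 whenever
r̂ ≥ 1/2. Linkage groups are connected components of the LOD ≥ 5 graph
(edges additionally need r̂ < 1/2); markers with no edge are reported
unlinked. A marker linked to two otherwise separate groups merges them —
connected components make that choice implicitly, and such bridges are
logged rather than resolved.

Within a group, markers with pairwise r̂ = 0 collapse into co-segregation
bins ordered as units. Bin order minimises the sum of adjacent
recombination fractions (SARF): a greedy nearest-neighbour chain started
from one end of the most distal bin pair, refined by 2-opt segment
reversals until no improvement. 2-opt provably never increases SARF, and
on the simulated study design (20 markers at 5 cM, n = 93) it recovers the
true order up to reversal in well over 90% of runs. Orientation is fixed
deterministically (lexicographically smallest terminal marker first);
anchor markers with known chromosome labels, when supplied, relabel groups
by majority vote. Distances are Haldane, d = −50·ln(1 − 2r̂), accumulated
along the order; group length is the last cumulative position.

Order recovery is only defined up to bin structure: markers with r̂ = 0
have no identifiable internal order at the given sample size, so recovery
is scored up to reversal *and* within-bin permutation throughout the test
suite.

## QTL analysis

The scan is Haley–Knott-style regression on expected genotype scores
rather than a mixture-likelihood EM: for DH populations at the effect
sizes of interest the two are practically equivalent, and the regression
form is deterministic and fast enough to permute honestly. Genotypes are
coded +1/−1; between markers the conditional expectation given the
flanking calls follows Haldane no-interference probabilities, decaying as
e^(−2d/100) beyond the last informative marker and equalling the hard
call at a called marker. The grid covers each group at a 1-cM walk.

At each position the line-mean trait is regressed on the expectation plus
cofactors; cofactors within 50 cM of the position are excluded from both
the null and the full model. LR = n·ln(RSS0/RSS1) is reported as
LOD = 0.217·LR — the constant is kept at the conventional printed value
0.217 rather than the exact 1/(2 ln 10) ≈ 0.21715 so reported LODs follow
the field's convention. The additive effect is the coefficient on the
±1 score (half the fitted contrast between genotype classes); R² is the
QTL term's share of total trait variance beyond the cofactor model.

Cofactors (≤ 7) are chosen by forward-selection backward-elimination
stepwise regression at significance 0.1, with one candidate per
co-segregation bin (bin-mates are exactly collinear). Replicates enter
the QTL scan only through line means; they feed the heritability estimate.

**Permutation thresholds.** Experiment-wise thresholds are the empirical
(1−α) quantile of the genome-wide maximum LOD over (default) 1000 trait
permutations with a fixed seed. Crucially, the *whole* analysis — stepwise
cofactor selection included — is re-run on every permuted trait. With
cofactors frozen from the observed trait the threshold is strongly
anti-conservative: stepwise selection overfits (seven cofactors chosen
among ~140 candidates on ~93 lines absorb a large share of null
variance), and the window exclusion re-exposes each selected effect to
the scan; the measured genome-wide null false-positive rate was ≈ 0.25
instead of α = 0.05. Re-selection makes the observed maximum exchangeable
with the permuted ones under the global null, so the threshold is
calibrated by construction (measured ≈ 0.03–0.05). The frozen-cofactor
variant remains available (`reselect=False`) for comparison.

Declared QTL are per-group peaks above the threshold with 2-LOD support
intervals (widest contiguous run with LOD ≥ peak − 2, truncated at group
ends).

**Heritability.** Broad-sense H² = σG²/(σG² + σe²/r) from a one-way
random-effects decomposition: σe² is the within-genotype mean square,
σG² = max(0, (between-MS − within-MS)/r), r the replicates per genotype.
The derived trait GY = SN·GN·HGW is computed literally on genotype means
(hundred-grain weight is not divided by 100; GY is therefore on the scale
the formula defines, a unit caveat worth knowing when comparing yields).

## The simulator

`simdata` generates the full experiment with known truth. Defaults are
the study design the pipeline targets: 7 chromosomes × 20 polymorphic
loci at 5-cM spacing (the observed average marker density), 93 DH lines,
10× mean progeny depth, 40× parental depth (parents are sequenced deeper
for allele mining, roughly the ratio seen in practice), per-base
substitution error 0.001, negative-binomial depth (dispersion 10) and a
handful of high-copy repeat tags (copy number uniform in [20, 100]) that
exercise the 500× ceiling.

Meioses follow the Haldane model: crossovers between adjacent loci are
independent with probability r = (1 − e^(−2d/100))/2, no interference —
consistent with the map function used for distances. DH lines are
mosaics of the two parental haplotypes with no heterozygosity anywhere.
Phenotypes are sums of ±a over planted additive QTL plus an optional
unlinked polygenic deviation; residual noise is scaled to a target
broad-sense heritability, or set directly as a per-replicate SD.

What the simulator does *not* emulate: indels (tags are fixed-length, so
errors are substitutions only), quality-score structure (constant Phred
qualities), PCR duplicates, restriction-site polymorphism causing allele
dropout, segregation distortion, and crossover interference. Passing
tests therefore demonstrate correctness of the algorithms under the
stated statistical model, not robustness to every artefact of real
libraries; in particular real data would show dominant-style markers from
cut-site polymorphism and genuine distortion, both of which the pipeline
handles (classification, distortion profile) but the default simulation
does not generate.

## Numerical choices and problem sizes

* Two-point LOD at k = 0 uses the exact limit n·log10 2; r̂ ≥ 0.5 gives
  LOD 0, never negative.
* Rank-deficient designs (uninformative expectations, collinear
  cofactors) are handled by rank-revealing QR: dependent columns are
  dropped, and a position with no usable QTL term scores LOD 0.
* RSS ratios are floored at 1e−12 of scale, so a perfect fit (zero
  residual) yields a large finite LOD and a constant trait yields 0.
* 2-opt ties are broken by candidate index, and greedy chains by
  (distance, index), so ordering is deterministic given input order.
* Statistical calibration checks use a 2–5 cM permutation walk (the
  reduced grid changes the genome-wide maximum only marginally at 5-cM
  marker spacing) and 40–100 null replicates; recovery checks use 20–50
  independent seeds. These sizes give binomial 3-SD bands that the tests
  state explicitly.

## Known limitations

* Ordering is heuristic (SARF + 2-opt); it matches the identifiable truth
  on the simulated designs but is not an exhaustive ML order.
* The conflict rule discards all evidence at loci with opposing reads; at
  very high depth a 20:1 read ratio is almost certainly the majority
  allele, and the strict rule codes it missing.
* Map length estimates inherit the upward noise of summing ~20 adjacent
  Haldane terms at n ≈ 93 (SD ≈ 10 cM per ~95-cM group); single-group
  lengths are accurate to roughly ±20%, not better, at this sample size.
* CIM with re-selected permutations controls the genome-wise error rate
  under the global null; it is not a per-QTL confidence statement in the
  presence of other true QTL.
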