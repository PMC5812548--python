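# Methods

## The problem

Clustering 16S rRNA amplicon reads into OTUs at a fixed similarity
threshold (conventionally 97%, i.e. a 0.03 distance cut-off) implicitly
assumes every taxon's gene evolves at the same rate over every amplified
subregion. It does not: the nine hypervariable regions diverge at very
different rates across taxonomic families, so for a family whose species
are unusually conserved over the amplified window, a 3% cut-off merges
distinct species into one OTU, and diversity estimates become
amplicon-dependent. This package trains a per-taxon cut-off from a
type-strain reference alignment for any amplicon, then clusters reads
taxon by taxon at those trained cut-offs.

## Model and procedure

**Conservation score.** For a family alignment, each column `l` gets a bit
score `2 + Σ_b q_l^b log2 q_l^b` where `q_l^b` is the frequency of base
`b ∈ {A,C,G,T}` among the column's non-gap residues — equivalently
`2 − H_l`, two minus the column's Shannon entropy in bits. 2 means fully
conserved, 0 maximally variable. The score is per column; the
alignment-wide mean is exposed separately (`mean_bit_score`) as a summary
statistic. Ambiguity codes are excluded from the counts; an all-gap
column carries NaN ("not covered") rather than a score. The bit-score
complement (`2 − score`) and a moving average (default 30-column window,
truncated at the edges so the output keeps its length) are provided for
profiling; truncated-window averaging commutes with complementation,
which the suite checks.

**One-gap distance.** Pairwise distances on aligned sequences treat an
indel event of any length as one difference: a maximal run of columns in
which the *same* sequence is gapped while the other has bases counts as
one difference over one compared position. Columns gapped in both
sequences are skipped and do not interrupt a run (so a run resumes across
them); a run switching from one sequence to the other counts as two
events, since these are two indels. Base/base columns count one position
each, a difference when the bases differ; `N` is compared like a base.
The distance is differences over compared positions; zero comparable
positions is an error. `count_ends=False` restricts the comparison to the
overlap of the two sequences (terminal gap runs ignored), mirroring the
usual treatment of partial reads; the default counts them, matching the
cited tool's default. Gap-free inputs reduce exactly to the normalised
Hamming distance and take a vectorised fast path.

**Average-neighbor clustering.** Agglomerative average linkage on the
distance matrix: repeatedly merge the pair of clusters with the smallest
mean inter-cluster distance (arithmetic mean over all cross pairs,
maintained exactly via the size-weighted Lance–Williams update) while
that mean is ≤ the cut-off. Ties on the minimal mean are broken toward
the pair whose smallest member id sorts first, which makes the partition
independent of input order; the suite verifies equivalence against an
exhaustive implementation that recomputes every cluster-pair mean from
the raw matrix at each step. Distances are used at full precision; the
partition is reported at a single requested cut-off.

**Training the lookup table.** Per taxon at the chosen rank (family by
default, because it balances classification stability against
resolution): extract the amplicon's columns, compute all pairwise
one-gap distances among the taxon's type-strain sequences, sort them, and
take the 2.5th percentile as the taxon's cut-off — treating the lowest
2.5% of distances as outliers (within-species strain or paralogue
variation) without falling back to the minimum, which oversplits. The
percentile uses the nearest-rank rule (1-based index `ceil(p/100 · n)`,
floored at 1), which is deterministic and degrades gracefully for tiny
families — for fewer than 40 pairs it returns the first order statistic;
a linear-interpolation mode sits behind the `interpolate` flag. The raw
percentile is then clamped into [1%, 3%]: conserved taxa never demand
more than 99% similarity (guarding against sequencing-error inflation)
and divergent taxa never relax past the conventional 97%. Clamping is
applied to every trained row, including sparse ones. Taxa with fewer
than two usable sequences on the amplicon are omitted with a warning and
fall back to the default cut-off at execution time.

**Execution.** Each read is binned by its taxonomy label at the trained
rank, accepted when the label is non-empty and its bootstrap confidence
(when present) reaches the threshold (default 80). Each bin is clustered
by average linkage at its taxon's cut-off; reads that are unclassified,
below confidence, or belong to a taxon absent from the table are pooled
into one bucket clustered at the default cut-off (0.03) — they are never
discarded, and per-taxon OTU ids keep the partitions globally unique.
Novel families therefore degrade to exactly the conventional pipeline.

**Evaluation.** With one reference sequence per species a perfect
clustering returns one OTU per species, so overmerging is
`100·(S − O)/S` (and `pct_expected = 100·O/S` its complement).
Oversplitting counts, per species, every OTU beyond the first containing
that species' reads, expressed as a percentage of all OTUs. Improvement
is `100·(O_dynamic − O_default)/S_correct`. The rare-OTU filter removes
OTUs holding strictly fewer reads than `min_fraction · depth` (0.1% of a
25 000-read sample ⇒ fewer than 25 reads). Cross-amplicon concordance
emits all pairwise OTU-count combinations per sample plus the per-sample
standard deviation across amplicons (ddof = 1).

## Amplicon coordinates

Region-range amplicons span from the first region's start to the last
region's end, *including* the intervening conserved stretches, because a
real PCR product is contiguous. All coordinates are 1-based inclusive
alignment columns; the bundled V1..V9 table (E. coli numbering
convention) indexes the unaligned E. coli gene and is a convenience
default only — users aligning against their own reference must supply a
region map in that alignment's coordinates. Sliding windows of length L
and step s over a span produce `floor((span − L)/s) + 1` windows, all
ending inside the span.

## Synthetic data

The generator emulates a type-strain reference and a read set with
controlled divergence. Families evolve on a star phylogeny: a uniform
random ancestor, each species an independent mutant with per-region
substitution probability r per site (uniform replacement among the other
three bases). The star model is chosen over a birth–death tree because it
gives the closed form `E[d] = 2r(1−r) + (2/3)r²` for the expected
pairwise distance (verified by Monte Carlo in the suite), which the
tests invert (`rate_for_distance`) to place families at target
divergences. Reads are a species' amplicon with i.i.d. base errors
(default 0.001 per site, a realistic post-quality-filtering substitution
load; gap columns untouched), carrying their true family at confidence
100. Defaults: 10 families × 6 species on a width-1500 alignment,
between-species divergence 0.04 per site where not specified, 20 reads
per species. What the simulator does *not* emulate — indels and
alignment error, chimeras, quality-correlated errors, multiple 16S
copies per genome, non-star phylogenies, taxonomy misclassification —
bounds what green tests show: they validate the machinery and its
contracts on idealised communities, not performance on real amplicon
data.

## Numerical and design choices

- Merging uses `mean ≤ cutoff`; a cut-off equal to the largest pending
  mean therefore still merges. Because the nearest-rank percentile of a
  small family equals its minimum distance, a family's trained cut-off
  can coincide with a realized inter-species distance; real reads carry
  sequencing error that lifts the read-level means strictly above the
  reference distance, so contrast experiments simulate reads at error
  rate 0.001 rather than 0.
- Representative choice when curating a reference (collapsing
  within-cut-off groups) is the lexicographically smallest seq_id per
  cluster: deterministic and database-order independent.
- "Pending classification" families are recognised by a configurable
  case-insensitive substring list (default: "unclassified",
  "incertae sedis", "uncultured"); no canonical enumeration exists.
- U→T and case folding happen at load time; '-' and '.' are both gaps.
- Family subsampling draws uniformly without replacement from the
  family's sorted ids with a caller-supplied seed.
- Problem sizes in the tests and the acceptance script (families of
  4–12 species, widths 1000–2000, ≤ 500 reads) are chosen so every
  closed-form or oracle check runs at desk scale while keeping the
  statistical margins (≥ 3 standard errors) that make the stochastic
  assertions seed-robust.

## Known limitations

- Trained cut-offs assume one 16S copy per species (type strains);
  intragenomic paralogue variation is not modelled and is a documented
  source of oversplitting in practice.
- The entropy-based bit score is unweighted (no sequence weighting, no
  gap penalties), which can differ from covariance-model profile scores
  produced by upstream aligners.
- Reference-scale results quoted for the curated public databases
  (e.g. the 46.4% full-length overmerging arithmetic) are reproduced as
  arithmetic on the published species/OTU counts; recomputing them from
  raw databases requires those databases and their exact upstream
  alignment, which is out of scope here.
- The fallback for unclassified reads pools them into a single bucket at
  the default cut-off; in habitats where most reads are unclassified the
  method converges to the conventional pipeline by construction.
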