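# dynotu

Taxon-dependent dynamic cut-offs for OTU clustering of 16S rRNA amplicon
reads.

## Why

Grouping amplicon reads into operational taxonomic units (OTUs) at a
fixed 97% similarity threshold assumes all 16S rRNA variable regions
evolve at the same rate in every lineage. They do not: over a given
amplicon, species of a conserved family can sit well within 3% of each
other and collapse into one OTU, biasing diversity estimates and making
results incomparable between primer sets. `dynotu` is for microbial
ecologists who want OTUs that track species boundaries more closely:
it **trains** a per-family clustering cut-off for any amplicon from a
type-strain reference alignment, and **executes** taxonomy-aware
clustering with those cut-offs.

## Method in brief

For each taxon T (family by default) with sequences in the reference,
and an amplicon A:

1. extract A's columns from T's aligned type-strain sequences;
2. compute all pairwise one-gap distances `d_ij` (an indel run counts as
   a single difference);
3. sort them and take the nearest-rank 2.5th percentile as the raw
   cut-off `c_T = Q_2.5({d_ij})` (the lowest distances are treated as
   strain-level outliers);
4. clamp: `c_T ← min(max(c_T, 0.01), 0.03)`.

Reads are then binned by their taxonomy label at the trained rank
(bootstrap confidence ≥ 80 required when present) and each bin is
clustered by average-neighbor (average-linkage) agglomerative clustering
at `c_T`; unclassified reads and novel families use the default cut-off
(0.03). Evaluation metrics include overmerging `100·(S − O)/S`,
oversplitting (surplus OTUs per species over all OTUs), and improvement
`100·(O_dynamic − O_default)/S`.

## Worked example

Simulate a small community in which one family is evolutionarily
conserved (inter-species distance ≈ 0.02) and four are divergent
(≈ 0.08), train a lookup table, and compare dynamic against fixed-cut-off
clustering:

```python
from dynotu import (AmpliconSpec, assign_taxa, average_neighbor_cluster,
                    dynamic_cluster, overmerging_pct, pairwise_distances,
                    train_lookup)
from dynotu.simulate import (SimulationConfig, rate_for_distance,
                             simulate_reads, simulate_reference)

rates = {"Family01": rate_for_distance(0.02)}
rates |= {f"Family{i:02d}": rate_for_distance(0.08) for i in range(2, 6)}
cfg = SimulationConfig(n_families=5, species_per_family=6,
                       alignment_width=2000,
                       per_family_region_rates=rates, seed=7)
db, _ = simulate_reference(cfg)

spec = AmpliconSpec.full_length()
table = train_lookup(db, spec)
print({t: round(r.cutoff, 3) for t, r in table.rows.items()})

sim = simulate_reads(db, spec, reads_per_species=15, error_rate=0.001,
                     seed=8)
assignment = assign_taxa(sim.taxonomy,
                         read_ids=[r.seq_id for r in sim.reads])
dynamic = dynamic_cluster(sim.reads, assignment, table)
fixed = average_neighbor_cluster(pairwise_distances(sim.reads), 0.03)
print("fixed 3%:", fixed.n_otus, "OTUs,",
      f"{overmerging_pct(len(db), fixed.n_otus):.1f}% overmerged")
print("dynamic: ", dynamic.n_otus, "OTUs,",
      f"{overmerging_pct(len(db), dynamic.n_otus):.1f}% overmerged")
```

Output:

```
{'Family01': 0.013, 'Family02': 0.03, 'Family03': 0.03, 'Family04': 0.03, 'Family05': 0.03}
fixed 3%: 25 OTUs, 16.7% overmerged
dynamic:  30 OTUs, 0.0% overmerged
```

The conserved family earned a stricter cut-off (0.013 instead of 0.03),
so its six species stay separate under dynamic clustering — with the
fixed 97% rule they collapse into one OTU and a sixth of the community's
species diversity disappears.

The same workflow is available from the shell:

```sh
dynotu train --ref ref.align.fasta --tax ref.tax --window 201:700 \
             --level family --out lookup.tsv
dynotu cluster --reads reads.align.fasta --read-tax reads.tax \
               --lookup lookup.tsv --out otus.list
dynotu simulate --config sim.yaml --out-dir fixtures/
```

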