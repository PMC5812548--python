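"""Training and execution of taxon-dependent OTU clustering cut-offs.

Training: for every taxon (family by default) in a reference database,
extract the amplicon, compute all pairwise one-gap distances, take a low
percentile (2.5 by default, nearest-rank) of the ordered distances as
the taxon's cut-off, and clamp it into [1%, 3%].  Divergent taxa thus
keep the conventional 3% ceiling while conserved taxa earn a more
stringent threshold.

Execution: reads are grouped by their assigned taxon and each group is
clustered by average linkage at that taxon's trained cut-off; reads whose
taxon is unknown, insufficiently confident, or absent from the lookup
table fall back to the default cut-off (3%, i.e. the usual 97% rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .amplicons import AmpliconSpec, RegionMap, extract_amplicon
from .cluster import OTUPartition, _merge_clusters
from .distance import pairwise_distances
from .reference import AlignedSequence, ReferenceDB, read_taxonomy

UNCLASSIFIED = "unclassified"


@dataclass
class LookupRow:
    taxon: str
    n_species: int
    n_pairs: int
    raw_percentile_distance: float
    cutoff: float


@dataclass
class LookupTable:
    """Per-taxon clustering cut-offs trained for one amplicon."""

    level: str
    amplicon: AmpliconSpec
    default_cutoff: float
    clamp: tuple[float, float]
    percentile: float
    rows: dict[str, LookupRow] = field(default_factory=dict)
    amplicon_width: int | None = None

    def cutoff_for(self, taxon: str) -> float:
        row = self.rows.get(taxon)
        return row.cutoff if row is not None else self.default_cutoff

    def mean_cutoff(self) -> float:
        return float(np.mean([r.cutoff for r in self.rows.values()]))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#level\t{self.level}\n")
            fh.write(f"#amplicon\t{self.amplicon.label}\n")
            fh.write(f"#default_cutoff\t{self.default_cutoff:g}\n")
            fh.write(f"#clamp\t{self.clamp[0]:g}:{self.clamp[1]:g}\n")
            fh.write(f"#percentile\t{self.percentile:g}\n")
            if self.amplicon_width is not None:
                fh.write(f"#amplicon_width\t{self.amplicon_width}\n")
            fh.write("taxon\tn_species\tn_pairs\traw_p2.5\tcutoff\n")
            for row in self.rows.values():
                fh.write(f"{row.taxon}\t{row.n_species}\t{row.n_pairs}\t"
                         f"{row.raw_percentile_distance:.6f}\t"
                         f"{row.cutoff:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LookupTable":
        meta: dict[str, str] = {}
        rows: dict[str, LookupRow] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition("\t")
                    meta[key] = value
                    continue
                if line.startswith("taxon\t"):
                    continue
                taxon, n_sp, n_pairs, raw, cut = line.split("\t")
                rows[taxon] = LookupRow(taxon, int(n_sp), int(n_pairs),
                                        float(raw), float(cut))
        lo, _, hi = meta.get("clamp", "0.01:0.03").partition(":")
        table = cls(
            level=meta.get("level", "family"),
            amplicon=AmpliconSpec.parse(meta.get("amplicon", "full-length")),
            default_cutoff=float(meta.get("default_cutoff", 0.03)),
            clamp=(float(lo), float(hi)),
            percentile=float(meta.get("percentile", 2.5)),
            rows=rows,
        )
        if "amplicon_width" in meta:
            table.amplicon_width = int(meta["amplicon_width"])
        return table


def nearest_rank(sorted_values: Sequence[float], percentile: float) -> float:
    """Nearest-rank percentile: 1-based index ceil(p/100 * n) into the
    ascending sorted values (clamped to at least 1)."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty value list")
    k = max(1, math.ceil(percentile / 100.0 * n))
    return float(sorted_values[min(k, n) - 1])


def train_lookup(db: ReferenceDB,
                 spec: AmpliconSpec,
                 percentile: float = 2.5,
                 clamp: tuple[float, float] = (0.01, 0.03),
                 level: str = "family",
                 default_cutoff: float = 0.03,
                 region_map: RegionMap | None = None,
                 interpolate: bool = False,
                 count_ends: bool = True) -> LookupTable:
    """Train the per-taxon cut-off lookup table for one amplicon."""
    if len(db) == 0:
        raise ValueError("empty reference database")
    lo, hi = clamp
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"bad clamp interval {clamp}")
    view = extract_amplicon(db, spec, region_map=region_map)
    table = LookupTable(level=level, amplicon=spec,
                        default_cutoff=default_cutoff, clamp=(lo, hi),
                        percentile=percentile,
                        amplicon_width=view.alignment_width)
    for taxon, seqs in view.group_by_rank(level).items():
        if len(seqs) < 2:
            warnings.warn(
                f"taxon {taxon!r}: fewer than two usable sequences on "
                f"amplicon {spec.label}; omitted from lookup table")
            continue
        dm = pairwise_distances(seqs, count_ends=count_ends)
        values = np.sort(dm.condensed_form())
        if interpolate:
            raw = float(np.percentile(values, percentile))
        else:
            raw = nearest_rank(values, percentile)
        table.rows[taxon] = LookupRow(
            taxon=taxon,
            n_species=len(seqs),
            n_pairs=len(values),
            raw_percentile_distance=raw,
            cutoff=min(max(raw, lo), hi),
        )
    return table


@dataclass
class TaxonAssignment:
    """Reads grouped by taxon, plus the unclassified bucket."""

    by_taxon: dict[str, list[str]]
    unclassified: list[str]
    unclassified_fraction: float


def assign_taxa(taxonomy: str | Path | Mapping,
                level: str = "family",
                confidence_threshold: float = 80.0,
                read_ids: Iterable[str] | None = None) -> TaxonAssignment:
    """Group reads by their taxonomy label at ``level``.

    A read joins a taxon iff its label at the level is non-empty and, when
    bootstrap confidences are present, the label's confidence reaches the
    threshold; otherwise it lands in the unclassified bucket.  Reads listed
    in ``read_ids`` but absent from the taxonomy are unclassified (with a
    warning).
    """
    if not isinstance(taxonomy, Mapping):
        taxonomy = read_taxonomy(taxonomy)
    from .reference import RANKS
    idx = RANKS.index(level.lower())
    by_taxon: dict[str, list[str]] = {}
    unclassified: list[str] = []
    ids = list(read_ids) if read_ids is not None else list(taxonomy)
    missing = [r for r in ids if r not in taxonomy]
    if missing:
        warnings.warn(
            f"{len(missing)} read(s) missing from taxonomy treated as "
            f"unclassified (e.g. {missing[0]!r})")
    for read in ids:
        if read not in taxonomy:
            unclassified.append(read)
            continue
        labels, confs = taxonomy[read]
        label = labels[idx] if idx < len(labels) else ""
        conf_ok = True
        if confs is not None and idx < len(confs):
            conf = confs[idx]
            conf_ok = conf == conf and conf >= confidence_threshold
        if label and conf_ok:
            by_taxon.setdefault(label, []).append(read)
        else:
            unclassified.append(read)
    frac = len(unclassified) / len(ids) if ids else 0.0
    return TaxonAssignment(by_taxon={k: by_taxon[k] for k in sorted(by_taxon)},
                           unclassified=unclassified,
                           unclassified_fraction=frac)


def dynamic_cluster(reads: Sequence[AlignedSequence],
                    assignment: TaxonAssignment,
                    lookup: LookupTable,
                    count_ends: bool = True) -> OTUPartition:
    """Cluster reads per taxon at that taxon's trained cut-off.

    Taxa absent from the lookup table and the unclassified bucket are
    clustered at the table's default cut-off.  OTU ids are globally
    unique, prefixed by taxon.
    """
    by_id = {r.seq_id: r for r in reads}
    widths = {len(r) for r in reads}
    if len(widths) > 1:
        raise ValueError(f"reads have differing widths: {sorted(widths)}")
    if widths and lookup.amplicon_width is not None:
        w = widths.pop()
        if w != lookup.amplicon_width:
            raise ValueError(
                f"read width {w} does not match the lookup table's "
                f"amplicon width {lookup.amplicon_width}")
    assigned = set()
    groups: list[tuple[str, list[str], float]] = []
    for taxon, ids in assignment.by_taxon.items():
        present = [i for i in ids if i in by_id]
        assigned.update(present)
        if present:
            groups.append((taxon, present, lookup.cutoff_for(taxon)))
    leftover = [i for i in assignment.unclassified if i in by_id]
    stray = sorted(set(by_id) - assigned - set(leftover))
    if stray:
        warnings.warn(
            f"{len(stray)} read(s) not covered by the assignment treated "
            f"as unclassified (e.g. {stray[0]!r})")
        leftover = sorted(set(leftover) | set(stray))
    assigned.update(leftover)
    if leftover:
        groups.append((UNCLASSIFIED, leftover, lookup.default_cutoff))
    otus: dict[str, tuple[str, ...]] = {}
    for taxon, ids, cutoff in groups:
        seqs = [by_id[i] for i in sorted(ids)]
        if len(seqs) == 1:
            clusters = [[seqs[0].seq_id]]
        else:
            dm = pairwise_distances(seqs, count_ends=count_ends)
            clusters = _merge_clusters(list(dm.ids), dm.data, cutoff)
        clusters.sort(key=lambda c: c[0])
        for k, members in enumerate(clusters):
            otus[f"{taxon}_OTU{k + 1:04d}"] = tuple(members)
    return OTUPartition(cutoff="dynamic", otus=otus)


def filter_rare_otus(partition: OTUPartition,
                     read_counts: Mapping[str, int] | None = None,
                     min_fraction: float = 0.001,
                     depth: int | None = None) -> OTUPartition:
    """Remove OTUs holding strictly fewer reads than ``min_fraction * depth``
    (the rare-OTU rule: e.g. <0.1% of a 25 000-read sample drops OTUs with
    fewer than 25 reads)."""
    if depth is None or depth <= 0:
        raise ValueError("depth must be a positive integer")
    threshold = min_fraction * depth
    kept = {}
    for otu, members in partition.otus.items():
        total = sum((read_counts or {}).get(m, 1) for m in members)
        if total >= threshold:
            kept[otu] = members
    return OTUPartition(cutoff=partition.cutoff, otus=kept)


class DynamicOTUClusterer(BaseEstimator):
    """Taxonomy-aware OTU clustering with trained per-taxon cut-offs.

    ``fit`` trains the lookup table from a reference database for one
    amplicon; ``predict`` clusters aligned reads (with their per-read
    taxonomy) and returns one OTU label per read.

    Parameters
    ----------
    percentile : float, default 2.5
        Lower percentile of a taxon's ordered pairwise distances used as
        its cut-off (nearest-rank unless ``interpolate``).
    clamp : (float, float), default (0.01, 0.03)
        Trained cut-offs are clamped into this interval.
    default_cutoff : float, default 0.03
        Cut-off for unclassified reads and taxa absent from the table.
    level : str, default "family"
        Taxonomic rank at which cut-offs are trained and reads grouped.
    confidence_threshold : float, default 80.0
        Minimal bootstrap confidence for a read's label to count.
    interpolate : bool, default False
        Use linearly interpolated percentiles instead of nearest-rank.
    """

    def __init__(self, percentile: float = 2.5,
                 clamp: tuple[float, float] = (0.01, 0.03),
                 default_cutoff: float = 0.03,
                 level: str = "family",
                 confidence_threshold: float = 80.0,
                 interpolate: bool = False):
        self.percentile = percentile
        self.clamp = clamp
        self.default_cutoff = default_cutoff
        self.level = level
        self.confidence_threshold = confidence_threshold
        self.interpolate = interpolate

    def fit(self, X: ReferenceDB, y=None, *,
            amplicon: AmpliconSpec | None = None,
            region_map: RegionMap | None = None):
        if amplicon is None:
            amplicon = AmpliconSpec.full_length()
        self.lookup_ = train_lookup(
            X, amplicon, percentile=self.percentile, clamp=self.clamp,
            level=self.level, default_cutoff=self.default_cutoff,
            region_map=region_map, interpolate=self.interpolate)
        return self

    def partition(self, reads: Sequence[AlignedSequence],
                  taxonomy: str | Path | Mapping) -> OTUPartition:
        """Cluster reads into an :class:`OTUPartition`."""
        if not hasattr(self, "lookup_"):
            raise RuntimeError("fit must be called before partition/predict")
        assignment = assign_taxa(
            taxonomy, level=self.level,
            confidence_threshold=self.confidence_threshold,
            read_ids=[r.seq_id for r in reads])
        return dynamic_cluster(reads, assignment, self.lookup_)

    def predict(self, reads: Sequence[AlignedSequence],
                taxonomy: str | Path | Mapping) -> np.ndarray:
        part = self.partition(reads, taxonomy)
        lookup = {m: otu for otu, members in part.otus.items()
                  for m in members}
        return np.array([lookup[r.seq_id] for r in reads])
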