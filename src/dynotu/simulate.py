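"""Synthetic reference databases and read sets with controlled divergence.

Families are simulated on a star phylogeny: a random ancestor is drawn
and every species is an independent mutant of it, with a per-region
substitution probability per site (uniform replacement over the other
three bases).  For two independent mutants at per-site rate r the
expected pairwise distance has the closed form

    E[d] = 2 r (1 - r) + (2/3) r**2

which the generator's tests verify by Monte Carlo.  Reads are a species'
amplicon with i.i.d. base errors; the star model keeps these expectations
exact and makes every downstream module testable without downloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .amplicons import AmpliconSpec, RegionMap, extract_amplicon
from .reference import (RANKS, AlignedSequence, ReferenceDB, write_fasta,
                        write_taxonomy)

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

Taxonomy = dict[str, tuple[tuple[str, ...], tuple[float, ...] | None]]


def expected_pairwise_distance(rate: float) -> float:
    """Expected per-site distance between two independent mutants of one
    ancestor at substitution probability ``rate``."""
    return 2.0 * rate * (1.0 - rate) + (2.0 / 3.0) * rate ** 2


def rate_for_distance(distance: float) -> float:
    """Invert :func:`expected_pairwise_distance` (smaller root)."""
    if not 0.0 <= distance < 0.75:
        raise ValueError("achievable expected distances lie in [0, 0.75)")
    # (4/3) r^2 - 2 r + d = 0
    return (2.0 - math.sqrt(4.0 - 16.0 * distance / 3.0)) / (8.0 / 3.0)


@dataclass
class SimulationConfig:
    """Conditions for one simulated reference database.

    ``per_family_region_rates`` maps family name -> (region -> rate) or a
    single float for a uniform rate over the whole gene.  Families not
    listed get ``default_rate``.
    """

    n_families: int = 10
    species_per_family: int | tuple[int, int] = 6
    alignment_width: int = 1500
    region_map: RegionMap | None = None
    per_family_region_rates: dict[str, dict[str, float] | float] = field(
        default_factory=dict)
    default_rate: float = 0.04
    conserved_rate_factor: float = 0.1
    read_error_rate: float = 0.001
    reads_per_species: int = 20
    seed: int = 0

    def family_names(self) -> list[str]:
        return [f"Family{i + 1:02d}" for i in range(self.n_families)]


def _lineage(family: str) -> tuple[str, ...]:
    return ("Bacteria", "SimPhylum", "SimClass", "SimOrder", family,
            f"{family}_genus")


def _rate_vector(width: int,
                 region_rates: Mapping[str, float] | float,
                 region_map: RegionMap | None,
                 conserved_rate: float = 0.0) -> np.ndarray:
    """Per-column substitution probability."""
    if isinstance(region_rates, (int, float)):
        return np.full(width, float(region_rates))
    rates = np.full(width, conserved_rate)
    if region_map is None:
        raise ValueError("region_map required for per-region rates")
    for name, rate in region_rates.items():
        start, end = region_map.span(name)
        if end > width:
            raise ValueError(f"region {name} exceeds alignment width {width}")
        rates[start - 1:end] = rate
    return rates


def _mutate(template: np.ndarray, rates: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute each position with its rate; uniform over the other 3."""
    out = template.copy()
    hit = np.flatnonzero(rng.random(template.size) < rates)
    if hit.size:
        idx = np.searchsorted(_ALPHABET, template[hit])
        offset = rng.integers(1, 4, size=hit.size)
        out[hit] = _ALPHABET[(idx + offset) % 4]
    return out


def simulate_family(ancestor_length: int,
                    n_species: int,
                    region_rates: Mapping[str, float] | float,
                    region_map: RegionMap | None = None,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None,
                    family_name: str = "Family01",
                    conserved_rate: float = 0.0,
                    ) -> tuple[list[AlignedSequence], Taxonomy]:
    """One family alignment on a star phylogeny, plus taxonomy lines."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = _rate_vector(ancestor_length, region_rates, region_map,
                         conserved_rate)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("substitution rates must lie in [0, 1]")
    ancestor = rng.choice(_ALPHABET, size=ancestor_length)
    seqs: list[AlignedSequence] = []
    taxonomy: Taxonomy = {}
    lineage = _lineage(family_name)
    for s in range(n_species):
        cols = _mutate(ancestor, rates, rng).tobytes().decode("ascii")
        seq_id = f"{family_name}_sp{s + 1:03d}"
        seqs.append(AlignedSequence(seq_id, cols, lineage, seq_id))
        taxonomy[seq_id] = (lineage, None)
    return seqs, taxonomy


def simulate_reference(config: SimulationConfig
                       ) -> tuple[ReferenceDB, Taxonomy]:
    """A full reference database under the given conditions."""
    rng = np.random.default_rng(config.seed)
    all_seqs: list[AlignedSequence] = []
    taxonomy: Taxonomy = {}
    for family in config.family_names():
        if isinstance(config.species_per_family, tuple):
            lo, hi = config.species_per_family
            n_species = int(rng.integers(lo, hi + 1))
        else:
            n_species = config.species_per_family
        rates = config.per_family_region_rates.get(family,
                                                   config.default_rate)
        conserved = (config.default_rate * config.conserved_rate_factor
                     if not isinstance(rates, (int, float)) else 0.0)
        seqs, tax = simulate_family(
            config.alignment_width, n_species, rates,
            region_map=config.region_map, rng=rng, family_name=family,
            conserved_rate=conserved)
        all_seqs.extend(seqs)
        taxonomy.update(tax)
    return ReferenceDB(all_seqs), taxonomy


@dataclass
class SimulatedReads:
    reads: list[AlignedSequence]
    truth: dict[str, str]          # read_id -> species (reference seq_id)
    taxonomy: Taxonomy             # read_id -> (lineage, confidences)


def simulate_reads(db: ReferenceDB,
                   spec: AmpliconSpec,
                   reads_per_species: int = 20,
                   error_rate: float = 0.0,
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   region_map: RegionMap | None = None) -> SimulatedReads:
    """Aligned reads: each species' amplicon with i.i.d. base errors at
    ``error_rate`` (gap columns untouched), true family at confidence 100."""
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    view = extract_amplicon(db, spec, region_map=region_map)
    reads: list[AlignedSequence] = []
    truth: dict[str, str] = {}
    taxonomy: Taxonomy = {}
    for ref in view:
        template = np.frombuffer(ref.columns.encode("ascii"), dtype=np.uint8)
        nongap = np.isin(template, _ALPHABET)
        rates = np.where(nongap, error_rate, 0.0)
        for j in range(reads_per_species):
            cols = _mutate(template, rates, rng).tobytes().decode("ascii")
            read_id = f"{ref.seq_id}_r{j + 1:04d}"
            reads.append(AlignedSequence(read_id, cols, ref.lineage,
                                         ref.species_name))
            truth[read_id] = ref.seq_id
            taxonomy[read_id] = (ref.lineage, (100.0,) * len(ref.lineage))
    return SimulatedReads(reads=reads, truth=truth, taxonomy=taxonomy)


def write_truth(truth: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tspecies\n")
        for read_id in truth:
            fh.write(f"{read_id}\t{truth[read_id]}\n")


def write_simulation(db: ReferenceDB, taxonomy: Taxonomy,
                     sim_reads: SimulatedReads, out_dir: str | Path) -> None:
    """Write aligned FASTA + taxonomy for references and reads, and the
    read truth table, into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(db, out / "reference.align.fasta")
    write_taxonomy(taxonomy, out / "reference.tax")
    write_fasta(sim_reads.reads, out / "reads.align.fasta")
    write_taxonomy(sim_reads.taxonomy, out / "reads.tax")
    write_truth(sim_reads.truth, out / "reads.truth.tsv")
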