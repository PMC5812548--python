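"""Reference alignment + taxonomy handling.

A reference database holds one gapped 16S rRNA sequence per species (the
type strain), indexed by taxonomic family.  All sequences share one global
alignment coordinate system, so a column index means the same position in
every record.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

#: Taxonomic ranks carried by a lineage, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

GAP_CHARS = frozenset("-.")

#: Substrings (case-insensitive) marking a family label as "pending
#: classification".  The reference databases in this field use several
#: spellings; the list is configurable because no canonical enumeration
#: exists.
DEFAULT_PENDING_PATTERNS = ("unclassified", "incertae sedis", "uncultured")

_CONF_RE = re.compile(r"^(?P<label>.*?)\((?P<conf>\d+(?:\.\d+)?)\)$")


@dataclass(frozen=True)
class AlignedSequence:
    """One gapped sequence in a global alignment, with its lineage."""

    seq_id: str
    columns: str
    lineage: tuple[str, ...] = ()
    species_name: str = ""

    def __len__(self) -> int:
        return len(self.columns)

    def rank(self, level: str) -> str:
        """Lineage label at ``level`` (one of :data:`RANKS`), or ''."""
        idx = RANKS.index(level.lower())
        return self.lineage[idx] if idx < len(self.lineage) else ""

    @property
    def family(self) -> str:
        return self.rank("family")

    def is_all_gap(self) -> bool:
        return all(c in GAP_CHARS for c in self.columns)


class ReferenceDB:
    """Family-indexed collection of :class:`AlignedSequence`.

    Invariants: every member has the same column count
    (:attr:`alignment_width`), seq_ids are unique, and the family index
    covers exactly the sequences present.
    """

    def __init__(self, sequences: Sequence[AlignedSequence]):
        sequences = sorted(sequences, key=lambda s: s.seq_id)
        widths = {len(s) for s in sequences}
        if len(widths) > 1:
            offending = sorted({(s.seq_id, len(s)) for s in sequences},
                               key=lambda t: t[1])
            raise ValueError(
                "ragged alignment: sequence widths differ "
                f"(e.g. {offending[0][0]!r} has width {offending[0][1]}, "
                f"{offending[-1][0]!r} has width {offending[-1][1]})"
            )
        ids = [s.seq_id for s in sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seq_ids: {dupes}")
        self.sequences: list[AlignedSequence] = list(sequences)
        self.alignment_width: int = widths.pop() if widths else 0
        self._by_id = {s.seq_id: s for s in self.sequences}
        index: dict[str, list[str]] = {}
        for s in self.sequences:
            index.setdefault(s.family, []).append(s.seq_id)
        self.family_index: dict[str, tuple[str, ...]] = {
            fam: tuple(index[fam]) for fam in sorted(index)
        }

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def get(self, seq_id: str) -> AlignedSequence:
        return self._by_id[seq_id]

    @property
    def families(self) -> tuple[str, ...]:
        return tuple(self.family_index)

    def family_sequences(self, family: str) -> list[AlignedSequence]:
        return [self._by_id[i] for i in self.family_index[family]]

    def group_by_rank(self, level: str = "family") -> dict[str, list[AlignedSequence]]:
        """Group members by their lineage label at ``level`` (sorted keys)."""
        groups: dict[str, list[AlignedSequence]] = {}
        for s in self.sequences:
            groups.setdefault(s.rank(level), []).append(s)
        return {k: groups[k] for k in sorted(groups)}

    def subset(self, seq_ids: Iterable[str]) -> "ReferenceDB":
        wanted = set(seq_ids)
        return ReferenceDB([s for s in self.sequences if s.seq_id in wanted])


def normalize_columns(raw: str) -> str:
    """Uppercase, U->T, keep '-' and '.' as gap characters."""
    return raw.upper().replace("U", "T")


def parse_lineage(text: str) -> tuple[tuple[str, ...], tuple[float, ...] | None]:
    """Parse a semicolon-separated lineage with optional (confidence) tags.

    Returns ``(labels, confidences)``; confidences is None when no field
    carried one.
    """
    fields = [f.strip() for f in text.strip().rstrip(";").split(";")]
    labels: list[str] = []
    confs: list[float] = []
    any_conf = False
    for f in fields:
        m = _CONF_RE.match(f)
        if m:
            labels.append(m.group("label").strip().strip('"'))
            confs.append(float(m.group("conf")))
            any_conf = True
        else:
            labels.append(f.strip('"'))
            confs.append(float("nan"))
    return tuple(labels), (tuple(confs) if any_conf else None)


def read_taxonomy(path: str | Path) -> dict[str, tuple[tuple[str, ...], tuple[float, ...] | None]]:
    """Read a mothur-dialect taxonomy file: ``id<TAB>D;P;C;O;F;G;``."""
    out: dict[str, tuple[tuple[str, ...], tuple[float, ...] | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'id<TAB>lineage', got {line!r}")
            out[parts[0]] = parse_lineage(parts[1])
    return out


def load_reference(aligned_fasta_path: str | Path,
                   taxonomy_path: str | Path) -> ReferenceDB:
    """Load an aligned FASTA plus taxonomy file into a :class:`ReferenceDB`.

    Raises if a FASTA record is absent from the taxonomy or the alignment
    is ragged.
    """
    taxonomy = read_taxonomy(taxonomy_path)
    seqs: list[AlignedSequence] = []
    for rec in SeqIO.parse(str(aligned_fasta_path), "fasta"):
        if rec.id not in taxonomy:
            raise KeyError(
                f"sequence {rec.id!r} from {aligned_fasta_path} is missing "
                f"from taxonomy file {taxonomy_path}")
        labels, _ = taxonomy[rec.id]
        seqs.append(AlignedSequence(
            seq_id=rec.id,
            columns=normalize_columns(str(rec.seq)),
            lineage=labels,
            species_name=rec.id,
        ))
    return ReferenceDB(seqs)


def _is_pending(family: str, patterns: Sequence[str]) -> bool:
    low = family.lower()
    return (not family) or any(p.lower() in low for p in patterns)


def filter_families(db: ReferenceDB,
                    min_species: int = 3,
                    drop_unclassified: bool = True,
                    pending_patterns: Sequence[str] = DEFAULT_PENDING_PATTERNS,
                    ) -> ReferenceDB:
    """Drop families with fewer than ``min_species`` members and, optionally,
    families whose name marks a pending/unclassified status."""
    keep: list[str] = []
    for fam, ids in db.family_index.items():
        if len(ids) < min_species:
            continue
        if drop_unclassified and _is_pending(fam, pending_patterns):
            continue
        keep.extend(ids)
    return db.subset(keep)


def curate_database(db: ReferenceDB,
                    cutoff: float,
                    spec=None,
                    region_map=None) -> ReferenceDB:
    """Collapse within-family groups more similar than ``cutoff`` to one
    representative each.

    Each family is clustered (average linkage, one-gap distance) on the
    given amplicon (full-length by default); the lexicographically smallest
    seq_id of each cluster is kept.  The retained sequences keep their
    original full-length columns.
    """
    from .amplicons import AmpliconSpec, extract_amplicon
    from .cluster import average_neighbor_cluster
    from .distance import pairwise_distances

    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    if spec is None:
        spec = AmpliconSpec.full_length()
    view = extract_amplicon(db, spec, region_map=region_map)
    keep: set[str] = set()
    for fam in view.families:
        seqs = view.family_sequences(fam)
        if len(seqs) == 1:
            keep.add(seqs[0].seq_id)
            continue
        dm = pairwise_distances(seqs)
        part = average_neighbor_cluster(dm, cutoff)
        for members in part.otus.values():
            keep.add(min(members))
    # Sequences invisible on this amplicon (all-gap window) cannot be
    # compared, so they are retained as their own representatives.
    keep.update(s.seq_id for s in db if s.seq_id not in view)
    return db.subset(keep)


def subsample_families(db: ReferenceDB,
                       max_species: int = 7,
                       seed: int = 0) -> ReferenceDB:
    """Randomly keep at most ``max_species`` members per family
    (uniform, without replacement; deterministic for a fixed seed)."""
    if max_species < 1:
        raise ValueError("max_species must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for fam, ids in db.family_index.items():
        ids = sorted(ids)
        if len(ids) <= max_species:
            keep.extend(ids)
        else:
            picked = rng.choice(len(ids), size=max_species, replace=False)
            keep.extend(ids[i] for i in sorted(picked))
    return db.subset(keep)


def write_fasta(seqs: Iterable[AlignedSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n{s.columns}\n")


def write_taxonomy(taxonomy: Mapping[str, tuple[tuple[str, ...], tuple[float, ...] | None]],
                   path: str | Path) -> None:
    """Write a mothur-dialect taxonomy file (confidences kept if present)."""
    with open(path, "w") as fh:
        for seq_id in taxonomy:
            labels, confs = taxonomy[seq_id]
            if confs is None:
                body = ";".join(labels)
            else:
                body = ";".join(
                    f"{lab}({conf:g})" if conf == conf else lab
                    for lab, conf in zip(labels, confs))
            fh.write(f"{seq_id}\t{body};\n")
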