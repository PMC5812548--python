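"""Variable-region coordinates and artificial amplicon extraction.

The 16S rRNA gene carries nine hypervariable regions (V1..V9) separated by
conserved stretches.  An amplicon is specified either as a contiguous
variable-region range (the extracted span runs from the start of the first
region to the end of the last, *including* the intervening conserved
columns), as an explicit coordinate window, or as the full-length gene.
All coordinates are 1-based inclusive alignment columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .reference import GAP_CHARS, AlignedSequence, ReferenceDB

logger = logging.getLogger(__name__)

REGION_NAMES = tuple(f"V{i}" for i in range(1, 10))


class RegionMap:
    """Ordered, non-overlapping mapping of region names to (start, end)."""

    def __init__(self, regions: dict[str, tuple[int, int]]):
        prev_end = 0
        for name, (start, end) in regions.items():
            if start < 1 or end < start:
                raise ValueError(f"region {name}: bad span ({start}, {end})")
            if start <= prev_end:
                raise ValueError(
                    f"region {name} overlaps or disorders the previous region")
            prev_end = end
        self.regions: dict[str, tuple[int, int]] = {
            name: (int(s), int(e)) for name, (s, e) in regions.items()}

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def span(self, name: str) -> tuple[int, int]:
        return self.regions[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionMap) and self.regions == other.regions

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegionMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({str(k): (int(v[0]), int(v[1])) for k, v in raw.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RegionMap":
        regions: dict[str, tuple[int, int]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, start, end = line.split("\t")[:3]
                regions[name] = (int(start), int(end))
        return cls(regions)


def load_default_region_map() -> RegionMap:
    """Bundled V1..V9 coordinates on the E. coli 16S rRNA gene.

    The table is a convenience default following the usual E. coli
    numbering convention; real analyses should override it with
    coordinates mapped into their own alignment.
    """
    ref = resources.files("dynotu").joinpath("data/ecoli_regions.yaml")
    with resources.as_file(ref) as path:
        return RegionMap.from_yaml(path)


@dataclass(frozen=True)
class AmpliconSpec:
    """One amplicon: a region range, a coordinate window, or full-length."""

    kind: str                                   # region-range | window | full-length
    region_range: tuple[str, str] | None = None
    window: tuple[int, int] | None = None

    @classmethod
    def full_length(cls) -> "AmpliconSpec":
        return cls(kind="full-length")

    @classmethod
    def from_region_range(cls, first: str, last: str) -> "AmpliconSpec":
        if first not in REGION_NAMES or last not in REGION_NAMES:
            raise ValueError(f"unknown region in {first}-{last}")
        if REGION_NAMES.index(first) > REGION_NAMES.index(last):
            raise ValueError(f"region range {first}-{last} is not contiguous")
        return cls(kind="region-range", region_range=(first, last))

    @classmethod
    def from_window(cls, start: int, end: int) -> "AmpliconSpec":
        if start < 1 or end < start:
            raise ValueError(f"bad window ({start}, {end})")
        return cls(kind="window", window=(int(start), int(end)))

    @classmethod
    def parse(cls, text: str) -> "AmpliconSpec":
        """Parse 'V3-V4', 'V4', '201:700' or 'full-length'."""
        text = text.strip()
        if text.lower() in ("full-length", "full", "full_length"):
            return cls.full_length()
        if ":" in text:
            start, end = text.split(":")
            return cls.from_window(int(start), int(end))
        if "-" in text:
            first, last = text.split("-")
            return cls.from_region_range(first.strip(), last.strip())
        return cls.from_region_range(text, text)

    @property
    def label(self) -> str:
        if self.kind == "full-length":
            return "full-length"
        if self.kind == "region-range":
            a, b = self.region_range
            return a if a == b else f"{a}-{b}"
        return f"{self.window[0]}:{self.window[1]}"

    def resolve(self, region_map: RegionMap | None = None,
                alignment_width: int | None = None) -> tuple[int, int]:
        """Concrete (start, end) columns, 1-based inclusive."""
        if self.kind == "full-length":
            if alignment_width is None:
                raise ValueError("alignment_width needed for full-length spec")
            return (1, alignment_width)
        if self.kind == "window":
            return self.window
        if region_map is None:
            raise ValueError("region_map needed to resolve a region range")
        first, last = self.region_range
        return (region_map.span(first)[0], region_map.span(last)[1])


def region_combinations(region_map: RegionMap, k: int) -> list[AmpliconSpec]:
    """All contiguous combinations of ``k`` adjacent variable regions.

    For nine regions there are ``10 - k`` such amplicons (e.g. k=7 gives
    V1-V7, V2-V8, V3-V9).
    """
    names = region_map.names
    if not 1 <= k <= len(names):
        raise ValueError(f"k must be in [1, {len(names)}], got {k}")
    return [AmpliconSpec.from_region_range(names[i], names[i + k - 1])
            for i in range(len(names) - k + 1)]


def sliding_windows(span_start: int, span_end: int, length: int,
                    step: int = 50) -> list[AmpliconSpec]:
    """Fixed-length windows advancing by ``step`` within the span; every
    window ends at or before ``span_end``."""
    if step < 1:
        raise ValueError("step must be >= 1")
    if length > span_end - span_start + 1:
        raise ValueError(
            f"window length {length} exceeds span {span_start}-{span_end}")
    return [AmpliconSpec.from_window(s, s + length - 1)
            for s in range(span_start, span_end - length + 2, step)]


def extract_amplicon(db: ReferenceDB, spec: AmpliconSpec,
                     region_map: RegionMap | None = None) -> ReferenceDB:
    """Restrict the database to the spec's columns.

    Sequences that are entirely gaps over the window are dropped (counted
    in the log); a family losing all its members disappears with a warning.
    The full-length spec returns the database unchanged.
    """
    if spec.kind == "full-length":
        return db
    start, end = spec.resolve(region_map, db.alignment_width)
    if not (1 <= start <= end <= db.alignment_width):
        raise ValueError(
            f"amplicon {spec.label} outside alignment bounds "
            f"1..{db.alignment_width}")
    kept: list[AlignedSequence] = []
    dropped = 0
    for s in db:
        window = s.columns[start - 1:end]
        if all(c in GAP_CHARS for c in window):
            dropped += 1
            continue
        kept.append(AlignedSequence(s.seq_id, window, s.lineage,
                                    s.species_name))
    if dropped:
        logger.info("extract_amplicon(%s): dropped %d all-gap sequence(s)",
                    spec.label, dropped)
    out = ReferenceDB(kept)
    lost = set(db.families) - set(out.families)
    if lost:
        warnings.warn(
            f"amplicon {spec.label}: families with no remaining sequences "
            f"removed: {sorted(lost)}")
    return out
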