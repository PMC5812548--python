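"""Evaluation metrics: overmerging, oversplitting, improvement,
species loss and cross-amplicon concordance.

With one reference sequence per species, a perfect clustering returns one
OTU per species; overmerging is the shortfall, 100*(S - O)/S.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cluster import OTUPartition


@dataclass
class EvalReport:
    n_species: int
    n_otus: int
    overmerge_pct: float
    pct_expected: float
    oversplit_pct: float = math.nan
    improvement_pct: float = math.nan

    def to_tsv(self, path: str | Path) -> None:
        fields = self.__dataclass_fields__
        with open(path, "w") as fh:
            fh.write("\t".join(fields) + "\n")
            fh.write("\t".join(f"{getattr(self, f):g}" for f in fields) + "\n")


def pct_expected(n_species: int, n_otus: int) -> float:
    """Percentage of the expected OTU count actually recovered."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    return 100.0 * n_otus / n_species


def overmerging_pct(n_species: int, n_otus: int) -> float:
    """Percentage of species lost to merging: 100*(S - O)/S."""
    if n_species <= 0:
        raise ValueError("n_species must be positive")
    if n_otus > n_species:
        raise ValueError(
            f"n_otus ({n_otus}) exceeds n_species ({n_species}); overmerging "
            "assumes one reference sequence per species")
    return 100.0 * (n_species - n_otus) / n_species


def oversplitting_pct(partition: OTUPartition,
                      truth: Mapping[str, str]) -> float:
    """Percentage of OTUs that are surplus splits of some species.

    For each species, every OTU beyond the first that contains at least
    one of its reads counts as one surplus OTU (an OTU is counted once per
    species it contains).  Returns 100 * surplus / total OTUs.
    """
    per_species: dict[str, set[str]] = {}
    for otu, members in partition.otus.items():
        for read in members:
            if read not in truth:
                raise ValueError(f"read {read!r} missing from truth table")
            per_species.setdefault(truth[read], set()).add(otu)
    if partition.n_otus == 0:
        return 0.0
    surplus = sum(max(0, len(otus) - 1) for otus in per_species.values())
    return 100.0 * surplus / partition.n_otus


def improvement_pct(n_otus_dynamic: int, n_otus_default: int,
                    n_species_correct: int) -> float:
    """Gain in recovered OTUs relative to the correct species count:
    100 * (O_dynamic - O_default) / S."""
    if n_species_correct <= 0:
        raise ValueError("n_species_correct must be positive")
    return 100.0 * (n_otus_dynamic - n_otus_default) / n_species_correct


def species_loss(partition: OTUPartition, truth: Mapping[str, str]) -> int:
    """Detectable species minus surviving OTUs, floored at zero.

    A species is detectable when at least one of its reads survived into
    the partition.
    """
    detectable = {truth[r] for members in partition.otus.values()
                  for r in members}
    return max(0, len(detectable) - partition.n_otus)


def make_report(n_species: int, n_otus: int,
                partition: OTUPartition | None = None,
                truth: Mapping[str, str] | None = None,
                n_otus_default: int | None = None) -> EvalReport:
    report = EvalReport(
        n_species=n_species,
        n_otus=n_otus,
        overmerge_pct=overmerging_pct(n_species, n_otus),
        pct_expected=pct_expected(n_species, n_otus),
    )
    if partition is not None and truth is not None:
        report.oversplit_pct = oversplitting_pct(partition, truth)
    if n_otus_default is not None:
        report.improvement_pct = improvement_pct(n_otus, n_otus_default,
                                                 n_species)
    return report


def amplicon_concordance(per_sample_otu_counts: pd.DataFrame
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise OTU-count comparison across amplicons.

    ``per_sample_otu_counts`` is samples x amplicons.  Returns a long table
    with one row per (sample, amplicon pair) and a per-sample standard
    deviation of OTU counts across amplicons (ddof=1).  Samples with a
    missing cell are skipped with a warning.
    """
    if per_sample_otu_counts.shape[1] < 2:
        raise ValueError("need at least two amplicons")
    amps = list(per_sample_otu_counts.columns)
    rows = []
    sds = {}
    for sample, counts in per_sample_otu_counts.iterrows():
        if counts.isna().any():
            warnings.warn(f"sample {sample!r} has missing counts; skipped")
            continue
        for a, b in itertools.combinations(amps, 2):
            rows.append((sample, a, b, counts[a], counts[b]))
        sds[sample] = float(np.std(counts.to_numpy(dtype=float), ddof=1))
    pairs = pd.DataFrame(rows, columns=["sample", "ampliconA", "ampliconB",
                                        "otusA", "otusB"])
    return pairs, pd.Series(sds, name="otu_count_sd")
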