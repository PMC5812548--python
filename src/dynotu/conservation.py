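"""Per-column conservation bit scores for family alignments.

Each alignment column is scored as ``2 - H`` where ``H`` is the Shannon
entropy (in bits) of the column's nucleotide frequencies over {A,C,G,T}.
A score of 2 marks a fully conserved position, 0 a maximally variable one.
Frequencies are computed over non-gap residues only; ambiguity codes (N
etc.) are excluded from the counts.  Columns with zero non-gap residues
carry NaN (the "not covered" marker) rather than a score.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import AlignedSequence, ReferenceDB

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

ColumnFrequencies = namedtuple("ColumnFrequencies", ["freqs", "coverage"])


@dataclass
class ConservationProfile:
    """Per-column bit scores (NaN = column not covered) for one family."""

    family: str
    scores: np.ndarray      # float, shape (W,), values in [0, 2] or NaN
    coverage: np.ndarray    # int, shape (W,), non-gap residue count

    @property
    def W(self) -> int:
        return int(self.scores.size)

    def __len__(self) -> int:
        return self.W


def _char_matrix(family_seqs: Iterable[AlignedSequence | str]) -> np.ndarray:
    rows = []
    for s in family_seqs:
        text = s.columns if isinstance(s, AlignedSequence) else s
        rows.append(np.frombuffer(text.encode("ascii"), dtype=np.uint8))
    if not rows:
        raise ValueError("need at least one sequence")
    widths = {r.size for r in rows}
    if len(widths) > 1:
        raise ValueError(f"sequences have differing widths: {sorted(widths)}")
    return np.vstack(rows)


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """Counts of A,C,G,T per column; shape (4, W)."""
    return np.stack([(mat == b).sum(axis=0) for b in _BASES])


def column_frequencies(family_seqs: Iterable[AlignedSequence | str],
                       column_index: int) -> ColumnFrequencies:
    """Nucleotide frequencies q_b at a 1-based column over non-gap residues.

    Returns ``(freqs, coverage)``; an all-gap column gives NaN frequencies
    and coverage 0.
    """
    mat = _char_matrix(family_seqs)
    if not 1 <= column_index <= mat.shape[1]:
        raise IndexError(
            f"column_index {column_index} outside [1, {mat.shape[1]}]")
    counts = _base_counts(mat[:, [column_index - 1]])[:, 0].astype(float)
    coverage = int(counts.sum())
    if coverage == 0:
        return ColumnFrequencies(np.full(4, np.nan), 0)
    return ColumnFrequencies(counts / coverage, coverage)


def bit_score_profile(family_seqs: Iterable[AlignedSequence | str],
                      family: str = "") -> ConservationProfile:
    """Per-column conservation bit score: 2 + sum_b q_b log2 q_b."""
    mat = _char_matrix(family_seqs)
    counts = _base_counts(mat).astype(float)          # (4, W)
    coverage = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = counts / coverage
        term = np.where(counts > 0, q * np.log2(np.where(counts > 0, q, 1.0)), 0.0)
    scores = 2.0 + term.sum(axis=0)
    scores = np.where(coverage > 0, scores, np.nan)
    # clip tiny negative round-off (NaN passes through untouched)
    scores = np.clip(scores, 0.0, 2.0)
    return ConservationProfile(family=family, scores=scores,
                               coverage=coverage.astype(int))


def mean_bit_score(profile: ConservationProfile) -> float:
    """Alignment-wide mean bit score over covered columns (summary statistic)."""
    return float(np.nanmean(profile.scores))


def smoothed_profile(profile: ConservationProfile,
                     window: int = 30) -> ConservationProfile:
    """Moving average of the scores with truncated edge windows.

    The output has the same length; near the edges the average runs over
    the columns actually available.  Uncovered (NaN) columns are excluded
    from each window's average and stay NaN only where a window contains
    no covered column at all.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > profile.W:
        raise ValueError(f"window {window} exceeds profile length {profile.W}")
    valid = ~np.isnan(profile.scores)
    vals = np.where(valid, profile.scores, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(valid.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    return ConservationProfile(profile.family, out, profile.coverage.copy())


def complement_profile(profile: ConservationProfile) -> ConservationProfile:
    """Bit-score complement: 2 - score (high values mark variable positions)."""
    return ConservationProfile(profile.family, 2.0 - profile.scores,
                               profile.coverage.copy())


def heatmap_matrix(db: ReferenceDB) -> pd.DataFrame:
    """Families x positions matrix of bit scores; NaN where a family has no
    coverage at a position.  Columns are 1-based alignment positions."""
    rows = {}
    for fam in db.families:
        prof = bit_score_profile(db.family_sequences(fam), family=fam)
        rows[fam] = prof.scores
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=range(1, db.alignment_width + 1))


def write_heatmap_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label="family")
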