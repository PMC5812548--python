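"""One-gap pairwise distances on aligned sequences.

The one-gap model treats an insertion/deletion event, however long, as a
single difference: a maximal run of columns in which the same sequence is
gapped while the other carries bases counts as ONE difference over ONE
compared position.  Columns where both sequences are gapped are skipped
and do not interrupt such a run.  Base-vs-base columns count one compared
position each, a difference when the bases differ.  The distance is
differences / compared positions.

With ``count_ends=False`` the comparison is restricted to the overlap of
the two sequences (leading/trailing gap runs of either sequence are
ignored entirely).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .reference import AlignedSequence

_GAP_DASH = ord("-")
_GAP_DOT = ord(".")


def _encode(seq: AlignedSequence | str) -> np.ndarray:
    text = seq.columns if isinstance(seq, AlignedSequence) else seq
    return np.frombuffer(text.encode("ascii"), dtype=np.uint8)


def _gap_mask(arr: np.ndarray) -> np.ndarray:
    return (arr == _GAP_DASH) | (arr == _GAP_DOT)


def _run_count(mask: np.ndarray) -> int:
    """Number of maximal True-runs in a boolean array."""
    if mask.size == 0:
        return 0
    starts = int(mask[0]) + int(np.count_nonzero(mask[1:] & ~mask[:-1]))
    return starts


def onegap_distance(a: AlignedSequence | str, b: AlignedSequence | str,
                    count_ends: bool = True) -> float:
    """One-gap distance between two equally wide aligned sequences."""
    x, y = _encode(a), _encode(b)
    if x.size != y.size:
        raise ValueError(
            f"unequal alignment widths: {x.size} vs {y.size}")
    xg, yg = _gap_mask(x), _gap_mask(y)
    if not count_ends:
        xb = np.flatnonzero(~xg)
        yb = np.flatnonzero(~yg)
        if xb.size == 0 or yb.size == 0:
            raise ValueError("no comparable positions (all-gap sequence)")
        lo = max(xb[0], yb[0])
        hi = min(xb[-1], yb[-1])
        if hi < lo:
            raise ValueError("no comparable positions (sequences do not overlap)")
        x, y, xg, yg = x[lo:hi + 1], y[lo:hi + 1], xg[lo:hi + 1], yg[lo:hi + 1]
    # drop shared-gap columns; this fuses runs separated only by them
    keep = ~(xg & yg)
    x, y, xg, yg = x[keep], y[keep], xg[keep], yg[keep]
    base_both = ~xg & ~yg
    positions = int(np.count_nonzero(base_both))
    diffs = int(np.count_nonzero(base_both & (x != y)))
    runs = _run_count(xg) + _run_count(yg)
    positions += runs
    diffs += runs
    if positions == 0:
        raise ValueError("no comparable positions between sequences")
    return diffs / positions


def pairwise_distances(seqs: Sequence[AlignedSequence],
                       count_ends: bool = True) -> DistanceMatrix:
    """All-pairs one-gap distances, ids ordered by seq_id.

    Gap-free inputs reduce to per-column mismatch fractions and take a
    vectorised fast path.
    """
    seqs = sorted(seqs, key=lambda s: s.seq_id)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    ids = [s.seq_id for s in seqs]
    mat = np.vstack([_encode(s) for s in seqs])
    if not _gap_mask(mat.ravel()).any():
        # no gaps anywhere: one-gap distance == normalised Hamming distance
        d = squareform(pdist(mat, metric="hamming"))
        return DistanceMatrix(d, ids)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = onegap_distance(seqs[i], seqs[j],
                                                    count_ends=count_ends)
            except ValueError as exc:
                raise ValueError(
                    f"distance failed for pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
    return DistanceMatrix(d, ids)


def write_distances_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Write the lower triangle as ``id1<TAB>id2<TAB>distance`` (mothur
    column dialect)."""
    ids = list(dm.ids)
    with open(path, "w") as fh:
        for i in range(1, len(ids)):
            for j in range(i):
                fh.write(f"{ids[i]}\t{ids[j]}\t{dm[i, j]:.6f}\n")
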