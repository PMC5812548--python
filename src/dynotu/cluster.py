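"""Average-neighbor (average-linkage) agglomerative OTU clustering.

Clusters are merged greedily: at each step the pair of clusters with the
smallest mean inter-cluster distance (arithmetic mean over all cross
pairs) is merged, as long as that mean does not exceed the cut-off.  Ties
are broken by the pair whose smallest member id sorts first, which makes
the partition independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skbio import DistanceMatrix
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class OTUPartition:
    """Mapping of OTU ids to member sequence ids at a stated cut-off."""

    cutoff: str
    otus: dict[str, tuple[str, ...]]

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def member_ids(self) -> set[str]:
        return {m for members in self.otus.values() for m in members}

    def sizes(self) -> dict[str, int]:
        return {otu: len(members) for otu, members in self.otus.items()}

    def write_list(self, path: str | Path) -> None:
        """mothur ``.list`` dialect: label, numOtus, comma-joined members."""
        cells = [",".join(members) for members in self.otus.values()]
        with open(path, "w") as fh:
            fh.write("\t".join([self.cutoff, str(self.n_otus), *cells]) + "\n")

    def write_long_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("otu_id\tseq_id\n")
            for otu, members in self.otus.items():
                for m in members:
                    fh.write(f"{otu}\t{m}\n")

    @classmethod
    def from_clusters(cls, clusters: Iterable[Sequence[str]],
                      cutoff: str, prefix: str = "OTU") -> "OTUPartition":
        ordered = sorted((tuple(sorted(c)) for c in clusters),
                         key=lambda c: c[0])
        otus = {f"{prefix}{i + 1:04d}": members
                for i, members in enumerate(ordered)}
        return cls(cutoff=cutoff, otus=otus)


def _merge_clusters(ids: Sequence[str], d: np.ndarray,
                    cutoff: float) -> list[list[str]]:
    """Core greedy average-linkage merge; returns clusters of ids."""
    n = len(ids)
    if n == 0:
        return []
    if n == 1:
        return [[ids[0]]]
    D = d.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    size = np.ones(n)
    members: list[list[int]] = [[i] for i in range(n)]
    min_id = list(ids)
    n_active = n
    while n_active > 1:
        m = D.min()
        if not np.isfinite(m) or m > cutoff:
            break
        # deterministic tie-break: pair whose smallest member id sorts first
        ti, tj = np.nonzero(D == m)
        best = None
        for i, j in zip(ti.tolist(), tj.tolist()):
            if i >= j:
                continue
            key = tuple(sorted((min_id[i], min_id[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        # Lance-Williams update gives the exact size-weighted mean
        si, sj = size[i], size[j]
        other = active.copy()
        other[[i, j]] = False
        D[i, other] = D[other, i] = (si * D[i, other] + sj * D[j, other]) / (si + sj)
        D[j, :] = D[:, j] = np.inf
        active[j] = False
        size[i] = si + sj
        members[i].extend(members[j])
        members[j] = []
        min_id[i] = min(min_id[i], min_id[j])
        n_active -= 1
    return [sorted(ids[k] for k in members[i])
            for i in range(n) if active[i]]


def _as_matrix(X, ids=None) -> tuple[list[str], np.ndarray]:
    if isinstance(X, DistanceMatrix):
        return list(X.ids), X.data
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square distance matrix")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if np.diagonal(arr).any():
        raise ValueError("distance matrix must have a zero diagonal")
    if ids is None:
        ids = [str(i) for i in range(arr.shape[0])]
    elif len(ids) != arr.shape[0]:
        raise ValueError("ids length does not match matrix size")
    return list(ids), arr


class AverageNeighborOTU(ClusterMixin, BaseEstimator):
    """Average-neighbor OTU clustering on a precomputed distance matrix.

    Parameters
    ----------
    cutoff : float, default 0.03
        Maximal mean inter-cluster distance at which two clusters may
        still be merged (0.03 corresponds to the conventional 97%
        similarity threshold).

    Attributes
    ----------
    ids_ : list of str
        Sequence ids in the matrix's order.
    labels_ : ndarray of int
        Cluster index per input sequence; clusters are numbered by their
        smallest member id.
    clusters_ : list of list of str
        Member ids per cluster, same numbering as ``labels_``.
    n_clusters_ : int
    """

    def __init__(self, cutoff: float = 0.03):
        self.cutoff = cutoff

    def fit(self, X, y=None, ids: Sequence[str] | None = None):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must be in [0, 1], got {self.cutoff}")
        self.ids_, d = _as_matrix(X, ids)
        clusters = _merge_clusters(self.ids_, d, self.cutoff)
        clusters.sort(key=lambda c: c[0])
        self.clusters_ = clusters
        lookup = {m: k for k, members in enumerate(clusters) for m in members}
        self.labels_ = np.array([lookup[i] for i in self.ids_])
        self.n_clusters_ = len(clusters)
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, **fit_params).labels_


def average_neighbor_cluster(dm: DistanceMatrix, cutoff: float,
                             label: str | None = None,
                             prefix: str = "OTU") -> OTUPartition:
    """Cluster a distance matrix into OTUs at a single cut-off."""
    model = AverageNeighborOTU(cutoff=cutoff).fit(dm)
    return OTUPartition.from_clusters(
        model.clusters_,
        cutoff=label if label is not None else f"{cutoff:g}",
        prefix=prefix)
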