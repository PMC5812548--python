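import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

from dynotu.amplicons import RegionMap
from dynotu.reference import AlignedSequence, ReferenceDB


@pytest.fixture
def toy_region_map():
    """Nine tiny regions on a width-100 toy alignment."""
    return RegionMap({f"V{i}": (i * 10 - 5, i * 10) for i in range(1, 10)})


@pytest.fixture
def toy_db():
    """Three families on a width-20 alignment with hand-set divergence."""
    def seq(seq_id, cols, family):
        lineage = ("Bacteria", "P", "C", "O", family, family + "_g")
        return AlignedSequence(seq_id, cols, lineage, seq_id)

    base = "ACGTACGTACGTACGTACGT"
    mut1 = "ACGTACGTACGTACGTACGA"          # 1 diff from base (d=0.05)
    mut4 = "TCGTACGAACGTACTTACGA"          # 4 diffs from base (d=0.20)
    other = "GGGGCCCCAAAATTTTGGGG"
    seqs = [
        seq("famA_1", base, "FamA"),
        seq("famA_2", mut1, "FamA"),
        seq("famA_3", mut4, "FamA"),
        seq("famB_1", other, "FamB"),
        seq("famB_2", other[:-1] + "A", "FamB"),
        seq("famB_3", "A" + other[1:], "FamB"),
        seq("famC_1", base[::-1], "FamC"),
        seq("famC_2", base[::-1], "FamC"),
    ]
    return ReferenceDB(seqs)


def naive_average_neighbor(ids, d, cutoff):
    """Exhaustive reference clustering: recompute every cluster-pair mean
    from the raw matrix at each step; same merge rule and tie-break."""
    ids = list(ids)
    pos = {i: k for k, i in enumerate(ids)}
    clusters = [frozenset([i]) for i in ids]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                vals = [d[pos[x], pos[y]]
                        for x in clusters[a] for y in clusters[b]]
                mean = sum(vals) / len(vals)
                key = (mean, tuple(sorted((min(clusters[a]),
                                           min(clusters[b])))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (mean, _), a, b = best
        if mean > cutoff:
            break
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return {frozenset(c) for c in clusters}
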