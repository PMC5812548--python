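import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dynotu.amplicons import AmpliconSpec
from dynotu.cluster import OTUPartition, average_neighbor_cluster
from dynotu.distance import pairwise_distances
from dynotu.dynamic import (DynamicOTUClusterer, LookupTable, assign_taxa,
                            dynamic_cluster, filter_rare_otus, nearest_rank,
                            train_lookup)
from dynotu.reference import AlignedSequence, ReferenceDB
from dynotu.simulate import simulate_family


def _family_db(distance_per_pair: dict[str, float], width: int = 1000,
               seed: int = 0) -> ReferenceDB:
    """Families of 3+ species whose realized pairwise distances sit near a
    target, built by star-phylogeny simulation."""
    from dynotu.simulate import rate_for_distance

    seqs = []
    rng = np.random.default_rng(seed)
    for fam, dist in distance_per_pair.items():
        fam_seqs, _ = simulate_family(width, 4, rate_for_distance(dist),
                                      rng=rng, family_name=fam)
        seqs.extend(fam_seqs)
    return ReferenceDB(seqs)


class TestNearestRank:
    def test_tiny_family_uses_first_order_statistic(self):
        assert nearest_rank([0.012, 0.020, 0.025], 2.5) == 0.012

    def test_matches_sort_and_index_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            vals = np.sort(rng.uniform(0, 0.2, n))
            p = float(rng.uniform(0.5, 99.5))
            k = max(1, math.ceil(p / 100 * n))
            assert nearest_rank(vals, p) == vals[k - 1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nearest_rank([], 2.5)


class TestTrainLookup:
    def test_clamp_rule(self):
        # all-pairs distance ~0.05 -> ceiling 0.03; ~0.004 -> floor 0.01
        db = _family_db({"High": 0.05, "Low": 0.004}, seed=1)
        table = train_lookup(db, AmpliconSpec.full_length())
        assert table.rows["High"].cutoff == 0.03
        assert table.rows["Low"].cutoff == 0.01
        assert table.rows["High"].raw_percentile_distance > 0.03
        assert table.rows["Low"].raw_percentile_distance < 0.01

    def test_unclamped_raw_kept(self):
        db = _family_db({"Mid": 0.02}, seed=2)
        table = train_lookup(db, AmpliconSpec.full_length())
        row = table.rows["Mid"]
        assert row.cutoff == row.raw_percentile_distance
        assert 0.01 <= row.cutoff <= 0.03

    def test_row_bookkeeping(self):
        db = _family_db({"FamQ": 0.02}, seed=4)
        table = train_lookup(db, AmpliconSpec.full_length())
        row = table.rows["FamQ"]
        assert row.n_species == 4
        assert row.n_pairs == row.n_species * (row.n_species - 1) // 2

    def test_raw_matches_empirical_quantile(self):
        db = _family_db({"FamR": 0.03}, seed=5)
        table = train_lookup(db, AmpliconSpec.full_length())
        dm = pairwise_distances(db.family_sequences("FamR"))
        vals = np.sort(dm.condensed_form())
        assert table.rows["FamR"].raw_percentile_distance == \
            nearest_rank(vals, 2.5)

    def test_single_member_taxon_omitted_with_warning(self):
        seqs = [AlignedSequence("solo", "ACGT" * 10,
                                ("B", "P", "C", "O", "Lonely", "G")),
                AlignedSequence("a", "ACGT" * 10, ("B", "P", "C", "O", "F", "G")),
                AlignedSequence("b", "ACGA" * 10, ("B", "P", "C", "O", "F", "G"))]
        with pytest.warns(UserWarning, match="Lonely"):
            table = train_lookup(ReferenceDB(seqs), AmpliconSpec.full_length())
        assert "Lonely" not in table.rows and "F" in table.rows

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            train_lookup(ReferenceDB([]), AmpliconSpec.full_length())

    def test_cutoffs_always_inside_clamp(self):
        db = _family_db({"A": 0.002, "B": 0.01, "C": 0.02, "D": 0.06}, seed=6)
        table = train_lookup(db, AmpliconSpec.full_length())
        for row in table.rows.values():
            assert 0.01 <= row.cutoff <= 0.03

    def test_higher_divergence_never_lower_raw(self):
        # monotone: scaling every distance up cannot decrease the percentile
        rng = np.random.default_rng(8)
        vals = np.sort(rng.uniform(0.005, 0.05, 21))
        assert nearest_rank(vals * 1.5, 2.5) >= nearest_rank(vals, 2.5)

    def test_tsv_roundtrip(self, tmp_path):
        db = _family_db({"FamA": 0.02, "FamB": 0.05}, seed=7)
        table = train_lookup(db, AmpliconSpec.from_window(1, 1000))
        path = tmp_path / "lookup.tsv"
        table.to_tsv(path)
        back = LookupTable.from_tsv(path)
        assert back.level == table.level
        assert back.amplicon == table.amplicon
        assert back.default_cutoff == table.default_cutoff
        assert back.clamp == table.clamp
        assert back.amplicon_width == table.amplicon_width
        for taxon, row in table.rows.items():
            assert back.rows[taxon].cutoff == pytest.approx(row.cutoff)


class TestAssignTaxa:
    TAX = {
        "r1": (("B", "P", "C", "O", "Enterobacteriaceae", "G"),
               (100.0,) * 6),
        "r2": (("B", "P", "C", "O", "Enterobacteriaceae", "G"),
               (100, 100, 100, 100, 60, 50)),
        "r3": (("B", "P", "C", "O", "", ""), None),
        "r4": (("B", "P", "C", "O", "Lachnospiraceae", "G"), None),
    }

    def test_confident_read_assigned(self):
        res = assign_taxa(self.TAX)
        assert "r1" in res.by_taxon["Enterobacteriaceae"]

    def test_low_confidence_goes_unclassified(self):
        res = assign_taxa(self.TAX)
        assert "r2" in res.unclassified

    def test_empty_label_goes_unclassified(self):
        res = assign_taxa(self.TAX)
        assert "r3" in res.unclassified
        assert res.unclassified_fraction == pytest.approx(0.5)

    def test_no_confidences_means_threshold_vacuous(self):
        res = assign_taxa(self.TAX)
        assert "r4" in res.by_taxon["Lachnospiraceae"]

    def test_missing_read_warned_and_unclassified(self):
        with pytest.warns(UserWarning, match="ghost"):
            res = assign_taxa(self.TAX, read_ids=["r1", "ghost"])
        assert "ghost" in res.unclassified

    def test_threshold_is_inclusive(self):
        res = assign_taxa(self.TAX, confidence_threshold=60.0)
        assert "r2" in res.by_taxon["Enterobacteriaceae"]


class TestDynamicCluster:
    @staticmethod
    def _table(rows=None, default=0.03, width=None):
        table = LookupTable(level="family",
                            amplicon=AmpliconSpec.full_length(),
                            default_cutoff=default, clamp=(0.01, 0.03),
                            percentile=2.5, amplicon_width=width)
        if rows:
            from dynotu.dynamic import LookupRow
            for taxon, cutoff in rows.items():
                table.rows[taxon] = LookupRow(taxon, 3, 3, cutoff, cutoff)
        return table

    @staticmethod
    def _reads(spec_list):
        return [AlignedSequence(i, s) for i, s in spec_list]

    def test_all_unclassified_reduces_to_default_pipeline(self):
        reads = self._reads([("r1", "ACGTACGTAC"), ("r2", "ACGTACGTAA"),
                             ("r3", "TTTTACGTAC")])
        assignment = assign_taxa({r.seq_id: (("",) * 6, None) for r in reads})
        part = dynamic_cluster(reads, assignment, self._table())
        ref = average_neighbor_cluster(pairwise_distances(reads), 0.03)
        assert set(map(frozenset, part.otus.values())) == \
            set(map(frozenset, ref.otus.values()))
        assert all(o.startswith("unclassified_") for o in part.otus)

    def test_family_cutoffs_split_what_default_merges(self):
        # reads 2% apart: split at the family's 0.01, merged at default 0.03
        a = "ACGT" * 25
        b = a[:-8] + "ACGAACGA"                 # 2 diffs over 100
        tax = {"x1": (("B", "P", "C", "O", "Tight", "G"), None),
               "x2": (("B", "P", "C", "O", "Tight", "G"), None)}
        reads = self._reads([("x1", a), ("x2", b)])
        assignment = assign_taxa(tax)
        strict = dynamic_cluster(reads, assignment,
                                 self._table({"Tight": 0.01}))
        assert strict.n_otus == 2
        loose = dynamic_cluster(reads, assignment, self._table())
        assert loose.n_otus == 1

    def test_novel_family_uses_default_cutoff(self):
        a = "ACGT" * 25
        b = a[:-8] + "ACGAACGA"
        tax = {"x1": (("B", "P", "C", "O", "Novel", "G"), None),
               "x2": (("B", "P", "C", "O", "Novel", "G"), None)}
        part = dynamic_cluster(self._reads([("x1", a), ("x2", b)]),
                               assign_taxa(tax), self._table())
        assert part.n_otus == 1
        assert list(part.otus)[0].startswith("Novel_")

    def test_read_count_conserved_and_ids_prefixed(self):
        a = "ACGT" * 25
        tax = {"x1": (("B", "P", "C", "O", "F1", "G"), None),
               "x2": (("B", "P", "C", "O", "F2", "G"), None),
               "x3": (("",) * 6, None)}
        reads = self._reads([("x1", a), ("x2", a), ("x3", a)])
        part = dynamic_cluster(reads, assign_taxa(tax),
                               self._table({"F1": 0.01, "F2": 0.01}))
        assert part.member_ids() == {"x1", "x2", "x3"}
        prefixes = {o.split("_OTU")[0] for o in part.otus}
        assert prefixes == {"F1", "F2", "unclassified"}

    def test_width_mismatch_rejected(self):
        reads = self._reads([("x1", "ACGT"), ("x2", "ACGA")])
        tax = {"x1": (("",) * 6, None), "x2": (("",) * 6, None)}
        with pytest.raises(ValueError, match="width"):
            dynamic_cluster(reads, assign_taxa(tax),
                            self._table(width=100))


class TestFilterRareOTUs:
    @staticmethod
    def _partition(sizes):
        otus = {f"OTU{k}": tuple(f"r{k}_{i}" for i in range(n))
                for k, n in enumerate(sizes)}
        return OTUPartition(cutoff="0.03", otus=otus)

    def test_strict_boundary_at_stated_depth(self):
        part = self._partition([24, 25, 400])
        out = filter_rare_otus(part, depth=25000)
        assert [len(m) for m in out.otus.values()] == [25, 400]

    def test_zero_fraction_is_identity(self):
        part = self._partition([1, 2, 3])
        out = filter_rare_otus(part, min_fraction=0.0, depth=25000)
        assert out.otus == part.otus

    def test_single_big_otu_kept(self):
        part = self._partition([25000])
        out = filter_rare_otus(part, depth=25000)
        assert out.n_otus == 1

    def test_read_counts_weighting(self):
        part = OTUPartition(cutoff="x", otus={"OTU0": ("a",), "OTU1": ("b",)})
        out = filter_rare_otus(part, read_counts={"a": 30, "b": 10},
                               depth=25000)
        assert list(out.otus) == ["OTU0"]

    def test_depth_required(self):
        with pytest.raises(ValueError):
            filter_rare_otus(self._partition([5]), depth=0)


class TestDynamicOTUClusterer:
    def test_fit_predict_roundtrip(self):
        db = _family_db({"FamA": 0.05, "FamB": 0.05}, width=600, seed=9)
        model = DynamicOTUClusterer()
        model.fit(db)
        assert set(model.lookup_.rows) == {"FamA", "FamB"}
        from dynotu.simulate import simulate_reads
        sim = simulate_reads(db, AmpliconSpec.full_length(),
                             reads_per_species=3, error_rate=0.0, seed=10)
        labels = model.predict(sim.reads, sim.taxonomy)
        assert labels.shape == (len(sim.reads),)
        # error-free reads of one species always share an OTU
        by_species = {}
        for read, label in zip(sim.reads, labels):
            by_species.setdefault(sim.truth[read.seq_id], set()).add(label)
        assert all(len(v) == 1 for v in by_species.values())

    def test_get_params_sklearn_contract(self):
        model = DynamicOTUClusterer(percentile=5.0)
        params = model.get_params()
        assert params["percentile"] == 5.0
        model.set_params(default_cutoff=0.02)
        assert model.default_cutoff == 0.02

    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            DynamicOTUClusterer().predict([], {})
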