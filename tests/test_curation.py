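import numpy as np
import pandas as pd
import pytest

from dietbarcoder import (
    DietBarcoderError,
    FilterReport,
    ReadTable,
    TagAssignmentTable,
    TaxonPath,
    aggregate_replicates,
    apply_range_rules,
    assign_taxonomy,
    cap_rank,
    cluster_greedy,
    demultiplex,
    denoise_merge,
    length_filter,
    min_count_filter,
    remove_contaminants,
    remove_host,
    run_cascade,
    tagjump_filter,
)
from dietbarcoder.model import RefRecord, ReferenceDatabase

from conftest import toy_table, toy_units


def seqs_of_length(lengths, seed=5):
    rng = np.random.default_rng(seed)
    return ["".join(rng.choice(list("ACGT"), size=n)) for n in lengths]


class TestDemultiplex:
    def test_duplicate_tag_pair_is_config_error(self):
        rows = pd.DataFrame(
            [
                {"unit_id": "u1", "forward_tag": "AAAACCCC", "reverse_tag": "GGGGTTTT",
                 "forward_primer": "ACGTACGTACGT", "reverse_primer": "TGCATGCATGCA"},
                {"unit_id": "u2", "forward_tag": "AAAACCCC", "reverse_tag": "GGGGTTTT",
                 "forward_primer": "ACGTACGTACGT", "reverse_primer": "TGCATGCATGCA"},
            ]
        )
        with pytest.raises(DietBarcoderError):
            TagAssignmentTable(rows)

    def test_short_read_unassigned(self):
        tags = TagAssignmentTable(
            pd.DataFrame(
                [{"unit_id": "u1", "forward_tag": "AAAACCCC", "reverse_tag": "GGGGTTTT",
                  "forward_primer": "ACGTACGTACGT", "reverse_primer": "TGCATGCATGCA"}]
            )
        )
        table = demultiplex(["ACGTAC"], tags)
        assert table.total_reads == 0
        assert demultiplex.last_unassigned == 1

    def test_two_mismatches_tolerated(self):
        fp, rp = "ACGTACGTACGT", "TGCATGCATGCA"
        tags = TagAssignmentTable(
            pd.DataFrame(
                [{"unit_id": "u1", "forward_tag": "AAAACCCC", "reverse_tag": "GGGGTTTT",
                  "forward_primer": fp, "reverse_primer": rp}]
            )
        )
        insert = "ACCGGTTACCGGTT"
        comp = str.maketrans("ACGT", "TGCA")
        fp2 = "TTGTACGTACGT"  # 2 substitutions
        read = "AAAACCCC" + fp2 + insert + rp.translate(comp)[::-1] + "GGGGTTTT".translate(comp)[::-1]
        table = demultiplex([read], tags)
        assert table.total_reads == 1
        assert table.sequences == [insert]


class TestLengthFilter:
    def test_sper01_bounds_remove_9bp(self):
        seqs = seqs_of_length([9, 50, 221])
        t = toy_table(np.full((3, 8), 5), sequences=seqs)
        out = length_filter(t, 10, 220)
        assert out.sequences == [seqs[1]]

    def test_identity_bounds(self):
        t = toy_table(np.full((2, 8), 5))
        out = length_filter(t, 0, 10**9)
        assert out.sequences == t.sequences

    def test_all_removed_keeps_units(self):
        t = toy_table(np.full((2, 8), 5))
        out = length_filter(t, 1, 2)
        assert out.n_sequences == 0
        assert out.units.equals(t.units)


class TestMinCountFilter:
    def test_threshold_boundary(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 0] = 9
        counts[1, 0] = 10
        t = toy_table(counts)
        out = min_count_filter(t, 10)
        assert out.sequences == [t.sequences[1]]

    def test_zero_threshold_identity(self):
        t = toy_table(np.arange(16).reshape(2, 8))
        out = min_count_filter(t, 0)
        assert np.array_equal(out.counts, t.counts)

    def test_totals_include_controls(self):
        # library totals span samples AND controls: 4 sequences x 6+2 units
        counts = np.zeros((4, 8), dtype=int)
        counts[0, :6] = [1, 1, 1, 1, 1, 1]  # 6 in samples only -> dropped
        counts[1, :6] = [2, 2, 2, 1, 1, 1]  # 9 -> dropped
        counts[2, :6] = [2, 2, 2, 1, 1, 1]
        counts[2, 6] = 1  # plus a blank read: 10 -> kept
        counts[3, 7] = 12  # negative control only: 12 -> kept
        t = toy_table(counts)
        out = min_count_filter(t, 10)
        assert out.sequences == [t.sequences[2], t.sequences[3]]


class TestDenoiseMerge:
    def test_child_merged_into_parent(self):
        parent = "A" * 20 + "C" * 20
        child = parent[:-1] + "G"  # 1 substitution
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :3] = [500, 300, 200]  # 1000 total
        counts[1, :3] = [10, 5, 5]  # 20 total
        t = toy_table(counts, sequences=[parent, child])
        out = denoise_merge(t)
        assert out.sequences == [parent]
        assert out.library_totals()[0] == 1020
        assert list(out.counts[0, :3]) == [510, 305, 205]

    def test_equal_abundance_not_merged(self):
        a = "A" * 20 + "C" * 20
        b = a[:-1] + "G"
        counts = np.full((2, 8), 3)
        t = toy_table(counts, sequences=[a, b])
        out = denoise_merge(t)
        assert out.n_sequences == 2

    def test_zero_ratio_identity(self):
        a = "A" * 20 + "C" * 20
        b = a[:-1] + "G"
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 0] = 1000
        counts[1, 0] = 1
        t = toy_table(counts, sequences=[a, b])
        out = denoise_merge(t, child_ratio=0.0)
        assert out.n_sequences == 2

    def test_indel_counts_as_mismatch(self):
        a = "A" * 20 + "C" * 20
        b = a[:-1]  # single deletion
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 0] = 1000
        counts[1, 0] = 10
        t = toy_table(counts, sequences=[a, b])
        out = denoise_merge(t)
        assert out.sequences == [a]


class TestClusterGreedy:
    def test_threshold_one_is_identity(self):
        t = toy_table(np.full((3, 8), 4), sequences=seqs_of_length([40, 41, 42]))
        out = cluster_greedy(t, 1.0)
        assert sorted(out.sequences) == sorted(t.sequences)

    def test_97pct_variant_joins(self):
        rng = np.random.default_rng(1)
        rep = "".join(rng.choice(list("ACGT"), size=100))
        minor = rep[:50] + ("A" if rep[50] != "A" else "C") + rep[51:]  # 99% identical
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 0] = 100
        counts[1, 0] = 60
        t = toy_table(counts, sequences=[rep, minor])
        out = cluster_greedy(t, 0.97)
        assert out.sequences == [rep]
        assert out.counts[0, 0] == 160

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(5)]
        counts = np.array([[30, 1, 0, 0, 0, 0, 0, 0],
                           [20, 1, 0, 0, 0, 0, 0, 0],
                           [10, 0, 1, 0, 0, 0, 0, 0],
                           [5, 0, 0, 1, 0, 0, 0, 0],
                           [2, 0, 0, 0, 1, 0, 0, 0]])
        t = toy_table(counts, sequences=seqs)
        ref = cluster_greedy(t, 0.97)
        perm = [3, 1, 4, 0, 2]
        t2 = ReadTable([seqs[i] for i in perm], counts[perm], t.units, t.library_id)
        out = cluster_greedy(t2, 0.97)
        assert out.sequences == ref.sequences
        assert np.array_equal(out.counts, ref.counts)


def _db_with(seqs_taxa, scope="local"):
    records = [RefRecord(s, tuple(taxa)) for s, taxa in seqs_taxa]
    return ReferenceDatabase(records, scope=scope)


def _sp(genus, species, family="Fabaceae"):
    return TaxonPath(("Plantae", "Streptophyta", "Magnoliopsida", "Fabales",
                      family, genus, f"{genus} {species}"))


class TestAssignTaxonomy:
    def test_multispecies_shared_reference(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        db = _db_with([(seq, [_sp("Vachellia", "nilotica"), _sp("Caesalpinia", "decapetala")])])
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 0] = 10
        t = toy_table(counts, sequences=[seq])
        [a] = assign_taxonomy(t, db, None)
        assert a.matched_db == "local"
        assert a.identity == 1.0
        assert a.label == "Caesalpinia decapetala/Vachellia nilotica"
        assert a.assigned_rank == "family"

    def test_below_threshold_unassigned(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        other = "".join(rng.choice(list("ACGT"), size=80))
        db = _db_with([(other, [_sp("Genusa", "x")])])
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 0] = 10
        t = toy_table(counts, sequences=[seq])
        [a] = assign_taxonomy(t, db, db)
        assert a.matched_db == "none"
        assert a.taxon is None

    def test_local_97_beats_global_100(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        local_ref = seq[:-2] + ("AA" if not seq.endswith("AA") else "CC")  # 98%
        local = _db_with([(local_ref, [_sp("Localis", "hit")])])
        glob = _db_with([(seq, [_sp("Globalis", "hit")])], scope="global")
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 0] = 10
        t = toy_table(counts, sequences=[seq])
        [a] = assign_taxonomy(t, local, glob)
        assert a.matched_db == "local"
        assert a.taxon.at("genus") == "Localis"

    def test_tie_resolves_to_common_rank(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        # two distinct references, both 1 substitution away (equal identity)
        ref1 = ("A" if seq[0] != "A" else "C") + seq[1:]
        ref2 = seq[:-1] + ("A" if seq[-1] != "A" else "C")
        db = _db_with([(ref1, [_sp("Genx", "a")]), (ref2, [_sp("Geny", "b")])])
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 0] = 10
        t = toy_table(counts, sequences=[seq])
        [a] = assign_taxonomy(t, db, None)
        assert a.assigned_rank == "family"
        assert a.label == "Genx a/Geny b"


class TestRangeRules:
    def _assignment(self):
        p = _sp("Vachellia", "exotica")
        from dietbarcoder.model import TaxonomicAssignment

        return TaxonomicAssignment("ACGT", "local", 1.0, p, p.name, "species")

    def test_invalid_species_valid_genus(self):
        [a] = apply_range_rules([self._assignment()],
                                {"Vachellia exotica": (False, True)})
        assert a.assigned_rank == "genus"
        assert a.demoted == "range_mismatch"
        assert a.label == "Vachellia"

    def test_invalid_species_invalid_genus(self):
        [a] = apply_range_rules([self._assignment()],
                                {"Vachellia exotica": (False, False)})
        assert a.assigned_rank == "family"
        assert a.label == "Fabaceae"

    def test_valid_species_unchanged(self):
        [a] = apply_range_rules([self._assignment()],
                                {"Vachellia exotica": (True, True)})
        assert a.assigned_rank == "species"
        assert a.demoted is None

    def test_missing_species_warns_and_demotes(self):
        with pytest.warns(UserWarning):
            [a] = apply_range_rules([self._assignment()], {})
        assert a.assigned_rank == "family"


class TestCapRank:
    def _assignment(self, rank):
        p = _sp("Hodotermes", "mossambicus").truncated(rank)
        from dietbarcoder.model import TaxonomicAssignment

        return TaxonomicAssignment("ACGT", "global", 1.0, p, p.name, rank)

    def test_genus_capped_to_family(self):
        [a] = cap_rank([self._assignment("genus")], "family")
        assert a.assigned_rank == "family"
        assert a.demoted == "family_cap"

    def test_family_unchanged(self):
        [a] = cap_rank([self._assignment("family")], "family")
        assert a.assigned_rank == "family"
        assert a.demoted is None

    def test_species_cap_is_identity(self):
        [a] = cap_rank([self._assignment("species")], "species")
        assert a.assigned_rank == "species"


class TestRemoveHost:
    def test_paper_read_arithmetic(self):
        rng = np.random.default_rng(7)
        host_seq = "".join(rng.choice(list("ACGT"), size=80))
        diet_seq = "".join(rng.choice(list("ACGT"), size=80))
        counts = np.zeros((2, 8), dtype=int)
        counts[0, 0] = 961_542
        counts[1, 0] = 736_897
        t = toy_table(counts, sequences=[host_seq, diet_seq])
        from dietbarcoder.model import TaxonomicAssignment

        vervet = TaxonPath(("Animalia", "Chordata", "Mammalia", "Primates",
                            "Cercopithecidae", "Chlorocebus", "Chlorocebus pygerythrus"))
        diet = _sp("Dieta", "x")
        assignments = [
            TaxonomicAssignment(host_seq, "global", 1.0, vervet, vervet.name, "species"),
            TaxonomicAssignment(diet_seq, "global", 1.0, diet, diet.name, "species"),
        ]
        assert t.total_reads == 1_698_439
        out, report = remove_host(t, assignments, ["Chlorocebus pygerythrus"])
        assert out.total_reads == 736_897
        assert report.stages[-1].reads_removed == 961_542

    def test_empty_host_list_identity(self, small_table):
        table, _ = small_table
        out, _ = remove_host(table, [], [])
        assert np.array_equal(out.counts, table.counts)

    def test_host_removed_from_controls_too(self):
        rng = np.random.default_rng(8)
        host_seq = "".join(rng.choice(list("ACGT"), size=60))
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 6] = 50  # only in the blank
        t = toy_table(counts, sequences=[host_seq])
        from dietbarcoder.model import TaxonomicAssignment

        vervet = _sp("Chlorocebus", "pygerythrus", family="Cercopithecidae")
        a = TaxonomicAssignment(host_seq, "global", 1.0, vervet, vervet.name, "species")
        out, _ = remove_host(t, [a], ["Chlorocebus pygerythrus"])
        assert out.n_sequences == 0


class TestRemoveContaminants:
    def test_abundant_in_negative_removed(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :6] = [1, 1, 1, 1, 1, 1]
        counts[0, 7] = 50  # 50/53 of the extraction negative
        counts[1, :6] = [99, 99, 99, 99, 99, 99]
        counts[1, 7] = 3
        t = toy_table(counts)
        out, _ = remove_contaminants(t)
        assert out.sequences == [t.sequences[1]]

    def test_absent_from_controls_kept(self):
        counts = np.zeros((1, 8), dtype=int)
        counts[0, :6] = 10
        t = toy_table(counts)
        out, _ = remove_contaminants(t)
        assert out.n_sequences == 1

    def test_no_controls_identity_with_warning(self):
        counts = np.full((1, 6), 4)
        units = toy_units(blanks=0, negatives=0)
        t = ReadTable(["ACGTACGTAC"], counts, units)
        with pytest.warns(UserWarning):
            out, _ = remove_contaminants(t)
        assert np.array_equal(out.counts, t.counts)


class TestTagjumpFilter:
    def test_no_blank_reads_identity(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[:, :6] = 100
        t = toy_table(counts)
        out, report = tagjump_filter(t)
        assert report.tagjump_ratio == 0.0
        assert np.array_equal(out.counts, t.counts)

    def test_hand_computed_ratio(self):
        # single blank, single leaking sequence: b/T = 2/1000 = 0.002;
        # a cell of that sequence at 0.1% of T (1 read) is < 2 and zeroed
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :6] = [500, 300, 150, 47, 0, 1]
        counts[0, 6] = 2  # blank
        counts[1, :6] = [10000, 5000, 3000, 1000, 500, 500]
        t = toy_table(counts)
        out, report = tagjump_filter(t)
        assert report.tagjump_ratio == pytest.approx(0.002)
        assert out.counts[0, 5] == 0  # 1 < 0.002*1002
        assert out.counts[0, 3] == 47  # 47 >= 2.004
        # second sequence: threshold 0.002*20000 = 40 < all cells
        assert np.array_equal(out.counts[1, :6], counts[1, :6])

    def test_conservation_in_report(self):
        counts = np.zeros((2, 8), dtype=int)
        counts[0, :6] = [500, 300, 150, 47, 0, 1]
        counts[0, 6] = 2
        counts[1, :6] = 100
        t = toy_table(counts)
        out, report = tagjump_filter(t)
        s = report.stages[-1]
        assert s.reads_in == s.reads_out + s.reads_removed


class TestAggregateReplicates:
    def _table(self, reps):
        counts = np.zeros((1, 8), dtype=int)
        counts[0, :3] = reps
        return toy_table(counts)

    def test_mean_below_floor_zeroed(self):
        out = aggregate_replicates(self._table([6, 7, 0]))
        assert out.values.loc[:, "s1"].iloc[0] == 0.0

    def test_mean_retained(self):
        out = aggregate_replicates(self._table([10, 20, 30]))
        assert out.values.loc[:, "s1"].iloc[0] == pytest.approx(20.0)

    def test_single_presence_zeroed(self):
        out = aggregate_replicates(self._table([100, 0, 0]))
        assert out.values.loc[:, "s1"].iloc[0] == 0.0

    def test_controls_dropped(self):
        out = aggregate_replicates(self._table([10, 20, 30]))
        assert list(out.values.columns) == ["s1", "s2"]

    def test_too_few_replicates_excluded_with_warning(self):
        counts = np.full((1, 8), 7)
        units = toy_units()
        units = units.drop(index=["s2.r2", "s2.r3"])
        t = ReadTable(["ACGTACGTAC"], counts[:, :6], units)
        report = FilterReport()
        with pytest.warns(UserWarning):
            out = aggregate_replicates(t, report=report)
        assert list(out.values.columns) == ["s1"]
        assert report.excluded_samples == ["s2"]


class TestCascade:
    def test_zero_artifact_cascade_is_replicate_mean(self, small_cfg, small_truth):
        from dietbarcoder import gen_read_table

        table, truth = gen_read_table(small_truth, small_cfg)
        res = run_cascade(table, truth.reference_db, None)
        smp = table.units[table.units["unit_type"] == "sample"]
        for sid, grp in smp.groupby("sample_id"):
            cols = [table.units.index.get_loc(u) for u in grp.index]
            block = table.counts[:, cols]
            mean = block.mean(axis=1)
            present = (block > 0).sum(axis=1) >= 2
            expect = np.where(present & (mean >= 5), mean, 0.0)
            got = res.samples.values[sid].reindex(table.sequences).fillna(0.0).to_numpy()
            assert np.allclose(got, expect)

    def test_stage_order(self, small_cfg, small_truth):
        from dietbarcoder import gen_read_table

        table, truth = gen_read_table(small_truth, small_cfg)
        res = run_cascade(table, truth.reference_db, None)
        names = [s.stage for s in res.report.stages]
        assert names == [
            "length_filter", "min_count_filter", "denoise_merge", "cluster_greedy",
            "remove_contaminants", "tagjump_filter", "aggregate_replicates",
        ]

    def test_read_conservation_every_stage(self, small_cfg, small_truth):
        from dietbarcoder import gen_read_table

        table, truth = gen_read_table(small_truth, small_cfg)
        res = run_cascade(table, truth.reference_db, None)
        for s in res.report.stages[:-1]:  # last stage averages replicates
            assert s.reads_in == s.reads_out + s.reads_removed
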