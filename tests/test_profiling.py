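import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gutclpb.profiling import (
    FormatError,
    HmmerHit,
    OrfLocation,
    ReadAlignment,
    assign_reads_to_orfs,
    best_annotation_per_orf,
    build_function_table,
    filter_taxa,
    parse_hits,
    reads_from_frame,
)
from gutclpb.synthetic import FamilySpec, make_metagenome, make_orf_population

from oracles import recount_reads_per_ko


def _write(tmp_path, text, name="hits.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestParseHits:
    def test_well_formed_file(self, tmp_path):
        path = _write(
            tmp_path,
            "orf_id\tko\tevalue\tbitscore\n"
            "orf1\tK03695\t1e-30\t250.0\n"
            "orf2\tK01358\t1e-10\t90.5\n"
            "orf3\tK03695\t2e-5\t40.1\n",
        )
        hits = parse_hits(path)
        assert len(hits) == 3
        assert hits[0].orf_id == "orf1" and hits[0].ko == "K03695"
        assert hits[0].evalue == pytest.approx(1e-30)
        assert hits[0].bitscore == 250.0

    def test_header_only_file_gives_empty_list(self, tmp_path):
        assert parse_hits(_write(tmp_path, "orf_id\tko\tevalue\tbitscore\n")) == []

    def test_unparsable_evalue_cites_row_number(self, tmp_path):
        path = _write(
            tmp_path, "orf_id\tko\tevalue\tbitscore\norf1\tK03695\tabc\t250.0\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            parse_hits(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = _write(tmp_path, "orf_id\tko\tevalue\norf1\tK03695\t1e-30\n")
        with pytest.raises(FormatError, match="bitscore"):
            parse_hits(path)


class TestBestAnnotation:
    def test_lower_evalue_wins(self):
        hits = [HmmerHit("orfA", "K03695", 1e-30, 100), HmmerHit("orfA", "K01358", 1e-10, 500)]
        assert best_annotation_per_orf(hits) == {"orfA": "K03695"}

    def test_evalue_tie_broken_by_bitscore(self):
        hits = [HmmerHit("orfB", "K1", 1e-5, 50), HmmerHit("orfB", "K2", 1e-5, 60)]
        assert best_annotation_per_orf(hits) == {"orfB": "K2"}

    def test_full_tie_broken_by_ko_lexicographic(self):
        hits = [HmmerHit("orfC", "K9", 1e-5, 50), HmmerHit("orfC", "K2", 1e-5, 50)]
        assert best_annotation_per_orf(hits) == {"orfC": "K2"}

    def test_single_hit_is_kept(self):
        assert best_annotation_per_orf([HmmerHit("o", "K1", 1.0, 10)]) == {"o": "K1"}

    def test_order_independence(self):
        hits = [
            HmmerHit("o", "K5", 1e-8, 70),
            HmmerHit("o", "K1", 1e-5, 90),
            HmmerHit("o", "K3", 1e-8, 80),
        ]
        for perm in ([0, 1, 2], [2, 1, 0], [1, 2, 0]):
            assert best_annotation_per_orf([hits[i] for i in perm]) == {"o": "K3"}


class TestAssignReads:
    def test_read_fully_inside_orf_assigned(self):
        reads = [ReadAlignment("r1", "c1", 100, 199)]
        orfs = [OrfLocation("c1", 50, 400, "+", "orfA")]
        assert assign_reads_to_orfs(reads, orfs) == {"orfA": 1}

    def test_exactly_half_overlap_is_assigned(self):
        reads = [ReadAlignment("r1", "c1", 95, 104)]  # overlap 100..104 = 5 of 10
        orfs = [OrfLocation("c1", 100, 300, "+", "orfA")]
        assert assign_reads_to_orfs(reads, orfs) == {"orfA": 1}

    def test_below_half_overlap_unassigned(self):
        reads = [ReadAlignment("r1", "c1", 94, 103)]  # overlap 4 of 10
        orfs = [OrfLocation("c1", 100, 300, "+", "orfA")]
        assert assign_reads_to_orfs(reads, orfs) == {}

    def test_read_on_contig_without_orfs_unassigned(self):
        reads = [ReadAlignment("r1", "cX", 1, 100)]
        orfs = [OrfLocation("c1", 1, 300, "+", "orfA")]
        assert assign_reads_to_orfs(reads, orfs) == {}

    def test_overlap_tie_goes_to_smaller_start(self):
        # read [100,199] overlaps both ORFs by 100
        reads = [ReadAlignment("r1", "c1", 100, 199)]
        orfs = [
            OrfLocation("c1", 90, 199, "+", "late"),
            OrfLocation("c1", 50, 199, "+", "early"),
        ]
        assert assign_reads_to_orfs(reads, orfs) == {"early": 1}


class TestFunctionTable:
    def test_counts_sum_reads_per_ko(self):
        table = build_function_table(
            {"o1": "K03695", "o2": "K03695"}, {"S1": {"o1": 5, "o2": 5}}
        )
        assert table.counts.loc["S1", "K03695"] == 10
        assert table.relative.loc["S1", "K03695"] == 1.0

    def test_multi_category_ko_contributes_to_each(self):
        table = build_function_table(
            {"o1": "K1"},
            {"S1": {"o1": 10}},
            ko2categories={"K1": {"catA", "catB"}},
        )
        assert table.category_counts.loc["S1", "catA"] == 10
        assert table.category_counts.loc["S1", "catB"] == 10
        assert table.category_counts.loc["S1"].sum() >= table.counts.loc["S1"].sum()

    def test_unknown_ko_counted_under_unmapped(self):
        table = build_function_table({"o1": "K1"}, {"S1": {"o1": 3}}, ko2categories={})
        assert table.category_counts.loc["S1", "unmapped"] == 3

    def test_unannotated_orf_reads_dropped_and_logged(self):
        table = build_function_table({"o1": "K1"}, {"S1": {"o1": 2, "ghost": 7}})
        assert table.dropped_reads["S1"] == 7
        assert table.counts.loc["S1"].sum() == 2

    def test_relative_rows_sum_to_one(self):
        table = build_function_table(
            {"o1": "K1", "o2": "K2", "o3": "K3"},
            {"S1": {"o1": 3, "o2": 5, "o3": 2}, "S2": {"o1": 1}},
        )
        assert np.allclose(table.relative.sum(axis=1), 1.0)

    def test_relative_scale_invariant(self):
        orf2ko = {"o1": "K1", "o2": "K2"}
        base = build_function_table(orf2ko, {"S1": {"o1": 3, "o2": 9}})
        doubled = build_function_table(orf2ko, {"S1": {"o1": 6, "o2": 18}})
        assert base.relative.equals(doubled.relative)


class TestFilterTaxa:
    @pytest.mark.parametrize(
        "counts, kept",
        [
            ((11, 11, 0), True),
            ((10, 10, 10), False),  # "more than 10" is strict
            ((100, 0, 0), False),  # only one qualifying sample
            ((11, 0, 12), True),
        ],
    )
    def test_rule_examples(self, counts, kept):
        df = pd.DataFrame([counts], index=["taxon"], columns=["s1", "s2", "s3"])
        assert ("taxon" in filter_taxa(df).index) is kept

    @given(
        arrays(
            dtype=np.int64,
            shape=st.tuples(st.integers(1, 8), st.integers(2, 6)),
            elements=st.integers(0, 30),
        )
    )
    def test_matches_bruteforce_scan(self, values):
        df = pd.DataFrame(values)
        expected = [i for i in df.index if sum(1 for v in values[i] if v > 10) >= 2]
        assert list(filter_taxa(df).index) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            filter_taxa(pd.DataFrame([[-1, 5]]))


class TestPipelineConservation:
    def _pipeline_counts(self, hits_df, locs_df, reads_df):
        """Run the full profiling path on generated tables."""
        hits = [
            HmmerHit(r.orf_id, r.ko, r.evalue, r.bitscore)
            for r in hits_df.itertuples(index=False)
        ]
        orf2ko = best_annotation_per_orf(hits)
        orfs = [
            OrfLocation(r.contig, r.start, r.end, r.strand, r.orf_id)
            for r in locs_df.itertuples(index=False)
        ]
        per_sample = {}
        for sample, grp in reads_df.groupby("sample"):
            per_sample[sample] = assign_reads_to_orfs(
                reads_from_frame(grp[["read_id", "contig", "start", "end"]]), orfs
            )
        return build_function_table(orf2ko, per_sample), orf2ko

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_bruteforce_recount(self, reference, seed):
        specs = [FamilySpec("f1", n_orfs=8, motif_mismatches=0, flank_identity=0.9)]
        records, _, _ = make_orf_population(reference, specs, seed=seed)
        tables = make_metagenome(
            records, reads_per_orf=lambda rng: int(rng.integers(0, 8)),
            n_decoy_orfs=3, seed=seed, n_samples=2,
        )
        hits_df, locs_df, reads_df, truth = tables
        table, _ = self._pipeline_counts(hits_df, locs_df, reads_df)
        recount = recount_reads_per_ko(hits_df, locs_df, reads_df)
        for sample in table.counts.index:
            for ko in table.counts.columns:
                assert table.counts.loc[sample, ko] == recount.get(sample, {}).get(ko, 0)

    def test_target_ko_counts_equal_generator_truth(self, reference):
        specs = [FamilySpec("f1", n_orfs=10, motif_mismatches=0, flank_identity=1.0)]
        records, _, _ = make_orf_population(reference, specs, seed=11)
        hits_df, locs_df, reads_df, truth = make_metagenome(
            records, reads_per_orf=4, n_decoy_orfs=2, seed=11, n_samples=3
        )
        table, _ = self._pipeline_counts(hits_df, locs_df, reads_df)
        for sample, per_ko in truth.reads_per_ko.items():
            for ko, expected in per_ko.items():
                assert table.counts.loc[sample, ko] == expected
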