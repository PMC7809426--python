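import math

import numpy as np
import pandas as pd
import pytest

from meliflora import assign
from meliflora.assign import (
    ASSIGNED,
    EXCLUDED_CROSS_CLADE,
    EXCLUDED_LOW_SCORE,
    HIT_COLUMNS,
    NO_HIT,
    DEFAULT_SCORING,
    align_queries,
    assign_queries,
    combine_markers,
    consensus_assign,
    filter_low_scores,
    read_hit_table,
    tabulate_counts,
    write_hit_table,
)


def hits_df(rows):
    """rows: (query, subject, bit_score)"""
    return pd.DataFrame(
        [(q, s, 100.0, 100, b) for q, s, b in rows], columns=HIT_COLUMNS
    )


def oracle_consensus(tied_taxa, taxonomy):
    """Brute-force taxonomy walk over the tied-top subject set."""
    lineages = [taxonomy.lineage(t) for t in tied_taxa]
    if len({lin["species"] for lin in lineages}) == 1:
        return lineages[0]["species"], "species"
    if len({lin["genus"] for lin in lineages}) == 1:
        return lineages[0]["genus"], "genus"
    if len({lin["family"] for lin in lineages}) == 1:
        return lineages[0]["family"], "family"
    return None, None


class TestAligner:
    def test_exact_match_is_strict_maximum(self, small_db):
        refs = small_db.marker_sequences("rbcL")
        t0 = small_db.taxon_ids[0]
        hits = align_queries({"q": refs[t0]}, refs)
        best = hits.sort_values("bit_score", ascending=False)
        assert best.iloc[0]["subject_id"] == t0
        assert best.iloc[0]["bit_score"] > best.iloc[1]["bit_score"]

    def test_single_mismatch_scores_strictly_lower(self, small_db):
        refs = small_db.marker_sequences("rbcL")
        t0 = small_db.taxon_ids[0]
        seq = refs[t0]
        mutated = ("A" if seq[0] != "A" else "C") + seq[1:]
        hits = align_queries({"exact": seq, "mut": mutated}, {t0: seq})
        exact = hits[hits.query_id == "exact"]["bit_score"].iloc[0]
        mut = hits[hits.query_id == "mut"]["bit_score"].iloc[0]
        assert mut < exact

    def test_bits_match_hand_computed_closed_form(self):
        """15-bp exact match: S = 15*2 = 30, bits = (lam*S - ln K)/ln 2."""
        seq = "ACGTACGTACGTACG"
        hits = align_queries({"q": seq}, {"r": seq})
        expected = (0.625 * 30 - math.log(0.41)) / math.log(2)
        assert hits["bit_score"].iloc[0] == pytest.approx(expected, abs=1e-9)
        assert hits["pident"].iloc[0] == 100.0

    def test_ambiguous_query_skipped(self, small_db):
        refs = small_db.marker_sequences("rbcL")
        hits = align_queries({"q": "N" * 200}, refs)
        assert hits.empty

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_queries({"q": "ACGT"}, {})


class TestHitTableIO:
    def test_round_trip(self, tmp_path):
        hits = hits_df([("q1", "x0", 505.0), ("q1", "x1", 400.0), ("q2", "x2", 33.5)])
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        again = read_hit_table(path)
        pd.testing.assert_frame_equal(again[HIT_COLUMNS], hits, check_dtype=False)

    def test_bit_score_parsed_as_float(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("q1\tx0\t99.5\t450\t2\t0\t1\t450\t1\t450\t1e-100\t505.0\n")
        hits = read_hit_table(path)
        assert hits["bit_score"].iloc[0] == 505.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("")
        assert read_hit_table(path).empty

    def test_unresolvable_subject_dropped(self, tmp_path, flat_taxonomy):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\tx0\t99\t450\t0\t0\t1\t450\t1\t450\t0\t500\n"
            "q1\tzz\t99\t450\t0\t0\t1\t450\t1\t450\t0\t499\n"
        )
        hits = read_hit_table(path, flat_taxonomy)
        assert list(hits["subject_id"]) == ["x0"]


class TestLowScoreFilter:
    def test_first_percentile_excludes_lowest_of_100(self):
        hits = hits_df([(f"q{i}", "x0", float(i)) for i in range(1, 101)])
        kept, excluded = filter_low_scores(hits, 0.01)
        # sort-and-threshold oracle: 1st percentile of 1..100 lies above 1
        best = sorted(float(b) for b in hits["bit_score"])
        thr = np.quantile(best, 0.01)
        assert excluded == {f"q{i}" for i in range(1, 101) if i < thr} == {"q1"}
        assert len(kept) == 99

    def test_all_equal_scores_nothing_excluded(self):
        hits = hits_df([(f"q{i}", "x0", 50.0) for i in range(10)])
        kept, excluded = filter_low_scores(hits, 0.01)
        assert not excluded and len(kept) == 10

    def test_empty_table(self):
        kept, excluded = filter_low_scores(hits_df([]), 0.01)
        assert kept.empty and not excluded

    def test_percentile_uses_best_score_per_query(self):
        # q1 has a low secondary hit but a high best: must not be excluded
        hits = hits_df(
            [("q1", "x0", 100.0), ("q1", "x1", 1.0)]
            + [(f"q{i}", "x0", 50.0) for i in range(2, 102)]
        )
        _, excluded = filter_low_scores(hits, 0.01)
        assert "q1" not in excluded


class TestConsensus:
    def test_single_species_tie(self, flat_taxonomy):
        a = consensus_assign(hits_df([("q", "x0", 500), ("q", "x0", 500)]), flat_taxonomy)
        assert (a.status, a.rank, a.name) == (ASSIGNED, "species", "G0 s0")

    def test_two_species_one_genus(self, flat_taxonomy):
        a = consensus_assign(hits_df([("q", "x0", 500), ("q", "x1", 500)]), flat_taxonomy)
        assert (a.status, a.rank, a.name) == (ASSIGNED, "genus", "G0")

    def test_two_genera_one_family(self, flat_taxonomy):
        a = consensus_assign(hits_df([("q", "x0", 500), ("q", "x2", 500)]), flat_taxonomy)
        assert (a.status, a.rank, a.name) == (ASSIGNED, "family", "F0")

    def test_cross_family_tie_excluded(self, flat_taxonomy):
        a = consensus_assign(hits_df([("q", "x0", 500), ("q", "x4", 500)]), flat_taxonomy)
        assert a.status == EXCLUDED_CROSS_CLADE and a.rank is None

    def test_no_hits(self, flat_taxonomy):
        a = consensus_assign(hits_df([]), flat_taxonomy)
        assert a.status == NO_HIT

    def test_lower_scored_hits_ignored(self, flat_taxonomy):
        # a sub-maximal cross-family hit must not coarsen the rank
        a = consensus_assign(
            hits_df([("q", "x0", 500), ("q", "x4", 499.9)]), flat_taxonomy
        )
        assert (a.status, a.rank) == (ASSIGNED, "species")

    def test_tolerance_window_widens_tied_set(self, flat_taxonomy):
        a = consensus_assign(
            hits_df([("q", "x0", 500), ("q", "x1", 499.9)]), flat_taxonomy,
            top_bits_tolerance=0.5,
        )
        assert (a.status, a.rank) == (ASSIGNED, "genus")

    def test_matches_oracle_on_randomized_hit_tables(self, flat_taxonomy, rng):
        for _ in range(100):
            n = int(rng.integers(1, 6))
            subjects = rng.choice(flat_taxonomy.taxon_ids, size=n)
            scores = rng.choice([500.0, 499.0, 498.0], size=n)
            hits = hits_df([("q", s, b) for s, b in zip(subjects, scores)])
            a = consensus_assign(hits, flat_taxonomy)
            tied = {s for s, b in zip(subjects, scores) if b == scores.max()}
            name, rank = oracle_consensus(tied, flat_taxonomy)
            if name is None:
                assert a.status == EXCLUDED_CROSS_CLADE
            else:
                assert (a.name, a.rank) == (name, rank)

    def test_rank_coarsening_is_monotone(self, flat_taxonomy, rng):
        """Adding a tied top hit never yields a finer rank."""
        order = {"species": 0, "genus": 1, "family": 2, None: 3}
        for _ in range(50):
            n = int(rng.integers(1, 5))
            subjects = list(rng.choice(flat_taxonomy.taxon_ids, size=n))
            base = consensus_assign(
                hits_df([("q", s, 500.0) for s in subjects]), flat_taxonomy
            )
            extra = str(rng.choice(flat_taxonomy.taxon_ids))
            more = consensus_assign(
                hits_df([("q", s, 500.0) for s in subjects + [extra]]), flat_taxonomy
            )
            assert order[more.rank] >= order[base.rank]


class TestTabulateCombine:
    def test_counts_routed_to_assigned_taxon(self, flat_taxonomy):
        asg = assign_queries(hits_df([("u1", "x0", 500)]), flat_taxonomy)
        counts = pd.DataFrame({"S": [5]}, index=pd.Index(["u1"], name="query_id"))
        layer, totals = tabulate_counts(asg, counts)
        assert layer.at["S", "G0 s0"] == 5
        assert totals[ASSIGNED] == 5

    def test_same_taxon_queries_summed(self, flat_taxonomy):
        asg = assign_queries(
            hits_df([("u1", "x0", 500), ("u1", "x1", 500),
                     ("u2", "x0", 500), ("u2", "x1", 500)]),
            flat_taxonomy,
        )
        counts = pd.DataFrame({"S": [3, 4]}, index=pd.Index(["u1", "u2"], name="query_id"))
        layer, _ = tabulate_counts(asg, counts)
        assert layer.at["S", "G0"] == 7

    def test_status_totals_conserve_input_counts(self, flat_taxonomy, rng):
        rows = []
        for i in range(120):
            subj = str(rng.choice(flat_taxonomy.taxon_ids))
            rows.append((f"u{i}", subj, float(rng.choice([500, 400, 3]))))
        hits = hits_df(rows)
        qids = [f"u{i}" for i in range(150)]  # 30 queries with no hits
        asg = assign_queries(hits, flat_taxonomy, all_query_ids=qids)
        counts = pd.DataFrame(
            rng.integers(0, 10, size=(150, 3)), index=pd.Index(qids, name="query_id"),
            columns=["s1", "s2", "s3"],
        )
        _, totals = tabulate_counts(asg, counts)
        assert totals.sum() == counts.to_numpy().sum()

    def test_combine_markers_sums_cells(self):
        rbcl = pd.DataFrame({"Rubus": [100]}, index=["S1"])
        its2 = pd.DataFrame({"Rubus": [50]}, index=["S1"])
        combined = combine_markers(rbcl, its2)
        assert combined.at["S1", "Rubus"] == 150

    def test_marker_exclusive_taxon_carried_through(self):
        rbcl = pd.DataFrame({"Rubus": [100]}, index=["S1"])
        its2 = pd.DataFrame({"Trifolium": [50]}, index=["S1"])
        combined = combine_markers(rbcl, its2)
        assert combined.at["S1", "Rubus"] == 100
        assert combined.at["S1", "Trifolium"] == 50

    def test_empty_layers(self):
        empty = pd.DataFrame(index=["S1"])
        assert combine_markers(empty, empty).empty

    def test_sample_axis_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample axis"):
            combine_markers(
                pd.DataFrame({"A": [1]}, index=["S1"]),
                pd.DataFrame({"A": [1]}, index=["S2"]),
            )


class TestEndToEndAssignment:
    def test_error_free_reads_assigned_to_true_species(self, small_db):
        """>=99% of error-free merged reads identified at species rank."""
        from meliflora.simulate.communities import TrueComposition
        from meliflora.pipeline import simulate_and_run

        taxa = small_db.taxon_ids
        comps = [
            TrueComposition(f"s{i}", 6, 2017, {t: 1 / len(taxa) for t in taxa})
            for i in range(2)
        ]
        res = simulate_and_run(small_db, comps, n_pairs=400,
                               substitution_rate=0.0, seed=3)
        for marker, asg in res.assignments.items():
            assigned = asg[asg["status"] == ASSIGNED]
            assert (assigned["rank"] == "species").mean() >= 0.99
        # every count lands on the true species name
        total = res.combined.to_numpy().sum()
        assert total > 0
        for t in taxa:
            name = small_db.taxonomy.rank_of(t, "species")
            assert res.combined[name].sum() > 0

    def test_sister_species_tie_lands_at_genus(self, flat_taxonomy):
        """Two tied references from sister species -> genus rank, always."""
        for i in range(0, 8, 2):
            a = consensus_assign(
                hits_df([("q", f"x{i}", 500.0), ("q", f"x{i+1}", 500.0)]),
                flat_taxonomy,
            )
            assert (a.status, a.rank) == (ASSIGNED, "genus")
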