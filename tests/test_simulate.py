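import numpy as np
import pytest

from meliflora.profiles import AbundanceClass
from meliflora.readproc import merge_pair
from meliflora.seqdata import array_to_seq, revcomp
from meliflora.simulate import (
    expected_proportions,
    generate_reference_db,
    simulate_communities,
    simulate_landscape,
    simulate_pollen_counts,
    simulate_reads,
)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestReferenceDB:
    def test_count_bookkeeping(self):
        db = generate_reference_db(n_taxa=20, species_per_genus=2, seq_length=500, seed=1)
        assert len(db.sequences) == 40  # 20 taxa x 2 markers
        assert db.taxonomy.table["genus"].nunique() == 10

    def test_chain_taxonomy_degenerate_shape(self):
        db = generate_reference_db(
            n_taxa=2, species_per_genus=1, genera_per_family=1,
            families_per_clade=1, seed=7,
        )
        t = db.taxonomy.table
        # chain shape: every rank has as many groups as species
        assert all(t[r].nunique() == 2 for r in ("species", "genus", "family", "clade"))

    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        fastas = []
        for _ in range(2):
            db = generate_reference_db(n_taxa=6, seed=42)
            buf = tmp_path / f"{len(fastas)}.fasta"
            db.to_fasta(buf)
            fastas.append(buf.read_bytes())
        assert fastas[0] == fastas[1]

    def test_identity_ordering_within_vs_between_genus(self):
        db = generate_reference_db(n_taxa=8, seq_length=500, seed=3)
        seqs = db.marker_sequences("rbcL")
        tax = db.taxonomy
        within, between = [], []
        ids = list(seqs)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                ident = _identity(seqs[a], seqs[b])
                if tax.rank_of(a, "genus") == tax.rank_of(b, "genus"):
                    within.append(ident)
                else:
                    between.append(ident)
        assert min(within) > max(between)

    def test_non_nestable_shape_rejected(self):
        with pytest.raises(ValueError, match="nestable"):
            generate_reference_db(n_taxa=10, species_per_genus=2, n_genera=3, seed=0)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_reference_db(n_taxa=1, seed=0)
        with pytest.raises(ValueError):
            generate_reference_db(n_taxa=5, seq_length=50, seed=0)


class TestCommunities:
    def test_simplex_validity(self, small_db, small_communities):
        comps, _ = small_communities
        for c in comps:
            assert abs(sum(c.proportions.values()) - 1) < 1e-9
            assert all(p >= 0 for p in c.proportions.values())

    def test_high_concentration_uniform_seasonality_limit(self, small_db):
        season = {t: (7.0, 2.0) for t in small_db.taxon_ids}
        comps, _ = simulate_communities(
            5, small_db.taxon_ids, seasonality=season, concentration=1e7, seed=3
        )
        for c in comps:
            assert np.allclose(list(c.proportions.values()), 1 / 8, atol=1e-3)

    def test_single_taxon_weight(self, small_db):
        weights = {t: 0.0 for t in small_db.taxon_ids}
        weights[small_db.taxon_ids[0]] = 1.0
        comps, _ = simulate_communities(
            3, small_db.taxon_ids, base_weights=weights, seed=4
        )
        for c in comps:
            assert c.proportions[small_db.taxon_ids[0]] == pytest.approx(1.0)

    def test_mean_matches_analytic_expectation(self, small_db):
        """Dirichlet mean = seasonal weights, checked over 100 samples."""
        season = {t: (float(4 + i % 7), 1.5) for i, t in enumerate(small_db.taxon_ids)}
        conc = 30.0
        comps, _ = simulate_communities(
            100, small_db.taxon_ids, months=[6], seasonality=season,
            concentration=conc, seed=5,
        )
        expected = expected_proportions(small_db.taxon_ids, 6, season)
        observed = np.array(
            [[c.proportions[t] for t in small_db.taxon_ids] for c in comps]
        )
        # Dirichlet component variance: m(1-m)/(conc+1)
        se = np.sqrt(expected * (1 - expected) / (conc + 1) / 100)
        assert np.all(np.abs(observed.mean(0) - expected) <= 3 * se + 1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_communities(3, [], seed=0)

    def test_months_outside_season_rejected(self, small_db):
        with pytest.raises(ValueError, match="month"):
            simulate_communities(3, small_db.taxon_ids, months=[2, 3], seed=0)


class TestReads:
    def test_error_free_reads_reassemble_amplicon(self, small_db, small_communities):
        comps, _ = small_communities
        reads = simulate_reads(comps[0], small_db, n_pairs=50,
                               read_length=300, substitution_rate=0.0, seed=6)
        batch = reads["rbcL"]
        for i in range(len(batch)):
            amplicon = small_db.sequence(batch.source_taxon[i], "rbcL")
            res = merge_pair(
                array_to_seq(batch.fwd[i]), batch.fwd_qual[i],
                array_to_seq(batch.rev[i]), batch.rev_qual[i],
            )
            assert res.sequence == amplicon

    def test_pure_composition_gives_single_source(self, small_db):
        from meliflora.simulate.communities import TrueComposition

        t0 = small_db.taxon_ids[0]
        comp = TrueComposition("s", 6, 2017, {t0: 1.0})
        reads = simulate_reads(comp, small_db, n_pairs=200, seed=7)
        for batch in reads.values():
            assert set(batch.source_taxon) == {t0}
            assert len(batch) == 200  # n_pairs conserved

    def test_marker_bias_shifts_read_fractions(self, small_db):
        from meliflora.simulate.communities import TrueComposition

        a, b = small_db.taxon_ids[:2]
        comp = TrueComposition("s", 6, 2017, {a: 0.5, b: 0.5})
        n = 10000
        reads = simulate_reads(
            comp, small_db, n_pairs=n, marker_bias={"rbcL": {a: 2.0, b: 1.0}}, seed=8
        )
        frac_a = sum(t == a for t in reads["rbcL"].source_taxon) / n
        se = np.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(frac_a - 2 / 3) <= 3 * se
        # ITS2 unbiased
        frac_a_its = sum(t == a for t in reads["ITS2"].source_taxon) / n
        assert abs(frac_a_its - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_zero_pairs_is_valid_empty(self, small_db, small_communities):
        comps, _ = small_communities
        reads = simulate_reads(comps[0], small_db, n_pairs=0, seed=9)
        assert all(len(b) == 0 for b in reads.values())

    def test_source_label_collapse_commutes_with_count_collapse(
        self, small_db, small_communities
    ):
        """Aggregating read sources to genus = aggregating taxon counts."""
        comps, _ = small_communities
        reads = simulate_reads(comps[0], small_db, n_pairs=500, seed=10)
        batch = reads["rbcL"]
        by_taxon: dict[str, int] = {}
        for t in batch.source_taxon:
            by_taxon[t] = by_taxon.get(t, 0) + 1
        by_genus_direct: dict[str, int] = {}
        for t in batch.source_taxon:
            g = small_db.taxonomy.rank_of(t, "genus")
            by_genus_direct[g] = by_genus_direct.get(g, 0) + 1
        by_genus_from_counts: dict[str, int] = {}
        for t, k in by_taxon.items():
            g = small_db.taxonomy.rank_of(t, "genus")
            by_genus_from_counts[g] = by_genus_from_counts.get(g, 0) + k
        assert by_genus_direct == by_genus_from_counts

    def test_bad_substitution_rate_rejected(self, small_db, small_communities):
        comps, _ = small_communities
        with pytest.raises(ValueError):
            simulate_reads(comps[0], small_db, n_pairs=5, substitution_rate=0.3, seed=0)


class TestPollen:
    def test_pure_sample_is_predominant(self, small_db):
        from meliflora.simulate.communities import TrueComposition

        t0 = small_db.taxon_ids[0]
        comp = TrueComposition("s", 6, 1952, {t0: 1.0})
        rec = simulate_pollen_counts(comp, small_db.taxonomy, seed=1)
        genus = small_db.taxonomy.rank_of(t0, "genus")
        assert rec.counts == {genus: 200}
        assert rec.classes == {genus: AbundanceClass.PREDOMINANT.value}

    def test_congeners_collapse_to_one_genus_count(self, small_db):
        from meliflora.simulate.communities import TrueComposition

        a, b = small_db.taxon_ids[:2]  # same genus by construction
        assert small_db.taxonomy.rank_of(a, "genus") == small_db.taxonomy.rank_of(b, "genus")
        comp = TrueComposition("s", 6, 1952, {a: 0.5, b: 0.5})
        rec = simulate_pollen_counts(comp, small_db.taxonomy, seed=2)
        assert len(rec.counts) == 1
        assert rec.n_grains == 200

    def test_multinomial_expectation_over_seeds(self, small_db):
        from meliflora.simulate.communities import TrueComposition

        a, c = small_db.taxon_ids[0], small_db.taxon_ids[2]  # different genera
        comp = TrueComposition("s", 6, 1952, {a: 0.3, c: 0.7})
        ga = small_db.taxonomy.rank_of(a, "genus")
        n_seeds, n_grains = 500, 200
        mean_a = np.mean(
            [
                simulate_pollen_counts(comp, small_db.taxonomy, seed=s).counts.get(ga, 0)
                for s in range(n_seeds)
            ]
        )
        se = np.sqrt(n_grains * 0.3 * 0.7 / n_seeds)
        assert abs(mean_a - n_grains * 0.3) <= 3 * se

    def test_unknown_rank_rejected(self, small_db, small_communities):
        comps, _ = small_communities
        with pytest.raises(ValueError, match="rank"):
            simulate_pollen_counts(comps[0], small_db.taxonomy, id_rank="order", seed=0)


class TestLandscape:
    def test_single_habitat(self):
        grid, _ = simulate_landscape(10, 1, {"grass": 1.0}, seed=1)
        assert (grid.cells["habitat"] == "grass").all()

    def test_quota_fractions_exact_to_one_cell(self):
        palette = {"grass": 0.4, "arable": 0.35, "wood": 0.25}
        grid, _ = simulate_landscape(50, 0.5, palette, seed=2)  # 100x100 cells
        frac = grid.habitat_fractions()
        for hab, target in palette.items():
            assert abs(frac[hab] - target) < 1e-4  # quota is exact to 1/10000

    def test_crop_circle_area_matches_enumeration(self):
        r = 3.0
        grid, _ = simulate_landscape(
            20, 0.25, {"grass": 1.0}, crop_fields=[("beans", (10, 10), r)], seed=3
        )
        flagged = int(grid.cells["crop_beans"].sum())
        # enumeration oracle: count cell centers inside the circle
        oracle = sum(
            1
            for x in (np.arange(80) + 0.5) * 0.25
            for y in (np.arange(80) + 0.5) * 0.25
            if (x - 10) ** 2 + (y - 10) ** 2 <= r**2
        )
        assert flagged == oracle
        assert abs(flagged - np.pi * r**2 / 0.25**2) / oracle < 0.02

    def test_seed_determinism(self):
        g1, h1 = simulate_landscape(10, 1, {"a": 0.5, "b": 0.5}, n_hives=5, seed=9)
        g2, h2 = simulate_landscape(10, 1, {"a": 0.5, "b": 0.5}, n_hives=5, seed=9)
        assert g1.cells.equals(g2.cells)
        assert h1.equals(h2)

    def test_resolution_must_divide_extent(self):
        with pytest.raises(ValueError, match="divide"):
            simulate_landscape(10, 3, {"a": 1.0}, seed=0)
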