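import numpy as np
import pandas as pd
import pytest

import habflux as hf
from habflux.core_io import GuildRecord, TaxonomyRecord
from habflux.migration import HabitatPair, MigrationCall


def _pair_table(side_a, side_b, taxa=None):
    """Build a two-habitat table from per-side count blocks (taxa x samples)."""
    side_a, side_b = np.atleast_2d(side_a), np.atleast_2d(side_b)
    n_taxa = side_a.shape[0]
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    ids_a = [f"soil_{j}" for j in range(side_a.shape[1])]
    ids_b = [f"water_{j}" for j in range(side_b.shape[1])]
    table = hf.FeatureTable(taxa, ids_a + ids_b, np.hstack([side_a, side_b]))
    pair = HabitatPair("soil", "water", tuple(ids_a), tuple(ids_b))
    rows = ([{"sample_id": s, "habitat": "soil", "park": "P1", "replicate": 1,
              "region": "V4"} for s in ids_a]
            + [{"sample_id": s, "habitat": "water", "park": "P1", "replicate": 1,
                "region": "V4"} for s in ids_b])
    return table, hf.SampleMetadata(pd.DataFrame(rows)), pair


class TestHabitatPairs:
    def test_full_design_yields_ten_pairs(self, small_scenario):
        _, metadata, *_ = small_scenario
        pairs = hf.habitat_pairs(metadata)
        assert len(pairs) == 10
        assert all(p.habitat_a < p.habitat_b for p in pairs)

    def test_identical_habitats_rejected(self):
        with pytest.raises(ValueError):
            HabitatPair("soil", "soil", ("a",), ("b",))


class TestSharedPrevalentTaxa:
    def test_strict_majority_per_side(self):
        # taxon 0: present 10/18 both sides (> 0.5) -> kept
        # taxon 1: present 9/18 on one side (= 0.5, not >) -> dropped
        a = np.zeros((2, 18), dtype=int)
        b = np.zeros((2, 18), dtype=int)
        a[0, :10] = 1; b[0, :10] = 1
        a[1, :9] = 1;  b[1, :18] = 1
        table, metadata, pair = _pair_table(a, b)
        taxa = hf.shared_prevalent_taxa(table, metadata, pair)
        assert taxa == ["t0"]

    def test_pooled_mode(self):
        a = np.zeros((1, 4), dtype=int)
        b = np.zeros((1, 4), dtype=int)
        a[0, :4] = 1  # 4/8 pooled = 0.5, not > 0.5
        table, metadata, pair = _pair_table(a, b)
        assert hf.shared_prevalent_taxa(table, metadata, pair, mode="pooled") == []

    def test_raising_threshold_never_adds_taxa(self):
        rng = np.random.default_rng(0)
        a = (rng.random((40, 10)) < 0.6).astype(int)
        b = (rng.random((40, 10)) < 0.6).astype(int)
        table, metadata, pair = _pair_table(a, b)
        previous = None
        for prevalence in (0.3, 0.5, 0.7, 0.9):
            taxa = set(hf.shared_prevalent_taxa(table, metadata, pair,
                                                prevalence=prevalence))
            if previous is not None:
                assert taxa <= previous
            previous = taxa

    def test_empty_result_warns(self):
        table, metadata, pair = _pair_table(np.zeros((1, 3), int) + [[1, 0, 0]],
                                            np.ones((1, 3), int))
        with pytest.warns(UserWarning):
            assert hf.shared_prevalent_taxa(table, metadata, pair) == []


class TestBreadthShiftTest:
    def test_identical_sides_give_p_one(self):
        block = np.tile([[4, 3, 2, 1]], (8, 1))
        table, _, pair = _pair_table(block, block)
        with pytest.warns(UserWarning):
            p, frame = hf.breadth_shift_test(table, pair, list(table.taxon_ids))
        assert p == 1.0
        assert np.allclose(frame["B_a"], frame["B_b"])

    def test_systematic_breadth_shift_detected(self):
        # side a: each taxon concentrated in one sample (B ~ 1);
        # side b: spread evenly (B ~ n)
        rng = np.random.default_rng(1)
        n_taxa, n = 20, 8
        a = np.zeros((n_taxa, n), dtype=int)
        a[np.arange(n_taxa), rng.integers(0, n, n_taxa)] = 40
        b = np.full((n_taxa, n), 5, dtype=int)
        table, _, pair = _pair_table(a, b)
        p, frame = hf.breadth_shift_test(table, pair, list(table.taxon_ids))
        assert p < 0.05
        assert (frame["B_a"] < frame["B_b"]).all()

    def test_unscreened_taxa_excluded(self):
        block = np.tile([[4, 3, 2, 1]], (4, 1))
        table, _, pair = _pair_table(block, block * 2)
        with pytest.warns(UserWarning):
            _, frame = hf.breadth_shift_test(table, pair, ["t0", "t1"])
        assert list(frame.index) == ["t0", "t1"]


class TestCallMigrants:
    def test_identical_abundances_called_migrant(self):
        block = np.tile([[10, 20, 30, 40]], (3, 1))
        table, _, pair = _pair_table(block, block)
        calls = hf.call_migrants(table, pair, list(table.taxon_ids))
        assert all(c.migrant and c.p_value == 1.0 for c in calls)

    def test_strong_shift_called_non_migrant(self):
        # t0 shifts tenfold; t1 is a constant background so relative
        # abundances are informative
        rng = np.random.default_rng(2)
        a = np.vstack([rng.poisson(100, size=(1, 10)),
                       np.full((1, 10), 5000)])
        b = np.vstack([rng.poisson(1000, size=(1, 10)),
                       np.full((1, 10), 5000)])
        table, _, pair = _pair_table(a, b)
        calls = hf.call_migrants(table, pair, ["t0"])
        assert not calls[0].migrant
        assert calls[0].p_value < 0.01

    def test_raising_alpha_never_adds_migrants(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(50, size=(30, 10))
        b = rng.poisson(60, size=(30, 10))
        table, _, pair = _pair_table(a, b)
        taxa = list(table.taxon_ids)
        counts = []
        for alpha in (0.01, 0.05, 0.2, 0.5):
            calls = hf.call_migrants(table, pair, taxa, alpha=alpha)
            counts.append(sum(c.migrant for c in calls))
        assert counts == sorted(counts, reverse=True)

    def test_bh_correction_adds_migrants(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(50, size=(40, 10))
        b = rng.poisson(65, size=(40, 10))
        table, _, pair = _pair_table(a, b)
        taxa = list(table.taxon_ids)
        raw = sum(c.migrant for c in hf.call_migrants(table, pair, taxa))
        bh = sum(c.migrant for c in hf.call_migrants(table, pair, taxa,
                                                     correction="bh"))
        assert bh >= raw

    def test_operating_characteristics_on_planted_scenario(self):
        table, metadata, pair, migrants, shifted = hf.simulate_migration_pair(seed=0)
        taxa = hf.shared_prevalent_taxa(table, metadata, pair)
        calls = {c.taxon_id: c for c in hf.call_migrants(table, pair, taxa)}
        planted = [t for t in migrants if t in calls]
        shifted_called = [t for t in shifted if t in calls]
        sensitivity = np.mean([calls[t].migrant for t in planted])
        specificity = np.mean([not calls[t].migrant for t in shifted_called])
        # single-seed smoke bound; the tight multi-seed operating
        # characteristic lives in the acceptance suite
        assert sensitivity >= 0.8
        assert specificity >= 0.8


class TestSummaries:
    def _calls(self):
        return [
            MigrationCall("soil-water", "t1", 0.8, 0.01, 0.01, True),
            MigrationCall("soil-water", "t2", 0.6, 0.02, 0.02, True),
            MigrationCall("soil-water", "t3", 0.01, 0.10, 0.01, False),
        ]

    def test_supergroup_counts_conserve_migrants(self):
        taxonomy = {
            "t1": TaxonomyRecord("t1", ("Opisthokonta", "Fungi")),
            "t2": TaxonomyRecord("t2", ("Opisthokonta", "Metazoa")),
            "t3": TaxonomyRecord("t3", ("Rhizaria",)),
        }
        out = hf.summarize_migrants_by_supergroup(self._calls(), taxonomy)
        assert out["n_taxa"].sum() == 2  # only migrant calls counted
        assert set(out["supergroup"]) == {"Opisthokonta"}

    def test_missing_taxonomy_binned_unassigned(self):
        out = hf.summarize_migrants_by_supergroup(self._calls(), {})
        assert set(out["supergroup"]) == {"unassigned"}

    def test_guild_abundance_sums(self):
        taxonomy = {
            "t1": TaxonomyRecord("t1", ("Opisthokonta", "Fungi", "", "", "", "", "",
                                        "Aspergillus")),
            "t2": TaxonomyRecord("t2", ("Opisthokonta", "Fungi", "", "", "", "", "",
                                        "Unlisted")),
        }
        guilds = {"Aspergillus": GuildRecord("Aspergillus", "pathotroph")}
        out = hf.summarize_migrant_guilds(self._calls(), taxonomy, guilds)
        by_mode = out.set_index("trophic_mode")["summed_mean_rel"]
        assert by_mode["pathotroph"] == pytest.approx(0.01)
        assert by_mode["unassigned"] == pytest.approx(0.02)  # never dropped

    def test_non_fungi_excluded_from_guilds(self):
        taxonomy = {"t1": TaxonomyRecord("t1", ("Rhizaria",))}
        guilds = {"x": GuildRecord("x", "saprotroph")}
        out = hf.summarize_migrant_guilds(self._calls(), taxonomy, guilds)
        assert out.empty

    def test_empty_guild_db_rejected(self):
        with pytest.raises(ValueError):
            hf.summarize_migrant_guilds(self._calls(), {}, {})
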