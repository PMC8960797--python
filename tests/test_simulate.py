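"""The synthetic generator: seeded determinism, planted structure,
dropout model and the env-table effect controls."""

import numpy as np
import pytest
from scipy import stats

from traitatlas import (
    KOAnnotationTable,
    SyntheticSpec,
    ValidationError,
    classify_coherence,
    gen_env_tables,
    gen_ko_tables,
    gen_taxonomy,
    gen_trait_matrix,
    map_otus,
)
from traitatlas.modules import call_all, module_matrix
from traitatlas.simulate import make_module_definitions


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field, value",
        [("n_genomes", 0), ("n_traits", 0), ("block_trait_occupancy", 1.5),
         ("annotation_dropout", -0.1), ("taxon_concordance", 2.0)],
    )
    def test_invalid_field_named(self, field, value):
        with pytest.raises(ValidationError, match=field):
            SyntheticSpec(**{field: value})

    def test_blocks_bounded_by_items(self):
        with pytest.raises(ValidationError):
            SyntheticSpec(n_genomes=3, n_gfc_blocks=5)


class TestTraitMatrix:
    def test_seeded_determinism(self):
        spec = SyntheticSpec(n_genomes=30, n_traits=30, seed=7)
        m1, t1 = gen_trait_matrix(spec)
        m2, t2 = gen_trait_matrix(spec)
        assert np.array_equal(m1.values, m2.values)
        assert t1.genome_block == t2.genome_block

    def test_degenerate_probabilities_block_diagonal(self):
        spec = SyntheticSpec(
            n_genomes=20, n_traits=20, n_gfc_blocks=4, n_ltc_blocks=4,
            block_trait_occupancy=1.0, background_occupancy=0.0, seed=3,
        )
        m, truth = gen_trait_matrix(spec)
        frame = m.to_frame()
        for g in m.genomes:
            for t in m.traits:
                expected = truth.genome_block[g] == truth.trait_block[t] % 4
                assert bool(frame.loc[g, t]) is expected

    def test_every_item_assigned_once(self):
        m, truth = gen_trait_matrix(SyntheticSpec(n_genomes=25, n_traits=19, seed=1))
        assert set(truth.genome_block) == set(m.genomes)
        assert set(truth.trait_block) == set(m.traits)

    def test_within_block_prevalence_converges(self):
        spec = SyntheticSpec(
            n_genomes=200, n_traits=40, n_gfc_blocks=2, n_ltc_blocks=2,
            block_trait_occupancy=0.9, background_occupancy=0.05, seed=5,
        )
        m, truth = gen_trait_matrix(spec)
        frame = m.to_frame()
        for t in m.traits[:10]:
            carriers = [
                g for g in m.genomes
                if truth.genome_block[g] == truth.trait_block[t] % 2
            ]
            prev = frame.loc[carriers, t].mean()
            assert abs(prev - 0.9) <= 0.05  # binomial tail at n=100


class TestKOTables:
    def _matrix(self, seed=2):
        spec = SyntheticSpec(
            n_genomes=20, n_traits=20, n_gfc_blocks=2, n_ltc_blocks=2,
            block_trait_occupancy=1.0, background_occupancy=0.0, seed=seed,
        )
        return gen_trait_matrix(spec)

    def test_zero_dropout_round_trip(self):
        m, truth = self._matrix()
        module_traits = [
            t for t in m.traits if m.trait_meta.loc[t, "category"] == "kegg_module"
        ]
        defs = make_module_definitions(module_traits, seed=0)
        ko = gen_ko_tables(m, defs, dropout=0.0, seed=0)
        recon = module_matrix(call_all(defs, ko))
        frame = m.to_frame()
        for t in module_traits:
            mid = t.split(":", 1)[1]
            assert (recon[mid].reindex(frame.index).fillna(0)
                    == frame[t]).all(), t

    def test_full_dropout_two_reaction_module_never_reconstructed(self):
        m, _ = self._matrix()
        module_traits = [
            t for t in m.traits if m.trait_meta.loc[t, "category"] == "kegg_module"
        ]
        defs = make_module_definitions(
            module_traits, seed=0, n_reactions_range=(2, 2)
        )
        ko = gen_ko_tables(m, defs, dropout=1.0, seed=0)
        recon = module_matrix(call_all(defs, ko))
        assert (recon.to_numpy() == 0).all()

    def test_missing_definition_errors(self):
        m, _ = self._matrix()
        with pytest.raises(ValidationError, match="without definition"):
            gen_ko_tables(m, [], dropout=0.0)

    def test_dropout_prevalence_bound(self):
        """Reconstructed prevalence >= planted prevalence times the
        binomial probability that at most one of 8 singleton reactions is
        fully lost at 10% per-KO dropout (each reaction has 2 one-KO
        alternatives: loss prob 0.01)."""
        spec = SyntheticSpec(
            n_genomes=100, n_traits=10, n_gfc_blocks=1, n_ltc_blocks=1,
            block_trait_occupancy=1.0, background_occupancy=0.0, seed=9,
        )
        m, truth = gen_trait_matrix(spec)
        module_traits = [
            t for t in m.traits if m.trait_meta.loc[t, "category"] == "kegg_module"
        ]
        defs = make_module_definitions(
            module_traits, seed=1, n_reactions_range=(8, 8), complex_prob=0.0
        )
        ko = gen_ko_tables(m, defs, dropout=0.1, seed=2, truth=truth)
        recon = module_matrix(call_all(defs, ko))
        p_reaction_lost = 0.1 * 0.1
        p_ok = stats.binom.cdf(1, 8, p_reaction_lost)
        for t in module_traits:
            mid = t.split(":", 1)[1]
            planted_prev = m.to_frame()[t].mean()
            assert recon[mid].mean() >= planted_prev * p_ok - 0.1
        # gaps recorded exactly where reconstruction failed
        for g, t in truth.annotation_gaps:
            mid = t.split(":", 1)[1]
            assert recon.loc[g, mid] == 0


class TestTaxonomy:
    def test_full_concordance_gives_monophyletic_gfcs(self):
        spec = SyntheticSpec(
            n_genomes=24, n_traits=12, n_gfc_blocks=4, n_ltc_blocks=4, seed=3
        )
        _, truth = gen_trait_matrix(spec)
        records = gen_taxonomy(truth, concordance=1.0, seed=0)
        taxonomy = {r.genome_id: r.taxon_at("genus") for r in records}
        labels = classify_coherence(truth.genome_block, taxonomy)
        assert (labels["label"] == "monophyletic").all()

    def test_half_concordance_match_fraction(self):
        spec = SyntheticSpec(n_genomes=200, n_traits=10, n_gfc_blocks=4,
                             n_ltc_blocks=4, seed=4)
        _, truth = gen_trait_matrix(spec)
        records = gen_taxonomy(truth, concordance=0.5, seed=1)
        match = np.mean(
            [r.taxon_at("genus") == f"g_block{truth.genome_block[r.genome_id]}"
             for r in records]
        )
        assert 0.4 <= match <= 0.6  # binomial interval at n=200

    def test_rank_path_consistent(self):
        spec = SyntheticSpec(n_genomes=8, n_traits=8, n_gfc_blocks=4,
                             n_ltc_blocks=4, seed=5)
        _, truth = gen_trait_matrix(spec)
        records = gen_taxonomy(truth, concordance=1.0, seed=0)
        r1 = gen_taxonomy(truth, concordance=1.0, seed=0)
        assert records == r1  # seeded determinism
        for r in records:
            assert list(r.taxonomy) == ["domain", "phylum", "class", "order",
                                        "family", "genus"]


class TestEnvTables:
    def _truth(self):
        spec = SyntheticSpec(n_genomes=30, n_traits=10, n_gfc_blocks=3,
                             n_ltc_blocks=3, seed=6)
        _, truth = gen_trait_matrix(spec)
        return truth

    def test_zero_noise_all_specific(self):
        truth = self._truth()
        hits, _ = gen_env_tables(truth, n_otus=20, specificity_noise=0.0, seed=0)
        gfc = dict(truth.genome_block)
        mapping = map_otus(hits, gfc, threshold=97.0)
        assert (mapping["specificity_index"] == 1.0).all()
        assert mapping["mapped"].all()

    def test_planted_effect_separates_groups(self):
        truth = self._truth()
        _, pairs = gen_env_tables(
            truth, n_otus=40, effect_size=3.0, seed=1, n_pairs_per_group=50
        )
        same = pairs.loc[pairs["group"] == "same_gfc", "score"]
        diff = pairs.loc[pairs["group"] == "different_gfc", "score"]
        assert len(same) == len(diff) == 50
        assert same.mean() - diff.mean() > 2.0

    def test_seeded_determinism(self):
        truth = self._truth()
        h1, p1 = gen_env_tables(truth, n_otus=15, specificity_noise=0.2,
                                effect_size=1.0, seed=9)
        h2, p2 = gen_env_tables(truth, n_otus=15, specificity_noise=0.2,
                                effect_size=1.0, seed=9)
        assert h1.equals(h2) and p1.equals(p2)
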