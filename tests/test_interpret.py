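"""Coherence labels, LTC presence rules and categories, enrichment,
genome-size expectation and the sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from traitatlas import (
    PipelineConfig,
    TraitMatrix,
    ValidationError,
    classify_coherence,
    enrichment_test,
    ltc_presence,
    sensitivity_analysis,
    size_expectation,
)
from traitatlas.profiles import InteractionProfile


class TestCoherence:
    def _labels(self, assignment, taxonomy):
        df = classify_coherence(assignment, taxonomy)
        return dict(zip(df["gfc_id"], df["label"]))

    def test_monophyletic(self):
        assignment = {"a": 0, "b": 0, "c": 1}
        taxonomy = {"a": "X", "b": "X", "c": "Y"}
        assert self._labels(assignment, taxonomy) == {
            0: "monophyletic", 1: "monophyletic"
        }

    def test_paraphyletic(self):
        # GFC 0 holds 2 of genus X's 3 genomes and nothing else
        assignment = {"a": 0, "b": 0, "c": 1}
        taxonomy = {"a": "X", "b": "X", "c": "X"}
        labels = self._labels(assignment, taxonomy)
        assert labels[0] == "paraphyletic" and labels[1] == "paraphyletic"

    def test_polyphyletic(self):
        assignment = {"a": 0, "b": 0}
        taxonomy = {"a": "X", "b": "Y"}
        assert self._labels(assignment, taxonomy)[0] == "polyphyletic"

    def test_missing_taxon_excluded_with_warning(self):
        assignment = {"a": 0, "b": 0}
        with pytest.warns(UserWarning, match="lack a taxon"):
            df = classify_coherence(assignment, {"a": "X", "b": ""})
        assert df.loc[0, "label"] == "monophyletic"

    def test_relabel_invariance(self):
        assignment = {"a": 0, "b": 0, "c": 1, "d": 1}
        tax1 = {"a": "X", "b": "X", "c": "Y", "d": "Z"}
        tax2 = {k: {"X": "Q", "Y": "R", "Z": "S"}[v] for k, v in tax1.items()}
        assert self._labels(assignment, tax1) == self._labels(assignment, tax2)


class TestLTCPresence:
    def _setup(self, genome_rows, ltc_traits=4):
        traits = [f"kegg_module:T{j}" for j in range(ltc_traits)]
        m = TraitMatrix(
            np.array(genome_rows, dtype=np.int8),
            [f"g{i}" for i in range(len(genome_rows))], traits,
        )
        ltc = {t: 0 for t in traits}
        return m, ltc

    def test_strict_majority_rule_in_genome(self):
        # 3 of 4 traits -> present (75% > 50%); 2 of 4 -> absent
        m, ltc = self._setup([[1, 1, 1, 0], [1, 1, 0, 0]])
        gfc = {"g0": 0, "g1": 0}
        _, by_genome, _ = ltc_presence(m, ltc, gfc)
        assert bool(by_genome.loc["g0", 0]) is True
        assert bool(by_genome.loc["g1", 0]) is False

    def test_gfc_presence_rule(self):
        # LTC present in 6 of 10 grouped genomes -> present in the GFC
        rows = [[1, 1, 1, 1]] * 6 + [[0, 0, 0, 0]] * 4
        m, ltc = self._setup(rows)
        gfc = {f"g{i}": 0 for i in range(10)}
        _, _, by_gfc = ltc_presence(m, ltc, gfc)
        assert bool(by_gfc.loc[0, 0]) is True

    def test_half_is_not_enough_for_gfc(self):
        rows = [[1, 1, 1, 1]] * 5 + [[0, 0, 0, 0]] * 5
        m, ltc = self._setup(rows)
        gfc = {f"g{i}": 0 for i in range(10)}
        summary, _, by_gfc = ltc_presence(m, ltc, gfc)
        assert bool(by_gfc.loc[0, 0]) is False
        assert bool(summary.loc[0, "unclustered"]) is True

    @pytest.mark.parametrize(
        "presence, category",
        [(0.95, "core"), (0.9, "common"), (0.5, "common"), (0.3, "ancillary"),
         (0.31, "common"), (0.1, "ancillary")],
    )
    def test_category_boundaries(self, presence, category):
        n = 100
        k = int(round(presence * n))
        rows = [[1, 1, 1, 1]] * k + [[0, 0, 0, 0]] * (n - k)
        m, ltc = self._setup(rows)
        gfc = {f"g{i}": 0 for i in range(n)}
        summary, _, _ = ltc_presence(m, ltc, gfc)
        assert summary.loc[0, "genome_presence"] == pytest.approx(presence)
        assert summary.loc[0, "category"] == category

    def test_empty_ltc_errors(self):
        m, _ = self._setup([[1, 1, 1, 1]])
        with pytest.raises(ValidationError, match="no traits"):
            ltc_presence(m, {}, {"g0": 0})

    def test_mean_within_r_uses_raw_phi(self):
        col = np.array([1, 1, 0, 0], dtype=np.int8)
        m = TraitMatrix(
            np.column_stack([col, col, 1 - col]),
            [f"g{i}" for i in range(4)],
            ["kegg_module:A", "kegg_module:B", "kegg_module:C"],
        )
        ltc = {"kegg_module:A": 0, "kegg_module:B": 0, "kegg_module:C": 1}
        summary, _, _ = ltc_presence(m, ltc, {f"g{i}": 0 for i in range(4)})
        assert summary.loc[0, "mean_within_r"] == pytest.approx(1.0)
        # background mean includes the -1 correlations with trait C
        assert summary.attrs["mean_r_all_pairs"] < summary.loc[0, "mean_within_r"]


class TestEnrichment:
    def _flagged_matrix(self, rows):
        traits = [f"kegg_module:T{j}" for j in range(len(rows[0]))]
        meta = pd.DataFrame(
            {"category": "kegg_module", "interaction": True,
             "substrate": "", "role": ""},
            index=pd.Index(traits, name="trait_id"),
        )
        return TraitMatrix(
            np.array(rows, dtype=np.int8),
            [f"g{i}" for i in range(len(rows))], traits, meta,
        )

    def test_identical_genomes_flat_p(self):
        m = self._flagged_matrix([[1, 1, 0]] * 12)
        gfc = {f"g{i}": i % 3 for i in range(12)}
        res = enrichment_test(m, gfc, n_permutations=199, seed=0)
        assert (res["p"] == 1.0).all()

    def test_maximal_enrichment_floor_p(self):
        rows = [[1, 1, 1]] * 5 + [[0, 0, 0]] * 15
        m = self._flagged_matrix(rows)
        gfc = {f"g{i}": (0 if i < 5 else 1 + i % 3) for i in range(20)}
        res = enrichment_test(m, gfc, n_permutations=999, seed=1)
        assert res.loc[res["gfc_id"] == 0, "p"].iloc[0] == pytest.approx(1 / 1000)

    def test_planted_moderate_enrichment_detected(self):
        rng = np.random.default_rng(2)
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            # 5 flagged traits; enriched GFC (20 genomes) carries ~2 more
            n_bg, n_en = 80, 20
            bg = (rng.random((n_bg, 5)) < 0.3).astype(np.int8)
            en = (rng.random((n_en, 5)) < 0.7).astype(np.int8)
            m = self._flagged_matrix(np.vstack([en, bg]).tolist())
            gfc = {f"g{i}": (0 if i < n_en else 1 + i % 4) for i in range(100)}
            res = enrichment_test(m, gfc, n_permutations=999, seed=seed)
            if res.loc[res["gfc_id"] == 0, "p"].iloc[0] < 0.05:
                detected += 1
        assert detected >= 18

    def test_too_few_permutations_rejected(self):
        m = self._flagged_matrix([[1]] * 4)
        with pytest.raises(ValidationError):
            enrichment_test(m, {f"g{i}": 0 for i in range(4)}, n_permutations=10)


class TestSizeExpectation:
    def _profiles(self, sizes, counts):
        return [
            InteractionProfile(genome_id=f"g{i}", n_interaction_traits=c,
                               genome_size=s)
            for i, (s, c) in enumerate(zip(sizes, counts))
        ]

    def test_exact_line_zero_residuals(self):
        sizes = [1_000_000, 2_000_000, 3_000_000, 4_000_000]
        counts = [2, 4, 6, 8]
        per_genome, _ = size_expectation(
            self._profiles(sizes, counts), {}, n_permutations=199
        )
        assert np.allclose(per_genome["residual"], 0.0, atol=1e-9)

    def test_planted_offset_recovered(self):
        rng = np.random.default_rng(4)
        sizes = rng.uniform(2e6, 6e6, 50)
        counts = 1e-6 * sizes * 2 + rng.normal(0, 0.5, 50)
        taxon = np.array(["bg"] * 40 + ["up"] * 10)
        counts[taxon == "up"] += 3.0
        profiles = self._profiles(sizes.astype(int), counts)
        taxonomy = {f"g{i}": taxon[i] for i in range(50)}
        per_genome, per_taxon = size_expectation(
            profiles, taxonomy, n_permutations=499, seed=0
        )
        up = per_taxon.set_index("taxon").loc["up"]
        assert 2.0 <= up["mean_residual"] <= 4.0
        assert up["p"] < 0.05

    def test_slope_recovered_within_two_se(self):
        rng = np.random.default_rng(6)
        sizes = rng.uniform(2e6, 6e6, 80)
        true_slope = 3e-6
        counts = true_slope * sizes + rng.normal(0, 1.0, 80)
        per_genome, _ = size_expectation(
            self._profiles(sizes.astype(int), counts), {}, n_permutations=199
        )
        assert abs(per_genome.attrs["slope"] - true_slope) <= 2 * per_genome.attrs["stderr"]

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError, match=">= 3 genomes"):
            size_expectation(self._profiles([1e6], [1]), {})
        with pytest.raises(ValidationError, match="variance"):
            size_expectation(self._profiles([1e6] * 5, [1, 2, 3, 4, 5]), {})


class TestSensitivity:
    def test_noiseless_blocks_stable(self, small_dataset):
        data = small_dataset
        taxonomy = {
            g.genome_id: g.taxon_at("genus") for g in data.genomes
        }
        cfg = PipelineConfig(seed=0, overrepresented_frac=0.05)
        report = sensitivity_analysis(
            data.matrix, taxonomy, cfg, q_grid=(0.5,)
        )
        assert report["downsampling"], "all replicates skipped"
        for rep in report["downsampling"]:
            assert rep["ari_vs_full"] == pytest.approx(1.0)
        assert {r["fraction"] for r in report["downsampling"]} == {0.8, 0.6, 0.4}
        assert report["overrepresented_taxa"]  # every genus holds 25% here
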