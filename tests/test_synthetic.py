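"""Synthetic-data generator: determinism, planted effects, recovery."""

import numpy as np
import pandas as pd
import pytest

from glycoquant.pipeline import run_pipeline
from glycoquant.profiling import subtype_psm_fractions
from glycoquant.quant import compute_channel_factors
from glycoquant.synthetic import (
    SimConfig,
    default_composition_pool,
    evaluate_recovery,
    generate_catalog,
    simulate_experiment,
)


class TestConfig:
    def test_effect_fractions_must_sum_below_one(self):
        cfg = SimConfig(frac_common_up=0.6, frac_common_down=0.6)
        with pytest.raises(ValueError, match="> 1"):
            cfg.validate()

    def test_unknown_yaml_fields_named(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_glycoproteins: 5\nbogus_field: 1\n")
        with pytest.raises(ValueError, match="bogus_field"):
            SimConfig.from_yaml(path)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        cfg = SimConfig(n_glycoproteins=17, sigma_log2=0.1)
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        assert SimConfig.from_yaml(path) == cfg


class TestCatalog:
    def test_deterministic_per_seed(self):
        cfg = SimConfig(n_glycoproteins=30)
        a = generate_catalog(cfg, np.random.default_rng(1))
        b = generate_catalog(cfg, np.random.default_rng(1))
        pd.testing.assert_frame_equal(a, b)
        c = generate_catalog(cfg, np.random.default_rng(2))
        assert not a.equals(c)

    def test_degenerate_sizes(self):
        cfg = SimConfig(
            n_glycoproteins=10, mean_extra_sites=0.0, mean_extra_glycans=0.0
        )
        catalog = generate_catalog(cfg, np.random.default_rng(0))
        # exactly one site per protein, one glycan per site
        assert len(catalog) == 10
        assert catalog["protein"].nunique() == 10

    def test_pure_oligo_pool(self):
        cfg = SimConfig(
            n_glycoproteins=20, subtype_mass_fractions=(0.0, 1.0, 0.0)
        )
        catalog = generate_catalog(cfg, np.random.default_rng(0))
        assert (catalog["subtype"] == "oligo-mannose").all()
        assert catalog["glycan"].str.startswith("N2").all()

    def test_glycopeptide_ids_unique(self, default_sim):
        assert default_sim.catalog["glycopeptide_id"].is_unique

    def test_pool_weights_normalized(self):
        pool = default_composition_pool()
        assert pool["weight"].sum() == pytest.approx(1.0)
        assert (pool["weight"] > 0).all()

    def test_oligo_mannose_enriched_on_endomembrane_proteins(self):
        cfg = SimConfig(n_glycoproteins=400)
        catalog = generate_catalog(cfg, np.random.default_rng(5))
        frac = catalog.groupby("endomembrane")["subtype"].apply(
            lambda s: (s == "oligo-mannose").mean()
        )
        assert frac[True] > frac[False]


class TestSimulation:
    def test_full_determinism(self):
        cfg = SimConfig(n_glycoproteins=20)
        a = simulate_experiment(cfg, seed=9)
        b = simulate_experiment(cfg, seed=9)
        pd.testing.assert_frame_equal(a.glyco_psms, b.glyco_psms)
        pd.testing.assert_frame_equal(a.protein_psms, b.protein_psms)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_subtype_psm_mix_matches_targets(self, default_sim):
        """Default weights give ~59.8/29.1/11.1 complex/oligo/hybrid
        PSM percentages (within sampling tolerance)."""
        out = subtype_psm_fractions(default_sim.glyco_psms).set_index("subtype")
        assert out.loc["complex", "percent"] == pytest.approx(59.8, abs=3.0)
        assert out.loc["oligo-mannose", "percent"] == pytest.approx(29.1, abs=3.0)
        assert out.loc["hybrid", "percent"] == pytest.approx(11.1, abs=3.0)

    def test_noiseless_null_ratios_exactly_one(self, design):
        cfg = SimConfig(
            n_glycoproteins=30,
            sigma_log2=0.0,
            frac_common_up=0.0,
            frac_common_down=0.0,
            frac_low_unique=0.0,
            frac_high_unique=0.0,
            frac_protein_driven=0.0,
            frac_occupancy_shift=0.0,
        )
        sim = simulate_experiment(cfg, seed=2)
        res = run_pipeline(sim.glyco_psms, sim.protein_psms)
        for c in design.comparisons:
            assert np.allclose(res.calls[f"log2_{c}"], 0.0, atol=1e-9)

    def test_noiseless_effects_propagate_exactly(self, noiseless_sim,
                                                 noiseless_run, design):
        """With sigma=0 every quantified ratio equals its planted truth
        at glycopeptide, protein and occupancy level."""
        merged = noiseless_run.calls.merge(
            noiseless_sim.truth,
            left_on="feature_id",
            right_on="glycopeptide_id",
        )
        assert len(merged) == len(noiseless_run.calls)
        for c in design.comparisons:
            assert np.allclose(
                merged[f"log2_{c}"], merged[f"true_glyco_log2_{c}"], atol=1e-9
            )
            quantified = merged["parent_protein_quantified"]
            assert np.allclose(
                merged.loc[quantified, f"occ_log2_{c}"],
                merged.loc[quantified, f"true_occ_log2_{c}"],
                atol=1e-9,
            )

    def test_channel_loading_removed_by_normalization(self, design):
        """A 2x loading on one channel is fully absorbed: null ratios
        return to exactly 1 after normalization."""
        cfg = SimConfig(
            n_glycoproteins=20,
            sigma_log2=0.0,
            channel_loadings=(2.0, 1.0, 1.0, 1.0),
            frac_common_up=0.0,
            frac_common_down=0.0,
            frac_low_unique=0.0,
            frac_high_unique=0.0,
            frac_protein_driven=0.0,
            frac_occupancy_shift=0.0,
        )
        sim = simulate_experiment(cfg, seed=4)
        factors = compute_channel_factors(sim.protein_psms, design)
        # closed form: the scaled channel gets 2^(3/4), others 2^(-1/4)
        assert factors["126"] == pytest.approx(2 ** 0.75)
        assert factors["127N"] == pytest.approx(2 ** -0.25)
        res = run_pipeline(sim.glyco_psms, sim.protein_psms)
        for c in design.comparisons:
            assert np.allclose(res.calls[f"log2_{c}"], 0.0, atol=1e-9)

    def test_truth_labels_consistent_with_effects(self, default_sim, design):
        truth = default_sim.truth
        # protein-driven => zero occupancy effect everywhere
        pd_rows = truth[truth["label"] == "protein-driven"]
        occ_cols = [f"true_occ_log2_{c}" for c in design.comparisons]
        assert np.allclose(pd_rows[occ_cols], 0.0)
        # common-up => equal positive tumor/para effects in both groups
        up = truth[truth["label"] == "common-up"]
        assert (up["true_glyco_log2_tumorL_vs_paraL"] > 0).all()
        assert np.allclose(
            up["true_glyco_log2_tumorL_vs_paraL"],
            up["true_glyco_log2_tumorH_vs_paraH"],
        )
        # unique => change confined to one tumor group
        low = truth[truth["label"] == "lowAFP-unique"]
        assert (low["true_glyco_log2_tumorL_vs_tumorH"] > 0).all()
        assert np.allclose(low["true_glyco_log2_paraL_vs_paraH"], 0.0)


class TestRecovery:
    def test_perfect_calls_score_one(self, design):
        truth = pd.DataFrame(
            {
                "glycopeptide_id": ["a", "b", "c", "d"],
                "label": ["common-up", "common-down", "lowAFP-unique", "null"],
            }
        )
        calls = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c", "d"],
                "common_label": ["up", "down", "none", "none"],
                "unique_label": ["none", "none", "lowAFP-unique", "none"],
            }
        )
        rec = evaluate_recovery(calls, truth).set_index("label")
        for label in ("common-up", "common-down", "lowAFP-unique"):
            assert rec.loc[label, "precision"] == 1.0
            assert rec.loc[label, "recall"] == 1.0

    def test_no_calls_gives_zero_recall_na_precision(self):
        truth = pd.DataFrame(
            {"glycopeptide_id": ["a"], "label": ["common-up"]}
        )
        calls = pd.DataFrame(
            columns=["feature_id", "common_label", "unique_label"]
        )
        rec = evaluate_recovery(calls, truth).set_index("label")
        assert rec.loc["common-up", "recall"] == 0.0
        assert np.isnan(rec.loc["common-up", "precision"])

    def test_unknown_ids_rejected(self):
        truth = pd.DataFrame({"glycopeptide_id": ["a"], "label": ["null"]})
        calls = pd.DataFrame(
            {"feature_id": ["z"], "common_label": ["none"],
             "unique_label": ["none"]}
        )
        with pytest.raises(ValueError, match="unknown glycopeptides"):
            evaluate_recovery(calls, truth)

    def test_default_config_recovery(self, default_sim, default_run):
        """Planted effects recovered on quantified features; no
        protein-driven feature ever mislabeled group-unique."""
        rec = evaluate_recovery(
            default_run.calls[["feature_id", "common_label", "unique_label"]],
            default_sim.truth,
        ).set_index("label")
        for label in ("common-up", "common-down"):
            assert rec.loc[label, "recall_quantified"] >= 0.9
            assert rec.loc[label, "precision"] == 1.0
        # protein-driven truths must never be called unique
        merged = default_run.calls.merge(
            default_sim.truth,
            left_on="feature_id",
            right_on="glycopeptide_id",
        )
        mislabeled = merged[
            (merged["label"] == "protein-driven")
            & (merged["unique_label"] != "none")
        ]
        assert len(mislabeled) == 0

    def test_null_features_not_called_common(self, default_sim, default_run):
        merged = default_run.calls.merge(
            default_sim.truth,
            left_on="feature_id",
            right_on="glycopeptide_id",
        )
        nulls = merged[merged["label"] == "null"]
        assert (nulls["common_label"] == "none").all()
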