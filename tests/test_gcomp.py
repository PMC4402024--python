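"""The Monte-Carlo g-computation estimator and bootstrap inference."""

import numpy as np
import pandas as pd
import pytest

import medpaths as mp
from medpaths.crossworld import SensitivityConfig
from medpaths.gcomp import ALL_CELLS, EstimationConfig, combine_effect_tables
from medpaths.models import ModelError, ModelSpec

from conftest import POC_TRUTH


@pytest.fixture(scope="module")
def poc_table(poc_dataset):
    specs = mp.default_specs(poc_dataset, interactions=True)
    models = {r: mp.fit_model(poc_dataset, specs[r], r) for r in ("m1", "m2", "y")}
    return mp.build_counterfactual_table(
        models, poc_dataset, SensitivityConfig(rho=0.5, seed=9, K=50)
    )


class TestTableConstruction:
    def test_all_sixteen_cells_populated(self, poc_table, poc_dataset):
        assert set(poc_table.cells) == set(ALL_CELLS)
        for v in poc_table.cells.values():
            assert v.shape == (poc_dataset.n * 50,)

    def test_outcome_model_ignoring_everything_gives_equal_cells(self, poc_dataset):
        specs = mp.default_specs(poc_dataset, interactions=True)
        models = {r: mp.fit_model(poc_dataset, specs[r], r) for r in ("m1", "m2", "y")}
        # Y model with every X/M coefficient zeroed: only confounders remain
        models["y"].params[:] = 0.0
        models["y"].params["Intercept"] = 7.0
        table = mp.build_counterfactual_table(
            models, poc_dataset, SensitivityConfig(rho=1.0, seed=1, K=2)
        )
        ref = table.cells[(0, 0, 0, 0)]
        for idx in ALL_CELLS:
            np.testing.assert_array_equal(table.cells[idx], ref)

    def test_m2_independent_of_m1_world_when_coefficient_zero(self, poc_dataset):
        """With the M1 -> M2 coefficient forced to zero, cells differing only
        in a3 have identical distributions (equal means within MC error)."""
        specs = mp.default_specs(poc_dataset, interactions=False)
        models = {r: mp.fit_model(poc_dataset, specs[r], r) for r in ("m1", "m2", "y")}
        models["m2"].params["m1"] = 0.0
        table = mp.build_counterfactual_table(
            models, poc_dataset, SensitivityConfig(rho=1.0, seed=2, K=100)
        )
        a = table.cells[(1, 1, 1, 0)]
        b = table.cells[(1, 1, 1, 1)]
        se = np.std(a - b) / np.sqrt(len(a))
        assert abs(np.mean(a) - np.mean(b)) < 3 * se + 1e-12

    def test_missing_model_role_rejected(self, poc_dataset):
        with pytest.raises(ModelError, match="missing fitted model"):
            mp.build_counterfactual_table({}, poc_dataset, SensitivityConfig())


class TestEffectEstimation:
    def test_product_of_coefficients_recovery(self, poc_table):
        effects = mp.estimate_effects(poc_table)
        n = poc_table.n_subjects
        for _, row in effects.df.iterrows():
            if row["effect"] == "TCE":
                continue
            label = row["effect"].split("-")[0]
            # MC + sampling tolerance: cluster-level SE is ~sigma/sqrt(n)
            assert row["estimate"] == pytest.approx(POC_TRUTH[label], abs=0.12)

    def test_null_exposure_gives_null_effects(self):
        params = mp.TrueSEMParams.product_of_coefficients(
            direct=0.0, x_to_m1=0.0, x_to_m2=0.0
        )
        ds = mp.generate_observed(params, 1500, seed=13)
        res = mp.analyze(ds, config=EstimationConfig(rho_grid=(0.5,), K=50, seed=3))
        est = res.point[0.5]
        for c in mp.enumerate_effects():
            assert abs(est[c.name]) < 0.15

    def test_decomposition_sums_equal_tce_exactly(self, poc_table):
        effects = mp.estimate_effects(poc_table)
        dec = mp.estimate_decompositions(effects)
        assert len(dec) == 24
        resid = (dec["sum"] - dec["TCE"]).abs().max()
        assert resid < 1e-10 * max(abs(effects.tce), 1.0)

    def test_decomposition_one_components(self, poc_table):
        dec = mp.estimate_decompositions(mp.estimate_effects(poc_table))
        row = dec.loc[dec["decomposition"] == 1].iloc[0]
        assert (row["NDE_code"], row["NIE1_code"], row["NIE2_code"], row["NIE12_code"]) \
            == (1, 2, 5, 8)

    def test_mismatched_provenance_rejected(self, poc_dataset, poc_table):
        specs = mp.default_specs(poc_dataset, interactions=True)
        models = {r: mp.fit_model(poc_dataset, specs[r], r) for r in ("m1", "m2", "y")}
        other = mp.build_counterfactual_table(
            models, poc_dataset, SensitivityConfig(rho=0.0, seed=9, K=50)
        )
        with pytest.raises(ValueError, match="provenance"):
            combine_effect_tables(
                [mp.estimate_effects(poc_table), mp.estimate_effects(other)]
            )

    def test_reduced_system_six_decompositions_and_null_via_both(self):
        params = mp.TrueSEMParams.product_of_coefficients(m1_to_m2=0.0)
        ds = mp.generate_observed(params, 1500, seed=17)
        res = mp.analyze(
            ds, config=EstimationConfig(rho_grid=(1.0,), K=50, seed=5, reduced=True)
        )
        dec = res.decompositions[1.0]
        assert len(dec) == 6
        assert (dec["sum"] - dec["TCE"]).abs().max() < 1e-10
        est = res.point[1.0]
        assert est["NDE-00"] == pytest.approx(1.0, abs=0.15)
        assert est["NIE1-00"] == pytest.approx(0.30, abs=0.12)
        assert est["NIE2-00"] == pytest.approx(0.21, abs=0.12)

    def test_y_draw_flag_leaves_expectations_unchanged(self, poc_dataset):
        cfgs = [
            EstimationConfig(rho_grid=(1.0,), K=50, seed=7, y_draw=flag)
            for flag in (False, True)
        ]
        tces = [
            mp.analyze(poc_dataset, config=c).point[1.0]["TCE"] for c in cfgs
        ]
        assert tces[0] == pytest.approx(tces[1], abs=0.15)


class TestBootstrap:
    def test_zero_noise_sem_gives_zero_ses(self):
        # every structural equation deterministic; confounder nonlinearities
        # keep the downstream designs full rank
        rng = np.random.default_rng(19)
        n = 400
        x = (rng.random(n) < 0.5).astype(float)
        c = rng.standard_normal(n)
        m1 = 0.2 + 0.5 * x + 0.3 * c**2
        m2 = 0.1 + 0.3 * x + 0.4 * m1 + 0.2 * c**3
        y = 1.0 + x + 0.6 * m1 + 0.7 * m2 + 0.5 * c
        ds = mp.Dataset(
            df=pd.DataFrame({"x": x.astype(int), "m1": m1, "m2": m2, "y": y, "c": c}),
            exposure="x", m1="m1", m2="m2", outcome="y", confounders=("c",),
        )
        specs = {
            "m1": ModelSpec(["x", "c^2"]),
            "m2": ModelSpec(["x", "m1", "c^3"]),
            "y": ModelSpec(["x", "m1", "m2", "c"]),
        }
        res = mp.analyze(
            ds, specs=specs, config=EstimationConfig(rho_grid=(1.0,), K=5, B=20, seed=3)
        )
        frame = res.effects_frame()
        assert frame["se"].max() < 1e-8

    def test_ses_shrink_as_root_n(self, poc_params):
        ses = {}
        for n in (250, 1000):
            ds = mp.generate_observed(poc_params, n, seed=23)
            res = mp.analyze(
                ds,
                config=EstimationConfig(rho_grid=(1.0,), K=20, B=60, seed=29),
                cells=[(1, 1, 1, 1), (0, 0, 0, 0)],
            )
            ses[n] = float(res.replicates[1.0]["TCE"].std(ddof=1))
        ratio = ses[250] / ses[1000]
        assert 1.6 < ratio < 2.4

    def test_percentile_ci_requires_enough_replicates(self):
        with pytest.raises(ValueError, match="percentile"):
            EstimationConfig(B=10, ci_method="percentile")

    def test_ci_brackets_estimate(self, poc_dataset):
        res = mp.analyze(
            poc_dataset,
            config=EstimationConfig(rho_grid=(1.0,), K=10, B=25, seed=31),
        )
        frame = res.effects_frame().dropna(subset=["se"])
        assert (frame["ci_low"] <= frame["estimate"] + 1e-12).all()
        assert (frame["estimate"] <= frame["ci_high"] + 1e-12).all()


class TestLSEMComparator:
    def test_matches_hand_products_on_fixture_sem(self, poc_dataset):
        specs = mp.default_specs(poc_dataset, interactions=False)
        out = mp.lsem_comparator(poc_dataset, specs)
        assert out["direct"] == pytest.approx(1.0, abs=0.12)
        assert out["via_m1"] == pytest.approx(0.30, abs=0.08)
        assert out["via_m2"] == pytest.approx(0.21, abs=0.08)
        assert out["via_both"] == pytest.approx(0.14, abs=0.08)
        assert out["total"] == pytest.approx(sum(POC_TRUTH.values()), abs=0.2)

    def test_all_zero_slopes_give_zero_paths(self):
        params = mp.TrueSEMParams.product_of_coefficients(
            direct=0.0, x_to_m1=0.0, x_to_m2=0.0, m1_to_m2=0.0,
            m1_to_y=0.0, m2_to_y=0.0,
        )
        ds = mp.generate_observed(params, 3000, seed=37)
        out = mp.lsem_comparator(ds, mp.default_specs(ds, interactions=False))
        for v in out.values():
            assert abs(v) < 0.12

    def test_interaction_specs_rejected(self, poc_dataset):
        specs = mp.default_specs(poc_dataset, interactions=True)
        with pytest.raises(ModelError, match="interaction-free"):
            mp.lsem_comparator(poc_dataset, specs)

    def test_agrees_with_gcomputation_without_interactions(self, poc_dataset):
        lsem = mp.lsem_comparator(
            poc_dataset, mp.default_specs(poc_dataset, interactions=False)
        )
        res = mp.analyze(
            poc_dataset,
            specs=mp.default_specs(poc_dataset, interactions=False),
            config=EstimationConfig(rho_grid=(1.0,), K=100, seed=41),
        )
        est = res.point[1.0]
        assert est["NDE-000"] == pytest.approx(lsem["direct"], abs=0.08)
        assert est["NIE1-000"] == pytest.approx(lsem["via_m1"], abs=0.08)
        assert est["NIE2-000"] == pytest.approx(lsem["via_m2"], abs=0.08)
        assert est["NIE12-000"] == pytest.approx(lsem["via_both"], abs=0.08)
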