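import numpy as np
import pandas as pd
import pytest

from mangrove_allometry.allometry import ModelForm, ModelFormName, fit_model, predict
from mangrove_allometry.mensuration import HeightClass
from mangrove_allometry.published_models import builtin_registry
from mangrove_allometry.root_reconstruction import RootType
from mangrove_allometry.synthetic_data import (
    SimulationConfig,
    simulate_root_system,
    simulate_stand,
    simulate_trees,
)

POWER = ModelForm(ModelFormName.POWER, ("x",))


class TestSimulateTrees:
    def test_forty_five_trees_fifteen_per_class(self):
        trees = simulate_trees(SimulationConfig(seed=1))
        assert len(trees) == 45
        counts = {c: 0 for c in HeightClass}
        for t in trees:
            counts[t.height_class] += 1
        assert all(v == 15 for v in counts.values())

    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(seed=42)
        assert simulate_trees(cfg) == simulate_trees(cfg)

    def test_different_seed_differs(self):
        assert simulate_trees(SimulationConfig(seed=1)) != simulate_trees(SimulationConfig(seed=2))

    def test_zero_cv_diameters_follow_the_link_exactly(self):
        cfg = SimulationConfig(seed=5, diameter_cv=0.0)
        for t in simulate_trees(cfg):
            assert t.diameter_cm == pytest.approx(
                cfg.diameter_alpha * t.height_cm**cfg.diameter_beta, rel=1e-12
            )

    def test_heights_within_class_bounds(self):
        cfg = SimulationConfig(seed=9)
        for t in simulate_trees(cfg):
            lo, hi = cfg.height_bounds_cm[t.height_class.value]
            assert lo < t.height_cm <= hi


class TestYamlConfig:
    def test_roundtrip_preserves_simulation(self, tmp_path):
        cfg = SimulationConfig(seed=13, n_per_class=4, mass_cv=0.07)
        cfg.to_yaml(tmp_path / "config.yml")
        back = SimulationConfig.from_yaml(tmp_path / "config.yml")
        assert simulate_trees(back) == simulate_trees(cfg)


class TestSimulateRootSystem:
    def test_exactly_two_excavated_primaries(self, registry):
        cfg = SimulationConfig(seed=3)
        tree = simulate_trees(cfg)[0]
        samples, _ = simulate_root_system(tree, cfg, registry, np.random.default_rng(0))
        exc_primaries = [s for s in samples if s.excavated and s.root_type is RootType.PRIMARY]
        assert len(exc_primaries) == cfg.excavated_primaries_per_tree == 2

    def test_zero_cv_masses_equal_model_predictions(self, registry):
        cfg = SimulationConfig(seed=3, mass_cv=0.0)
        tree = simulate_trees(cfg)[20]  # a C2 tree
        samples, crown = simulate_root_system(tree, cfg, registry, np.random.default_rng(0))
        cls = tree.height_class.value
        for s in samples:
            if s.dry_mass_kg is None:
                continue  # unexcavated: latent until reconstruction
            comp = "UNEXCAVATED_PRIMARY" if s.root_type is RootType.PRIMARY else "UNEXCAVATED_SECONDARY"
            expected = max(predict(registry.get_model(cls, comp), {"x": s.basal_diameter_cm}), 0.0)
            assert s.dry_mass_kg == pytest.approx(expected, rel=1e-9)
        crown_expected = max(predict(registry.get_model(cls, "ROOT_CROWN"), tree.predictors()), 0.0)
        assert crown.dry_mass_kg == pytest.approx(crown_expected, rel=1e-9)

    def test_excavated_fresh_and_subsample_consistent(self, registry):
        cfg = SimulationConfig(seed=3)
        tree = simulate_trees(cfg)[0]
        samples, _ = simulate_root_system(tree, cfg, registry, np.random.default_rng(1))
        for s in samples:
            if s.excavated:
                assert s.subsample_dry_g / s.subsample_fresh_g == pytest.approx(cfg.dry_fresh_ratio)
                assert s.dry_mass_kg == pytest.approx(s.fresh_mass_kg * cfg.dry_fresh_ratio)


class TestParameterRecovery:
    @pytest.mark.parametrize(
        "cls,comp",
        [
            ("C1", "UNEXCAVATED_PRIMARY"),
            ("C2", "UNEXCAVATED_PRIMARY"),
            ("C2", "UNEXCAVATED_SECONDARY"),
            ("C3", "UNEXCAVATED_PRIMARY"),
            ("C3", "UNEXCAVATED_SECONDARY"),
        ],
    )
    def test_power_coefficients_recovered_within_5pct(self, registry, cls, comp):
        """Fitting root samples generated from each per-class power
        equation (200 roots, 5% multiplicative noise) recovers the
        generating coefficients within 5% relative error."""
        from tests_helpers import root_fit_frame

        df = root_fit_frame(registry, cls, comp, n=200, cv=0.05, seed=0)
        fitted = fit_model(POWER, df)
        truth = registry.get_model(cls, comp).coefficients
        rel = np.abs(np.asarray(fitted.coefficients) - truth) / np.abs(truth)
        assert rel.max() < 0.05

    def test_zero_noise_recovery_exact(self, registry):
        from tests_helpers import root_fit_frame

        df = root_fit_frame(registry, "C2", "UNEXCAVATED_SECONDARY", n=50, cv=0.0, seed=0)
        fitted = fit_model(POWER, df)
        truth = registry.get_model("C2", "UNEXCAVATED_SECONDARY").coefficients
        assert np.allclose(fitted.coefficients, truth, rtol=1e-6)


class TestPipelineClosure:
    def test_noiseless_stand_reproduces_model_predictions(self, registry):
        """Reconstruction over a zero-noise synthetic stand returns exactly
        the masses the generating equations predict, and the per-class
        densities follow from the stem counts."""
        cfg = SimulationConfig(seed=11, mass_cv=0.0, diameter_cv=0.0, crown_r1_cv=0.0)
        stems = {"C1": 1000.0, "C2": 500.0, "C3": 200.0}
        stand = simulate_stand(cfg, stems, registry)
        trees = {t.tree_id: t for t in stand["trees"]}
        for ledger in stand["tree_bgb"]:
            tree = trees[ledger.tree_id]
            cls = tree.height_class.value
            crown_expected = max(predict(registry.get_model(cls, "ROOT_CROWN"), tree.predictors()), 0.0)
            assert ledger.crown_kg == pytest.approx(crown_expected, rel=1e-9, abs=1e-12)
            # every root mass (excavated or predicted) equals its equation value
            prim = sum(
                max(predict(registry.get_model(cls, "UNEXCAVATED_PRIMARY"), {"x": s.basal_diameter_cm}), 0)
                for s in stand["root_samples"]
                if s.tree_id == ledger.tree_id and s.root_type is RootType.PRIMARY
            )
            assert ledger.primary_kg == pytest.approx(prim, rel=1e-9)
            assert ledger.total_kg == pytest.approx(
                ledger.crown_kg + ledger.primary_kg + ledger.secondary_kg, rel=1e-12
            )
        # density expansion: mean per-tree BGB x stems/ha / 1000
        for cls in ("C1", "C2", "C3"):
            masses = [
                l.total_kg for l in stand["tree_bgb"] if trees[l.tree_id].height_class.value == cls
            ]
            assert stand["bgb_mg_ha"][cls] == pytest.approx(np.mean(masses) * stems[cls] / 1000.0)

    def test_stand_deterministic_in_seed(self, registry):
        cfg = SimulationConfig(seed=21)
        stems = {"C1": 100.0, "C2": 100.0, "C3": 100.0}
        a = simulate_stand(cfg, stems, registry)
        b = simulate_stand(cfg, stems, registry)
        assert a["bgb_mg_ha"] == b["bgb_mg_ha"]
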