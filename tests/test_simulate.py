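import numpy as np
import pandas as pd
import pytest

from pathlmm import (
    PathwaySet, ScenarioSpec, erase_time, inject_condition_effect,
    inject_time_effect, make_h1_dataset, make_vsize_dataset,
    permute_condition,
)
from .conftest import make_quant_table


class TestPermuteCondition:
    def test_values_untouched(self, toy_qt):
        out = permute_condition(toy_qt, seed=5)
        pd.testing.assert_frame_equal(out.values, toy_qt.values)

    def test_individual_level_label_multiset(self, toy_qt):
        out = permute_condition(toy_qt, seed=5)
        orig = toy_qt.design.groupby("individual", observed=True)["condition"].first()
        new = out.design.groupby("individual", observed=True)["condition"].first()
        assert sorted(orig) == sorted(new)
        # each individual still has exactly one condition (validated on build)
        assert out.design.groupby("individual", observed=True)["condition"].nunique().max() == 1

    def test_two_individuals_exhaustive(self):
        qt = make_quant_table(n_ind=2, T=2)
        outcomes = set()
        for seed in range(30):
            out = permute_condition(qt, seed=seed)
            labels = tuple(
                out.design.groupby("individual", observed=True)["condition"].first()
            )
            outcomes.add(labels)
        assert outcomes == {("A", "B"), ("B", "A")}

    def test_single_condition_noop(self):
        qt = make_quant_table(n_ind=4, T=2, conditions=("A",))
        out = permute_condition(qt, seed=0)
        pd.testing.assert_frame_equal(out.design, qt.design)

    def test_seed_determinism(self, toy_qt):
        a = permute_condition(toy_qt, seed=9)
        b = permute_condition(toy_qt, seed=9)
        pd.testing.assert_frame_equal(a.design, b.design)


class TestEraseTime:
    def test_zero_noise_copies_first_block(self, toy_qt):
        out = erase_time(toy_qt, noise_factor=0.0, seed=0)
        t1 = out.design["time"] == "t0"
        first = out.values.loc[t1].set_axis(
            out.design.loc[t1, "individual"], axis=0
        )
        for t in ("t1", "t2"):
            rows = out.design["time"] == t
            block = out.values.loc[rows].set_axis(
                out.design.loc[rows, "individual"], axis=0
            )
            pd.testing.assert_frame_equal(block, first.loc[block.index])

    def test_noise_variance_scaling(self):
        """sigma_b^2 = noise_factor * range, checked empirically."""
        qt = make_quant_table(n_ind=20, T=3, n_met=200, seed=1)
        S_range = None
        base = erase_time(qt, noise_factor=0.0, seed=0)
        S = base.values.to_numpy()
        S_range = S.max() - S.min()
        out = erase_time(qt, noise_factor=0.05, seed=2)
        resid = out.values.to_numpy() - S
        # flooring at 0 clips the lower tail; restrict to unclipped cells
        unclipped = out.values.to_numpy() > 0
        emp_var = resid[unclipped].var()
        assert emp_var == pytest.approx(0.05 * S_range, rel=0.05)

    def test_missing_first_time_errors(self, toy_qt):
        keep = ~((toy_qt.design["individual"] == "i0")
                 & (toy_qt.design["time"] == "t0"))
        from pathlmm import QuantTable
        sub = QuantTable(toy_qt.values.loc[keep], toy_qt.design.loc[keep])
        with pytest.raises(ValueError, match="i0"):
            erase_time(sub, seed=0)


class TestInjectCondition:
    def test_scenario_multipliers(self, toy_qt):
        out = inject_condition_effect(toy_qt, {"m1"}, {"A": 1.0, "B": 10.0})
        treated = (toy_qt.design["condition"] == "B").to_numpy()
        np.testing.assert_allclose(
            out.values.loc[treated, "m1"],
            toy_qt.values.loc[treated, "m1"] * 10.0,
        )
        np.testing.assert_allclose(
            out.values.loc[~treated, "m1"], toy_qt.values.loc[~treated, "m1"]
        )
        # non-target columns bit-identical
        pd.testing.assert_frame_equal(
            out.values.drop(columns="m1"), toy_qt.values.drop(columns="m1")
        )

    def test_unit_gammas_identity(self, toy_qt):
        out = inject_condition_effect(toy_qt, {"m1", "m2"}, {"A": 1.0, "B": 1.0})
        pd.testing.assert_frame_equal(out.values, toy_qt.values)

    def test_unknown_condition_key_errors(self, toy_qt):
        with pytest.raises(ValueError, match="unknown"):
            inject_condition_effect(toy_qt, {"m1"}, {"A": 1.0, "Z": 2.0})


class TestInjectTime:
    def test_scenario_scaling_no_noise(self, toy_qt):
        gamma = {"t0": 1.0, "t1": 5.0, "t2": 10.0}
        out = inject_time_effect(toy_qt, {"m1"}, gamma, noise_factor=0.0, seed=0)
        t0 = toy_qt.design["time"] == "t0"
        first = toy_qt.values.loc[t0, "m1"].set_axis(
            toy_qt.design.loc[t0, "individual"]
        )
        for t, g in gamma.items():
            rows = out.design["time"] == t
            got = out.values.loc[rows, "m1"].set_axis(
                out.design.loc[rows, "individual"]
            )
            np.testing.assert_allclose(got, first.loc[got.index] * g)

    def test_unit_gamma_matches_erase_time(self, toy_qt):
        gamma = {t: 1.0 for t in toy_qt.time_levels}
        a = inject_time_effect(
            toy_qt, set(toy_qt.metabolites), gamma, noise_factor=0.0, seed=0
        )
        b = erase_time(toy_qt, noise_factor=0.0, seed=0)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_keep_mode_leaves_nontargets(self, toy_qt):
        gamma = {"t0": 1.0, "t1": 2.0, "t2": 3.0}
        out = inject_time_effect(
            toy_qt, {"m1"}, gamma, noise_factor=0.0, seed=0, nontargets="keep"
        )
        pd.testing.assert_frame_equal(
            out.values.drop(columns="m1"), toy_qt.values.drop(columns="m1")
        )


class TestDatasetBuilders:
    def make_ps(self):
        return PathwaySet({
            "p1": frozenset({"m1", "m2"}),
            "p2": frozenset({"m2", "m3"}),
            "p3": frozenset({"m4", "m5"}),
            "p4": frozenset({"m5", "m6"}),
        })

    def test_h1_deterministic_and_truthful(self, toy_qt):
        spec = ScenarioSpec(effect="condition", k=2,
                            gamma_d={"A": 1.0, "B": 10.0}, seed=42)
        out1, truth1 = make_h1_dataset(toy_qt, self.make_ps(), spec)
        out2, truth2 = make_h1_dataset(toy_qt, self.make_ps(), spec)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert truth1 == truth2
        assert len(truth1["selected_pathways"]) == 2
        expected = set().union(
            *(self.make_ps()[p] for p in truth1["selected_pathways"])
        )
        assert set(truth1["target_metabolites"]) == expected

    def test_condition_time_composes(self, toy_qt):
        gamma_d = {"A": 1.0, "B": 3.0}
        gamma_t = {"t0": 1.0, "t1": 2.0, "t2": 3.0}
        spec = ScenarioSpec(
            effect="condition_time", k=2, gamma_d=gamma_d, gamma_t=gamma_t,
            noise_factor=0.0, seed=7,
        )
        out, truth = make_h1_dataset(toy_qt, self.make_ps(), spec)
        targets = frozenset(truth["target_metabolites"])
        # replay: the pathway selection consumes the first generator draw
        rng = np.random.default_rng(7)
        rng.choice(self.make_ps().ids, size=2, replace=False)
        manual = inject_time_effect(
            toy_qt, targets, gamma_t, noise_factor=0.0, seed=rng
        )
        manual = inject_condition_effect(manual, targets, gamma_d)
        pd.testing.assert_frame_equal(out.values, manual.values)

    def test_k_too_large_errors(self, toy_qt):
        spec = ScenarioSpec(effect="condition", k=9,
                            gamma_d={"A": 1.0, "B": 2.0})
        with pytest.raises(ValueError, match="k="):
            make_h1_dataset(toy_qt, self.make_ps(), spec)

    def test_vsize_ptilde_edges(self, toy_qt):
        ps = PathwaySet({
            "big": frozenset({"m1", "m2", "m3", "m4"}),
            "other": frozenset({"m5", "m6"}),
        })
        spec = ScenarioSpec(
            effect="condition", mode="VSize", k=2,
            gamma_d={"A": 1.0, "B": 10.0}, p_tilde=1, seed=0,
        )
        out, truth = make_vsize_dataset(toy_qt, ps, spec)
        assert truth["vsize_pathway"] == "big"
        assert len(truth["vsize_members"]) == 1
        # p_tilde = size: all members differential
        spec4 = ScenarioSpec(
            effect="condition", mode="VSize", k=2,
            gamma_d={"A": 1.0, "B": 10.0}, p_tilde=4, seed=0,
        )
        _, truth4 = make_vsize_dataset(toy_qt, ps, spec4)
        assert set(truth4["vsize_members"]) == set(ps["big"])

    def test_vsize_zero_ptilde_errors(self, toy_qt):
        ps = self.make_ps()
        spec = ScenarioSpec(effect="condition", mode="VSize", k=1,
                            gamma_d={"A": 1.0, "B": 2.0}, p_tilde=0)
        with pytest.raises(ValueError, match="p_tilde"):
            make_vsize_dataset(toy_qt, ps, spec)
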