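"""Subgroup workflow: splitting, additivity, equality tests."""

import numpy as np
import pytest

from masem.dataset import MasemDataset, StudyRecord
from masem.model import MultiGroupModel, parse_model
from masem.simulate import _PATH_MODEL, SimulationCondition, generate_meta_dataset, path_population_matrix
from masem.stage1_fixed import FixedStage1Result
from masem.stage1_random import pool_random
from masem.stage2 import fit_wls, fit_wls_multigroup
from masem.subgroup import (
    fit_multigroup_stage2,
    split_dataset,
    subgroup_analysis,
)
from masem.subgroup import test_parameter_equality as parameter_equality_test
from masem.subgroup import test_stage1_equality as stage1_equality_test
from tests.conftest import make_homogeneous_dataset

PATH_VARS = ["v1", "v2", "v3", "v4"]


def stage1_stub(P, acov, n=1000):
    return FixedStage1Result(P=P, acov=acov, chi2=0.0, df=0, total_n=n, converged=True)


def pd_acov(q, scale, seed):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((q, 2 * q))
    return (A @ A.T + 2 * q * np.eye(q)) / scale


class TestSplitDataset:
    def _data(self, k=6):
        rng = np.random.default_rng(0)
        P = np.array([[1.0, 0.3], [0.3, 1.0]])
        return make_homogeneous_dataset(P, k, 50, rng)

    def test_strictly_above_threshold_goes_to_first_label(self):
        data = self._data(4)
        values = {"s0": 10, "s1": 60, "s2": 50, "s3": 70}
        out = split_dataset(data, values, 50)
        groups = {s.study_id: s.group for s in out.studies}
        assert groups == {"s0": "low", "s1": "high", "s2": "low", "s3": "high"}

    def test_degenerate_split_rejected(self):
        data = self._data(4)
        with pytest.raises(ValueError, match="< 2"):
            split_dataset(data, {s.study_id: 1.0 for s in data.studies}, 50)

    def test_missing_moderator_value_rejected(self):
        data = self._data(3)
        with pytest.raises(ValueError, match="missing"):
            split_dataset(data, {"s0": 1.0}, 0.5)


class TestMultigroupStage2:
    def test_unconstrained_joint_fit_is_sum_of_separate_fits(self):
        P1 = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        r1 = P1.copy()
        r1[0, 3] = r1[3, 0] = P1[0, 3] + 0.05  # misfit so chi2 > 0
        P2 = path_population_matrix(0.20, -0.25, 0.40, -0.25)
        r2 = P2.copy()
        r2[1, 3] = r2[3, 1] = P2[1, 3] - 0.04
        s1 = {"a": stage1_stub(r1, pd_acov(6, 1e4, 1)), "b": stage1_stub(r2, pd_acov(6, 1e4, 2))}
        mg = MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL})
        joint = fit_multigroup_stage2(s1, mg)
        sep = [fit_wls(s1[g], _PATH_MODEL) for g in ("a", "b")]
        assert joint.chi2 == pytest.approx(sum(f.chi2 for f in sep), abs=1e-6)
        assert joint.df == sum(f.df for f in sep)

    def test_identical_groups_fully_constrained_match_single_fit(self):
        P = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        r = P.copy()
        r[0, 3] = r[3, 0] = P[0, 3] + 0.05
        acov = pd_acov(6, 1e4, 3)
        single = fit_wls(stage1_stub(r, acov), _PATH_MODEL)
        s1 = {"a": stage1_stub(r, acov), "b": stage1_stub(r, acov)}
        mg = MultiGroupModel(
            ["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL},
            {"b31", "b32", "b43", "psi12"},
        )
        joint = fit_multigroup_stage2(s1, mg)
        assert joint.chi2 == pytest.approx(2 * single.chi2, rel=1e-5, abs=1e-8)
        for name in ("b31", "b32", "b43", "psi12"):
            assert joint.theta[name] == pytest.approx(single.theta[name], abs=1e-6)

    def test_chi2_monotone_in_constraint_set(self):
        P1 = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        P2 = path_population_matrix(0.20, -0.25, 0.42, -0.22)
        s1 = {"a": stage1_stub(P1, pd_acov(6, 1e4, 4)), "b": stage1_stub(P2, pd_acov(6, 1e4, 5))}
        chis = []
        for labels in [set(), {"b43"}, {"b43", "b31"}, {"b43", "b31", "b32", "psi12"}]:
            mg = MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL}, labels)
            chis.append(fit_multigroup_stage2(s1, mg).chi2)
        assert all(chis[i] <= chis[i + 1] + 1e-6 for i in range(3))

    def test_constraint_label_absent_from_group_rejected(self):
        other = parse_model("v3 ~ c31:v1 + b32:v2\nv4 ~ b43:v3\nv1 ~~ psi12:v2", PATH_VARS)
        P = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        s1 = {"a": stage1_stub(P, pd_acov(6, 1e4, 6)), "b": stage1_stub(P, pd_acov(6, 1e4, 7))}
        mg = MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": other}, {"b31"})
        with pytest.raises(ValueError, match="absent"):
            fit_multigroup_stage2(s1, mg)


class TestParameterEquality:
    def _fits(self, labels):
        P1 = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        P2 = path_population_matrix(0.25, -0.30, 0.42, -0.30)
        s1 = {"a": stage1_stub(P1, pd_acov(6, 2e5, 8)), "b": stage1_stub(P2, pd_acov(6, 2e5, 9))}
        free = fit_multigroup_stage2(
            s1, MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL})
        )
        con = fit_multigroup_stage2(
            s1, MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL}, labels)
        )
        return free, con

    def test_true_difference_is_detected_with_precise_inputs(self):
        free, con = self._fits({"b43"})
        report = parameter_equality_test(free, con)
        assert report["delta_df"] == 1
        assert report["decision"] == "rejected"

    def test_identical_models_not_rejected(self):
        P = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        s1 = {"a": stage1_stub(P, pd_acov(6, 1e4, 10)), "b": stage1_stub(P, pd_acov(6, 1e4, 11))}
        mg = MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL})
        free = fit_multigroup_stage2(s1, mg)
        report = parameter_equality_test(free, fit_multigroup_stage2(
            s1, MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL}, {"b31"})
        ))
        assert report["p_value"] > 0.9  # same populations: no misfit increase

    def test_different_stage1_inputs_rejected(self):
        free, _ = self._fits({"b43"})
        P = path_population_matrix(0.25, -0.30, 0.30, -0.30)
        s1 = {"a": stage1_stub(P, pd_acov(6, 1e4, 12)), "b": stage1_stub(P, pd_acov(6, 1e4, 13))}
        other = fit_multigroup_stage2(
            s1, MultiGroupModel(["a", "b"], {"a": _PATH_MODEL, "b": _PATH_MODEL}, {"b43"})
        )
        with pytest.raises(ValueError, match="stage-1"):
            parameter_equality_test(free, other)

    def test_nesting_violation_rejected(self):
        free, con = self._fits({"b43"})
        with pytest.raises(ValueError):
            parameter_equality_test(con, free)


class TestStage1Equality:
    def test_fixed_effects_delta_df_counts_constrained_correlations(self, rho3, rng):
        g1 = make_homogeneous_dataset(rho3, 6, 150, rng, group="a", prefix="a")
        g2 = make_homogeneous_dataset(rho3, 6, 150, rng, group="b", prefix="b")
        data = MasemDataset(g1.variables, g1.studies + g2.studies)
        dchi, ddf, p = stage1_equality_test(data, effects="fixed")
        assert ddf == 3  # p(p-1)/2 per extra group
        assert dchi >= 0 and 0 <= p <= 1

    def test_random_effects_mean_equality(self, rho3, rng):
        g1 = make_homogeneous_dataset(rho3, 8, 150, rng, group="a", prefix="a")
        g2 = make_homogeneous_dataset(rho3, 8, 150, rng, group="b", prefix="b")
        data = MasemDataset(g1.variables, g1.studies + g2.studies)
        dchi, ddf, p = stage1_equality_test(data, effects="random", what="means")
        assert ddf == 3
        assert dchi >= 0 and 0 <= p <= 1

    def test_requires_subgroups(self, rho3, rng):
        data = make_homogeneous_dataset(rho3, 5, 100, rng)
        with pytest.raises(ValueError, match="subgroup"):
            stage1_equality_test(data)


class TestWorkflow:
    def test_full_subgroup_analysis_on_generated_data(self):
        cond = SimulationCondition(k_per_subgroup=15, reps=1, seed=5)
        data = generate_meta_dataset(cond, np.random.default_rng(5))
        analysis = subgroup_analysis(
            data,
            lambda g: _PATH_MODEL,
            {"direct_effects": {"b31", "b32", "b43"}},
            effects="random",
        )
        free = analysis.stage2_free
        con = analysis.stage2_constrained["direct_effects"]
        assert free.df == 4 and con.df == 7
        dchi, ddf, p = analysis.tests["direct_effects"]
        assert ddf == 3 and dchi >= 0
        # additivity of the unconstrained joint model
        seps = [fit_wls(analysis.stage1[g], _PATH_MODEL) for g in analysis.groups]
        assert free.chi2 == pytest.approx(sum(f.chi2 for f in seps), abs=1e-6)
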