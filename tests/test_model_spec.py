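import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from bayesce.model_spec import (MODEL_LABELS, AgeTransform, ConstraintSet,
                                CovariateSpec, ModelConfig, StateSpace,
                                build_model_config, build_parameter_index,
                                config_from_dict, config_to_dict,
                                icd_state_space, linear_predictors,
                                transition_probabilities, two_state_config)

# hand-enumerated free-parameter counts (see §2.1-style enumeration in the
# module docstrings): base case 59, then the printed deltas
EXPECTED_COUNTS = dict(zip(
    MODEL_LABELS, [59, 71, 55, 54, 59, 66, 73, 73, 87, 101]))


class TestStateSpace:
    def test_icd_structure(self):
        sp = icd_state_space()
        assert sp.n_states == 8
        assert sp.absorbing == {8}
        expected = {(1, s) for s in range(1, 9)}
        for r in range(2, 8):
            expected |= {(r, r), (r, 1), (r, 8)}
        expected.add((8, 8))
        assert sp.permitted == expected

    def test_reference_is_out_of_hospital(self):
        sp = icd_state_space()
        for r in range(1, 8):
            assert sp.reference(r) == 1

    def test_absorbing_must_self_loop_only(self):
        with pytest.raises(ValueError):
            StateSpace(("a", "b"), frozenset({2}),
                       frozenset({(1, 1), (1, 2), (2, 2), (2, 1)}))

    def test_transient_needs_exit(self):
        with pytest.raises(ValueError):
            StateSpace(("a", "b"), frozenset({2}),
                       frozenset({(1, 1), (2, 2)}))


class TestParameterCounts:
    @pytest.mark.parametrize("label", MODEL_LABELS)
    def test_printed_counts(self, label):
        index = build_parameter_index(build_model_config(label))
        assert index.n_free == EXPECTED_COUNTS[label]

    def test_two_state_single_intercept(self):
        index = build_parameter_index(two_state_config())
        assert index.n_free == 1
        assert index.names == ("mu_12",)

    def test_m1_death_row_tied_once(self, m1_index):
        assert "mu_D" in m1_index.names
        # tied slots map to one position
        positions = {m1_index.position[(r, 8, 0)] for r in range(1, 8)}
        assert len(positions) == 1

    def test_every_slot_has_exactly_one_status(self, m1_config):
        status = m1_config.slot_status()
        n_slots = sum(1 for _ in m1_config.all_slots())
        assert len(status) == n_slots

    def test_overlapping_tie_groups_rejected(self):
        sp = icd_state_space()
        covs = (CovariateSpec("aad"),)
        ties = (("g1", frozenset({(1, 2, 0), (1, 3, 0)})),
                ("g2", frozenset({(1, 3, 0), (1, 4, 0)})))
        with pytest.raises(ValueError, match="more than one tie group"):
            ModelConfig("bad", sp, covs, ConstraintSet(ties)).slot_status()

    def test_tie_group_with_zeroed_slot_rejected(self):
        sp = icd_state_space()
        covs = (CovariateSpec("aad"),)
        ties = (("g1", frozenset({(1, 2, 0), (1, 3, 0)})),)
        with pytest.raises(ValueError, match="both zeroed and tied"):
            ModelConfig("bad", sp, covs,
                        ConstraintSet(ties, frozenset({(1, 2, 0)})))

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown model label"):
            build_model_config("M11")

    def test_constraint_on_non_permitted_transition_rejected(self):
        sp = icd_state_space()
        with pytest.raises(ValueError, match="not a valid slot"):
            ModelConfig("bad", sp, (CovariateSpec("aad"),),
                        ConstraintSet(zero_set=frozenset({(2, 3, 0)})))


class TestCovariates:
    def test_piecewise_age_two_indicators(self):
        at = AgeTransform("piecewise")
        assert at.n_columns == 2
        assert list(at.values(55.0)) == [0.0, 0.0]
        assert list(at.values(65.0)) == [1.0, 0.0]
        assert list(at.values(75.0)) == [0.0, 1.0]
        assert list(at.values(60.0)) == [1.0, 0.0]  # closed on the left
        assert list(at.values(70.0)) == [0.0, 1.0]

    def test_polynomial_age_centered_scaled(self):
        at = AgeTransform("polynomial", degree=3)
        z = (83.0 - 63.0) / 10.0
        np.testing.assert_allclose(at.values(83.0), [z, z**2, z**3])

    def test_polynomial_degree_columns(self):
        for d, label in [(2, "M5"), (3, "M6"), (4, "M7")]:
            cfg = build_model_config(label)
            age_cols = [c for c in cfg.column_names if c.startswith("age_")]
            assert len(age_cols) == d

    def test_interaction_multiplies_treatment(self):
        cfg = build_model_config("M8")
        x_icd = cfg.covariate_vector(
            {"aad": 0, "sex": 0, "lvef": 1, "country": 1}, 73.0)
        x_aad = cfg.covariate_vector(
            {"aad": 1, "sex": 0, "lvef": 1, "country": 1}, 73.0)
        cols = ["intercept"] + cfg.column_names
        for name, vi, va in zip(cols, x_icd, x_aad):
            if name.startswith("aad_x_age"):
                assert vi == 0.0 and va != 0.0

    def test_fractional_covariate_allowed(self, m1_config):
        x = m1_config.covariate_vector(
            {"aad": 0, "sex": 0.13, "lvef": 1, "country": 1}, 63.0)
        assert x[2] == 0.13

    def test_missing_covariate_raises(self, m1_config):
        with pytest.raises(KeyError, match="sex"):
            m1_config.covariate_vector({"aad": 0, "lvef": 1, "country": 1}, 63.0)


class TestPredictorsAndProbabilities:
    def test_zero_theta_uniform_from_state1(self, m1_config, m1_index):
        x = m1_config.covariate_vector(
            {"aad": 1, "sex": 0, "lvef": 1, "country": 1}, 63.0)
        p = transition_probabilities(m1_index, np.zeros(59), x, 1)
        np.testing.assert_allclose(p, np.full(8, 1 / 8))

    def test_zero_theta_uniform_from_state2(self, m1_config, m1_index):
        x = m1_config.covariate_vector(
            {"aad": 1, "sex": 0, "lvef": 1, "country": 1}, 63.0)
        p = transition_probabilities(m1_index, np.zeros(59), x, 2)
        expected = np.zeros(8)
        expected[[0, 1, 7]] = 1 / 3
        np.testing.assert_allclose(p, expected)

    def test_absorbing_row(self, m1_config, m1_index):
        x = m1_config.covariate_vector(
            {"aad": 1, "sex": 0, "lvef": 1, "country": 1}, 63.0)
        p = transition_probabilities(m1_index, np.zeros(59), x, 8)
        expected = np.zeros(8)
        expected[7] = 1.0
        np.testing.assert_allclose(p, expected)

    def test_single_coefficient_identity(self):
        index = build_parameter_index(two_state_config((CovariateSpec("z"),)))
        assert index.n_free == 2
        cfg = index.config
        b = 0.7
        theta = np.zeros(2)
        theta[index.position[(1, 2, 1)]] = b
        x = cfg.covariate_vector({"z": 1.0}, 63.0)
        eta = linear_predictors(index, theta, x, 1)
        np.testing.assert_allclose(eta, [b])
        x0 = cfg.covariate_vector({"z": 0.0}, 63.0)
        np.testing.assert_allclose(linear_predictors(index, theta, x0, 1), [0.0])

    def test_tied_death_row_same_logodds(self, m1_config, m1_index):
        rng = np.random.default_rng(0)
        theta = rng.normal(0, 0.5, 59)
        x = m1_config.covariate_vector(
            {"aad": 1, "sex": 1, "lvef": 0, "country": 0}, 66.0)
        death_eta = []
        for r in range(1, 8):
            eta = linear_predictors(m1_index, theta, x, r)
            dests = m1_config.state_space.destinations(r)
            death_eta.append(eta[dests.index(8)])
        np.testing.assert_allclose(death_eta, death_eta[0])

    def test_overflow_handled(self, m1_config, m1_index):
        theta = np.zeros(59)
        theta[m1_index.position[(1, 8, 0)]] = 700.0
        x = m1_config.covariate_vector(
            {"aad": 0, "sex": 0, "lvef": 0, "country": 0}, 50.0)
        p = transition_probabilities(m1_index, theta, x, 1)
        assert np.all(np.isfinite(p))
        assert p[7] == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.sampled_from(list(MODEL_LABELS)))
    def test_rows_sum_to_one_and_zero_off_permitted(self, seed, label):
        cfg = build_model_config(label)
        index = build_parameter_index(cfg)
        rng = np.random.default_rng(seed)
        theta = rng.normal(0, 2, index.n_free)
        raw = {"aad": float(rng.integers(2)), "sex": float(rng.random()),
               "lvef": float(rng.integers(2)), "country": float(rng.integers(2))}
        x = cfg.covariate_vector(raw, float(rng.uniform(40, 90)))
        sp = cfg.state_space
        for r in range(1, 9):
            p = transition_probabilities(index, theta, x, r)
            assert abs(p.sum() - 1.0) < 1e-12
            for s in range(1, 9):
                if (r, s) not in sp.permitted:
                    assert p[s - 1] == 0.0


class TestSerialization:
    @pytest.mark.parametrize("label", ["M1", "M2", "M7", "M10"])
    def test_yaml_round_trip_lossless(self, label):
        cfg = build_model_config(label)
        text = yaml.safe_dump(config_to_dict(cfg))
        back = config_from_dict(yaml.safe_load(text))
        assert back == cfg
        assert build_parameter_index(back).names == build_parameter_index(cfg).names

    def test_digest_stable_and_distinct(self):
        assert build_model_config("M1").digest() == build_model_config("M1").digest()
        assert build_model_config("M1").digest() != build_model_config("M2").digest()
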