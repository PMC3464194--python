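import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rewardctl.decision import (
    MARMOSET,
    STEVENS_GRID,
    TAMARIN,
    ChoiceModel,
    CohortSpec,
    MonkeyParams,
    Option,
    choice_probability,
    indifference_point,
    option_utility,
    sample_cohort,
    stevens_pipeline,
)
from rewardctl.feedback import simulate_trial
from rewardctl.horizon import InternalParams, TaskParams
from rewardctl.ocp_linear import closed_form_utility_objectI


@pytest.fixture(scope="module")
def mean_marmoset():
    from rewardctl.ocp_linear import identify_parameters

    vig, g = identify_parameters((0.35, 1.0, 0.75), (2.45, 3.0, 1.84))
    return MonkeyParams(vig, g)


class TestOptionUtility:
    def test_zero_distance(self):
        p = MonkeyParams(vigor=4.0, gamma=2.0)
        assert option_utility(p, Option(0.0, 1.5)) == 6.0

    def test_decreasing_in_distance(self):
        p = MonkeyParams(vigor=1.0, gamma=2.0)
        us = [option_utility(p, Option(A, 3.0))
              for A in np.arange(0.35, 2.46, 0.35)]
        assert np.all(np.diff(us) < 0)

    def test_increasing_in_reward(self):
        p = MonkeyParams(vigor=1.0, gamma=2.0)
        us = [option_utility(p, Option(1.0, r)) for r in (1.0, 2.0, 3.0)]
        assert np.all(np.diff(us) > 0)

    def test_unviable_option_worth_zero(self):
        p = MonkeyParams(vigor=0.001, gamma=0.5)
        assert option_utility(p, Option(5.0, 1.0)) == 0.0


class TestIndifference:
    def test_equal_rewards_no_crossover_inside(self):
        p = MonkeyParams(vigor=5.0, gamma=2.0)
        ref = Option(0.35, 1.0)
        # same reward farther away is always worse: no sign change
        assert indifference_point(p, ref, 1.0, (0.40, 2.45)) is None

    def test_reference_configuration_has_crossover(self):
        p = MonkeyParams(vigor=1.0, gamma=2.0)
        x = indifference_point(p, Option(0.35, 1.0), 3.0, (0.35, 2.45))
        assert x is not None
        assert 0.35 < x < 2.45

    def test_bisection_matches_grid(self, mean_marmoset):
        p = mean_marmoset
        x = indifference_point(p, Option(0.35, 1.0), 3.0, (0.35, 2.45))
        grid = np.arange(0.35, 2.45, 0.001)
        ref_u = option_utility(p, Option(0.35, 1.0))
        diff = np.array([option_utility(p, Option(A, 3.0)) - ref_u
                         for A in grid])
        k = np.flatnonzero(np.diff(np.sign(diff)))[0]
        assert abs(x - grid[k]) <= 0.002


class TestChoice:
    def test_equal_utilities(self):
        assert choice_probability(1.0, 1.0, ChoiceModel(1.0)) == 0.5

    def test_low_temperature_deterministic(self):
        assert choice_probability(2.0, 1.0, ChoiceModel(1e-6)) == \
            pytest.approx(1.0)

    @given(j1=st.floats(-50, 50), j2=st.floats(-50, 50),
           beta=st.floats(0.05, 10))
    @settings(max_examples=60, deadline=None)
    def test_complementarity(self, j1, j2, beta):
        m = ChoiceModel(beta)
        assert choice_probability(j1, j2, m) + \
            choice_probability(j2, j1, m) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_beta(self):
        with pytest.raises(ValueError):
            ChoiceModel(beta=0.0)


class TestCohortSampling:
    def test_zero_variance_equals_means(self):
        spec = CohortSpec((0.35, 1.0, 0.75, 1e-12), (2.45, 3.0, 1.84, 1e-12),
                          n=5)
        durations, params, _ = sample_cohort(spec,
                                             np.random.default_rng(0))
        assert np.allclose(durations[:, 0], 0.75, atol=1e-9)
        assert np.allclose(durations[:, 1], 1.84, atol=1e-9)
        vs = [p.vigor for p in params]
        assert np.ptp(vs) < 1e-6

    def test_mean_close_to_specified(self):
        spec = CohortSpec(MARMOSET.cond1, MARMOSET.cond2, n=100)
        durations, _, _ = sample_cohort(spec, np.random.default_rng(2))
        sd1 = spec.sds[0]
        assert abs(durations[:, 0].mean() - 0.75) < 3 * sd1 / np.sqrt(100)

    def test_seeded_reproducibility(self):
        d1, p1, _ = sample_cohort(MARMOSET, np.random.default_rng(5))
        d2, p2, _ = sample_cohort(MARMOSET, np.random.default_rng(5))
        assert np.array_equal(d1, d2)
        assert all(a == b for a, b in zip(p1, p2))

    def test_resample_policy_censors_low_ratios(self):
        # under the resampling policy every retained pair is identifiable
        d, p, n_un = sample_cohort(MARMOSET, np.random.default_rng(8),
                                   on_failure="resample")
        assert n_un > 0          # some draws were unidentifiable
        ratios = d[:, 1] / d[:, 0]
        assert ratios.min() > 2.0  # censored below the identifiable limit

    def test_refit_policy_keeps_all_draws(self):
        d, p, n_un = sample_cohort(MARMOSET, np.random.default_rng(8))
        gammas = np.array([m.gamma for m in p])
        assert n_un > 0
        assert (gammas == 1e5).sum() == n_un  # boundary-refit subjects

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            sample_cohort(MARMOSET, np.random.default_rng(0),
                          on_failure="discard")

    def test_sd_is_sem_scaled(self):
        assert MARMOSET.sds[0] == pytest.approx(0.061 * 2.0)
        assert TAMARIN.sds[1] == pytest.approx(0.050 * 2.0)


class TestStevensPipeline:
    @pytest.fixture(scope="class")
    def result(self):
        return stevens_pipeline(seed=0)

    def test_species_separable_in_parameter_space(self):
        # the identified clouds are linearly separable to > 90 %; measured
        # on exactly identified subjects (boundary-refit subjects of both
        # species stack on the gamma limit and blur the clouds)
        from sklearn.linear_model import LogisticRegression

        res = stevens_pipeline(seed=0, on_failure="resample")
        X, y = [], []
        for label, species in enumerate(("marmoset", "tamarin")):
            for p in res[species].params:
                X.append([np.log(p.vigor), np.log(p.gamma)])
                y.append(label)
        clf = LogisticRegression(C=1e4).fit(X, y)
        assert clf.score(X, y) > 0.9

    def test_tamarin_never_reverses(self, result):
        assert result["tamarin"].reversal_cm is None

    def test_marmoset_reverses_within_grid(self, result):
        assert result["marmoset"].reversal_cm is not None
        assert result["marmoset"].reversal_cm <= 245.0

    def test_majority_of_marmosets_reverse(self, result):
        frac = np.mean(np.isfinite(result["marmoset"].indifference))
        assert frac > 0.5

    def test_dataframe_shape(self, result):
        df = result["marmoset"].to_dataframe()
        assert len(df) == 100
        assert "u_large_245cm" in df.columns

    def test_zero_variance_matches_single_monkey(self, mean_marmoset):
        tiny = 1e-12
        spec = CohortSpec((0.35, 1, 0.75, tiny), (2.45, 3, 1.84, tiny), n=3)
        # (the analogous degenerate cohort for the other species is
        # unidentifiable: its exact mean duration ratio lies below the
        # identifiable limit, so it is exercised with the same stats here)
        res = stevens_pipeline(marmoset=spec, tamarin=spec, seed=1)
        p = res["marmoset"].params[0]
        assert p.vigor == pytest.approx(mean_marmoset.vigor, rel=1e-4)
        assert p.gamma == pytest.approx(mean_marmoset.gamma, rel=1e-4)


class TestParameterDissociation:
    def test_vigor_and_discount_shift_indifference_same_way(self):
        ref = Option(0.35, 1.0)
        hi_v = indifference_point(MonkeyParams(50.0, 2.0), ref, 3.0,
                                  (0.35, 8.0))
        lo_v = indifference_point(MonkeyParams(16.0, 2.0), ref, 3.0,
                                  (0.35, 8.0))
        assert lo_v < hi_v  # lower vigor: reversal closer (small-reward bias)
        hi_g = indifference_point(MonkeyParams(50.0, 4.0), ref, 3.0,
                                  (0.35, 30.0))
        lo_g = indifference_point(MonkeyParams(50.0, 1.0), ref, 3.0,
                                  (0.35, 30.0))
        assert lo_g < hi_g

    def test_durations_dissociate(self):
        from rewardctl.ocp_linear import closed_form_duration_objectI as T

        # lower vigor lengthens movements...
        assert T(0.35, 1.0, 16.0, 2.0) > T(0.35, 1.0, 50.0, 2.0)
        # ...while lower gamma (same indifference shift) shortens them
        assert T(0.35, 1.0, 50.0, 1.0) < T(0.35, 1.0, 50.0, 4.0)


class TestDecisionActionConsistency:
    def test_choice_utility_equals_realized_utility(self, point_mass,
                                                    mean_marmoset):
        # the utility used for the decision equals discounted reward minus
        # realized effort of the zero-noise closed-loop execution
        p = mean_marmoset
        u_decision = option_utility(p, Option(0.35, 1.0))
        internal = InternalParams(rho=p.vigor, eps=1.0, gamma=p.gamma)
        task = TaskParams([0.35, 0.0], 1.0)
        trace, out = simulate_trial(point_mass, task, internal,
                                    horizon_max=1.5,
                                    rng=np.random.default_rng(0))
        eff = float(np.sum(np.exp(-trace.time / p.gamma)
                           * trace.controls[:, 0] ** 2) * 0.001)
        realized = p.vigor * 1.0 * np.exp(-out.duration / p.gamma) - eff
        assert realized == pytest.approx(u_decision, rel=0.02)
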