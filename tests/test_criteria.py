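import math

import numpy as np
import pytest

from markovselect import (
    Alphabet,
    DirichletPrior,
    MemorySpec,
    TrajectorySet,
    aic_bic,
    count_transitions,
    criteria_values,
    dic,
    evaluate_all,
    lho,
    log_multivariate_beta,
    loo,
    marginal_criteria,
    select_model,
    stirling_log_beta,
    waic,
)

AB = Alphabet(("-", "+"))


def empty_counts():
    """A count table with no observations (zero-length bookkeeping only)."""
    from markovselect.trajectories import CountTable

    return CountTable(0, AB, {}, [{}])


def exact_log_beta(values):
    """log B for positive integers via exact factorials."""
    num = sum(math.lgamma(v) for v in values)
    return num - math.lgamma(sum(values))


class TestLogBeta:
    def test_b_1_1_is_one(self):
        assert log_multivariate_beta([1.0, 1.0]) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "vec", [[7, 13], [3, 6], [2, 3, 4], [1, 1, 1, 1]]
    )
    def test_matches_exact_factorials(self, vec):
        assert log_multivariate_beta(vec) == pytest.approx(exact_log_beta(vec), abs=1e-12)

    def test_printed_values(self):
        assert log_multivariate_beta([7, 13]) == pytest.approx(-12.7734, abs=1e-4)
        assert log_multivariate_beta([3, 6]) == pytest.approx(-5.1240, abs=1e-4)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_multivariate_beta([1.0, 0.0])

    def test_rowwise_broadcast(self):
        out = log_multivariate_beta(np.array([[7.0, 13.0], [3.0, 6.0]]))
        np.testing.assert_allclose(out, [exact_log_beta([7, 13]), exact_log_beta([3, 6])])


class TestStirling:
    @pytest.mark.parametrize(
        "vec,rtol",
        [([100.0, 100.0], 1e-6), ([1000.0, 2000.0, 3000.0], 1e-8), ([250.0, 400.0], 1e-6)],
    )
    def test_agrees_with_exact_for_large_components(self, vec, rtol):
        exact = log_multivariate_beta(vec)
        assert abs(stirling_log_beta(vec) - exact) / abs(exact) < rtol

    def test_small_arguments_no_error(self):
        # asymptotic regime only: inaccurate but defined
        assert math.isfinite(stirling_log_beta([1.0, 1.0]))


class TestAicBic:
    def test_worked_h0_literal(self, worked_h0):
        a, b, k = aic_bic(worked_h0, "literal")
        assert k == 1
        assert a == pytest.approx(22.9145 + 2, abs=1e-3)
        assert b == pytest.approx(22.9145 + math.log(18), abs=1e-3)

    def test_worked_h1_both_modes(self, worked_h1):
        a_lit, _, k_lit = aic_bic(worked_h1, "literal")
        a_ctx, _, k_ctx = aic_bic(worked_h1, "contexts")
        assert (k_lit, k_ctx) == (2, 3)
        assert a_lit == pytest.approx(24.1622, abs=1e-3)
        assert a_ctx == pytest.approx(26.1622, abs=1e-3)

    def test_empty_counts(self):
        a, _, k = aic_bic(empty_counts(), "literal")
        assert (a, k) == (2.0, 1.0)

    def test_literal_mode_rejects_merged_table(self, worked_h1):
        from markovselect import merge_contexts

        spec = MemorySpec(partition=((("-",),), (("+",), (".",))))
        with pytest.raises(ValueError):
            aic_bic(merge_contexts(worked_h1, spec), "literal")


class TestMarginal:
    def test_worked_h0_nlml(self, worked_h0):
        nlml, _, _ = marginal_criteria(worked_h0)
        assert nlml == pytest.approx(-2 * exact_log_beta([7, 13]), abs=1e-10)
        assert nlml == pytest.approx(25.5469, abs=1e-4)

    def test_empty_counts_all_zero(self):
        assert marginal_criteria(empty_counts()) == (0.0, 0.0, 0.0)

    def test_single_trajectory_lppd_equals_lpd(self):
        ts = TrajectorySet(AB, [tuple("+-++-++")])
        counts = count_transitions(ts, 0)
        _, nlpd, nlppd = marginal_criteria(counts)
        assert nlppd == pytest.approx(nlpd, abs=1e-12)


class TestLooLho:
    def test_worked_h0_loo_exact(self, worked_h0):
        expected = -2 * (
            (exact_log_beta([7, 13]) - exact_log_beta([5, 8]))
            + (exact_log_beta([7, 13]) - exact_log_beta([3, 6]))
        )
        assert loo(worked_h0) == pytest.approx(expected, abs=1e-10)
        assert loo(worked_h0) == pytest.approx(24.2778, abs=1e-4)

    def test_single_trajectory_loo_equals_nlml(self):
        ts = TrajectorySet(AB, [tuple("+-++-++")])
        for h in (0, 1):
            counts = count_transitions(ts, h)
            assert loo(counts) == pytest.approx(marginal_criteria(counts)[0], abs=1e-12)

    def test_lho_two_identical_trajectories_symmetric(self):
        ts = TrajectorySet(AB, [tuple("+-++"), tuple("+-++")])
        counts = count_transitions(ts, 1)
        # halves are identical so each contributes the same term: LHO = 2x one half
        half = -2 * sum(
            exact_log_beta((np.array(v) + np.array(v) + 1).tolist())
            - exact_log_beta((np.array(v) + 1).tolist())
            for v in (d.tolist() for d in counts.per_traj[0].values())
        )
        assert lho(counts) == pytest.approx(2 * half, abs=1e-10)

    def test_lho_single_trajectory_is_error(self):
        ts = TrajectorySet(AB, [tuple("+-")])
        with pytest.raises(ValueError):
            lho(count_transitions(ts, 0))


class TestWaicDic:
    def test_empty_counts_zero(self):
        assert waic(empty_counts(), variant=1) == (0.0, 0.0)
        assert waic(empty_counts(), variant=2) == (0.0, 0.0)
        assert dic(empty_counts(), variant=1) == (0.0, 0.0)
        assert dic(empty_counts(), variant=2) == (0.0, 0.0)

    def test_waic2_matches_termwise_reimplementation(self, worked_h1):
        """Independent double loop over trajectories and contexts."""
        from scipy.special import polygamma

        a = np.ones(2)
        k = 0.0
        for d in worked_h1.per_traj:
            for ctx, nj in d.items():
                N = worked_h1.pooled[ctx]
                k += sum(
                    nj[m] ** 2 * polygamma(1, a[m] + N[m]) for m in range(2)
                ) - nj.sum() ** 2 * polygamma(1, N.sum() + a.sum())
        _, k_pkg = waic(worked_h1, variant=2)
        assert k_pkg == pytest.approx(float(k), abs=1e-12)

    def test_dic_plugin_uses_posterior_mean(self, worked_h0):
        # plug-in deviance at mean [7/20, 13/20]
        plug = -2 * (6 * math.log(7 / 20) + 12 * math.log(13 / 20))
        d1, k1 = dic(worked_h0, variant=1)
        assert d1 - 2 * k1 == pytest.approx(plug, abs=1e-10)


class TestEvaluateAll:
    def test_worked_aic_column(self, worked):
        report = evaluate_all(worked, [MemorySpec(order=0), MemorySpec(order=1)])
        np.testing.assert_allclose(
            report.table["AIC"].values, [24.9145, 24.1622], atol=1e-3
        )

    def test_empty_spec_list_is_error(self, worked):
        with pytest.raises(ValueError):
            evaluate_all(worked, [])

    def test_partition_row_has_two_parameters(self, worked):
        spec = MemorySpec(partition=((("-",),), (("+",), (".",))))
        report = evaluate_all(worked, [MemorySpec(order=0), spec])
        assert report.table.loc[spec.label(), "k_param"] == 2

    def test_single_trajectory_warns_and_omits_lho(self):
        ts = TrajectorySet(AB, [tuple("+-++-++")])
        with pytest.warns(UserWarning, match="LHO"):
            report = evaluate_all(ts, [MemorySpec(order=0)])
        assert np.isnan(report.table["LHO"].iloc[0])

    def test_prior_insensitivity_grows_with_counts(self, worked):
        """Per-transition LOO gap between alpha=1 and alpha=1/2 shrinks as J grows."""
        gaps = []
        for scale in (1, 10, 100):
            ts = TrajectorySet(AB, list(worked.trajectories) * scale)
            counts = count_transitions(ts, 1)
            gaps.append(
                abs(loo(counts, DirichletPrior.uniform(2)) - loo(counts, DirichletPrior.jeffreys(2)))
                / counts.total_transitions
            )
        assert gaps[0] > gaps[1] > gaps[2]


class TestSelectModel:
    def test_argmin_by_aic(self, worked):
        report = evaluate_all(worked, [MemorySpec(order=0), MemorySpec(order=1)])
        assert select_model(report, "AIC") == MemorySpec(order=1)

    def test_tie_breaks_to_simpler_model(self, worked):
        report = evaluate_all(worked, [MemorySpec(order=0), MemorySpec(order=1)])
        report.table.loc[:, "AIC"] = 1.0  # force a tie
        assert select_model(report, "AIC") == MemorySpec(order=0)

    def test_missing_criterion_is_error(self, worked):
        report = evaluate_all(worked, [MemorySpec(order=0)])
        with pytest.raises(KeyError):
            select_model(report, "XYZ")

    def test_lho_with_single_trajectory_is_error(self):
        ts = TrajectorySet(AB, [tuple("+-++-++")])
        with pytest.warns(UserWarning):
            report = evaluate_all(ts, [MemorySpec(order=0)])
        with pytest.raises(ValueError):
            select_model(report, "LHO")


class TestCriteriaValues:
    def test_matches_individual_functions(self, worked_h1):
        vals = criteria_values(worked_h1)
        assert vals["LOO"] == pytest.approx(loo(worked_h1), abs=1e-12)
        assert vals["LHO"] == pytest.approx(lho(worked_h1), abs=1e-12)
        nlml, nlpd, nlppd = marginal_criteria(worked_h1)
        assert vals["nLML"] == pytest.approx(nlml, abs=1e-12)
        assert vals["nLPD"] == pytest.approx(nlpd, abs=1e-12)
        assert vals["nLPPD"] == pytest.approx(nlppd, abs=1e-12)
        for variant, key in ((1, "WAIC1"), (2, "WAIC2")):
            assert vals[key] == pytest.approx(waic(worked_h1, variant=variant)[0], abs=1e-12)
        for variant, key in ((1, "DIC1"), (2, "DIC2")):
            assert vals[key] == pytest.approx(dic(worked_h1, variant=variant)[0], abs=1e-12)

    def test_deviance_nonnegative_and_nonincreasing_in_h(self, worked):
        from markovselect import count_all_orders

        tables = count_all_orders(worked, 3)
        devs = [criteria_values(tables[h])["deviance"] for h in range(4)]
        assert all(d >= 0 for d in devs)
        assert all(b <= a + 1e-12 for a, b in zip(devs, devs[1:]))
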