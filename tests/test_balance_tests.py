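"""Rule predictions, selection-time optimality, Monte-Carlo nulls, likelihoods."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from codonbalance.balance_tests import (
    expected_selection_time,
    null_distance_test,
    optimal_usage_numeric,
    predict_usage,
    rule_likelihood,
    synonymous_correlation_sign_test,
    trna_availability_correlation,
)
from codonbalance.genetic_code import UsageVector


def uv(*vals, keys=None):
    keys = keys or [f"c{i}" for i in range(len(vals))]
    return UsageVector(dict(zip(keys, vals)))


class TestPredictUsage:
    def test_proportional_is_identity(self):
        q = uv(0.5, 0.5)
        assert predict_usage(q, "proportional").values == q.values

    def test_square_renormalizes(self):
        p = predict_usage(uv(2 / 3, 1 / 3), "square")
        assert p["c0"] == pytest.approx(0.8)
        assert p["c1"] == pytest.approx(0.2)

    def test_truncation_picks_modal_trna(self):
        p = predict_usage(uv(0.3, 0.7), "truncation")
        assert p.values == {"c0": 0.0, "c1": 1.0}

    def test_truncation_tie_flagged_lexicographic(self):
        with pytest.warns(UserWarning, match="tie"):
            p = predict_usage(uv(0.5, 0.5), "truncation")
        assert p["c0"] == 1.0

    @pytest.mark.parametrize("rule", ["proportional", "square", "truncation"])
    def test_predictions_are_valid_usage_vectors(self, rng, rule):
        for _ in range(50):
            k = int(rng.integers(2, 7))
            e = rng.standard_exponential(k)
            p = predict_usage(uv(*(e / e.sum())), rule)
            assert sum(p.values.values()) == pytest.approx(1.0)


class TestExpectedSelectionTime:
    def test_balanced_usage_attains_minimum_one(self, rng):
        for k in (2, 3, 6):
            e = rng.standard_exponential(k)
            q = uv(*(e / e.sum()))
            assert expected_selection_time(q, q) == pytest.approx(1.0)

    def test_exclusive_use_against_even_pool(self):
        assert expected_selection_time(uv(1.0, 0.0), uv(0.5, 0.5)) == 2.0

    def test_grid_search_confirms_proportional_optimum(self):
        q = uv(0.8, 0.2)
        best, best_t = None, math.inf
        for i in range(1, 10_000):
            p = uv(i * 1e-4, 1 - i * 1e-4)
            t = expected_selection_time(p, q)
            if t < best_t:
                best, best_t = p["c0"], t
        assert best == pytest.approx(0.8, abs=1e-4)
        assert best_t == pytest.approx(1.0, abs=1e-6)

    def test_numeric_minimizer_returns_q(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 7))
            e = rng.standard_exponential(k)
            q = e / e.sum()
            p = optimal_usage_numeric(q)
            assert np.max(np.abs(p - q)) < 1e-3
            assert np.sum(p**2 / q) == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-3, max_value=1e3),
            min_size=2,
            max_size=6,
        ),
        st.lists(
            st.floats(min_value=1e-3, max_value=1e3),
            min_size=2,
            max_size=6,
        ),
    )
    def test_selection_time_never_below_balanced_minimum(self, ps, qs):
        """t >= 1 for any usage, with equality exactly at p = q."""
        k = min(len(ps), len(qs))
        p = np.array(ps[:k]) / np.sum(ps[:k])
        q = np.array(qs[:k]) / np.sum(qs[:k])
        keys = [f"c{i}" for i in range(k)]
        t = expected_selection_time(
            uv(*p, keys=keys), uv(*q, keys=keys)
        )
        assert t >= 1.0 - 1e-9
        if np.allclose(p, q, atol=1e-12):
            assert t == pytest.approx(1.0)

    def test_zero_trna_with_usage_is_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            t = expected_selection_time(uv(0.5, 0.5), uv(1.0, 0.0))
        assert math.isinf(t)


class TestNullDistanceTest:
    def test_perfect_fit_has_p_zero(self):
        q = {"E": uv(0.7, 0.3)}
        res = null_distance_test(q, q, replicates=2000, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 0.0

    def test_two_codon_closed_form(self):
        q = {"E": uv(0.5, 0.5)}
        obs = {"E": uv(0.62, 0.38)}
        res = null_distance_test(obs, q, replicates=400_000, seed=3)
        # distance = sqrt(2)|u - 1/2| with u uniform: P(dist < d) = sqrt(2) d
        assert res.p_value == pytest.approx(math.sqrt(2) * res.statistic, abs=0.01)

    @pytest.mark.parametrize("direction", ["codon", "trna"])
    def test_uniform_observed_uniform_prediction(self, direction):
        q = {"E": uv(0.5, 0.5), "K": uv(0.5, 0.5)}
        res = null_distance_test(q, q, direction=direction, replicates=1000, seed=1)
        assert res.p_value == 0.0

    def test_distance_zero_iff_proportional(self, rng):
        e = rng.standard_exponential(3)
        q = {"A": uv(*(e / e.sum()), keys=list("xyz"))}
        res = null_distance_test(q, q, replicates=10, seed=0)
        assert res.per_family["A"][0] == 0.0
        other = {"A": uv(*np.roll(e / e.sum(), 1), keys=list("xyz"))}
        res2 = null_distance_test(other, q, replicates=10, seed=0)
        assert res2.per_family["A"][0] > 0


class TestRuleLikelihood:
    def test_same_rule_ratio_zero(self, rng):
        e = rng.standard_exponential(4)
        q = {"A": uv(*(e / e.sum()))}
        counts = {"A": {f"c{i}": float(rng.integers(1, 50)) for i in range(4)}}
        assert rule_likelihood(counts, q, "proportional", "proportional") == 0.0

    def test_proportional_counts_beat_square(self):
        q = {"A": uv(0.6, 0.4)}
        counts = {"A": {"c0": 60.0, "c1": 40.0}}
        assert rule_likelihood(counts, q, "proportional", "square") > 0

    def test_truncation_zero_likelihood_is_sentinel_inf(self):
        q = {"A": uv(0.6, 0.4)}
        counts = {"A": {"c0": 60.0, "c1": 40.0}}
        assert rule_likelihood(counts, q, "proportional", "truncation") == math.inf
        assert rule_likelihood(counts, q, "truncation", "proportional") == -math.inf

    def test_matches_independent_log_domain_computation(self, rng):
        fams = {}
        q = {}
        for aa in "ABC":
            k = int(rng.integers(2, 5))
            e = rng.standard_exponential(k)
            q[aa] = uv(*(e / e.sum()))
            fams[aa] = {
                f"c{i}": float(rng.integers(0, 40)) for i in range(k)
            }
        got = rule_likelihood(fams, q, "proportional", "square", effective_total=None)
        want = 0.0
        for aa, counts in fams.items():
            keys = sorted(counts)
            x = np.array([counts[k] for k in keys])
            qv = np.array([q[aa][k] for k in keys])
            sq = qv**2 / np.sum(qv**2)
            for pred, sign in ((qv, 1.0), (sq, -1.0)):
                ll = math.lgamma(x.sum() + 1) - sum(
                    math.lgamma(v + 1) for v in x
                )
                ll += float(np.sum(x[x > 0] * np.log(pred[x > 0])))
                want += sign * ll
        assert got == pytest.approx(want / math.log(10))


class TestAvailabilityCorrelation:
    def test_constant_cst_signalled(self):
        aas = list("ACDEFG")
        with pytest.raises(ValueError, match="variance"):
            trna_availability_correlation(
                {a: 1 / 6 for a in aas},
                {a: i + 1.0 for i, a in enumerate(aas)},
                {a: 0.5 for a in aas},
            )

    def test_perfect_anticorrelation(self):
        aas = list("ACDEFG")
        copies = {a: float(i + 1) for i, a in enumerate(aas)}
        freq = {a: 1 / 6 for a in aas}
        total = sum(copies.values())
        cst = {a: 1.0 - copies[a] / total / freq[a] * 0.1 for a in aas}
        r, p = trna_availability_correlation(freq, copies, cst, permutations=500, seed=0)
        assert r == pytest.approx(-1.0)
        assert p <= 1 / 500

    def test_permutation_p_matches_exhaustive_oracle(self, rng):
        aas = list("ACDEFG")
        freq = {a: 1 / 6 for a in aas}
        copies = {a: float(rng.integers(1, 20)) for a in aas}
        cst = {a: float(rng.uniform(0.2, 1.0)) for a in aas}
        r, p = trna_availability_correlation(
            freq, copies, cst, permutations=4000, seed=1
        )
        total = sum(copies.values())
        avail = np.array([copies[a] / total / freq[a] for a in aas])
        vals = np.array([cst[a] for a in aas])
        rs = [
            stats.pearsonr(avail, np.array(perm)).statistic
            for perm in itertools.permutations(vals)
        ]
        exact = np.mean([x <= r + 1e-12 for x in rs])
        assert p == pytest.approx(exact, abs=0.03)


class TestSignTest:
    def test_twelve_of_eighteen_matches_reported_value(self):
        signs = {f"a{i}": -1.0 for i in range(12)}
        signs.update({f"b{i}": 1.0 for i in range(6)})
        p = synonymous_correlation_sign_test(signs)
        assert round(p, 2) == 0.12

    def test_null_expectation_not_significant(self):
        signs = {f"a{i}": -1.0 for i in range(9)}
        signs.update({f"b{i}": 1.0 for i in range(9)})
        assert synonymous_correlation_sign_test(signs) > 0.5

    def test_all_negative_extreme(self):
        signs = {f"a{i}": -1.0 for i in range(18)}
        p = synonymous_correlation_sign_test(signs)
        assert p == pytest.approx(2.0**-18)

    def test_zeros_excluded_with_warning(self):
        signs = {"a": -1.0, "b": 0.0, "c": -1.0}
        with pytest.warns(UserWarning, match="excluded"):
            p = synonymous_correlation_sign_test(signs)
        assert p == pytest.approx(0.25)
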