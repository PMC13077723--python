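"""ROR, PRR, chi-square, BCPNN and MGPS: examples, oracles, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import faersig as fs
from faersig import disproportionality as dp
from faersig.errors import ConfigurationError, FitError

from oracles import bcpnn_fraction_oracle, ebgm_quadrature_oracle

T = fs.ContingencyTable

cells = st.integers(min_value=1, max_value=5000)
tables = st.builds(T, cells, cells, cells, cells)


class TestRor:
    def test_identity_table(self):
        est, lo, hi = fs.ror(T(10, 10, 10, 10))
        assert est == 1.0
        assert lo == pytest.approx(1 / hi)

    def test_point_estimate(self):
        assert fs.ror(T(20, 10, 5, 40))[0] == 16.0

    def test_wald_ci_frozen_values(self):
        # exp(ln 16 +/- 1.96 * sqrt(1/20 + 1/10 + 1/5 + 1/40))
        _, lo, hi = fs.ror(T(20, 10, 5, 40))
        assert lo == pytest.approx(4.818009149189651, rel=1e-12)
        assert hi == pytest.approx(53.133979632034745, rel=1e-12)

    def test_zero_cell_undefined_unless_haldane(self):
        assert all(math.isnan(x) for x in fs.ror(T(0, 10, 5, 40)))
        est, lo, hi = fs.ror(T(0, 10, 5, 40), haldane=True)
        assert 0 < lo < est < hi


class TestPrr:
    def test_examples(self):
        assert fs.prr(T(10, 10, 10, 10))[0] == 1.0
        assert fs.prr(T(20, 10, 5, 40))[0] == 6.0  # 20*45 / (5*30)

    def test_ci_frozen_values(self):
        _, lo, hi = fs.prr(T(20, 10, 5, 40))
        assert lo == pytest.approx(2.528172194653747, rel=1e-12)
        assert hi == pytest.approx(14.239536403464987, rel=1e-12)

    def test_zero_c_undefined(self):
        assert all(math.isnan(x) for x in fs.prr(T(5, 10, 0, 40)))

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_sign_agrees_with_ror(self, t):
        # a/(a+b) > c/(c+d)  <=>  ad > bc
        sign = lambda x: (x > 0) - (x < 0)  # noqa: E731
        ror_e = fs.ror(t)[0]
        prr_e = fs.prr(t)[0]
        assert sign(prr_e - 1) == sign(ror_e - 1) == sign(t.a * t.d - t.b * t.c)


class TestChisq:
    def test_floored_at_zero(self):
        assert fs.chisq_yates(T(10, 10, 10, 10)) == 0.0

    def test_matches_library(self):
        want = chi2_contingency([[20, 10], [5, 40]], correction=True).statistic
        assert fs.chisq_yates(T(20, 10, 5, 40)) == pytest.approx(want, rel=1e-12)

    def test_zero_margin_undefined(self):
        assert math.isnan(fs.chisq_yates(T(0, 0, 5, 40)))

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_library_oracle_property(self, t):
        want = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=True).statistic
        assert fs.chisq_yates(t) == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestBcpnn:
    def test_empty_table_prior_centers_ic_at_zero(self):
        ic, v_ic, ic025 = fs.bcpnn(T(0, 0, 0, 0))
        assert ic == 0.0
        assert v_ic > 0 and ic025 == -2 * math.sqrt(v_ic)

    def test_frozen_exact_values(self):
        ic, v_ic, ic025 = fs.bcpnn(T(20, 10, 5, 40))
        assert ic == pytest.approx(0.9074512292479149, abs=1e-12)
        assert v_ic == pytest.approx(0.1648922225140992, abs=1e-12)
        assert ic025 == pytest.approx(0.09531276195530047, abs=1e-11)

    def test_invalid_priors_rejected(self):
        with pytest.raises(ConfigurationError):
            fs.BcpnnPriors(alpha1=0.0)

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_exact_rational_oracle(self, t):
        ic, v_ic, ic025 = fs.bcpnn(t)
        o_ic, o_v, o_ic025 = bcpnn_fraction_oracle(t.a, t.b, t.c, t.d)
        assert ic == pytest.approx(o_ic, abs=1e-12)
        assert v_ic == pytest.approx(o_v, abs=1e-12)
        assert ic025 == pytest.approx(o_ic025, abs=1e-11)

    def test_monotone_approach_to_unshrunk_limit(self):
        """Scaling (4,1,1,4) by k: E(IC) rises toward the raw log2
        observed/expected ratio of the table."""
        limit = math.log2(4 * 10 / (5 * 5))
        ics = [fs.bcpnn(T(4 * k, k, k, 4 * k))[0] for k in (1, 10, 100, 1000)]
        assert all(x < y for x, y in zip(ics, ics[1:]))
        assert all(ic < limit for ic in ics)
        assert ics[-1] == pytest.approx(limit, abs=0.01)

    @given(st.builds(T, st.integers(1, 5000), cells, cells, cells))
    @settings(max_examples=200, deadline=None)
    def test_shrinkage_never_exceeds_raw_ratio(self, t):
        """|E(IC)| stays within the raw log2 observed/expected magnitude,
        up to the posterior uncertainty the priors contribute."""
        expected = (t.a + t.b) * (t.a + t.c) / t.n
        raw = math.log2(t.a / expected)
        ic, v_ic, _ = fs.bcpnn(t)
        assert abs(ic) <= abs(raw) + 2 * math.sqrt(v_ic) + 1e-9


class TestMgps:
    prior = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)

    def test_quadrature_oracle(self):
        """Closed-form conjugate posterior vs direct numerical
        integration of prior x likelihood, to 1e-6."""
        for a_i, e_i in [(0, 0.5), (1, 2.0), (5, 1.3), (12, 4.0), (50, 10.0)]:
            got = dp._ebgm_pair(float(a_i), e_i, self.prior)
            want = ebgm_quadrature_oracle(a_i, e_i, self.prior)
            assert got[0] == pytest.approx(want[0], rel=1e-6)
            assert got[1] == pytest.approx(want[1], rel=1e-6)

    def test_weak_prior_large_count_limit_is_observed_over_expected(self):
        # near-improper single component prior, large counts: EBGM -> a/E
        theta = (1e-6, 1e-6, 1e-6, 1e-6, 0.5)
        ebgm, ebgm05 = dp._ebgm_pair(50000.0, 10000.0, theta)
        assert ebgm == pytest.approx(5.0, rel=1e-3)
        assert ebgm05 < ebgm

    def test_zero_count_shrinks_below_one(self):
        res = fs.ebgm_mgps([T(0, 10, 50, 1000), T(3, 7, 53, 1000)],
                           fs.MgpsOptions(prior=self.prior))
        assert res.ebgm[0] < 1.0
        assert res.ebgm05[0] < res.ebgm[0]

    def test_monotone_in_observed_count(self):
        # fixed expected count: shrunk estimate strictly increases with a
        vals = [dp._ebgm_pair(float(a), 5.0, self.prior)[0] for a in range(0, 30)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_degenerate_corpus_advises_fixed_prior(self):
        with pytest.raises(FitError, match="fixed prior"):
            fs.ebgm_mgps([T(0, 10, 50, 1000), T(0, 7, 53, 1000)])

    def test_fit_recovers_likelihood_dominance(self):
        """Fitted hyperparameters never fit worse than the truth that
        generated the corpus, and posterior summaries still match the
        quadrature oracle under the fitted prior."""
        rng = np.random.default_rng(42)
        truth = (0.5, 0.5, 3.0, 1.5, 0.4)
        e = rng.uniform(0.5, 20.0, size=500)
        comp = rng.random(500) < truth[4]
        lam = np.where(comp, rng.gamma(truth[0], 1 / truth[1], 500),
                       rng.gamma(truth[2], 1 / truth[3], 500))
        a = rng.poisson(lam * e)
        theta_hat, ll_hat = dp.fit_mgps_prior(a.astype(float), e)
        ll_truth, _, _ = dp._mixture_logmarginal(a.astype(float), e, truth)
        assert ll_hat >= float(ll_truth.sum()) - 1e-6
        for i in (0, 1, 2):
            got = dp._ebgm_pair(float(a[i]), float(e[i]), theta_hat)
            want = ebgm_quadrature_oracle(int(a[i]), float(e[i]), theta_hat)
            assert got[0] == pytest.approx(want[0], rel=1e-6)
            assert got[1] == pytest.approx(want[1], rel=1e-6)

    def test_requires_corpus(self):
        with pytest.raises(ConfigurationError):
            fs.ebgm_mgps([T(1, 2, 3, 4)])


class TestSignalFlags:
    def _result(self, **kw):
        base = dict(event_label="X", a=10, ror=5.0, ror_ci_low=2.0,
                    ror_ci_high=10.0, prr=5.0, prr_ci_low=2.0, prr_ci_high=10.0,
                    chisq=30.0, ic=1.5, v_ic=0.1, ic_minus_2sd=0.8,
                    ebgm=5.0, ebgm05=3.0)
        base.update(kw)
        return fs.SignalResult(**base)

    def test_low_count_gate_suppresses_everything(self):
        r, = fs.evaluate_signals([self._result(a=2, ror=1000.0, ror_ci_low=500.0)])
        assert not any(r.flags.values())

    def test_strong_ror_signal(self):
        # the shape of a strong SOC-level association: 69 reports,
        # ROR 6.36 (4.99, 8.11)
        r, = fs.evaluate_signals([self._result(
            a=69, ror=6.36, ror_ci_low=4.99, ror_ci_high=8.11)])
        assert r.flags["ror_signal"]

    def test_boundary_policy(self):
        # ROR >= 2 inclusive, CI lower bound > 1 strict
        r, = fs.evaluate_signals([self._result(ror=2.0, ror_ci_low=1.0)])
        assert not r.flags["ror_signal"]
        r, = fs.evaluate_signals([self._result(ror=2.0, ror_ci_low=1.0001)])
        assert r.flags["ror_signal"]
        r, = fs.evaluate_signals([self._result(prr=2.0, chisq=4.0)])
        assert r.flags["prr_signal"]  # both PRR cuts inclusive
        r, = fs.evaluate_signals([self._result(ic_minus_2sd=0.0)])
        assert not r.flags["bcpnn_signal"]

    def test_undefined_statistics_never_signal(self):
        nan = float("nan")
        r, = fs.evaluate_signals([self._result(ror=nan, ror_ci_low=nan,
                                               prr=nan, chisq=nan,
                                               ebgm05=nan)])
        assert not r.flags["ror_signal"] and not r.flags["prr_signal"]
        assert not r.flags["ebgm_signal"]
        assert r.flags["bcpnn_signal"]  # IC is defined for every table
        assert r.flags["any_of"] and not r.flags["all_of"]

    def test_combined_flags(self):
        r, = fs.evaluate_signals([self._result()])
        assert r.flags["all_of"] and r.flags["any_of"]


class TestRanking:
    def _r(self, label, ebgm, a=5):
        return fs.SignalResult(event_label=label, a=a, ebgm=ebgm)

    def test_descending_by_ebgm(self):
        ranked = fs.rank_results([self._r("Duodenal ulcer", 44.27),
                                  self._r("Erosive duodenitis", 227.4)])
        assert [r.event_label for r in ranked] == [
            "Erosive duodenitis", "Duodenal ulcer"]

    def test_tie_break_larger_a_first_then_label(self):
        ranked = fs.rank_results([self._r("B", 5.0, a=3), self._r("A", 5.0, a=9),
                                  self._r("C", 5.0, a=3)])
        assert [r.event_label for r in ranked] == ["A", "B", "C"]

    def test_shuffled_input_same_order(self):
        rng = np.random.default_rng(0)
        results = [self._r(f"E{i}", float(x), a=int(i % 7))
                   for i, x in enumerate(rng.random(50))]
        order1 = [r.event_label for r in fs.rank_results(results)]
        rng.shuffle(results)
        order2 = [r.event_label for r in fs.rank_results(results)]
        assert order1 == order2

    def test_nan_sorts_last_and_top_n(self):
        results = [self._r("A", float("nan")), self._r("B", 2.0), self._r("C", 9.0)]
        ranked = fs.rank_results(results, top_n=2)
        assert [r.event_label for r in ranked] == ["C", "B"]

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigurationError):
            fs.rank_results([self._r("A", 1.0)], key="flags")
        with pytest.raises(ConfigurationError):
            fs.rank_results([], key="ebgm")


def test_results_frame_columns():
    tables = [("X", T(20, 10, 5, 40)), ("Y", T(3, 27, 22, 23))]
    frame = dp.results_to_frame(fs.compute_signals(tables))
    assert list(frame.columns) == dp.RESULT_COLUMNS
    assert set(frame["event"]) == {"X", "Y"}
    row = frame.set_index("event").loc["X"]
    assert row["ror"] == 16.0 and row["case_reports"] == 20
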