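"""Brier score / IBS, concordance index, selection precision."""

import numpy as np
import pytest

from semisurv import (
    SurvivalDataset,
    brier_score,
    concordance_index,
    integrated_brier,
    selection_precision,
)


def step_oracle(ds):
    """Perfect predictor: S_i(t) = 1 before sample i's event, 0 after."""
    def pred(t):
        return (ds.time > t).astype(float)
    return pred


class TestBrierScore:
    def test_perfect_oracle_no_censoring(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1] * 4)
        for t in (0.5, 1.5, 2.5, 3.5):
            assert brier_score(t, step_oracle(ds), ds) == pytest.approx(0.0)

    def test_constant_predictor_no_censoring(self):
        ds = SurvivalDataset(X=np.zeros((5, 1)), time=[1, 2, 3, 4, 5], status=[1] * 5)
        s = 0.3
        t = 2.5  # 2 events <= t, 3 alive
        expected = (s ** 2 * 2 + (1 - s) ** 2 * 3) / 5
        assert brier_score(t, lambda _: np.full(5, s), ds) == pytest.approx(expected)

    def test_hand_value_with_censoring(self):
        # times (1, 2+, 3, 4), S(t|.) = 0.5 constant, t = 2.5:
        # censoring KM G: single censoring event at 2 with risk set {2,3,4},
        # so G(t) = 1 for t < 2 and 2/3 for t >= 2; left limits:
        #   i=1 event <= t: 0.25 / G(1-) = 0.25
        #   i=2 censored before t: 0
        #   i=3, i=4 alive: 0.25 / G(2.5-) = 0.25/(2/3) = 0.375 each
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1, 0, 1, 1])
        expected = (0.25 + 0.0 + 0.375 + 0.375) / 4
        got = brier_score(2.5, lambda _: np.full(4, 0.5), ds)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_negative_time_rejected(self):
        ds = SurvivalDataset(X=np.zeros((2, 1)), time=[1, 2], status=[1, 1])
        with pytest.raises(ValueError):
            brier_score(-1.0, lambda _: np.ones(2), ds)


class TestIntegratedBrier:
    def test_constant_bs_integrates_to_itself(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1] * 4)
        s = 0.5
        # constant S=0.5 with no censoring: BS(t) = (0.25*k + 0.25*(4-k))/4 = 0.25
        assert integrated_brier(lambda _: np.full(4, s), ds) == pytest.approx(0.25)

    def test_perfect_oracle_zero(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1] * 4)
        assert integrated_brier(step_oracle(ds), ds) == pytest.approx(0.0)

    def test_exact_sum_matches_riemann(self):
        rng = np.random.default_rng(0)
        n = 20
        ds = SurvivalDataset(X=np.zeros((n, 1)), time=rng.uniform(0.5, 5, n),
                             status=rng.integers(0, 2, n))
        rng2 = np.random.default_rng(1)
        base = rng2.uniform(0, 1, n)
        # per-sample constant survival probabilities: BS is then a step
        # function changing only at observed times, so the exact sum applies
        pred = lambda t: base
        exact = integrated_brier(pred, ds, grid="exact")
        # independent midpoint Riemann sum on a fine grid
        tmax = ds.time.max()
        ts = (np.arange(20000) + 0.5) * tmax / 20000
        from semisurv.metrics import _censoring_km
        G = _censoring_km(ds)
        riemann = np.mean([brier_score(t, pred, ds, G=G) for t in ts[::20]])
        assert exact == pytest.approx(riemann, abs=5e-3)


class TestConcordance:
    def test_perfect_and_reversed(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1] * 4)
        assert concordance_index([1, 2, 3, 4], ds) == 1.0
        assert concordance_index([4, 3, 2, 1], ds) == 0.0

    def test_toy_enumeration(self):
        ds = SurvivalDataset(X=np.zeros((4, 1)), time=[1, 2, 3, 4], status=[1] * 4)
        assert concordance_index([2, 1, 4, 3], ds) == pytest.approx(4 / 6)

    def test_censored_pairs_excluded(self):
        # i censored: pairs with t_i < t_j are not comparable
        ds = SurvivalDataset(X=np.zeros((3, 1)), time=[1, 2, 3], status=[0, 1, 1])
        # only comparable pair: (2, 3)
        assert concordance_index([5, 1, 2], ds) == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        n = 50
        ds = SurvivalDataset(X=np.zeros((n, 1)), time=rng.uniform(1, 9, n),
                             status=rng.integers(0, 2, n))
        f = rng.standard_normal(n)
        assert concordance_index(f, ds) == concordance_index(np.exp(f), ds)

    def test_ties_in_predictions_not_concordant(self):
        ds = SurvivalDataset(X=np.zeros((3, 1)), time=[1, 2, 3], status=[1, 1, 1])
        assert concordance_index([1, 1, 1], ds) == 0.0

    def test_matches_scikit_survival(self):
        from sksurv.metrics import concordance_index_censored

        rng = np.random.default_rng(3)
        n = 120
        ds = SurvivalDataset(X=np.zeros((n, 1)), time=rng.uniform(1, 9, n),
                             status=rng.integers(0, 2, n))
        f = rng.standard_normal(n)  # continuous: no ties
        ours = concordance_index(f, ds)
        ref = concordance_index_censored(ds.status.astype(bool), ds.time, -f)[0]
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_no_comparable_pairs_nan(self):
        ds = SurvivalDataset(X=np.zeros((2, 1)), time=[1, 2], status=[0, 0])
        assert np.isnan(concordance_index([1, 2], ds))


class TestSelectionPrecision:
    def test_perfect(self):
        rep = selection_precision(range(10), range(10))
        assert rep.precision == 1.0 and rep.n_correct == 10

    def test_partial(self):
        rep = selection_precision(range(20), range(8))
        assert rep.precision == pytest.approx(0.40)
        assert rep.n_correct == 8 and rep.n_selected == 20

    def test_empty_selection_flagged(self):
        rep = selection_precision([], range(10))
        assert np.isnan(rep.precision) and rep.n_selected == 0
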