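import numpy as np
import pandas as pd
import pytest

from ctdroc.doseroc import (censoring_survival, ctd_roc_threshold,
                            ctd_sensitivity_specificity, ctd_threshold_table,
                            ipcw_auc, stratified_km)
from ctdroc.roc import empirical_roc, mann_whitney_auc, youden_cutpoint


def _no_censoring_data(seed=0, n=200):
    """Markers drive dose; negatives censored exactly at the 500 mg horizon,
    so there is no censoring before the horizon."""
    rng = np.random.default_rng(seed)
    x = rng.normal(8, 3, n)
    latent = 10 ** (3.2 - 0.25 * (x - 8) + rng.normal(0, 0.6, n))
    grid = np.array([2.0, 7.0, 27.0, 77.0, 177.0, 277.0, 377.0])
    event = (latent <= 500).astype(int)
    dose = np.where(
        event == 1,
        [float(grid[max(np.searchsorted(grid, t, "left") - 1, 0)] if np.searchsorted(grid, t, "left") > 0 else 0.0)
         for t in np.minimum(latent, 499)],
        500.0,
    )
    return x, event, dose


class TestSeSp:
    def test_hand_worked_no_censoring(self):
        marker = [10, 8, 4, 2]
        event = [1, 1, 0, 0]
        dose = [27, 77, 500, 500]
        for est in ("km_subset", "ipcw"):
            se, sp = ctd_sensitivity_specificity(marker, event, dose, 5, 500, est)
            assert se == pytest.approx(1.0)
            assert sp == pytest.approx(1.0)

    def test_boundary_cutoff_below_support(self):
        marker = [10, 8, 4, 2]
        event = [1, 1, 0, 0]
        dose = [27, 77, 500, 500]
        se, sp = ctd_sensitivity_specificity(marker, event, dose, 0, 500)
        assert se == pytest.approx(1.0)
        assert sp == pytest.approx(0.0)

    def test_empirical_proportions_without_censoring(self):
        x, event, dose = _no_censoring_data(3)
        t = 500.0
        for c in np.percentile(x, [20, 50, 80]):
            se_e = np.mean(x[event == 1] > c)
            sp_e = np.mean(x[event == 0] <= c)
            for est in ("km_subset", "ipcw"):
                se, sp = ctd_sensitivity_specificity(x, event, dose, c, t, est)
                assert se == pytest.approx(se_e, abs=1e-10), est
                assert sp == pytest.approx(sp_e, abs=1e-10), est

    def test_intermediate_horizon_proportions(self):
        """At t below the censoring dose, cases are events by t and controls
        everyone else (no censoring before t), still exact proportions."""
        x, event, dose = _no_censoring_data(5)
        t = 77.0
        case = (event == 1) & (dose <= t)
        ctrl = ~case
        c = float(np.median(x))
        se, sp = ctd_sensitivity_specificity(x, event, dose, c, t, "km_subset")
        assert se == pytest.approx(np.mean(x[case] > c), abs=1e-10)
        assert sp == pytest.approx(np.mean(x[ctrl] <= c), abs=1e-10)


class TestIpcw:
    def test_auc_equals_mann_whitney_without_censoring(self):
        x, event, dose = _no_censoring_data(7)
        auc = ipcw_auc(x, event, dose, 500.0)
        assert auc == pytest.approx(
            mann_whitney_auc(x[event == 1], x[event == 0]), abs=1e-12
        )

    def test_weights_exceed_one_under_early_censoring(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.normal(0, 1, n)
        t_event = rng.exponential(200, n)
        t_cens = rng.uniform(50, 500, n)  # genuine early censoring
        event = (t_event <= t_cens).astype(int)
        dose = np.minimum(t_event, t_cens)
        g = censoring_survival(dose, event)
        assert g is not None
        assert g.survival.min() < 1.0
        auc = ipcw_auc(x, event, dose, 400.0)
        assert 0.0 <= auc <= 1.0

    def test_ipcw_se_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(0, 1, n)
        t_event = rng.exponential(150, n) * np.exp(-0.5 * x)
        t_cens = rng.uniform(100, 600, n)
        event = (t_event <= t_cens).astype(int)
        dose = np.minimum(t_event, t_cens)
        cuts = np.quantile(x, np.linspace(0.05, 0.95, 15))
        ses = [ctd_sensitivity_specificity(x, event, dose, c, 300.0, "ipcw")[0]
               for c in cuts]
        assert np.all(np.diff(ses) <= 1e-12)


class TestThreshold:
    def test_equals_binary_youden_without_censoring(self):
        """With censoring only at the horizon the dose-dependent threshold,
        Se, Sp and AUC reduce exactly to the binary-outcome quantities."""
        x, event, dose = _no_censoring_data(11)
        res = ctd_roc_threshold(x, event, dose, 500.0)
        binary = youden_cutpoint(empirical_roc(x, event))
        assert res.cutoff == pytest.approx(binary.cutoff)
        assert res.se_at_cut == pytest.approx(binary.se_at_cut, abs=1e-10)
        assert res.sp_at_cut == pytest.approx(binary.sp_at_cut, abs=1e-10)
        assert res.auc == pytest.approx(binary.auc, abs=1e-12)
        assert res.effective_horizon_mg == 500.0

    def test_uninformative_marker_null(self):
        rng = np.random.default_rng(4)
        n = 600
        x = rng.normal(size=n)
        event = rng.integers(0, 2, n)
        dose = np.where(event == 1, rng.choice([2.0, 27.0, 177.0], n), 500.0)
        res = ctd_roc_threshold(x, event, dose, 500.0)
        assert abs(res.auc - 0.5) < 0.07
        assert res.youden < 0.15

    def test_ppv_at_least_marginal_event_fraction(self):
        """When high-marker subjects react at low doses, PPV above the chosen
        cutoff beats the marginal event fraction."""
        x, event, dose = _no_censoring_data(13)
        res = ctd_roc_threshold(x, event, dose, 500.0)
        assert res.ppv >= event.mean()
        assert 0.0 <= res.npv <= 1.0

    def test_ppv_npv_accounting_without_censoring(self):
        """Law of total probability: PPV*P(X>c) + (1-NPV)*P(X<=c) = 1 - S(t)."""
        x, event, dose = _no_censoring_data(17)
        res = ctd_roc_threshold(x, event, dose, 500.0)
        p_above = np.mean(x > res.cutoff)
        lhs = res.ppv * p_above + (1.0 - res.npv) * (1 - p_above)
        assert lhs == pytest.approx(event.mean(), abs=1e-10)

    def test_horizon_fallback_all_positive(self):
        """A food with every challenge positive is inestimable at 500 mg and
        steps down to the largest estimable event dose."""
        marker = np.array([9.0, 7.0, 5.0, 3.0, 2.0, 1.0])
        event = np.ones(6, dtype=int)
        dose = np.array([0.0, 2.0, 7.0, 27.0, 78.0, 178.0])
        res = ctd_roc_threshold(marker, event, dose, 500.0)
        assert res.effective_horizon_mg < 500.0
        assert res.effective_horizon_mg in set(dose)
        assert np.isfinite(res.auc)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            ctd_roc_threshold([1, 2], [0, 0], [500, 500], 500.0)


class TestStratifiedKm:
    def test_empty_stratum_flagged(self):
        above, below, p = stratified_km([5, 6, 7], [1, 1, 0], [2, 7, 500], 0.0)
        assert below is None
        assert np.isnan(p)

    def test_informative_marker_dominance(self):
        x, event, dose = _no_censoring_data(19, n=400)
        res = ctd_roc_threshold(x, event, dose, 500.0)
        above, below, p = stratified_km(x, event, dose, res.cutoff)
        assert p < 0.01
        # above-threshold curve sits below at every shared event dose
        for d in above.dose_grid:
            assert above.at(d) <= below.at(d) + 1e-9

    def test_null_marker_p_uniform(self):
        """Stratifying on an uninformative marker gives null log-rank p."""
        rng = np.random.default_rng(23)
        pvals = []
        for _ in range(200):
            n = 60
            x = rng.normal(size=n)
            t = rng.exponential(100, n)
            event = (t < 400).astype(int)
            dose = np.minimum(t, 400.0)
            _, _, p = stratified_km(x, event, dose, 0.0)
            pvals.append(p)
        from scipy import stats
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestTable:
    def test_per_food_layout(self, records):
        tab = ctd_threshold_table(records)
        assert set(tab["marker"]) == {"spt", "sige", "siger"}
        ok = tab[tab["skipped"] == ""]
        assert ((ok["ppv"] >= 0) & (ok["ppv"] <= 1)).all()
        assert ((ok["npv"] >= 0) & (ok["npv"] <= 1)).all()
        assert (ok["effective_horizon_mg"] <= 500.0).all()
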