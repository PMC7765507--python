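"""Cox screening: follow-up truncation, Breslow Newton-Raphson vs brute force,
parameter recovery, prognosis classes, cross-cancer summary, anatomy ratios."""

import numpy as np
import pandas as pd
import pytest

from neurocoopt import survival as sv
from neurocoopt.errors import ValidationError
from neurocoopt.genelists import GeneList


# --- independent oracle: naive O(n^2) Breslow partial log-likelihood ---------

def naive_breslow_loglik(beta, times, events, x):
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_search_beta(times, events, x, lo=-3.0, hi=3.0, step=1e-3):
    grid = np.arange(lo, hi + step, step)
    lls = [naive_breslow_loglik(b, times, events, x) for b in grid]
    return grid[int(np.argmax(lls))]


def _fixture_cohort(rng, n=20, beta=0.8, censor_frac=0.3):
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-beta * x))
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    return t, event, x


class TestTruncateFollowup:
    def test_late_event_is_administratively_censored(self):
        surv = pd.DataFrame({"time_days": [4000.0, 1000.0], "event": [1, 1]})
        out = sv.truncate_followup(surv, 3650)
        assert out.loc[0, "time_days"] == 3650
        assert out.loc[0, "event"] == 0
        assert out.loc[1, "time_days"] == 1000 and out.loc[1, "event"] == 1

    def test_all_within_horizon_unchanged(self):
        surv = pd.DataFrame({"time_days": [10.0, 20.0], "event": [1, 0]})
        assert sv.truncate_followup(surv, 3650).equals(surv)

    def test_non_positive_times_raise(self):
        surv = pd.DataFrame({"time_days": [0.0], "event": [1]})
        with pytest.raises(ValidationError):
            sv.truncate_followup(surv)


class TestCoxUnivariate:
    def test_newton_matches_grid_search_on_small_fixtures(self, rng):
        """Solver beta agrees with a brute-force partial-likelihood grid search."""
        for _ in range(5):
            t, d, x = _fixture_cohort(rng, n=20)
            if d.sum() == 0:
                continue
            fit = sv.cox_univariate(t, d, x)
            assert fit.converged
            oracle = grid_search_beta(t, d, x)
            assert abs(fit.beta - oracle) <= 2e-3

    def test_loglik_matches_naive_oracle_with_ties(self, rng):
        t = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        d = np.array([1, 1, 0, 1, 1, 0])
        x = rng.normal(size=6)
        for beta in (-1.0, 0.0, 0.7):
            assert sv.breslow_loglik(beta, t, d, x) == pytest.approx(
                naive_breslow_loglik(beta, t, d, x), abs=1e-10)

    def test_matches_lifelines_on_tie_free_cohort(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t, d, x = _fixture_cohort(rng, n=80, beta=0.5)
        fit = sv.cox_univariate(t, d, x)
        frame = pd.DataFrame({"T": t, "E": d, "x": x})
        cph = lifelines.CoxPHFitter().fit(frame, duration_col="T", event_col="E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_shift_invariance_and_scale_equivariance(self, rng):
        t, d, x = _fixture_cohort(rng, n=50)
        base = sv.cox_univariate(t, d, x).beta
        assert sv.cox_univariate(t, d, x + 100.0).beta == pytest.approx(base, abs=1e-6)
        assert sv.cox_univariate(t, d, 2.0 * x).beta == pytest.approx(base / 2, abs=1e-6)

    def test_planted_beta_recovery(self, rng):
        """Mean absolute error of the estimate over replicates stays within 0.15."""
        errors = []
        for _ in range(100):
            n = 300
            x = rng.normal(size=n)
            event_time = rng.exponential(np.exp(-0.7 * x))
            censor = rng.exponential(1.5, size=n)
            t = np.minimum(event_time, censor)
            d = (event_time <= censor).astype(int)
            fit = sv.cox_univariate(t, d, x)
            errors.append(abs(fit.beta - 0.7))
        assert np.mean(errors) <= 0.15

    def test_null_covariate_type_one_error(self, rng):
        rejections = 0
        n_reps = 500
        for _ in range(n_reps):
            n = 200
            x = rng.normal(size=n)
            t = rng.exponential(size=n)
            d = (rng.uniform(size=n) > 0.3).astype(int)
            fit = sv.cox_univariate(t, d, x)
            rejections += fit.p <= 0.05
        rate = rejections / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= 2.5 * se + 0.005

    def test_degenerate_inputs_are_flagged_not_raised(self):
        t = np.array([1.0, 2.0, 3.0])
        no_events = sv.cox_univariate(t, [0, 0, 0], [1.0, 2.0, 3.0])
        assert not no_events.converged and no_events.reason == "no_events"
        constant = sv.cox_univariate(t, [1, 1, 0], [2.0, 2.0, 2.0])
        assert constant.reason == "constant_covariate"

    def test_perfect_separation_is_flagged(self):
        # covariate perfectly orders event times -> monotone likelihood
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        d = np.ones(6, dtype=int)
        x = -t
        fit = sv.cox_univariate(t, d, x)
        assert not fit.converged
        assert fit.reason in ("monotone_likelihood", "no_convergence",
                              "singular_information")


class TestClassifyPrognosis:
    @pytest.mark.parametrize("hr, p, expected", [
        (1.8, 0.001, "poor"),
        (0.6, 0.001, "favorable"),
        (1.8, 0.2, "ns"),
        (0.6, 0.2, "ns"),
    ])
    def test_rule_table(self, hr, p, expected):
        table = pd.DataFrame({"hr": [hr], "p": [p]})
        assert sv.classify_prognosis(table).iloc[0] == expected

    def test_nan_p_is_ns(self):
        table = pd.DataFrame({"hr": [float("nan")], "p": [float("nan")]})
        assert sv.classify_prognosis(table).iloc[0] == "ns"


class TestCrossCancerSummary:
    @staticmethod
    def _table(gene_classes):
        rows = []
        for gene, classes in gene_classes.items():
            for i, cls in enumerate(classes):
                rows.append({"gene": gene, "cancer_type": f"c{i}", "class": cls})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("n_cancers, expected", [(35, 9), (4, 1), (8, 2)])
    def test_recurrence_threshold_uses_ceiling(self, n_cancers, expected):
        assert sv.recurrence_threshold(n_cancers) == expected

    def test_qualification_at_threshold_edge(self):
        classes = {"hit": ["poor"] * 9 + ["ns"] * 26,
                   "miss": ["poor"] * 8 + ["ns"] * 27}
        summary = sv.cross_cancer_summary(self._table(classes))
        assert summary.threshold == 9
        assert "HIT" in summary.recurrent_poor
        assert "MISS" not in summary.recurrent_poor
        assert summary.per_gene.loc["hit", "n_poor_cancers"] == 9

    def test_counts_both_directions(self):
        classes = {"g": ["poor", "favorable", "ns", "poor"]}
        summary = sv.cross_cancer_summary(self._table(classes))
        assert summary.per_gene.loc["g", "n_poor_cancers"] == 2
        assert summary.per_gene.loc["g", "n_favorable_cancers"] == 1


class TestAnatomyEnrichment:
    @staticmethod
    def _classes(poor_by_cancer):
        rows = []
        for cancer, genes in poor_by_cancer.items():
            for gene, cls in genes.items():
                rows.append({"gene": gene, "cancer_type": cancer, "class": cls})
        return pd.DataFrame(rows)

    def test_direct_ratio(self):
        index = {"EMAPA:1": GeneList("EMAPA:1", ["A", "B", "C", "D"])}
        table = self._classes({"X": {"A": "poor", "B": "poor", "C": "ns", "D": "ns"}})
        out = sv.anatomy_enrichment(index, table)
        assert out.loc["EMAPA:1", "X"] == pytest.approx(0.5)

    def test_region_without_poor_genes_is_zero_everywhere(self):
        index = {"EMAPA:1": GeneList("EMAPA:1", ["A", "B"])}
        table = self._classes({"X": {"A": "ns", "B": "favorable"},
                               "Y": {"A": "ns", "B": "ns"}})
        out = sv.anatomy_enrichment(index, table)
        assert (out.loc["EMAPA:1"] == 0).all()

    def test_planted_region_fully_poor_scores_one(self):
        index = {"R": GeneList("R", ["A", "B"]), "S": GeneList("S", ["C"])}
        table = self._classes({"C1": {"A": "poor", "B": "poor", "C": "ns"}})
        out = sv.anatomy_enrichment(index, table)
        assert out.loc["R", "C1"] == 1.0
        assert out.loc["S", "C1"] == 0.0

    def test_ratios_bounded_and_monotone(self):
        index = {"R": GeneList("R", ["A", "B", "C"])}
        base = self._classes({"X": {"A": "poor", "B": "ns", "C": "ns"}})
        more = self._classes({"X": {"A": "poor", "B": "poor", "C": "ns"}})
        r1 = sv.anatomy_enrichment(index, base).loc["R", "X"]
        r2 = sv.anatomy_enrichment(index, more).loc["R", "X"]
        assert 0 <= r1 <= r2 <= 1


class TestCoxScreen:
    def test_planted_prognostic_genes_called_poor(self, sim_surv):
        table = sv.cox_screen(sim_surv.expression, sim_surv.surv)
        planted = table[table["gene"].isin(sim_surv.prognostic_truth.genes)]
        assert (planted["class"] == "poor").mean() >= 0.9
        nulls = table[~table["gene"].isin(sim_surv.prognostic_truth.genes)]
        assert (nulls["class"] != "ns").mean() <= 0.15

    def test_screen_applies_followup_truncation(self, sim_surv):
        table = sv.cox_screen(sim_surv.expression, sim_surv.surv, horizon_days=3650)
        assert not table.empty
        # the simulated cohort contains follow-up beyond ten years
        assert (sim_surv.surv["time_days"] > 3650).any()
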