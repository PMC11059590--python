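import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import glomkit as gk
from glomkit.stats import (
    EsrdEvent,
    compare_dependent_correlations,
    patient_indicators,
    prognosis_filter,
    prognostic_table,
)
from glomkit.types import ClinicalTrajectory


def _traj(times, egfr, prot=None, dialysis=None, transplant=None, pid="P0"):
    times = np.asarray(times, float)
    if prot is None:
        prot = np.full(times.size, np.nan)
    return ClinicalTrajectory(pid, times, np.asarray(egfr, float),
                              np.asarray(prot, float), dialysis, transplant)


class TestCohensKappa:
    def test_identical_lists(self):
        res = gk.cohens_kappa(["I", "II", "III"] * 5, ["I", "II", "III"] * 5)
        assert res.kappa == 1.0
        assert res.observed_agreement == 1.0

    def test_permutation_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.choice(["A", "B", "C"], 1000).tolist()
        b = list(a)
        rng.shuffle(b)
        res = gk.cohens_kappa(a, b)
        assert abs(res.kappa) < 0.1

    def test_hand_formula_2x2(self):
        # table [[20, 5], [10, 15]]: po = 0.7, pe = 0.5 -> kappa 0.4
        a = ["x"] * 25 + ["y"] * 25
        b = ["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15
        res = gk.cohens_kappa(a, b)
        assert res.observed_agreement == pytest.approx(0.7)
        assert res.expected_agreement == pytest.approx(0.5)
        assert res.kappa == pytest.approx(0.4)

    def test_random_tables_match_hand_formula(self):
        rng = np.random.default_rng(2)
        labels = ["a", "b", "c", "d"]
        for _ in range(25):
            n = int(rng.integers(10, 80))
            a = rng.choice(labels[: rng.integers(2, 5)], n).tolist()
            b = rng.choice(labels[: rng.integers(2, 5)], n).tolist()
            res = gk.cohens_kappa(a, b)
            # independent oracle: contingency arithmetic
            universe = sorted(set(a) | set(b))
            tab = np.zeros((len(universe),) * 2)
            for x, y in zip(a, b):
                tab[universe.index(x), universe.index(y)] += 1
            tab /= n
            po = np.trace(tab)
            pe = float(tab.sum(1) @ tab.sum(0))
            if pe < 1:
                assert res.kappa == pytest.approx((po - pe) / (1 - pe))

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.choice(["I", "IIa", "IIb"], 100).tolist()
        b = rng.choice(["I", "IIa", "IIb"], 100).tolist()
        assert gk.cohens_kappa(a, b).kappa == pytest.approx(gk.cohens_kappa(b, a).kappa)
        relabel = {"I": "z1", "IIa": "z2", "IIb": "z3"}
        ra = [relabel[x] for x in a]
        rb = [relabel[x] for x in b]
        assert gk.cohens_kappa(ra, rb).kappa == pytest.approx(gk.cohens_kappa(a, b).kappa)

    def test_constant_equal_raters_undefined(self):
        res = gk.cohens_kappa(["A"] * 10, ["A"] * 10)
        assert math.isnan(res.kappa)
        assert res.expected_agreement == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            gk.cohens_kappa(["A"], ["A", "B"])

    def test_linear_weights_soften_ordinal_disagreement(self):
        a = ["I"] * 50 + ["IIb"] * 50
        b = ["IIa"] * 50 + ["IIb"] * 50  # adjacent miss on half the items
        unweighted = gk.cohens_kappa(a, b).kappa
        weighted = gk.cohens_kappa(a, b, weights="linear").kappa
        assert weighted > unweighted


class TestSpearman:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert gk.spearman(x, x).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert gk.spearman(x, -(x**3)).r == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 25))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = gk.spearman(x, y)
            oracle = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
            assert res.r == pytest.approx(oracle)

    def test_constant_vector_explicit_nan(self):
        res = gk.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert math.isnan(res.r) and math.isnan(res.p)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            gk.spearman([1, 2], [3, 4])


class TestCompareDependentCorrelations:
    def test_equal_correlations_give_zero(self):
        res = compare_dependent_correlations(0.4, 0.4, 0.7, 50)
        assert res.z == 0.0 and res.p == 1.0

    def test_sign_follows_difference(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rjk, rjh = rng.uniform(-0.8, 0.8, 2)
            rkh = rng.uniform(-0.5, 0.9)
            res = compare_dependent_correlations(rjk, rjh, rkh, 80)
            if rjk != rjh:
                assert np.sign(res.z) == np.sign(rjk - rjh)

    def test_variants_agree_on_direction(self):
        for method in ("hittner2003", "dunn1969", "steiger1980", "meng1992"):
            res = compare_dependent_correlations(0.6, 0.3, 0.5, 100, method=method)
            assert res.z > 0
            assert 0 < res.p < 0.5

    def test_larger_n_larger_z(self):
        z_small = compare_dependent_correlations(0.5, 0.3, 0.4, 30).z
        z_big = compare_dependent_correlations(0.5, 0.3, 0.4, 300).z
        assert z_big > z_small

    def test_unit_correlation_rejected(self):
        with pytest.raises(ValueError, match="Fisher"):
            compare_dependent_correlations(1.0, 0.5, 0.5, 50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 10"):
            compare_dependent_correlations(0.5, 0.3, 0.4, 5)

    def test_null_calibration_small(self):
        # quick 800-rep check; the full 5000-rep version is an acceptance test
        rng = np.random.default_rng(6)
        rho, rkh = 0.3, 0.5
        chol = np.linalg.cholesky(np.array([
            [1, rho, rho], [rho, 1, rkh], [rho, rkh, 1]]))
        rej = 0
        reps = 800
        for _ in range(reps):
            x = rng.standard_normal((150, 3)) @ chol.T
            c = np.corrcoef(x, rowvar=False)
            res = compare_dependent_correlations(c[0, 1], c[0, 2], c[1, 2], 150)
            rej += res.p < 0.05
        assert 0.03 <= rej / reps <= 0.07


class TestTimeAverageProteinuria:
    def test_constant_series(self):
        t = _traj([0, 0.5, 1.7], [100, 90, 80], [2.0, 2.0, 2.0])
        assert gk.time_average_proteinuria(t) == pytest.approx(2.0)

    def test_linear_rise(self):
        t = _traj([0, 1.0], [100, 90], [0.0, 4.0])
        assert gk.time_average_proteinuria(t) == pytest.approx(2.0)

    def test_matches_dense_grid_integration(self):
        rng = np.random.default_rng(7)
        times = np.sort(np.r_[0.0, rng.uniform(0.05, 3.0, 8)])
        prot = rng.uniform(0.2, 6.0, times.size)
        t = _traj(times, np.full(times.size, 80.0), prot)
        grid = np.linspace(times[0], times[-1], 200001)
        dense = np.trapezoid(np.interp(grid, times, prot), grid) / (times[-1] - times[0])
        assert gk.time_average_proteinuria(t) == pytest.approx(dense, abs=1e-9)

    def test_within_series_range(self):
        rng = np.random.default_rng(8)
        times = np.sort(np.r_[0.0, rng.uniform(0.05, 3.0, 6)])
        prot = rng.uniform(0.2, 6.0, times.size)
        t = _traj(times, np.full(times.size, 80.0), prot)
        tap = gk.time_average_proteinuria(t)
        assert prot.min() <= tap <= prot.max()

    def test_single_measurement_undefined(self):
        t = _traj([0, 1.0], [100, 90], [2.0, np.nan])
        assert math.isnan(gk.time_average_proteinuria(t))


class TestEgfrSlope:
    def test_two_visits(self):
        assert gk.egfr_slope(_traj([0, 1.0], [100, 90])) == pytest.approx(-10.0)

    def test_noiseless_planted_slope_exact(self):
        times = np.r_[0.0, np.cumsum(np.full(7, 0.35))]
        egfr = 88.0 - 11.6 * times
        assert gk.egfr_slope(_traj(times, egfr)) == pytest.approx(-11.6, abs=1e-9)

    def test_shift_invariance(self):
        times = np.array([0, 0.4, 0.9, 1.6])
        egfr = np.array([90.0, 84.0, 71.0, 66.0])
        s1 = gk.egfr_slope(_traj(times, egfr))
        s2 = gk.egfr_slope(_traj(times, egfr + 25.0))
        assert s1 == pytest.approx(s2)

    def test_unbiased_on_noisy_trajectories(self):
        rng = np.random.default_rng(9)
        times = np.r_[0.0, np.cumsum(np.full(9, 0.3))]
        slopes = []
        for _ in range(1000):
            egfr = 90.0 - 5.0 * times + rng.normal(0, 3.0, times.size)
            slopes.append(gk.egfr_slope(_traj(times, np.maximum(egfr, 1.0))))
        se = np.std(slopes) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) + 5.0) < 4 * se + 0.05


class TestEsrdEvent:
    def test_never_below_threshold(self):
        res = gk.esrd_event(_traj([0, 1, 2], [80, 60, 40]))
        assert res == EsrdEvent(False, res.time_years, None)
        assert not res.event

    def test_persistent_low_egfr(self):
        # 14 at year 1.0 confirmed at year 1.3 -> event dated at onset
        res = gk.esrd_event(_traj([0, 1.0, 1.3], [60, 14, 13]))
        assert res.event and res.time_years == pytest.approx(1.0)

    def test_transient_dip_recovers(self):
        res = gk.esrd_event(_traj([0, 1.0, 1.0 + 1 / 12], [60, 14, 40]))
        assert not res.event

    def test_low_at_final_visit_counts(self):
        res = gk.esrd_event(_traj([0, 1.0], [60, 14]))
        assert res.event and res.time_years == pytest.approx(1.0)

    def test_transplant_immediate(self):
        res = gk.esrd_event(_traj([0, 0.5, 1.0], [60, 50, 45],
                                  transplant=[0, 1, 0]))
        assert res.event and res.reason == "transplant"
        assert res.time_years == pytest.approx(0.5)

    def test_dialysis_persistence(self):
        res = gk.esrd_event(_traj([0, 0.5, 0.9], [60, 50, 45],
                                  dialysis=[0, 1, 1]))
        assert res.event and res.time_years == pytest.approx(0.5)


class TestPrognosisFilter:
    def _visits(self, rows):
        return pd.DataFrame(rows, columns=["patient_id", "time_years", "egfr",
                                           "proteinuria_g24h"])

    def test_baseline_egfr_boundary(self):
        visits = self._visits([("A", 0.0, 29.9, 1.0), ("A", 0.5, 28.0, 1.0),
                               ("B", 0.0, 30.0, 1.0), ("B", 0.5, 28.0, 1.0)])
        kept, report = prognosis_filter(visits)
        assert set(kept["patient_id"]) == {"B"}
        assert report.n_excluded_baseline_egfr == 1

    def test_followup_boundary(self):
        visits = self._visits([("A", 0.0, 80.0, 1.0), ("A", 0.05, 78.0, 1.0),
                               ("B", 0.0, 80.0, 1.0), ("B", 1 / 12, 78.0, 1.0)])
        kept, report = prognosis_filter(visits)
        assert set(kept["patient_id"]) == {"B"}
        assert report.n_excluded_followup == 1

    def test_toy_cohort_counts(self):
        rows = []
        for pid, baseline, fu in [("A", 80, 1.0), ("B", 80, 1.0), ("C", 80, 1.0),
                                  ("D", 25, 1.0), ("E", 80, 0.05)]:
            rows += [(pid, 0.0, baseline, 1.0), (pid, fu, baseline - 5, 1.0)]
        kept, report = prognosis_filter(self._visits(rows))
        assert report.n_total == 5
        assert report.n_retained == 3
        assert set(kept["patient_id"]) == {"A", "B", "C"}


class TestPrognosticTable:
    def test_identical_raters_all_z_zero(self, big_cohort):
        visits, _ = prognosis_filter(big_cohort.visits)
        classes = big_cohort.patients.set_index("patient_id")["true_class"]
        table = prognostic_table(classes, visits, classes2=classes.copy())
        assert (table["z"] == 0).all()
        assert (table["p_z"] == 1).all()

    def test_planted_trends_significant(self):
        cohort = gk.generate_cohort(gk.CohortSpec(n_patients=200, seed=31))
        visits, _ = prognosis_filter(cohort.visits)
        classes = cohort.patients.set_index("patient_id")["true_class"]
        table = prognostic_table(classes, visits).set_index("indicator")
        slope = table.loc["egfr_slope"]
        assert slope["r"] < 0 and slope["p"] < 0.05
        assert table.loc["baseline_egfr", "r"] < 0
        assert table.loc["time_average_proteinuria", "r"] > 0
        assert table.loc["baseline_proteinuria", "r"] > 0

    def test_per_class_slope_medians_ordered(self, big_cohort):
        ind = patient_indicators(big_cohort.visits)
        merged = big_cohort.patients.set_index("patient_id").join(ind, rsuffix="_obs")
        med = merged.groupby("true_class")["egfr_slope"].median()
        med = med.reindex(["I", "IIa", "IIb", "III", "IV"])
        assert (med.diff().dropna() <= 0).all()

    def test_esrd_more_frequent_in_high_classes(self, big_cohort):
        ind = patient_indicators(big_cohort.visits)
        merged = big_cohort.patients.set_index("patient_id").join(ind, rsuffix="_obs")
        rate = merged.groupby("true_class")["esrd"].mean()
        assert rate["IV"] > rate["I"]
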