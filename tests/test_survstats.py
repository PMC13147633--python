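import itertools
import math

import numpy as np
import pandas as pd
import pytest

from netstrat import survstats


class TestKaplanMeier:
    def test_four_subject_no_censoring(self):
        km = survstats.km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(km.survival, [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(10, size=40).round(2) + 0.1
        km = survstats.km_curve(times, np.ones_like(times))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean())

    def test_all_censored(self):
        km = survstats.km_curve([5, 6, 7], [0, 0, 0])
        assert np.allclose(km.survival, 1.0)
        assert km.median is None

    def test_single_subject_event(self):
        km = survstats.km_curve([3.5], [1])
        assert km.survival[-1] == 0.0
        assert km.median == 3.5

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            survstats.km_curve([0.0, 1.0], [1, 1])

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.exponential(10, size=30) + 0.1
        events = rng.integers(0, 2, size=30)
        if events.sum() == 0:
            events[0] = 1
        km = survstats.km_curve(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0])
            )


def logrank_oracle(times, events, groups):
    """Hand tabulation of O, E, V at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g0)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1] * 8
        g = [0] * 4 + [1] * 4
        stat, p = survstats.logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_example_matches_hand_tabulation(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 1, 1]
        g = [0, 0, 1, 1]
        stat, _ = survstats.logrank_test(t, e, g)
        assert stat == pytest.approx(logrank_oracle(t, e, g), rel=1e-9)

    def test_random_data_matches_oracle(self, rng):
        t = rng.exponential(5, size=30) + 0.1
        e = rng.integers(0, 2, size=30)
        g = rng.integers(0, 2, size=30)
        e[:2] = 1
        g[:2] = [0, 1]
        stat, _ = survstats.logrank_test(t, e, g)
        assert stat == pytest.approx(logrank_oracle(t, e, g), rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            survstats.logrank_test([1, 2], [1, 1], [0, 0])

    def test_null_p_uniform(self):
        """Under the null the log-rank p-value is uniform (KS check over 500
        simulated cohorts of 38)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            t = rng.exponential(10, size=38) + 0.01
            e = (rng.random(38) > 0.2).astype(int)
            g = np.array([0] * 19 + [1] * 19)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            ps.append(survstats.logrank_test(t, e, g)[1])
        assert kstest(ps, "uniform").pvalue > 0.01


class TestCox:
    def _planted(self, rng, n=200, beta=math.log(4.5)):
        cluster = rng.integers(0, 2, size=n)
        rate = 0.02 * np.exp(beta * cluster)
        t = rng.exponential(1 / rate)
        e = np.ones(n, int)
        cens = rng.random(n) < 0.2
        t[cens] *= rng.random(cens.sum())
        e[cens] = 0
        return pd.DataFrame(
            {"time_months": t + 1e-3, "event": e, "cluster": cluster}
        )

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(5)
        covered = 0
        reps = 60
        for _ in range(reps):
            df = self._planted(rng, n=120, beta=0.0)
            fit = survstats.cox_ph(df, ["cluster"])
            if fit.ci_lower.iloc[0] <= 1.0 <= fit.ci_upper.iloc[0]:
                covered += 1
        assert covered / reps >= 0.88

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(6)
        truth = 4.5
        covered = 0
        reps = 40
        for _ in range(reps):
            df = self._planted(rng)
            fit = survstats.cox_ph(df, ["cluster"])
            if fit.ci_lower.iloc[0] <= truth <= fit.ci_upper.iloc[0]:
                covered += 1
        assert covered / reps >= 0.90

    def test_hr_equals_exp_coef_and_ci_order(self, rng):
        df = self._planted(rng)
        fit = survstats.cox_ph(df, ["cluster"])
        assert fit.hazard_ratios.iloc[0] == pytest.approx(
            math.exp(fit.coefficients.iloc[0])
        )
        assert fit.ci_lower.iloc[0] <= fit.hazard_ratios.iloc[0] <= fit.ci_upper.iloc[0]

    def test_categorical_covariates_expanded(self, rng):
        df = self._planted(rng, n=100)
        df["smoking"] = rng.choice(["never", "former", "current"], size=100)
        fit = survstats.cox_ph(df, ["cluster", "smoking"])
        names = list(fit.coefficients.index)
        assert "cluster" in names
        assert sum(n.startswith("smoking_") for n in names) == 2

    def test_score_direction_on_toy_data(self):
        """4 subjects, binary covariate: the group dying earlier must get the
        positive log-hazard."""
        df = pd.DataFrame(
            {"time_months": [1, 2, 8, 9], "event": [1, 1, 1, 1],
             "x": [1, 1, 0, 0]}
        )
        fit = survstats.cox_ph(df, ["x"])
        assert fit.coefficients.iloc[0] > 0

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_months": [1, 2], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError):
            survstats.cox_ph(df, ["x"])


class TestClusterStats:
    def test_printed_composition_accuracy(self):
        """Cluster composition 16R+6NR / 4R+12NR of 38 gives 28/38 = 0.74."""
        assignment = {f"p{i}": (0 if i < 22 else 1) for i in range(38)}
        labels = {}
        for i in range(38):
            if i < 22:
                labels[f"p{i}"] = "R" if i < 16 else "NR"
            else:
                labels[f"p{i}"] = "R" if i < 26 else "NR"
        acc, confusion, mapping = survstats.cluster_accuracy(assignment, labels)
        assert acc == pytest.approx(28 / 38)
        assert round(acc, 2) == 0.74
        assert confusion.to_numpy().sum() == 38

    def test_perfect_and_swap_invariance(self):
        assignment = {f"p{i}": int(i < 5) for i in range(10)}
        labels = {f"p{i}": ("R" if i < 5 else "NR") for i in range(10)}
        acc, _, _ = survstats.cluster_accuracy(assignment, labels)
        assert acc == 1.0
        swapped = {k: 1 - v for k, v in assignment.items()}
        acc2, _, _ = survstats.cluster_accuracy(swapped, labels)
        assert acc2 == 1.0

    def test_accuracy_at_least_half(self, rng):
        for _ in range(20):
            assignment = {f"p{i}": int(rng.integers(0, 2)) for i in range(12)}
            if len(set(assignment.values())) < 2:
                continue
            labels = {f"p{i}": rng.choice(["R", "NR"]) for i in range(12)}
            if len(set(labels.values())) < 2:
                continue
            acc, _, _ = survstats.cluster_accuracy(assignment, labels)
            assert acc >= 0.5

    def test_pure_clusters_enrichment(self):
        assignment = {f"p{i}": int(i >= 5) for i in range(10)}
        labels = {f"p{i}": ("R" if i < 5 else "NR") for i in range(10)}
        table = survstats.cluster_enrichment(assignment, labels)
        assert np.allclose(table["p"], 1 / 252)

    def test_single_cluster_p_one(self):
        assignment = {f"p{i}": 0 for i in range(10)}
        labels = {f"p{i}": ("R" if i < 5 else "NR") for i in range(10)}
        table = survstats.cluster_enrichment(assignment, labels)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_strict_tail_convention(self):
        assignment = {f"p{i}": (0 if i < 22 else 1) for i in range(38)}
        labels = {}
        for i in range(38):
            labels[f"p{i}"] = "R" if (i < 16 or 22 <= i < 26) else "NR"
        ge = survstats.cluster_enrichment(assignment, labels, convention="ge")
        gt = survstats.cluster_enrichment(assignment, labels, convention="gt")
        assert (gt["p"] <= ge["p"] + 1e-15).all()


def mannwhitney_exact_oracle(x, y):
    """Enumerate all C(n+m, n) rank splits (no ties)."""
    pooled = np.concatenate([x, y])
    n = len(x)
    obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    return min(1.0, 2.0 * min((us <= obs).mean(), (us >= obs).mean()))


class TestCompareClusters:
    def _frame(self, x, y):
        values = np.concatenate([x, y])
        idx = [f"p{i}" for i in range(len(values))]
        assignment = {p: int(i >= len(x)) for i, p in enumerate(idx)}
        return pd.DataFrame({"v": values}, index=idx), assignment

    def test_shifted_groups_exact_p(self):
        table, assignment = self._frame([1, 2, 3], [4, 5, 6])
        out = survstats.compare_clusters(table, assignment)
        assert out["U"].iloc[0] in (0.0, 9.0)
        assert out["p"].iloc[0] == pytest.approx(0.1)
        oracle = mannwhitney_exact_oracle(np.array([1, 2, 3]), np.array([4, 5, 6]))
        assert out["p"].iloc[0] == pytest.approx(min(oracle, 1.0))

    def test_identical_distributions_p_one(self):
        table, assignment = self._frame([1.5, 2.5, 3.5], [1.5, 2.5, 3.5])
        out = survstats.compare_clusters(table, assignment)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_enumeration_on_random_small_samples(self, rng):
        for _ in range(5):
            x = rng.permutation(20)[:5].astype(float)
            y = rng.permutation(40)[:6].astype(float) + 100 * rng.random()
            if len(np.unique(np.concatenate([x, y]))) < 11:
                continue
            table, assignment = self._frame(x, y)
            out = survstats.compare_clusters(table, assignment)
            assert out["p"].iloc[0] == pytest.approx(
                mannwhitney_exact_oracle(x, y), abs=1e-9
            )

    def test_power_on_location_shift(self):
        rng = np.random.default_rng(8)
        hits = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(size=19)
            y = rng.normal(loc=1.5, size=19)
            table, assignment = self._frame(x, y)
            out = survstats.compare_clusters(table, assignment)
            hits += out["p"].iloc[0] < 0.05
        assert hits / reps >= 0.90

    def test_bh_over_variables(self, rng):
        idx = [f"p{i}" for i in range(20)]
        table = pd.DataFrame(rng.normal(size=(20, 6)), index=idx)
        assignment = {p: int(i >= 10) for i, p in enumerate(idx)}
        out = survstats.compare_clusters(table, assignment)
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_tiny_cluster_rejected(self):
        table, _ = self._frame([1, 2, 3], [4])
        with pytest.raises(ValueError):
            survstats.compare_clusters(table, {"p0": 0, "p1": 0, "p2": 0, "p3": 1})


def fisher_2x2_oracle(table):
    """Full enumeration of 2x2 tables with fixed margins; two-sided by the
    probability rule."""
    a, b = table[0]
    c, d = table[1]
    r0, r1 = a + b, c + d
    c0 = a + c
    def prob(x):
        return (math.comb(c0, x) * math.comb(r0 + r1 - c0, r0 - x)
                / math.comb(r0 + r1, r0))
    obs = prob(a)
    return sum(prob(x) for x in range(max(0, r0 - (r0 + r1 - c0)),
                                      min(r0, c0) + 1)
               if prob(x) <= obs + 1e-12)


class TestBaselineBalance:
    def test_identical_composition_p_one(self):
        idx = [f"p{i}" for i in range(20)]
        clinical = pd.DataFrame(
            {"sex": (["m"] * 5 + ["f"] * 5) * 2, "age": np.arange(20, 40)},
            index=idx,
        )
        assignment = {p: int(i >= 10) for i, p in enumerate(idx)}
        out = survstats.baseline_balance(
            clinical, assignment, categorical=["sex"], continuous=["age"]
        )
        fisher_p = out.loc[out["covariate"] == "sex", "p"].iloc[0]
        assert fisher_p == pytest.approx(1.0)

    def test_2x2_matches_enumeration(self):
        table = np.array([[8, 2], [2, 8]])
        assert survstats.fisher_exact_2xk(table) == pytest.approx(
            fisher_2x2_oracle(table), abs=1e-12
        )

    @pytest.mark.parametrize("table,expected", [
        # reference values from an independent exact implementation
        ([[5, 1, 2], [1, 4, 3]], 0.145299145299),
        ([[6, 2, 4], [1, 7, 2]], 0.047565437658),
    ])
    def test_2x3_matches_reference(self, table, expected):
        assert survstats.fisher_exact_2xk(np.array(table)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_2x3_with_empty_column_equals_2x2(self):
        t2 = np.array([[7, 3], [2, 9]])
        t3 = np.array([[7, 3, 0], [2, 9, 0]])
        assert survstats.fisher_exact_2xk(t3) == pytest.approx(
            survstats.fisher_exact_2xk(t2), abs=1e-12
        )

    def test_age_null_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(2)
        ps = []
        for _ in range(200):
            idx = [f"p{i}" for i in range(30)]
            clinical = pd.DataFrame({"age": rng.normal(60, 8, 30)}, index=idx)
            assignment = {p: int(i >= 15) for i, p in enumerate(idx)}
            out = survstats.baseline_balance(
                clinical, assignment, categorical=[], continuous=["age"]
            )
            ps.append(out["p"].iloc[0])
        assert kstest(ps, "uniform").pvalue > 0.01
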