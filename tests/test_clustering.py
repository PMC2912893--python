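import itertools
import math

import numpy as np
import pytest

from qpcreff import (
    cluster_efficiencies,
    fit_all,
    fit_primer,
    group_fit_rss,
    optimal_partition,
    select_clusters,
)
from qpcreff.clustering import primer_suffstats

from conftest import exact_curve, make_table, rand_index


def noisy_table(rng, slopes, sd, levels=(1, 0.1, 0.01, 0.001)):
    x = np.log2(np.asarray(levels, dtype=float))
    rows = {
        f"p{i:02d}": list(20 + rng.uniform(0, 4) + s * x + rng.normal(0, sd, x.size))
        for i, s in enumerate(slopes)
    }
    return make_table(rows, np.asarray(levels, dtype=float))


def brute_force_partition(table, kept, k, tol=1e-9):
    """Enumerate every contiguous partition in sorted-slope order.

    Independent of the DP: same tie-break (rss within tol, most balanced,
    smallest boundary tuple), direct enumeration of boundary combinations.
    """
    ss = primer_suffstats(table, kept)
    order = np.lexsort((np.array(ss.primers), ss.slopes))
    sorted_primers = [ss.primers[i] for i in order]
    P = len(sorted_primers)
    best = None
    for cuts in itertools.combinations(range(1, P), k - 1):
        bounds = (0, *cuts, P)
        rss = 0.0
        for g in range(k):
            seg = sorted_primers[bounds[g]: bounds[g + 1]]
            rss += group_fit_rss(table, seg)[1]
        sizes = tuple(bounds[g + 1] - bounds[g] for g in range(k))
        cand = (rss, sum(s * s for s in sizes), bounds)
        if best is None or cand[0] < best[0] - tol or (
            abs(cand[0] - best[0]) <= tol and cand[1:] < best[1:]
        ):
            best = cand
    return best


class TestGroupFit:
    def test_single_member_reduces_to_individual_fit(self):
        rng = np.random.default_rng(1)
        t = noisy_table(rng, [-1.1], 0.2)
        gamma, rss = group_fit_rss(t, ["p00"])
        f = fit_primer(t, "p00")
        assert gamma == pytest.approx(f.beta1, abs=1e-12)
        assert rss == pytest.approx(f.rss, abs=1e-12)

    def test_shared_slope_noise_free_pair(self):
        t = make_table({"a": exact_curve(2.0, 20), "b": exact_curve(2.0, 24)})
        gamma, rss = group_fit_rss(t, ["a", "b"])
        assert gamma == pytest.approx(-1.0, abs=1e-6)
        assert rss == pytest.approx(0.0, abs=1e-9)

    def test_pooled_rss_at_least_sum_of_individual(self):
        rng = np.random.default_rng(2)
        t = noisy_table(rng, [-1.0, -1.3], 0.1)
        _, rss = group_fit_rss(t, ["p00", "p01"])
        individual = sum(fit_primer(t, p).rss for p in ("p00", "p01"))
        assert rss >= individual - 1e-12

    def test_matches_dummy_coded_ols_reference(self):
        """Closed-form pooled fit vs statsmodels OLS with primer dummies."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        t = noisy_table(rng, [-0.9, -1.1, -1.25], 0.3)
        gamma, rss = group_fit_rss(t, t.primer_ids)
        x = np.log2(t.dilution_levels)
        X, y = [], []
        for i, p in enumerate(t.primer_ids):
            for xj, ct in zip(x, t.row(p)):
                dummies = [1.0 if m == i else 0.0 for m in range(t.n_primers)]
                X.append(dummies + [xj])
                y.append(ct)
        fit = sm.OLS(np.array(y), np.array(X)).fit()
        assert gamma == pytest.approx(fit.params[-1], abs=1e-9)
        assert rss == pytest.approx(fit.ssr, abs=1e-9)


class TestOptimalPartition:
    def test_k1_matches_common_slope_model(self):
        rng = np.random.default_rng(4)
        t = noisy_table(rng, [-1.0, -1.1, -1.2, -0.95], 0.1)
        cm = optimal_partition(t, t.primer_ids, 1)
        _, rss = group_fit_rss(t, t.primer_ids)
        assert cm.rss == pytest.approx(rss, abs=1e-12)
        assert cm.k == 1 and cm.sizes == (4,)

    def test_recovers_two_well_separated_groups(self):
        rng = np.random.default_rng(5)
        slopes = [-1.0, -1.0, -1.0, -1.25, -1.25, -1.25]
        t = noisy_table(rng, slopes, 0.02)
        cm = optimal_partition(t, t.primer_ids, 2)
        groups = {p: cm.assignment[p] for p in t.primer_ids}
        assert len({groups[f"p{i:02d}"] for i in range(3)}) == 1
        assert len({groups[f"p{i:02d}"] for i in range(3, 6)}) == 1
        assert groups["p00"] != groups["p05"]

    def test_rss_non_increasing_and_r2_non_decreasing_in_k(self):
        rng = np.random.default_rng(6)
        t = noisy_table(rng, list(rng.uniform(-1.3, -0.9, 10)), 0.1)
        models = [optimal_partition(t, t.primer_ids, k) for k in range(1, 6)]
        for a, b in zip(models, models[1:]):
            assert b.rss <= a.rss + 1e-9
            assert b.r_squared >= a.r_squared - 1e-12

    @pytest.mark.parametrize("P,k", [(5, 2), (8, 3), (12, 4), (12, 2)])
    def test_dp_equals_exhaustive_enumeration(self, P, k):
        rng = np.random.default_rng(100 + P * 10 + k)
        t = noisy_table(rng, list(rng.uniform(-1.4, -0.8, P)), 0.15)
        cm = optimal_partition(t, t.primer_ids, k)
        rss, _, bounds = brute_force_partition(t, t.primer_ids, k)
        assert cm.rss == pytest.approx(rss, abs=1e-8)
        sizes = tuple(bounds[g + 1] - bounds[g] for g in range(k))
        assert cm.sizes == sizes

    def test_invalid_k_rejected(self):
        t = make_table({"a": exact_curve(1.9, 20), "b": exact_curve(2.0, 21)})
        for k in (0, 3):
            with pytest.raises(ValueError):
                optimal_partition(t, t.primer_ids, k)


class TestSelectClusters:
    def test_noise_free_single_slope_stops_at_k1(self):
        t = make_table({f"p{i}": exact_curve(1.9, 20 + i) for i in range(5)})
        cm, trace = select_clusters(t, t.primer_ids)
        assert cm.k == 1
        assert cm.rss == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_two_slopes_found_exactly(self):
        rows = {f"a{i}": exact_curve(1.8, 20 + i) for i in range(3)}
        rows |= {f"b{i}": exact_curve(2.1, 20 + i) for i in range(3)}
        t = make_table(rows)
        cm, trace = select_clusters(t, t.primer_ids)
        assert cm.k == 2
        assert {cm.assignment[p] for p in rows if p.startswith("a")} == {0}
        assert {cm.assignment[p] for p in rows if p.startswith("b")} == {1}
        assert cm.group_efficiencies[0] == pytest.approx(1.8, abs=1e-6)
        assert cm.group_efficiencies[1] == pytest.approx(2.1, abs=1e-6)

    def test_trace_all_accepted_but_last_f_stop(self):
        rng = np.random.default_rng(7)
        t = noisy_table(rng, list(rng.uniform(-1.3, -0.9, 12)), 0.1)
        cm, trace = select_clusters(t, t.primer_ids, k_max=6)
        if trace and not trace[-1].accepted:
            assert all(s.accepted for s in trace[:-1])
            assert cm.k == trace[-1].k_from

    def test_input_order_invariance(self):
        rng = np.random.default_rng(8)
        t = noisy_table(rng, list(rng.uniform(-1.3, -0.9, 8)), 0.1)
        ids = list(t.primer_ids)
        cm1, _ = select_clusters(t, ids)
        cm2, _ = select_clusters(t, ids[::-1])
        assert cm1.assignment == cm2.assignment
        assert cm1.group_slopes == cm2.group_slopes

    def test_group_slopes_and_efficiencies_strictly_ordered(self, array_results):
        cm = array_results.cluster_model
        assert all(a < b for a, b in zip(cm.group_slopes, cm.group_slopes[1:]))
        assert all(a < b for a, b in zip(cm.group_efficiencies, cm.group_efficiencies[1:]))

    def test_assignment_close_to_planted_groups_on_array_fixture(self, array_results, array_fixture):
        _, truth = array_fixture
        cm = array_results.cluster_model
        tmap = dict(zip(truth.primer, truth.group))
        primers = list(cm.assignment)
        ri = rand_index([tmap[p] for p in primers], [cm.assignment[p] for p in primers])
        assert ri > 0.8


class TestClusterEfficiencies:
    def test_singleton_group_keeps_individual_efficiency(self):
        rng = np.random.default_rng(9)
        t = noisy_table(rng, [-0.8, -1.0, -1.3], 0.01)
        cm = optimal_partition(t, t.primer_ids, 3)
        emap = cluster_efficiencies(cm)
        for p in t.primer_ids:
            f = fit_primer(t, p)
            assert emap[p] == pytest.approx(2 ** (-1 / f.beta1), rel=1e-9)

    def test_shared_slope_group_shares_efficiency(self):
        t = make_table({"a": exact_curve(1.9, 20), "b": exact_curve(1.9, 23)})
        cm = optimal_partition(t, ["a", "b"], 1)
        emap = cluster_efficiencies(cm)
        assert emap["a"] == emap["b"] == pytest.approx(1.9, abs=1e-9)
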