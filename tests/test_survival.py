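import numpy as np
import pandas as pd
import pytest
from scipy import stats

from munet.survival import (CutoffError, find_alive_cutoff, fit_aft,
                            lasso_select_eigengenes, logrank_pvalue,
                            select_best_subset, stratify_risk)
from conftest import make_survival


def brute_force_cutoff(preds, positives, direction, min_recall):
    """Plain-loop reference for the recall-constrained precision optimum."""
    uniq = sorted(set(preds))
    best = None
    n_pos = sum(positives)
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2
        group = [p < cut if direction == "high" else p > cut for p in preds]
        size = sum(group)
        if size == 0:
            continue
        tp = sum(1 for g, pos in zip(group, positives) if g and pos)
        if n_pos == 0 or tp / n_pos < min_recall:
            continue
        key = (tp / size, -size)
        if best is None or key > best[0]:
            best = (key, cut)
    if best is None:
        raise CutoffError("infeasible")
    return best[1]


def logrank_oracle(times, events, mask):
    """Hand O-E/V chi-square over the pooled distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        d = int(((times == t) & (events == 1)).sum())
        n = int(at_risk.sum())
        n1 = int((at_risk & mask).sum())
        d1 = int(((times == t) & (events == 1) & mask).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var
    return stats.chi2.sf(chi2, df=1)


class TestLassoSelect:
    def test_few_candidates_all_returned(self):
        surv, z = make_survival(60, seed=1)
        eig = pd.DataFrame([z, -z, z * 0.5], index=["1e", "1m", "2e"],
                           columns=surv.index)
        assert sorted(lasso_select_eigengenes(eig, surv)) == ["1e", "1m", "2e"]

    def test_planted_hazard_eigengene_selected(self):
        hits = 0
        for seed in range(25):
            surv, z = make_survival(150, seed=seed, b1=1.2)
            rng = np.random.default_rng(seed + 1000)
            rows = {"hit": z.to_numpy()}
            for j in range(20):
                rows[f"null{j}"] = rng.standard_normal(len(surv))
            eig = pd.DataFrame(rows, index=surv.index).T
            if "hit" in lasso_select_eigengenes(eig, surv):
                hits += 1
        assert hits >= 23  # >= ~95% of replicates

    def test_no_events_rejected(self):
        surv, z = make_survival(30, seed=2)
        surv["event"] = 0
        eig = pd.DataFrame(np.random.default_rng(0).standard_normal((5, 30)),
                           columns=surv.index)
        with pytest.raises(ValueError, match="events"):
            lasso_select_eigengenes(eig, surv)


class TestFitAFT:
    def test_recovers_planted_coefficient(self):
        surv, z = make_survival(500, seed=7, b1=0.8, censor_frac=0.2)
        fit = fit_aft(pd.DataFrame({"x": z}), surv)
        assert fit.coefficients["x"] == pytest.approx(0.8, abs=0.15)
        assert fit.scale == pytest.approx(0.5, abs=0.1)

    def test_zero_variance_design_gives_zero_slopes(self):
        surv, _ = make_survival(50, seed=3)
        design = pd.DataFrame({"flat": np.ones(50)}, index=surv.index)
        fit = fit_aft(design, surv)
        assert fit.coefficients["flat"] == 0.0

    def test_linear_predictor_monotone_in_covariate(self):
        surv, z = make_survival(100, seed=4, b1=1.0)
        fit = fit_aft(pd.DataFrame({"x": z}), surv)
        order = z.sort_values().index
        lp = fit.linear_predictor.loc[order]
        assert (np.diff(lp.to_numpy()) >= 0).all()


class TestFindAliveCutoff:
    def test_perfect_separation_reaches_precision_one(self):
        preds = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        dead = np.array([True, True, True, False, False, False])
        cut = find_alive_cutoff(preds, dead, "high", min_recall=0.5)
        group = preds < cut
        assert group.sum() > 0 and (dead[group]).all()

    def test_equals_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            preds = np.round(rng.standard_normal(n), 2)
            pos = rng.random(n) < 0.4
            if not pos.any():
                pos[0] = True
            for direction in ("high", "low"):
                for mr in (0.05, 0.1, 0.2):
                    try:
                        got = find_alive_cutoff(preds, pos, direction, mr)
                    except CutoffError:
                        with pytest.raises(CutoffError):
                            brute_force_cutoff(list(preds), list(pos),
                                               direction, mr)
                        continue
                    assert got == pytest.approx(
                        brute_force_cutoff(list(preds), list(pos),
                                           direction, mr))

    def test_raising_recall_never_raises_precision(self, rng):
        preds = rng.standard_normal(100)
        pos = rng.random(100) < 0.5

        def precision(mr):
            cut = find_alive_cutoff(preds, pos, "high", mr)
            group = preds < cut
            return (pos & group).sum() / group.sum()

        precisions = [precision(mr) for mr in (0.05, 0.2, 0.5)]
        assert precisions == sorted(precisions, reverse=True)

    def test_infeasible_recall_raises(self):
        with pytest.raises(CutoffError, match="recall"):
            find_alive_cutoff(np.array([1.0, 1.0, 1.0]),
                              np.array([True, False, True]), "high", 0.5)


class TestStratifyRisk:
    def test_three_way_partition(self):
        preds = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        groups = stratify_risk(preds, low_cutoff=2.5, high_cutoff=1.5)
        assert groups.tolist() == ["high", "intermediate", "low"]

    def test_all_above_low_cutoff_all_low(self):
        preds = pd.Series([5.0, 6.0], index=["a", "b"])
        assert (stratify_risk(preds, 4.0, 1.0) == "low").all()

    def test_partition_covers_everyone(self, rng):
        preds = pd.Series(rng.standard_normal(50))
        groups = stratify_risk(preds, 0.5, -0.5)
        assert groups.isin(["low", "intermediate", "high"]).all()
        assert len(groups) == 50

    def test_overlapping_cutoffs_rejected(self):
        preds = pd.Series([1.0, 2.0])
        with pytest.raises(ValueError, match="overlap"):
            stratify_risk(preds, low_cutoff=0.0, high_cutoff=1.0)


class TestLogrank:
    def test_identical_groups_p_one(self):
        times = np.array([3.0, 5.0, 7.0, 3.0, 5.0, 7.0])
        events = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        assert logrank_pvalue(times, events, groups) == pytest.approx(1.0)

    def test_matches_hand_formula_on_fixture(self):
        times = np.array([5.0, 8.0, 12.0, 20.0, 3.0, 9.0, 14.0, 25.0])
        events = np.array([1, 1, 0, 1, 1, 1, 1, 0])
        groups = np.array(list("AAAABBBB"))
        p = logrank_pvalue(times, events, groups)
        assert p == pytest.approx(logrank_oracle(times, events,
                                                 groups == "A"), abs=1e-10)

    def test_permutation_p_agrees_with_analytic(self, rng):
        surv, z = make_survival(40, seed=9, b1=0.5)
        groups = np.where(z > z.median(), "low", "high")
        times = surv["time"].to_numpy()
        events = surv["event"].to_numpy()
        p_analytic = logrank_pvalue(times, events, groups)
        observed = logrank_oracle(times, events, groups == "low")
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = rng.permutation(groups)
            if logrank_oracle(times, events, perm == "low") <= observed:
                count += 1
        p_perm = count / n_perm
        mc_err = 3 * np.sqrt(p_analytic * (1 - p_analytic) / n_perm)
        assert abs(p_perm - p_analytic) <= mc_err + 0.01


class TestSelectBestSubset:
    def test_matches_exhaustive_enumeration(self):
        surv, z = make_survival(120, seed=11, b1=1.0)
        rng = np.random.default_rng(5)
        eig = pd.DataFrame(
            {"1e": z, "2m": 0.5 * z + rng.standard_normal(120),
             "3em": rng.standard_normal(120)}, index=surv.index).T
        model, strat = select_best_subset(["1e", "2m", "3em"], eig, surv)
        from itertools import combinations

        from munet.survival import _evaluate_subset
        best = None
        for size in (1, 2, 3):
            for subset in combinations(sorted(["1e", "2m", "3em"]), size):
                try:
                    p, _, _ = _evaluate_subset(subset, eig, surv, 0.2, 0.05)
                except (CutoffError, ValueError):
                    continue
                key = (p, size, subset)
                if best is None or key < best:
                    best = key
        assert list(best[2]) == model.chosen_subset
        assert strat.log_rank_p == pytest.approx(best[0])

    def test_planted_eigengene_beats_noise_in_expectation(self):
        wins = 0
        for seed in range(20):
            surv, z = make_survival(120, seed=seed, b1=1.2)
            rng = np.random.default_rng(seed + 500)
            eig = pd.DataFrame({"hit": z,
                                "n1": rng.standard_normal(120),
                                "n2": rng.standard_normal(120)},
                               index=surv.index).T
            model, _ = select_best_subset(["hit", "n1", "n2"], eig, surv)
            if "hit" in model.chosen_subset:
                wins += 1
        assert wins >= 16

    def test_group_sizes_partition_patients(self):
        surv, z = make_survival(80, seed=13, b1=1.0)
        eig = pd.DataFrame({"1e": z}, index=surv.index).T
        _, strat = select_best_subset(["1e"], eig, surv)
        assert sum(strat.group_sizes.values()) == 80
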