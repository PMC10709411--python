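import numpy as np
import pandas as pd
import pytest
from scipy import stats

from munet.io import LocusGeneMap
from munet.preprocess import (FeatureElection, clean_methylation, compute_union,
                              elect_features, normalize_expression,
                              prepare_survival)


def _mat(rows, index, columns):
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


class TestNormalizeExpression:
    def test_log10_with_unit_offset(self):
        raw = _mat([[0.0, 9.0, 99.0]], ["g1"], ["a", "b", "c"])
        out = normalize_expression(raw, offset=1.0)
        assert np.allclose(out.to_numpy(), [[0.0, 1.0, 2.0]])
        assert out.attrs["log10_normalized"]

    def test_negative_values_rejected(self):
        raw = _mat([[-0.1, 1.0]], ["g1"], ["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            normalize_expression(raw)


class TestCleanMethylation:
    def test_drop_impute_and_threshold(self):
        meth = _mat(
            [[0.1, np.nan, np.nan, np.nan, 0.5],    # 60% missing -> dropped
             [0.2, np.nan, 0.4, 0.3, 0.3],          # 20% -> imputed with 0.3
             [0.1, np.nan, np.nan, 0.2, 0.3]],      # 40% -> kept
            ["cg1", "cg2", "cg3"], list("abcde"))
        out = clean_methylation(meth, max_missing_frac=0.5)
        assert list(out.index) == ["cg2", "cg3"]
        assert not out.isna().any().any()
        assert out.loc["cg2", "b"] == pytest.approx(0.3)

    def test_all_missing_locus_dropped_not_imputed(self):
        meth = _mat([[np.nan, np.nan], [0.1, 0.2]], ["cg1", "cg2"], ["a", "b"])
        out = clean_methylation(meth)
        assert list(out.index) == ["cg2"]

    def test_imputation_preserves_observed_mean(self, rng):
        vals = rng.uniform(size=(20, 10))
        mask = rng.random((20, 10)) < 0.3
        meth = pd.DataFrame(np.where(mask, np.nan, vals),
                            index=[f"cg{i}" for i in range(20)],
                            columns=[f"s{j}" for j in range(10)])
        out = clean_methylation(meth)
        for locus in out.index:
            observed = meth.loc[locus].dropna()
            assert out.loc[locus].mean() == pytest.approx(observed.mean())


class TestPrepareSurvival:
    @pytest.mark.parametrize("stage,risk", [
        ("I", "low"), ("IA", "low"), ("IB", "low"), ("II", "low"),
        ("IIA", "low"), ("IIB", "intermediate"), ("IIIA", "intermediate"),
        ("IIIB", "high"), ("IV", "high"), ("Stage IIIA", "intermediate"),
    ])
    def test_lung_stage_rule(self, stage, risk):
        clin = pd.DataFrame({"time": [10.0], "event": [1], "stage": [stage]},
                            index=pd.Index(["p1"], name="id"))
        assert prepare_survival(clin, "lungStage")["gold_risk"].iloc[0] == risk

    @pytest.mark.parametrize("afp,ishak,risk", [
        (600, 3, "high"), (100, 6, "high"), (100, 1, "low"),
        (100, 3, "intermediate"), (300, 1, "intermediate"),
        (np.nan, 1, "intermediate"),
    ])
    def test_afp_ishak_rule(self, afp, ishak, risk):
        clin = pd.DataFrame({"time": [10.0], "event": [0],
                             "afp": [afp], "ishak": [ishak]},
                            index=pd.Index(["p1"], name="id"))
        assert prepare_survival(clin, "afpIshak")["gold_risk"].iloc[0] == risk

    @pytest.mark.parametrize("braak,risk", [
        (0, "low"), (2, "low"), (3, "intermediate"), (4, "intermediate"),
        (5, "high"), (6, "high"),
    ])
    def test_braak_rule(self, braak, risk):
        clin = pd.DataFrame({"time": [80.0], "event": [1], "braak": [braak]},
                            index=pd.Index(["p1"], name="id"))
        assert prepare_survival(clin, "braak")["gold_risk"].iloc[0] == risk

    def test_cytogenetics_passthrough(self):
        clin = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": [1, 0, 1],
                             "cytogenetics": ["Favorable", "intermediate",
                                              "Poor"]},
                            index=pd.Index(["a", "b", "c"], name="id"))
        out = prepare_survival(clin, "cytogenetics")
        assert list(out["gold_risk"]) == ["low", "intermediate", "high"]

    def test_missing_time_rows_removed(self):
        clin = pd.DataFrame({"time": [1.0, np.nan], "event": [1, 1],
                             "stage": ["I", "I"]},
                            index=pd.Index(["a", "b"], name="id"))
        out = prepare_survival(clin, "lungStage")
        assert list(out.index) == ["a"]

    def test_unknown_stage_token_named_in_error(self):
        clin = pd.DataFrame({"time": [1.0], "event": [1], "stage": ["IX"]},
                            index=pd.Index(["a"], name="id"))
        with pytest.raises(ValueError, match="IX"):
            prepare_survival(clin, "lungStage")

    def test_missing_required_column_error(self):
        clin = pd.DataFrame({"time": [1.0], "event": [1]},
                            index=pd.Index(["a"], name="id"))
        with pytest.raises(ValueError, match="braak"):
            prepare_survival(clin, "braak")


def _election_inputs(rng, n_samples=60):
    ids = [f"s{i}" for i in range(n_samples)]
    time = rng.exponential(100, n_samples)
    surv = pd.DataFrame({"time": time, "event": rng.integers(0, 2, n_samples)},
                        index=pd.Index(ids, name="id"))
    tz = (time - time.mean()) / time.std()
    coupled = 0.6 * tz + 0.8 * rng.standard_normal((5, n_samples))
    null = rng.standard_normal((40, n_samples))
    expr = pd.DataFrame(np.vstack([coupled, null]),
                        index=[f"gc{i}" for i in range(5)]
                        + [f"gn{i}" for i in range(40)], columns=ids)
    meth = pd.DataFrame(rng.uniform(size=(10, n_samples)),
                        index=[f"cg{i}" for i in range(10)], columns=ids)
    return expr, meth, surv


class TestElectFeatures:
    def test_either_rule_keeps_time_correlated_gene(self, rng):
        expr, meth, surv = _election_inputs(rng)
        election = elect_features(expr, meth, surv, cor_cutoff=0.3)
        assert set(g for g in election.selected_genes
                   if g.startswith("gc")) == {f"gc{i}" for i in range(5)}

    def test_monotone_in_cutoff(self, rng):
        expr, meth, surv = _election_inputs(rng)
        low = elect_features(expr, meth, surv, cor_cutoff=0.1)
        high = elect_features(expr, meth, surv, cor_cutoff=0.3)
        assert high.selected_genes <= low.selected_genes
        assert high.selected_loci <= low.selected_loci

    def test_zero_variance_feature_excluded(self, rng):
        expr, meth, surv = _election_inputs(rng)
        expr.loc["flat"] = 1.0
        election = elect_features(expr, meth, surv, cor_cutoff=0.05)
        assert "flat" not in election.selected_genes

    def test_false_keep_rate_matches_null_distribution(self):
        """Null genes pass at the rate the exact null |r| tail predicts."""
        n, n_null, cutoff = 100, 400, 0.2
        t_val = cutoff * np.sqrt((n - 2) / (1 - cutoff ** 2))
        p_single = 2 * stats.t.sf(t_val, df=n - 2)
        rates, coupled_kept = [], []
        for seed in range(100):
            r = np.random.default_rng(seed)
            ids = [f"s{i}" for i in range(n)]
            time = r.exponential(100, n)
            surv = pd.DataFrame({"time": time,
                                 "event": r.integers(0, 2, n)},
                                index=pd.Index(ids, name="id"))
            tz = (time - time.mean()) / time.std()
            coupled = 0.45 * tz[None, :] \
                + 0.6 * r.standard_normal((50, n))
            null = r.standard_normal((n_null, n))
            expr = pd.DataFrame(np.vstack([coupled, null]),
                                index=[f"gc{i}" for i in range(50)]
                                + [f"gn{i}" for i in range(n_null)],
                                columns=ids)
            meth = pd.DataFrame(np.empty((0, n)), columns=ids)
            kept = elect_features(expr, meth, surv, cor_cutoff=cutoff
                                  ).selected_genes
            rates.append(sum(1 for g in kept if g.startswith("gn")) / n_null)
            coupled_kept.append(
                sum(1 for g in kept if g.startswith("gc")) / 50)
        # keep-if-either rule: between one and two single-test tails
        assert 0.5 * p_single < np.mean(rates) < 2.5 * p_single
        assert np.mean(coupled_kept) >= 0.8


class TestComputeUnion:
    MAP = LocusGeneMap.from_pairs([("cg1", "A"), ("cg2", "B")])

    def test_expands_both_directions(self):
        election = FeatureElection(frozenset({"A"}), frozenset({"cg2"}), 0.2)
        out = compute_union(election, self.MAP)
        assert out.selected_genes == {"A", "B"}
        assert out.selected_loci == {"cg1", "cg2"}

    def test_empty_election_stays_empty(self):
        election = FeatureElection(frozenset(), frozenset(), 0.2)
        out = compute_union(election, self.MAP)
        assert len(out) == 0

    def test_idempotent_under_many_to_many_map(self):
        lgmap = LocusGeneMap.from_pairs(
            [("cg1", "A"), ("cg1", "B"), ("cg2", "B"), ("cg3", "C")])
        election = FeatureElection(frozenset({"A"}), frozenset(), 0.2)
        once = compute_union(election, lgmap)
        twice = compute_union(once, lgmap)
        assert once.selected_genes == twice.selected_genes
        assert once.selected_loci == twice.selected_loci

    def test_monotone_never_removes(self):
        election = FeatureElection(frozenset({"A", "Z"}), frozenset({"cgX"}),
                                   0.2)
        out = compute_union(election, self.MAP)
        assert election.selected_genes <= out.selected_genes
        assert election.selected_loci <= out.selected_loci
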