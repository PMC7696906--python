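import numpy as np
import pandas as pd
import pytest

from conftest import make_quant
from coldphos.temporal import (DEPParams, TemporalProfiles, call_deps,
                               classify_archetypes, compute_profiles,
                               kmeans_cluster, pairwise_ttests,
                               redistribute_cluster_e)


def _profiles_from(mean_rows):
    """TemporalProfiles from a dict peptide_id -> 4 mean log2FCs; replicate
    FCs are the mean repeated three times."""
    times = [5, 15, 30, 60]
    ids = list(mean_rows)
    mean_df = pd.DataFrame([list(mean_rows[p]) for p in ids],
                           index=ids, columns=times)
    rep_cols = [f"{t}min_rep{r}" for t in times for r in (1, 2, 3)]
    rep_fc = pd.DataFrame([np.repeat(list(mean_rows[p]), 3) for p in ids],
                          index=ids, columns=rep_cols)
    return TemporalProfiles(times=times, replicate_fc=rep_fc, mean_fc=mean_df)


class TestComputeProfiles:
    def test_constant_intensities_give_zero_fc(self):
        q = make_quant({"a": [100.0] * 15})
        prof = compute_profiles(q)
        assert np.allclose(prof.mean_fc.loc["a"], 0.0)
        assert np.allclose(prof.replicate_fc.loc["a"], 0.0)

    def test_doubling_gives_fc_one(self):
        vals = [100.0] * 3 + [200.0] * 3 + [100.0] * 9
        q = make_quant({"a": vals})
        prof = compute_profiles(q)
        assert prof.replicate_fc.loc["a", "5min_rep1"] == pytest.approx(1.0)
        assert prof.mean_fc.loc["a", 5] == pytest.approx(1.0)

    def test_missing_baseline_excludes_row(self):
        vals = [np.nan] * 3 + [100.0] * 12
        q = make_quant({"a": vals, "b": [100.0] * 15})
        prof = compute_profiles(q)
        assert prof.excluded == ["a"]
        assert list(prof.mean_fc.index) == ["b"]

    def test_matches_cell_by_cell_recomputation(self, rng):
        rows = {f"p{i}": list(2.0 ** rng.normal(18, 1, size=15))
                for i in range(50)}
        q = make_quant(rows)
        prof = compute_profiles(q)
        for pid, vals in rows.items():
            base = np.log2(np.mean(vals[0:3]))
            for j, t in enumerate((5, 15, 30, 60)):
                for r in range(3):
                    expected = np.log2(vals[3 * (j + 1) + r]) - base
                    got = prof.replicate_fc.loc[pid, f"{t}min_rep{r + 1}"]
                    assert got == pytest.approx(expected, abs=1e-12)


class TestPairwiseTtests:
    def test_identical_groups_give_p_one(self):
        q = make_quant({"a": [100.0] * 15})
        p = pairwise_ttests(q)
        assert (p.loc["a"] == 1.0).all()

    def test_separated_groups_give_small_p(self, rng):
        base = 100.0 + rng.normal(0, 0.1, 3)
        t5 = 500.0 + rng.normal(0, 0.1, 3)
        vals = list(base) + list(t5) + [100.0] * 9
        q = make_quant({"a": vals})
        assert pairwise_ttests(q).loc["a", 5] < 0.01

    def test_insufficient_replicates_give_nan(self):
        vals = [100.0] * 3 + [200.0, np.nan, np.nan] + [100.0] * 9
        q = make_quant({"a": vals})
        assert np.isnan(pairwise_ttests(q).loc["a", 5])

    @pytest.mark.parametrize("equal_var", [False, True])
    def test_matches_closed_form(self, rng, equal_var):
        """Welch / Student t computed from the textbook formulas."""
        from scipy import stats
        for _ in range(20):
            vals = list(2.0 ** rng.normal(18, 1, size=15))
            q = make_quant({"a": vals})
            got = pairwise_ttests(q, equal_var=equal_var).loc["a", 5]
            a = np.log2(vals[3:6])
            b = np.log2(vals[0:3])
            va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
            na = nb = 3
            if equal_var:
                sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
                tstat = (np.mean(a) - np.mean(b)) / np.sqrt(sp * (1 / na + 1 / nb))
                df = na + nb - 2
            else:
                se2 = va / na + vb / nb
                tstat = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
                df = se2 ** 2 / ((va / na) ** 2 / (na - 1) +
                                 (vb / nb) ** 2 / (nb - 1))
            expected = 2 * stats.t.sf(abs(tstat), df)
            assert got == pytest.approx(expected, abs=1e-10)


class TestKmeansCluster:
    def _blob_profiles(self, rng, centers, n=50, sd=0.05):
        rows = {}
        for ci, c in enumerate(centers):
            for i in range(n):
                rows[f"c{ci}_{i}"] = np.asarray(c) + rng.normal(0, sd, 4)
        return _profiles_from(rows)

    def test_two_separated_blobs_perfectly_split(self, rng):
        prof = self._blob_profiles(rng, [(2, 0, 0, 0), (-2, 0, 0, 0)])
        res = kmeans_cluster(prof, k=2, seed=1)
        labels = res.assignments["kmeans_cluster"]
        first = labels[[i for i in labels.index if i.startswith("c0")]]
        second = labels[[i for i in labels.index if i.startswith("c1")]]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_same_seed_identical_assignments(self, rng):
        prof = self._blob_profiles(rng, [(2, 0, 0, 0), (0, 2, 0, 0),
                                         (0, 0, 2, 0)], sd=0.3)
        r1 = kmeans_cluster(prof, k=3, seed=9)
        r2 = kmeans_cluster(prof, k=3, seed=9)
        pd.testing.assert_frame_equal(r1.assignments, r2.assignments)

    def test_beats_random_assignments(self, rng):
        prof = self._blob_profiles(rng, [(2, 0, 0, 0), (0, 2, 0, 0)], sd=0.5)
        res = kmeans_cluster(prof, k=2, seed=3)
        X = prof.mean_fc.to_numpy()
        for s in range(50):
            r = np.random.default_rng(s)
            labels = r.integers(0, 2, len(X))
            wss = sum(((X[labels == c] - X[labels == c].mean(axis=0)) ** 2).sum()
                      for c in (0, 1) if (labels == c).any())
            assert res.inertia <= wss + 1e-9

    def test_k_larger_than_n_is_error(self, rng):
        prof = self._blob_profiles(rng, [(1, 0, 0, 0)], n=3)
        with pytest.raises(ValueError):
            kmeans_cluster(prof, k=8)


class TestClassifyArchetypes:
    @pytest.mark.parametrize("centroid,expected", [
        ((2.0, 0.3, 0.1, 0.0), "A"),
        ((0.2, 1.8, 0.4, 0.1), "B"),
        ((0.0, 0.2, 1.5, 0.4), "C"),
        ((0.1, 0.1, 0.3, 2.0), "D"),
        ((1.5, 0.9, 1.0, 1.3), "E"),
        ((-1.0, -1.2, -1.3, -1.5), "F"),
        ((-1.5, -0.4, -1.5, -0.8), "G"),
        ((0.05, -0.1, 0.02, 0.0), "H"),
    ])
    def test_shape_rules(self, centroid, expected):
        from coldphos.temporal import ClusterResult
        res = ClusterResult(
            assignments=pd.DataFrame({"kmeans_cluster": [0]},
                                     index=pd.Index(["p"], name="peptide_id")),
            centroids=pd.DataFrame([centroid], columns=[5, 15, 30, 60]),
            archetype_by_cluster={}, inertia=0.0)
        assert classify_archetypes(res).archetype_by_cluster[0] == expected

    def test_synthetic_recovery_above_90_percent(self, default_sim):
        q, *_ , truth = default_sim
        prof = compute_profiles(q)
        res = classify_archetypes(kmeans_cluster(prof, k=8, seed=4))
        tp = truth.peptides.set_index("peptide_id")
        merged = res.assignments.join(tp[["archetype"]], rsuffix="_true")
        acc = (merged["archetype"] == merged["archetype_true"]).mean()
        assert acc >= 0.90


class TestRedistributeClusterE:
    def _result_with_e(self, mean_rows):
        from coldphos.temporal import ClusterResult
        prof = _profiles_from(mean_rows)
        res = ClusterResult(
            assignments=pd.DataFrame(
                {"kmeans_cluster": [0] * len(mean_rows),
                 "archetype": ["E"] * len(mean_rows)},
                index=pd.Index(list(mean_rows), name="peptide_id")),
            centroids=pd.DataFrame([[1, 1, 1, 1]], columns=[5, 15, 30, 60]),
            archetype_by_cluster={0: "E"}, inertia=0.0)
        return redistribute_cluster_e(res, prof)

    @pytest.mark.parametrize("profile,expected", [
        ((1.2, 1.0, 1.0, 1.1), "early"),
        ((1.0, 1.0, 1.0, 1.6), "late"),
        ((1.0, 1.3, 1.3, 1.0), "early"),   # tie at 15 and 30 -> earlier
    ])
    def test_peak_time_rule(self, profile, expected):
        res = self._result_with_e({"p": profile})
        assert res.assignments.loc["p", "response_class"] == expected

    def test_response_classes_partition_everything(self, default_sim):
        q, *_ = default_sim
        prof = compute_profiles(q)
        res = classify_archetypes(kmeans_cluster(prof, k=8, seed=4))
        res = redistribute_cluster_e(res, prof)
        classes = set(res.assignments["response_class"])
        assert classes <= {"early", "late", "dephosphorylated", "unresponsive"}
        assert not res.assignments["response_class"].isna().any()
        assert len(res.assignments) == len(prof.mean_fc.dropna())


class TestCallDeps:
    def _single(self, rep_fcs, p=0.01):
        times = [5, 15, 30, 60]
        rep_cols = [f"{t}min_rep{r}" for t in times for r in (1, 2, 3)]
        rep = pd.DataFrame([rep_fcs + [0.0] * 9], index=["a"], columns=rep_cols)
        mean = pd.DataFrame([[np.mean(rep_fcs), 0, 0, 0]], index=["a"],
                            columns=times)
        prof = TemporalProfiles(times=times, replicate_fc=rep, mean_fc=mean)
        tt = pd.DataFrame([[p] * 4], index=["a"], columns=times)
        return call_deps(prof, tt)

    def test_two_of_three_passing_is_up(self):
        assert self._single([1.2, 1.1, 0.4]).loc["a", 5] == "up"

    def test_small_changes_are_none(self):
        assert self._single([0.3, 0.2, 0.1]).loc["a", 5] == "none"

    def test_significance_required(self):
        assert self._single([1.2, 1.1, 1.3], p=0.5).loc["a", 5] == "none"

    def test_down_call_symmetric(self):
        assert self._single([-1.2, -1.1, -0.4]).loc["a", 5] == "down"

    def test_matches_brute_force_predicate(self, rng):
        times = [5, 15, 30, 60]
        rep_cols = [f"{t}min_rep{r}" for t in times for r in (1, 2, 3)]
        n = 30
        rep = pd.DataFrame(rng.normal(0, 1.2, size=(n, 12)),
                           index=[f"p{i}" for i in range(n)], columns=rep_cols)
        mean = pd.DataFrame({t: rep[[f"{t}min_rep{r}" for r in (1, 2, 3)]]
                             .mean(axis=1) for t in times})
        prof = TemporalProfiles(times=times, replicate_fc=rep, mean_fc=mean)
        tt = pd.DataFrame(rng.uniform(0, 0.2, size=(n, 4)), index=rep.index,
                          columns=times)
        calls = call_deps(prof, tt, DEPParams())
        for pid in rep.index:
            for t in times:
                fcs = rep.loc[pid, [f"{t}min_rep{r}" for r in (1, 2, 3)]]
                sig = tt.loc[pid, t] < 0.05
                if (fcs >= 1).sum() >= 2 and sig:
                    expected = "up"
                elif (fcs <= -1).sum() >= 2 and sig:
                    expected = "down"
                else:
                    expected = "none"
                assert calls.loc[pid, t] == expected

    def test_raising_threshold_never_adds_up_calls(self, rng):
        times = [5, 15, 30, 60]
        rep_cols = [f"{t}min_rep{r}" for t in times for r in (1, 2, 3)]
        rep = pd.DataFrame(rng.normal(0.8, 0.8, size=(40, 12)),
                           index=[f"p{i}" for i in range(40)], columns=rep_cols)
        mean = pd.DataFrame({t: rep[[f"{t}min_rep{r}" for r in (1, 2, 3)]]
                             .mean(axis=1) for t in times})
        prof = TemporalProfiles(times=times, replicate_fc=rep, mean_fc=mean)
        tt = pd.DataFrame(0.01, index=rep.index, columns=times)
        lo = call_deps(prof, tt, DEPParams(up_threshold=0.8))
        hi = call_deps(prof, tt, DEPParams(up_threshold=1.2))
        assert ((hi == "up") & (lo != "up")).sum().sum() == 0

    def test_sensitivity_and_specificity_on_synthetic(self, default_sim):
        q, *_ , truth = default_sim
        prof = compute_profiles(q)
        tt = pairwise_ttests(q)
        deps = call_deps(prof, tt)
        tp = truth.peptides.set_index("peptide_id")
        a_ids = tp.index[tp.archetype == "A"].intersection(deps.index)
        h_ids = tp.index[tp.archetype == "H"].intersection(deps.index)
        assert (deps.loc[a_ids, 5] == "up").mean() >= 0.90
        assert (deps.loc[h_ids] == "none").all(axis=1).mean() >= 0.95
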