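import collections

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.base import clone
from sklearn.metrics import adjusted_rand_score

from lupus_ssc import simulate as sim
from lupus_ssc import ssc
from tests.conftest import truth_sample_labels


def three_blobs(rng, n_per=30, sep=6.0, dim=4):
    centers = np.zeros((3, dim))
    centers[1, 0] = sep
    centers[2, 1] = sep
    X = np.vstack([rng.normal(c, 1.0, size=(n_per, dim)) for c in centers])
    labels = np.repeat([0, 1, 2], n_per)
    return X, labels


class TestKMedoids:
    def test_recovers_separated_blobs(self, rng):
        X, labels = three_blobs(rng)
        D = squareform(pdist(X))
        got = ssc.kmedoids(D, 3, np.random.default_rng(1))
        assert adjusted_rand_score(labels, got) == 1.0


class TestChooseK:
    def test_unanimous_on_separated_spherical_clusters(self, rng):
        X, _ = three_blobs(rng)
        k, votes = ssc.choose_k(X, seed=0)
        assert k == 3
        assert set(votes.values()) == {3}

    def test_degenerate_identical_samples_rejected(self):
        X = np.ones((20, 3))
        with pytest.raises(ValueError, match="identical"):
            ssc.choose_k(X, seed=0)

    def test_single_blob_never_overclusters(self):
        for s in range(3):
            X = np.random.default_rng(40 + s).normal(size=(120, 8))
            k, _ = ssc.choose_k(X, seed=s, gap_b=20)
            assert k <= 2


class TestConsensusPartition:
    def test_unanimous_base_partitions_pass_through(self, rng):
        X, labels = three_blobs(rng)
        got, coassoc = ssc.consensus_partition(X, 3, seed=0)
        assert adjusted_rand_score(labels, got) == 1.0

    def test_coassociation_entries_quantized(self, rng):
        X = rng.normal(size=(25, 5))
        _, coassoc = ssc.consensus_partition(X, 3, seed=0)
        vals = np.unique(np.round(coassoc, 6))
        assert set(vals) <= {0.0, round(1 / 3, 6), round(2 / 3, 6), 1.0}


class TestCentroidsAndCorrection:
    def test_one_sample_per_cluster_centroids_are_samples(self, rng):
        X = rng.normal(size=(3, 4))
        cen = ssc.fit_centroids(X, [0, 1, 2])
        np.testing.assert_allclose(cen, X)

    def test_empty_cluster_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            ssc.fit_centroids(rng.normal(size=(4, 2)), [0, 0, 2, 2])

    def test_fixed_point_converges_in_one_iteration(self, rng):
        X, labels = three_blobs(rng, sep=10.0)
        cen = ssc.fit_centroids(X, labels)
        _, out_labels, n_iter, _ = ssc.iterative_correction(cen, X, labels=labels)
        assert n_iter == 1
        assert (out_labels == labels).all()

    def test_wcss_non_increasing(self, rng):
        X = rng.normal(size=(80, 6))
        labels = rng.integers(0, 3, 80)
        labels[:3] = [0, 1, 2]
        cen = ssc.fit_centroids(X, labels)
        _, _, _, trace = ssc.iterative_correction(cen, X, labels=labels)
        assert all(a >= b - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_label_noise_is_corrected(self, rng):
        X, labels = three_blobs(rng, sep=8.0)
        noisy = labels.copy()
        flip = rng.random(len(noisy)) < 0.1
        noisy[flip] = (noisy[flip] + 1) % 3
        cen = ssc.fit_centroids(X, noisy)
        _, corrected, _, _ = ssc.iterative_correction(cen, X, labels=noisy)
        assert adjusted_rand_score(labels, corrected) >= adjusted_rand_score(labels, noisy)

    def test_lost_cluster_keeps_previous_centroid(self, rng):
        X = rng.normal(size=(10, 2))
        cen = np.vstack([X.mean(axis=0), X.mean(axis=0) + 100.0])
        with pytest.warns(UserWarning, match="lost all members"):
            out_cen, labels, _, _ = ssc.iterative_correction(cen, X, labels=np.zeros(10, int))
        np.testing.assert_allclose(out_cen[1], cen[1])


class TestClassifyAndModel:
    def _model(self):
        return ssc.SubtypeModel(
            k=2,
            signature_genes=["g1", "g2"],
            gene_means=[0.0, 0.0],
            gene_sds=[1.0, 1.0],
            centroids=[[0.0, 0.0], [3.0, 0.0]],
            training_labels={"s0": 0, "s1": 1},
        )

    def test_sample_at_centroid_gets_zero_distance(self):
        model = self._model()
        samples = pd.DataFrame({"A": [3.0, 0.0]}, index=["g1", "g2"])
        out = ssc.classify(model, samples)
        assert out.loc[0, "label"] == 1
        assert out.loc[0, "dist_1"] == 0.0
        assert out.loc[0, "lik_1"] > out.loc[0, "lik_0"]

    def test_equidistant_ties_to_lowest_index_uniform_likelihood(self):
        model = self._model()
        samples = pd.DataFrame({"A": [1.5, 0.0]}, index=["g1", "g2"])
        out = ssc.classify(model, samples)
        assert out.loc[0, "label"] == 0
        assert out.loc[0, "lik_0"] == pytest.approx(0.5)

    def test_missing_signature_gene_rejected(self):
        model = self._model()
        samples = pd.DataFrame({"A": [1.0]}, index=["g1"])
        with pytest.raises(KeyError, match="g2"):
            ssc.classify(model, samples)

    def test_gene_sds_must_be_positive(self):
        with pytest.raises(ValueError, match="gene_sds"):
            ssc.SubtypeModel(
                k=2, signature_genes=["g"], gene_means=[0.0], gene_sds=[0.0],
                centroids=[[0.0], [1.0]],
            )

    def test_json_round_trip_reproduces_assignments(self, tmp_path, rng):
        X, _ = three_blobs(rng, n_per=15)
        frame = pd.DataFrame(X, index=[f"s{i}" for i in range(len(X))],
                             columns=[f"g{j}" for j in range(X.shape[1])])
        est = ssc.SubtypeClassifier(k=3, random_state=0).fit(frame)
        model = est.to_model()
        model.to_json(tmp_path / "m.json")
        back = ssc.SubtypeModel.from_json(tmp_path / "m.json")
        samples = frame.T
        pd.testing.assert_frame_equal(ssc.classify(model, samples), ssc.classify(back, samples))


class TestSubtypeClassifierEstimator:
    def test_clone_and_get_params(self):
        est = ssc.SubtypeClassifier(k=3, tol=0.02)
        cloned = clone(est)
        assert cloned.get_params()["tol"] == 0.02

    def test_predict_order_independent(self, rng):
        X, _ = three_blobs(rng)
        frame = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
        est = ssc.SubtypeClassifier(k=3, random_state=0).fit(frame)
        perm = rng.permutation(len(frame))
        a = est.predict(frame)
        b = est.predict(frame.iloc[perm])
        assert (a[perm] == b).all()

    def test_proba_rows_sum_to_one(self, rng):
        X, _ = three_blobs(rng)
        frame = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
        est = ssc.SubtypeClassifier(k=3, random_state=0).fit(frame)
        p = est.predict_proba(frame)
        np.testing.assert_allclose(p.sum(axis=1), 1.0)
        assert (np.argmin(est.distances(frame), axis=1) == np.argmax(p, axis=1)).all()

    def test_zero_variance_training_gene_rejected(self, rng):
        frame = pd.DataFrame({"g1": rng.normal(size=10), "g2": np.ones(10)})
        with pytest.raises(ValueError, match="zero-variance"):
            ssc.SubtypeClassifier(k=2).fit(frame)

    def test_end_to_end_holdout_recovery(self, small_cohort):
        expr, clin, truth = small_cohort
        sle = clin[clin["state"] == "SLE"]
        genes = sim.module_panel(truth)
        pats = sorted(sle["patient_id"].unique())
        rng = np.random.default_rng(3)
        rng.shuffle(pats)
        n_tr = int(round(2 / 3 * len(pats)))
        tr = sle[sle["patient_id"].isin(pats[:n_tr])]
        te = sle[sle["patient_id"].isin(pats[n_tr:])]
        est = ssc.SubtypeClassifier(k=3, random_state=1).fit(expr.loc[genes, tr["sample_id"]].T)
        true_tr = [truth.subtype_of_patient[p] for p in tr["patient_id"]]
        assert adjusted_rand_score(true_tr, est.labels_) >= 0.9
        mapping = {}
        for c in range(3):
            votes = collections.Counter(t for t, l in zip(true_tr, est.labels_) if l == c)
            mapping[c] = votes.most_common(1)[0][0]
        pred = est.predict(expr.loc[genes, te["sample_id"]].T)
        true_te = [truth.subtype_of_patient[p] for p in te["patient_id"]]
        acc = np.mean([mapping[c] == t for c, t in zip(pred, true_te)])
        assert acc >= 0.9


class TestNameSubtypes:
    def test_planted_names_recovered(self, small_cohort):
        expr, clin, truth = small_cohort
        from lupus_ssc.functional import ged_activity

        gs = sim.planted_genesets(truth, seed=0)
        sle = clin[clin["state"] == "SLE"]
        genes = sim.module_panel(truth)
        est = ssc.SubtypeClassifier(k=3, random_state=0).fit(expr.loc[genes, sle["sample_id"]].T)
        act = ged_activity(expr, clin, gs)
        names = ssc.name_subtypes(est.to_model(), act, gs, clin)
        assert set(names.values()) == {"mixed", "IFN-high", "NE-high"}
        truth_labels = truth_sample_labels(clin, truth)
        for c, name in names.items():
            members = [s for s, l in est.to_model().training_labels.items() if l == c]
            majority = collections.Counter(truth_labels[members]).most_common(1)[0][0]
            assert name == majority

    def test_no_elevation_is_error(self, small_cohort):
        expr, clin, truth = small_cohort
        from lupus_ssc.functional import ged_activity

        gs = sim.planted_genesets(truth, seed=0)
        act = ged_activity(expr, clin, gs)
        healthy = clin.loc[clin["state"] == "healthy", "sample_id"].tolist()
        model = ssc.SubtypeModel(
            k=2,
            signature_genes=["x"],
            gene_means=[0.0],
            gene_sds=[1.0],
            centroids=[[0.0], [1.0]],
            training_labels={healthy[0]: 0, healthy[1]: 1},
        )
        with pytest.raises(ValueError, match="neither module"):
            ssc.name_subtypes(model, act, gs, clin)


class TestSledaiBySubtype:
    def test_matches_brute_force_kruskal(self):
        groups = {"a": [1, 2, 3], "b": [7, 8, 9], "c": [14, 15, 16]}
        rows, labels = [], {}
        i = 0
        for g, vals in groups.items():
            for v in vals:
                sid = f"s{i}"
                rows.append(dict(patient_id=f"p{i}", sample_id=sid, state="SLE", sledai=v))
                labels[sid] = g
                i += 1
        clin = pd.DataFrame(rows)
        out = ssc.sledai_by_subtype(pd.Series(labels), clin, trim=False)
        # brute force: KW statistic from explicit rank sums (no ties here)
        all_vals = [v for vals in groups.values() for v in vals]
        ranks = stats.rankdata(all_vals)
        n = len(all_vals)
        idx = 0
        h = 0.0
        for vals in groups.values():
            r = ranks[idx: idx + len(vals)]
            h += r.sum() ** 2 / len(vals)
            idx += len(vals)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        assert out["statistic"] == pytest.approx(h, rel=1e-12)
        assert len(out["pairwise"]) == 3

    def test_trim_removes_tukey_outliers(self):
        vals = [3, 4, 5, 4, 3, 5, 4, 50]  # 50 is far outside the fences
        rows = [dict(patient_id=f"p{i}", sample_id=f"s{i}", state="SLE", sledai=v)
                for i, v in enumerate(vals)]
        labels = pd.Series({f"s{i}": ("a" if i % 2 else "b") for i in range(len(vals))})
        out = ssc.sledai_by_subtype(labels, pd.DataFrame(rows), trim=True)
        assert sum(out["groups"].values()) == len(vals) - 1

    def test_single_group_rejected(self):
        rows = [dict(patient_id=f"p{i}", sample_id=f"s{i}", state="SLE", sledai=i)
                for i in range(4)]
        labels = pd.Series({f"s{i}": "a" for i in range(4)})
        with pytest.raises(ValueError, match="2 subtypes"):
            ssc.sledai_by_subtype(labels, pd.DataFrame(rows))
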