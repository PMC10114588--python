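import numpy as np
import pytest

import labelboot as lb
from labelboot.io_formats import UNASSIGNED
from labelboot.preprocessing import ProcessedMatrix

from conftest import small_bundle, processed_pair, truth_map
from oracles import brute_force_singler


def pm(values, cell_prefix="c", gene_ids=None, zero_cells=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ProcessedMatrix(
        values=values,
        cell_ids=np.array([f"{cell_prefix}{i}" for i in range(n)], dtype=object),
        hvg_ids=(
            np.array([f"g{j}" for j in range(g)], dtype=object)
            if gene_ids is None
            else np.asarray(gene_ids, dtype=object)
        ),
        zero_cells=zero_cells,
    )


def cluster_matrix(rng, centers, n_per, noise=0.05):
    rows, labels = [], []
    for i, c in enumerate(centers):
        rows.append(c + noise * rng.normal(size=(n_per, len(c))))
        labels += [chr(65 + i)] * n_per
    return np.vstack(rows), np.array(labels, dtype=object)


class TestSinglerLike:
    def test_exact_reference_cell_recovered(self, small_ref_query):
        ref, qry, ref_pm, qry_pm = small_ref_query
        # a query identical to a reference cell of a well-separated type
        probe = ref_pm.subset([0])
        probe.cell_ids = np.array(["probe"], dtype=object)
        preds = lb.predict_singler_like(ref_pm, ref.dataset.labels, probe)
        assert preds[0].label == str(ref.dataset.labels[0])
        assert preds[0].confidence > 0.5

    def test_two_type_reference_single_round(self):
        rng = np.random.default_rng(0)
        vals, labels = cluster_matrix(
            rng, [np.r_[np.ones(5), np.zeros(5)], np.r_[np.zeros(5), np.ones(5)]], 6
        )
        ref_pm = pm(vals, "r")
        qry_pm = pm(vals[[0, 6]], "q")
        preds = lb.predict_singler_like(ref_pm, labels, qry_pm)
        assert [p.label for p in preds] == ["A", "B"]

    def test_fewer_than_two_labels_rejected(self):
        vals = np.random.default_rng(0).normal(size=(4, 6))
        with pytest.raises(ValueError, match="2 distinct labels"):
            lb.predict_singler_like(
                pm(vals, "r"), np.array(["A"] * 4, dtype=object), pm(vals, "q")
            )

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_elimination_oracle(self, trial):
        """Vectorized elimination equals the naive per-cell oracle on random
        instances with <=4 types, <=30 cells, <=20 genes."""
        rng = np.random.default_rng(500 + trial)
        n_types = int(rng.integers(2, 5))
        types = [chr(65 + i) for i in range(n_types)]
        n_cells = int(rng.integers(n_types * 2, 31))
        n_genes = int(rng.integers(6, 21))
        labels = np.array(
            [types[i % n_types] for i in range(n_cells)], dtype=object
        )
        vals = rng.normal(size=(n_cells, n_genes))
        vals /= np.linalg.norm(vals, axis=1, keepdims=True)
        qv = rng.normal(size=(3, n_genes))
        qv /= np.linalg.norm(qv, axis=1, keepdims=True)
        gpt = int(rng.integers(2, 8))
        preds = lb.predict_singler_like(
            pm(vals, "r"), labels, pm(qv, "q"), params={"genes_per_type": gpt}
        )
        for i, p in enumerate(preds):
            expected, _ = brute_force_singler(
                vals, labels, qv[i], genes_per_type=gpt
            )
            assert p.label == expected


class TestCcaMnn:
    def test_self_transfer_identity(self):
        rng = np.random.default_rng(1)
        centers = [np.r_[np.ones(6), np.zeros(12)],
                   np.r_[np.zeros(6), np.ones(6), np.zeros(6)],
                   np.r_[np.zeros(12), np.ones(6)]]
        vals, labels = cluster_matrix(rng, centers, 12)
        preds = lb.predict_cca_mnn(pm(vals, "r"), labels, pm(vals, "q"),
                                   params={"n_cca": 5})
        assert [p.label for p in preds] == list(labels)
        assert all(p.confidence == 1.0 for p in preds)

    def test_k1_reciprocal_pairs_match_brute_force(self):
        # same embedding recipe, naive all-pairs scan for the neighbor logic
        rng = np.random.default_rng(2)
        centers = [np.r_[np.ones(5), np.zeros(5)], np.r_[np.zeros(5), np.ones(5)]]
        rvals, rlabs = cluster_matrix(rng, centers, 10, noise=0.3)
        qvals, _ = cluster_matrix(rng, centers, 8, noise=0.3)
        preds = lb.predict_cca_mnn(
            pm(rvals, "r"), rlabs, pm(qvals, "q"), params={"k": 1, "n_cca": 4}
        )

        def std(X):
            mu, sd = X.mean(0), X.std(0)
            sd[sd == 0] = 1
            return (X - mu) / sd

        U, s, Vt = np.linalg.svd(std(rvals) @ std(qvals).T, full_matrices=False)
        re, qe = U[:, :4] * s[:4], Vt[:4].T * s[:4]
        re /= np.linalg.norm(re, axis=1, keepdims=True)
        qe /= np.linalg.norm(qe, axis=1, keepdims=True)
        d = ((qe[:, None, :] - re[None, :, :]) ** 2).sum(-1)
        for qi in range(len(qe)):
            r_star = int(np.argmin(d[qi]))
            mutual = int(np.argmin(d[:, r_star])) == qi
            if mutual:
                assert preds[qi].label == rlabs[r_star]
                assert preds[qi].confidence == 1.0
            else:
                assert preds[qi].label == rlabs[r_star]
                assert preds[qi].confidence == 0.0

    def test_boundary_cells_less_confident(self):
        rng = np.random.default_rng(3)
        a = np.r_[np.ones(8), np.zeros(8)]
        b = np.r_[np.zeros(8), np.ones(8)]
        rvals, rlabs = cluster_matrix(rng, [a, b], 25, noise=0.2)
        core, _ = cluster_matrix(rng, [a, b], 15, noise=0.2)
        boundary = 0.5 * (a + b) + 0.2 * rng.normal(size=(20, 16))
        qvals = np.vstack([core, boundary])
        preds = lb.predict_cca_mnn(
            pm(rvals, "r"), rlabs, pm(qvals, "q"), params={"n_cca": 4}
        )
        conf = np.array([p.confidence for p in preds])
        assert conf[30:].mean() < conf[:30].mean()

    def test_invalid_n_cca_rejected(self):
        vals = np.random.default_rng(0).normal(size=(6, 5))
        with pytest.raises(ValueError, match="n_cca"):
            lb.predict_cca_mnn(
                pm(vals, "r"), np.array(list("AABBAB"), dtype=object),
                pm(vals, "q"), params={"n_cca": 0},
            )


class TestToppairForest:
    def test_single_marker_pair_separates(self):
        rng = np.random.default_rng(4)
        n = 40
        vals = 0.05 * rng.normal(size=(2 * n, 10))
        vals[:n, 0] += 1.0   # marker of A
        vals[n:, 1] += 1.0   # marker of B
        labels = np.array(["A"] * n + ["B"] * n, dtype=object)
        q = 0.05 * rng.normal(size=(20, 10))
        q[:10, 0] += 1.0
        q[10:, 1] += 1.0
        preds = lb.predict_toppair_forest(
            pm(vals, "r"), labels, pm(q, "q"), seed=11
        )
        assert [p.label for p in preds] == ["A"] * 10 + ["B"] * 10

    def test_constant_matrix_degenerates_to_majority(self):
        vals = np.full((10, 6), 0.3)
        labels = np.array(["A"] * 6 + ["B"] * 4, dtype=object)
        preds = lb.predict_toppair_forest(
            pm(vals, "r"), labels, pm(np.full((3, 6), 0.3), "q"), seed=0
        )
        assert [p.label for p in preds] == ["A"] * 3

    def test_no_rand_profiles_never_unassigned(self, small_ref_query):
        ref, qry, ref_pm, qry_pm = small_ref_query
        preds = lb.predict_toppair_forest(
            ref_pm, ref.dataset.labels, qry_pm, params={"n_rand": 0}, seed=1
        )
        assert all(p.label != UNASSIGNED for p in preds)

    def test_rand_profiles_reject_shuffled_cells(self, small_ref_query):
        ref, qry, ref_pm, qry_pm = small_ref_query
        rng = np.random.default_rng(5)
        shuffled = qry_pm.values.copy()
        for j in range(shuffled.shape[1]):
            rng.shuffle(shuffled[:, j])
        probe = pm(shuffled, "shuf", gene_ids=qry_pm.hvg_ids)
        preds = lb.predict_toppair_forest(
            ref_pm, ref.dataset.labels, probe, params={"n_rand": 150}, seed=1
        )
        frac_rejected = np.mean([p.label == UNASSIGNED for p in preds])
        assert frac_rejected > 0.3


class TestCentroid:
    def test_exact_centroid_max_confidence(self):
        vals = np.array([[1.0, 0.0], [1.0, 0.2], [0.0, 1.0], [0.2, 1.0]])
        labels = np.array(["A", "A", "B", "B"], dtype=object)
        q = np.array([[1.0, 0.1]])
        preds = lb.predict_centroid(pm(vals, "r"), labels, pm(q, "q"))
        assert preds[0].label == "A"
        assert preds[0].confidence > 0.99

    def test_equidistant_tie_breaks_lexicographically(self):
        vals = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5]])
        labels = np.array(["B", "A"], dtype=object)
        q = np.array([[0.5, 0.5, 0.5]])
        preds = lb.predict_centroid(pm(vals, "r"), labels, pm(q, "q"))
        assert preds[0].label == "A"
        assert preds[0].confidence == pytest.approx(0.5, abs=1e-6)

    def test_single_label_reference_allowed(self):
        vals = np.random.default_rng(0).normal(size=(5, 4))
        preds = lb.predict_centroid(
            pm(vals, "r"), np.array(["A"] * 5, dtype=object),
            pm(vals[:2], "q"),
        )
        assert [(p.label, p.confidence) for p in preds] == [("A", 1.0)] * 2

    def test_well_separated_types_perfect(self, small_ref_query):
        ref, qry, ref_pm, qry_pm = small_ref_query
        preds = lb.predict_centroid(ref_pm, ref.dataset.labels, qry_pm)
        report = lb.evaluate(preds, truth_map(qry.dataset))
        assert report.macro_f1 > 0.95


class TestUniformContract:
    @pytest.mark.parametrize("name", sorted(lb.CLASSIFIERS))
    def test_reference_order_permutation_invariance(self, name):
        ref, qry = small_bundle(
            abundances=(("A", 40), ("B", 30), ("C", 20)),
            query_abundances=(("A", 10), ("B", 10), ("C", 10)),
            seed=13,
        )
        ref_pm, qry_pm = processed_pair(ref.dataset, qry.dataset, n_hvgs=80)
        spec = lb.ClassifierSpec(name, seed=3)
        base = lb.predict(spec, ref_pm, ref.dataset.labels, qry_pm)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ref_pm.n_cells)
        shuffled = ref_pm.subset(perm)
        again = lb.predict(spec, shuffled, ref.dataset.labels[perm], qry_pm)
        assert [(p.cell_id, p.label) for p in base] == [
            (p.cell_id, p.label) for p in again
        ]

    @pytest.mark.parametrize("name", sorted(lb.CLASSIFIERS))
    def test_zero_count_query_cells_unassigned(self, name):
        ref, qry = small_bundle(seed=21)
        ref_pm, qry_pm = processed_pair(ref.dataset, qry.dataset, n_hvgs=60)
        qry_pm.zero_cells[:3] = True  # emulate cells with no counts on HVGs
        preds = lb.predict(
            lb.ClassifierSpec(name, seed=0), ref_pm, ref.dataset.labels, qry_pm
        )
        for p in preds[:3]:
            assert p.label == UNASSIGNED
            assert p.confidence == 0.0

    def test_mismatched_gene_columns_rejected(self):
        vals = np.random.default_rng(0).normal(size=(6, 5))
        labels = np.array(list("AABBAB"), dtype=object)
        other = pm(vals[:, :4], "q", gene_ids=[f"h{j}" for j in range(4)])
        with pytest.raises(ValueError, match="gene columns"):
            lb.predict_centroid(pm(vals, "r"), labels, other)

    def test_unknown_classifier_name_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            lb.ClassifierSpec("nope")
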