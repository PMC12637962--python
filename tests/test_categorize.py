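import numpy as np
import pytest

from suppmat.categorize import (
    CategorizedSet,
    KSelectionReport,
    LabeledTableSet,
    assign_category,
    assign_category_centroid,
    build_kselection,
    fit_categories,
    gap_statistic,
    kmeans_fit,
    load_code_registry,
    make_code,
    name_clusters,
    select_k,
    silhouette,
    tau_from_other_fraction,
    wcss,
)
from conftest import gaussian_blobs
from oracles import brute_assign, exhaustive_kmeans_wcss


class TestKMeans:
    def test_k_equals_n(self):
        X = np.array([[0.0], [1.0], [5.0]])
        c, a = kmeans_fit(X, 3, seed=0)
        assert wcss(X, a, c) == 0.0
        assert len(set(a.tolist())) == 3

    def test_two_separated_pairs(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        c, a = kmeans_fit(X, 2, seed=0)
        assert a[0] == a[1] and a[2] == a[3] and a[0] != a[2]
        assert sorted(c.ravel().tolist()) == pytest.approx([0.05, 10.05])
        # independent check: matches the exhaustive-partition optimum
        assert wcss(X, a, c) == pytest.approx(exhaustive_kmeans_wcss(X, 2))

    def test_deterministic_given_seed(self):
        X = np.random.default_rng(3).normal(size=(40, 4))
        c1, a1 = kmeans_fit(X, 5, seed=9)
        c2, a2 = kmeans_fit(X, 5, seed=9)
        assert np.array_equal(a1, a2) and np.allclose(c1, c2)

    def test_k_out_of_range(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            kmeans_fit(X, 4, seed=0)
        with pytest.raises(ValueError):
            kmeans_fit(X, 0, seed=0)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_exhaustive_optimum(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        k = int(rng.integers(1, 4))
        X = rng.normal(size=(n, 2))
        c, a = kmeans_fit(X, k, seed=trial, n_init=20)
        assert wcss(X, a, c) == pytest.approx(exhaustive_kmeans_wcss(X, k), rel=1e-9)

    def test_weighted_equals_replication(self):
        # frequency weights must act like replicated points
        X = np.array([[0.0], [1.0], [10.0]])
        w = np.array([3.0, 1.0, 1.0])
        c, a = kmeans_fit(X, 2, seed=0, weights=w)
        Xrep = np.array([[0.0]] * 3 + [[1.0], [10.0]])
        cr, ar = kmeans_fit(Xrep, 2, seed=0, n_init=20)
        assert wcss(X, a, c, weights=w) == pytest.approx(wcss(Xrep, ar, cr))

    def test_no_empty_clusters(self):
        X = np.vstack([np.zeros((20, 2)), np.ones((1, 2))])
        c, a = kmeans_fit(X, 3, seed=1)
        assert len(set(a.tolist())) == 3


class TestWCSS:
    def test_zero_when_points_on_centroids(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0]])
        assert wcss(X, np.array([0, 1]), X.copy()) == 0.0

    def test_hand_computed(self):
        X = np.array([[0.0, 0.0], [0.0, 2.0]])
        assert wcss(X, np.array([0, 0]), np.array([[0.0, 1.0]])) == pytest.approx(2.0)

    def test_nesting_property(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        prev = np.inf
        for k in range(1, 8):
            c, a = kmeans_fit(X, k, seed=0, n_init=10)
            w = wcss(X, a, c)
            assert w <= prev + 1e-9
            prev = w


class TestGap:
    def test_single_tight_blob_selects_1(self):
        X = gaussian_blobs(1, n_per=40, seed=5)
        out = gap_statistic(X, range(1, 6), B=20, seed=2)
        assert out["chosen_k"] == 1

    def test_three_blobs_selects_3(self):
        X = gaussian_blobs(3, n_per=30, seed=8)
        out = gap_statistic(X, range(1, 7), B=20, seed=3)
        assert out["chosen_k"] == 3

    def test_finite_on_nondegenerate(self):
        X = np.random.default_rng(1).normal(size=(25, 3))
        out = gap_statistic(X, range(1, 6), B=5, seed=0)
        assert np.all(np.isfinite(out["gap"])) and np.all(np.isfinite(out["s"]))

    def test_degenerate_data_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            gap_statistic(np.ones((10, 2)), range(1, 4), B=3, seed=0)


class TestSilhouette:
    def test_two_singletons(self):
        X = np.array([[0.0], [5.0]])
        assert silhouette(X, np.array([0, 1])) == 0.0

    def test_hand_computed(self):
        X = np.array([[0.0], [0.2], [10.0], [10.2]])
        a = np.array([0, 0, 1, 1])
        # outer points: a=0.2, b=(10+10.2)/2=10.1; inner points: b=(9.8+10)/2=9.9
        expected = (9.9 / 10.1 + 9.7 / 9.9 + 9.7 / 9.9 + 9.9 / 10.1) / 4
        assert silhouette(X, a) == pytest.approx(expected, abs=1e-12)

    def test_random_assignment_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(60, 2))
        a = rng.integers(0, 2, size=60)
        assert silhouette(X, a) < 0.1

    def test_single_cluster_errors(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 2)), np.zeros(4, dtype=int))

    def test_bounds_and_sklearn_oracle(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(6)
        for trial in range(5):
            X = rng.normal(size=(40, 3))
            a = rng.integers(0, 4, size=40)
            if len(set(a.tolist())) < 2:
                continue
            ours = silhouette(X, a)
            assert -1.0 <= ours <= 1.0
            counts = np.bincount(a, minlength=4)
            if np.all(counts[np.unique(a)] > 1):
                assert ours == pytest.approx(silhouette_score(X, a), abs=1e-9)


class TestSelectK:
    def _report(self, ks, wcss_vals, gap_k, sil):
        return KSelectionReport(
            k_grid=list(ks), wcss=list(wcss_vals), gap=[0.0] * len(ks),
            gap_s=[0.0] * len(ks), silhouette=list(sil), gap_k=gap_k,
        )

    def test_unanimous(self):
        ks = [3, 4, 5, 6, 7]
        w = [100, 60, 20, 18, 17]  # max curvature at 5
        sil = [0.2, 0.3, 0.9, 0.4, 0.3]
        r = self._report(ks, w, 5, sil)
        assert select_k(r) == 5

    def test_median_rule(self):
        ks = [3, 4, 5, 6, 7]
        w = [100, 60, 30, 29, 28]  # elbow (max curvature) less... construct votes 4,5,6
        sil = [0.2, 0.3, 0.4, 0.9, 0.3]  # sil -> 6
        r = self._report(ks, w, 4, sil)  # gap -> 4; elbow -> 5
        assert r.k_grid[1 + int(np.argmax([w[i - 1] - 2 * w[i] + w[i + 1] for i in range(1, 4)]))] == 5
        assert select_k(r) == 5

    def test_grid_too_short(self):
        r = self._report([2, 3], [10, 5], 2, [0.1, 0.2])
        with pytest.raises(ValueError):
            select_k(r)

    @pytest.mark.parametrize("k_true", [1, 3, 5, 8])
    def test_blob_recovery(self, k_true):
        X = gaussian_blobs(k_true, n_per=25, seed=k_true)
        report = build_kselection(X, range(1, 11), B=20, seed=42, n_init=4)
        assert report.chosen_k == k_true

    def test_fixture_vocabulary_5_blob_benchmark(self):
        from conftest import tight_categories
        from suppmat.synth import CorpusSpec, generate_smfiles, make_labeled_seed

        spec = CorpusSpec(n_articles=40, categories=tight_categories(5, 5), files_per_article=2, seed=5)
        _, truth = generate_smfiles(spec)
        labeled = make_labeled_seed(truth, 1.0, seed=1)
        report = build_kselection(labeled.vectors, range(1, 9), B=20, seed=11, n_init=8)
        assert report.chosen_k == 5


class TestNaming:
    def test_modal_label(self):
        labeled = LabeledTableSet(
            ["t1", "t2", "t3", "t4"],
            np.eye(4),
            ["A", "A", "A", "B"],
        )
        rep, code = name_clusters({"t1": 0, "t2": 0, "t3": 0, "t4": 0}, labeled, registry={})
        assert rep[0] == "A"

    def test_tie_breaks_lexicographic(self):
        labeled = LabeledTableSet(["t1", "t2"], np.eye(2), ["B", "A"])
        rep, _ = name_clusters({"t1": 0, "t2": 0}, labeled, registry={})
        assert rep[0] == "A"

    def test_registry_code_gped(self):
        registry = load_code_registry()
        assert registry["Gene Expression Data"] == "GPED"
        labeled = LabeledTableSet(["t1"], np.eye(1), ["Gene Expression Data"])
        _, code = name_clusters({"t1": 0}, labeled)
        assert code[0] == "GPED"

    def test_registry_has_14_codes(self):
        registry = load_code_registry()
        assert len(registry) == 14
        assert len(set(registry.values())) == 14

    def test_generated_code_consonant_preferring(self):
        assert make_code("Novel Assay Panel", set()) == "NVLS"

    def test_code_collision_suffixing(self):
        taken = {"NVLS"}
        c2 = make_code("Novel Assay Panel", taken)
        assert c2 != "NVLS" and len(c2) == 4

    def test_othr_reserved(self):
        assert make_code("Other", set()) != "OTHR"


class TestAssign:
    def _categorized(self, seed=0, n=200, d=32):
        rng = np.random.default_rng(seed)
        vecs = rng.normal(size=(n, d))
        ids = [f"t{i:04d}" for i in range(n)]
        codes = [["GPED", "CPC", "MAV"][i % 3] for i in range(n)]
        return CategorizedSet(ids, vecs, codes)

    def test_identical_vector_similarity_1(self):
        cat = self._categorized()
        code, sim = assign_category(cat.vectors[7].copy(), cat, tau=0.0)
        assert sim == pytest.approx(1.0)
        assert code == cat.codes[7]

    def test_below_tau_is_othr(self):
        cat = CategorizedSet(["a"], np.array([[1.0, 0.0]]), ["GPED"])
        code, sim = assign_category(np.array([0.0, 1.0]), cat, tau=0.5)
        assert code == "OTHR" and sim == pytest.approx(0.0)

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            assign_category(np.ones(2), CategorizedSet([], np.zeros((0, 2)), []), 0.1)

    def test_brute_force_oracle_200x50(self):
        cat = self._categorized(seed=42)
        rng = np.random.default_rng(7)
        for _ in range(50):
            q = rng.normal(size=32)
            got = assign_category(q, cat, tau=0.3)
            want = brute_assign(q, cat.table_ids, cat.vectors, cat.codes, 0.3)
            assert got[0] == want[0]
            assert got[1] == pytest.approx(want[1], abs=1e-12)

    def test_tie_breaks_to_smaller_table_id(self):
        vecs = np.array([[1.0, 0.0], [1.0, 0.0]])
        cat = CategorizedSet(["a", "b"], vecs, ["CPC", "GPED"])
        code, _ = assign_category(np.array([2.0, 0.0]), cat, tau=0.0)
        assert code == "CPC"

    def test_other_fraction_monotone_in_tau(self):
        cat = self._categorized(seed=3)
        rng = np.random.default_rng(5)
        queries = rng.normal(size=(60, 32))
        fractions = []
        for tau in (0.0, 0.1, 0.2, 0.4, 0.8, 1.0):
            n_other = sum(assign_category(q, cat, tau=tau)[0] == "OTHR" for q in queries)
            fractions.append(n_other / len(queries))
        assert fractions == sorted(fractions)

    def test_centroid_mode(self):
        labeled = LabeledTableSet(
            ["a", "b", "c", "d"],
            np.array([[1.0, 0, 0], [0.9, 0.1, 0], [0, 0, 1.0], [0, 0.1, 0.9]]),
            ["Gene Expression Data"] * 2 + ["Survival Analysis"] * 2,
        )
        model = fit_categories(labeled, k=2, seed=0)
        code, sim = assign_category_centroid(np.array([1.0, 0.0, 0.0]), model, tau=0.1)
        assert code in set(model.code.values()) and sim > 0.9


class TestFitCategories:
    def test_model_invariants(self):
        rng = np.random.default_rng(2)
        labels = ["Gene Expression Data", "Survival Analysis", "Clinical Diagnostics Data"]
        vecs, ids, labs = [], [], []
        for li, lab in enumerate(labels):
            base = np.zeros(16)
            base[li * 5] = 1.0
            for i in range(10):
                ids.append(f"{lab[:2]}{i}")
                vecs.append(base + 0.01 * rng.normal(size=16))
                labs.append(lab)
        labeled = LabeledTableSet(ids, np.vstack(vecs), labs)
        model = fit_categories(labeled, k=3, seed=0)
        model.validate()
        assert set(model.representative.values()) == set(labels)
        assert set(model.code.values()) == {"GPED", "SA", "CDD"}
        assert "OTHR" not in model.code.values()

    def test_weighted_and_unweighted_modes(self):
        labeled = LabeledTableSet(
            [f"t{i}" for i in range(6)],
            np.vstack([np.eye(3), np.eye(3) * 0.9]),
            ["Gene Expression Data", "Survival Analysis", "Ecotoxicology Data"] * 2,
        )
        for weighted in (True, False):
            model = fit_categories(labeled, k=3, seed=1, weighted=weighted)
            assert model.k == 3
            model.validate()


def test_tau_from_other_fraction():
    sims = np.linspace(0, 1, 101)
    tau = tau_from_other_fraction(sims, 0.10)
    below = np.mean(sims < tau)
    assert below == pytest.approx(0.10, abs=0.02)
    with pytest.raises(ValueError):
        tau_from_other_fraction([], 0.1)
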