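import numpy as np
import pytest

from geneximb import (
    ClassDistribution,
    ExpressionDataset,
    apply_oversampler,
    borderline_smote,
    class_distribution,
    classify_neighborhoods,
    kmeans_smote,
    plan_balance_to_majority,
    smote,
    svm_smote,
)
from geneximb.oversampling import ResamplingPlan
from geneximb.synthetic_data import SyntheticSpec, generate

ALL_METHODS = ["smote", "b1", "b2", "svm", "kmeans"]


def _toy(points, labels):
    points = np.asarray(points, dtype=float)
    return ExpressionDataset(
        matrix=points,
        gene_ids=[f"g{j}" for j in range(points.shape[1])],
        sample_ids=[f"s{i}" for i in range(points.shape[0])],
        labels=np.array(labels, dtype=object),
    )


class TestPlan:
    def test_balance_to_majority_targets(self):
        dist = ClassDistribution(counts={"ALL": 27, "AML": 11},
                                 majority_class="ALL", minority_class="AML")
        plan = plan_balance_to_majority(dist)
        assert plan.target_counts == {"ALL": 27, "AML": 27}
        assert plan.need(dist) == {"ALL": 0, "AML": 16}

    def test_already_balanced_needs_nothing(self):
        dist = ClassDistribution(counts={"A": 10, "B": 10},
                                 majority_class="A", minority_class="A")
        assert all(v == 0 for v in plan_balance_to_majority(dist).need(dist).values())

    def test_five_class_targets_all_majority(self):
        counts = {"AML": 21, "BM": 8, "BM_CD34": 6, "PB": 8, "PBSC": 8}
        dist = ClassDistribution(counts=counts, majority_class="AML", minority_class="BM_CD34")
        plan = plan_balance_to_majority(dist)
        assert set(plan.target_counts.values()) == {21}

    def test_single_class_rejected(self):
        dist = ClassDistribution(counts={"A": 5}, majority_class="A", minority_class="A")
        with pytest.raises(ValueError):
            plan_balance_to_majority(dist)


class TestSmote:
    def test_two_point_interpolation_is_on_segment(self):
        train = _toy([[0, 0], [1, 1], [5, 5], [6, 6], [7, 7]],
                     ["m", "m", "M", "M", "M"])
        plan = ResamplingPlan(target_counts={"m": 3, "M": 3})
        aug, prov = smote(train, plan, k=1, seed=0)
        assert aug.n_samples == 6
        s = prov[0]
        # only neighbor pair is (0,0)-(1,1): synthetic lies on the diagonal
        assert s.values[0] == pytest.approx(s.values[1])
        assert 0.0 <= s.values[0] <= 1.0

    def test_zero_need_is_identity(self, tiny_dataset):
        plan = ResamplingPlan(target_counts={"A": 2, "B": 2})
        aug, prov = smote(tiny_dataset, plan, k=1, seed=0)
        assert prov == []
        np.testing.assert_array_equal(aug.matrix, tiny_dataset.matrix)
        assert aug.sample_ids == tiny_dataset.sample_ids

    def test_singleton_class_errors_unless_fallback(self):
        train = _toy([[0, 0], [5, 5], [6, 6]], ["m", "M", "M"])
        plan = ResamplingPlan(target_counts={"m": 2, "M": 2})
        with pytest.raises(ValueError, match="fallback"):
            smote(train, plan, k=5, seed=0)
        aug, prov = smote(train, plan, k=5, seed=0, allow_duplicate_fallback=True)
        np.testing.assert_array_equal(aug.matrix[-1], [0, 0])

    def test_synthetic_samples_inside_minority_bounding_box(self, imbalanced_binary):
        data, _ = imbalanced_binary
        plan = plan_balance_to_majority(class_distribution(data))
        aug, prov = smote(data, plan, k=5, seed=4)
        assert len(prov) == 52 - 9
        mino = data.matrix[data.labels == "min"]
        lo, hi = mino.min(axis=0), mino.max(axis=0)
        for s in prov:
            assert np.all(s.values >= lo - 1e-12) and np.all(s.values <= hi + 1e-12)


class TestNeighborhoods:
    def test_isolated_minority_is_noise(self):
        pts = [[0, 0]] + [[10 + i, 10] for i in range(6)]
        train = _toy(pts, ["m"] + ["M"] * 6)
        cats = classify_neighborhoods(train, "m", m=4)
        assert cats == {0: "noise"}

    def test_half_majority_neighbors_is_danger(self):
        # minority point with 2 minority + 2 majority among its 4 nearest
        pts = [[0, 0], [0, 1], [1, 0], [0, -1], [-1, 0], [50, 50], [51, 50], [50, 51]]
        train = _toy(pts, ["m", "m", "m", "M", "M", "M", "M", "M"])
        cats = classify_neighborhoods(train, "m", m=4)
        assert cats[0] == "danger"

    def test_deep_cluster_point_is_safe(self):
        spec = SyntheticSpec(
            n_classes=2, samples_per_class={"M": 30, "m": 12},
            n_genes=5, n_informative=5, effect_size=5.0, seed=9,
        )
        data, _ = generate(spec)
        cats = classify_neighborhoods(data, "m", m=5)
        # brute-force oracle: recount each minority point's neighbors directly
        X = data.matrix
        for abs_i, cat in cats.items():
            d = ((X - X[abs_i]) ** 2).sum(axis=1)
            order = [j for j in np.argsort(d, kind="stable") if j != abs_i][:5]
            m_maj = sum(1 for j in order if data.labels[j] != "m")
            expect = "noise" if m_maj == 5 else "danger" if 2 * m_maj >= 5 else "safe"
            assert cat == expect
        assert sum(1 for c in cats.values() if c == "safe") >= 10  # effect 5 => interior


class TestBorderline:
    def test_all_safe_falls_back_to_plain_seeding(self):
        spec = SyntheticSpec(
            n_classes=2, samples_per_class={"M": 20, "m": 8},
            n_genes=4, n_informative=4, effect_size=10.0, seed=2,
        )
        data, _ = generate(spec)
        plan = plan_balance_to_majority(class_distribution(data))
        with pytest.warns(UserWarning, match="danger"):
            aug, prov = borderline_smote(data, plan, variant="B1", seed=0)
        assert len(prov) == 12

    def test_b1_seeds_come_from_danger_set(self):
        # overlapping clusters so a danger set exists
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 1.0, (9, 2)), rng.normal(1.2, 1.0, (20, 2))])
        train = _toy(pts, ["m"] * 9 + ["M"] * 20)
        cats = classify_neighborhoods(train, "m", m=10)
        danger = {i for i, c in cats.items() if c == "danger"}
        assert danger  # construction sanity
        plan = ResamplingPlan(target_counts={"m": 20, "M": 20})
        aug, prov = borderline_smote(train, plan, k=3, m=10, variant="B1", seed=1)
        assert len(prov) == 11
        assert all(s.seed_index in danger for s in prov)

    def test_b2_majority_directed_gap_below_half(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 1.0, (9, 2)), rng.normal(1.2, 1.0, (20, 2))])
        train = _toy(pts, ["m"] * 9 + ["M"] * 20)
        plan = ResamplingPlan(target_counts={"m": 20, "M": 20})
        aug, prov = borderline_smote(train, plan, k=3, m=10, variant="B2", seed=5)
        maj_directed = [s for s in prov if train.labels[s.neighbor_index] != "m"]
        assert maj_directed  # coin flips at seed 5 hit both branches
        assert all(0.0 <= s.gap < 0.5 for s in maj_directed)
        min_directed = [s for s in prov if train.labels[s.neighbor_index] == "m"]
        assert all(0.0 <= s.gap <= 1.0 for s in min_directed)


class TestSvmSmote:
    def test_margin_support_vector_is_the_seed(self):
        # separable toy: minority point (1,0) is closest to the majority side
        train = _toy(
            [[1.0, 0.0], [0.0, 0.0], [-1.0, 0.0], [4.0, 0.0], [5.0, 0.0], [6.0, 0.0]],
            ["m", "m", "m", "M", "M", "M"],
        )
        from sklearn.svm import SVC

        y = (train.labels == "m").astype(int)
        svc = SVC(kernel="linear", C=1.0).fit(train.matrix, y)
        sv_min = set(svc.support_[y[svc.support_] == 1])
        plan = ResamplingPlan(target_counts={"m": 5, "M": 3})
        aug, prov = svm_smote(train, plan, k=2, m=3, seed=0)
        assert len(prov) == 2
        assert {s.seed_index for s in prov} <= sv_min

    def test_extrapolated_sample_collinear_beyond_seed(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(6, 0.5, (20, 2))])
        train = _toy(pts, ["m"] * 10 + ["M"] * 20)
        plan = ResamplingPlan(target_counts={"m": 20, "M": 20})
        aug, prov = svm_smote(train, plan, k=3, m=5, seed=2)
        extra = [s for s in prov if s.gap < 0]
        assert extra  # well-separated classes => safe seeds extrapolate
        for s in extra:
            seed_pt = train.matrix[s.seed_index]
            nb_pt = train.matrix[s.neighbor_index]
            # collinear: values - seed is parallel and opposite to neighbor - seed
            diff = s.values - seed_pt
            np.testing.assert_allclose(diff, s.gap * (nb_pt - seed_pt), atol=1e-12)

    def test_zero_need_identity(self, tiny_dataset):
        plan = ResamplingPlan(target_counts={"A": 2, "B": 2})
        aug, prov = svm_smote(tiny_dataset, plan, seed=0)
        assert prov == [] and aug.n_samples == 4


class TestKmeansSmote:
    def test_two_symmetric_clusters_split_evenly(self):
        rng = np.random.default_rng(0)
        c1 = rng.normal(0, 0.5, (10, 2))
        c2 = c1 + [100.0, 0.0]  # exact translate: identical size and spread
        far_majority = rng.normal(50, 0.5, (12, 2)) + [0.0, 100.0]
        train = _toy(np.vstack([c1, c2, far_majority]), ["m"] * 20 + ["M"] * 12)
        plan = ResamplingPlan(target_counts={"m": 40, "M": 12})
        aug, prov = kmeans_smote(train, plan, n_clusters=3, seed=1)
        assert len(prov) == 20
        left = sum(1 for s in prov if train.matrix[s.seed_index][0] < 50)
        assert abs(left - 10) <= 1  # 50/50 +-1 by largest-remainder rounding

    def test_seed_and_neighbor_share_cluster(self, imbalanced_binary):
        data, _ = imbalanced_binary
        plan = plan_balance_to_majority(class_distribution(data))
        from sklearn.cluster import KMeans

        aug, prov = kmeans_smote(data, plan, n_clusters=4, seed=6)
        km = KMeans(n_clusters=4, n_init=10, random_state=6).fit(data.matrix)
        for s in prov:
            assert km.labels_[s.seed_index] == km.labels_[s.neighbor_index]

    def test_no_eligible_cluster_falls_back(self):
        # minority scattered inside a majority blob: no cluster reaches 50%
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1.0, (40, 2))
        train = _toy(pts, ["m" if i < 5 else "M" for i in range(40)])
        plan = ResamplingPlan(target_counts={"m": 35, "M": 35})
        with pytest.warns(UserWarning, match="eligible"):
            aug, prov = kmeans_smote(train, plan, n_clusters=3, seed=0)
        assert len(prov) == 30


class TestSharedInvariants:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_counts_replay_and_immutability(self, method, imbalanced_binary):
        data, _ = imbalanced_binary
        plan = plan_balance_to_majority(class_distribution(data))
        aug, prov = apply_oversampler(method, data, plan=plan, seed=11)
        # (a) per-class counts match the plan exactly
        assert class_distribution(aug).counts == dict(plan.target_counts)
        # (b) provenance replays every synthetic sample exactly
        n0 = data.n_samples
        for i, s in enumerate(prov):
            np.testing.assert_array_equal(aug.matrix[n0 + i], s.replay(data.matrix))
        # (c) originals bitwise unchanged and first in order
        np.testing.assert_array_equal(aug.matrix[:n0], data.matrix)
        assert aug.sample_ids[:n0] == data.sample_ids
        # labels of synthetics match the oversampled class
        for i, s in enumerate(prov):
            assert aug.labels[n0 + i] == s.label

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_determinism_under_fixed_seed(self, method, imbalanced_binary):
        data, _ = imbalanced_binary
        a1, p1 = apply_oversampler(method, data, seed=21)
        a2, p2 = apply_oversampler(method, data, seed=21)
        np.testing.assert_array_equal(a1.matrix, a2.matrix)
        assert [(s.seed_index, s.neighbor_index, s.gap) for s in p1] == [
            (s.seed_index, s.neighbor_index, s.gap) for s in p2
        ]

    @pytest.mark.parametrize("method", ["smote", "b1", "b2", "kmeans"])
    def test_interpolation_convexity_from_provenance(self, method, imbalanced_binary):
        data, _ = imbalanced_binary
        _, prov = apply_oversampler(method, data, seed=31)
        for s in prov:
            lo = np.minimum(data.matrix[s.seed_index], data.matrix[s.neighbor_index])
            hi = np.maximum(data.matrix[s.seed_index], data.matrix[s.neighbor_index])
            assert np.all(s.values >= lo - 1e-12) and np.all(s.values <= hi + 1e-12)

    def test_multiclass_every_class_raised_to_majority(self, benchmark_fixtures):
        cu = benchmark_fixtures["cumida"]
        train = cu.dataset.subset_samples(cu.train_indices)
        aug, prov = apply_oversampler("smote", train, seed=3)
        counts = class_distribution(aug).counts
        assert set(counts.values()) == {21}
        assert len(prov) == 5 * 21 - 51

    def test_smote_matches_moment_oracle_on_2d_toy(self):
        # distributional cross-check: with k covering the whole minority set,
        # E[new] = E[seed] + E[gap] * (E[neighbor] - E[seed]) = minority mean,
        # since seeds cycle uniformly and neighbors are drawn uniformly.
        rng = np.random.default_rng(12)
        mino = rng.normal(0, 1, (12, 2))
        majo = rng.normal(8, 1, (300, 2))
        train = _toy(np.vstack([mino, majo]), ["m"] * 12 + ["M"] * 300)
        plan = ResamplingPlan(target_counts={"m": 300, "M": 300})
        _, prov = smote(train, plan, k=11, seed=0)
        synth = np.vstack([s.values for s in prov])
        # mean within Monte-Carlo error of the minority mean
        se = mino.std(axis=0) / np.sqrt(len(prov)) * 3 + 0.12
        np.testing.assert_allclose(synth.mean(axis=0), mino.mean(axis=0), atol=float(se.max()) + 0.15)
        # interpolation shrinks spread: synthetic variance below original
        assert np.all(synth.var(axis=0) <= mino.var(axis=0) * 1.1)
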