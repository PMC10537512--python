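import itertools

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from heterokit.io import MISSING
from heterokit.simulate import MarkerSpec, SimConfig, simulate_genotypes
from heterokit.structure import (
    MIXED,
    DistanceMatrix,
    admixture_em,
    evanno_delta_k,
    ibs_distance,
    pca_genotypes,
    ward_cluster,
)

from conftest import make_genotypes


class TestIbsDistance:
    def test_identical_samples_zero(self):
        geno = make_genotypes([[0, 1, 2, 1], [0, 1, 2, 1]])
        d = ibs_distance(geno)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_opposite_homozygotes_one(self):
        geno = make_genotypes([[0, 0, 0], [2, 2, 2]])
        assert ibs_distance(geno).values[0, 1] == pytest.approx(1.0)

    def test_het_vs_hom_half(self):
        geno = make_genotypes([[0], [1]])
        assert ibs_distance(geno).values[0, 1] == pytest.approx(0.5)

    def test_missing_markers_excluded(self):
        geno = make_genotypes([[0, 2, MISSING], [0, MISSING, 2]])
        # only marker 1 shared -> distance 0
        assert ibs_distance(geno).values[0, 1] == pytest.approx(0.0)

    def test_no_shared_markers_errors(self):
        geno = make_genotypes([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="share no"):
            ibs_distance(geno)

    def test_metric_on_complete_simulated_panel(self):
        geno, _ = simulate_genotypes(
            SimConfig(n_lines=10, seed=2,
                      marker=MarkerSpec(n_markers=150, missing_rate=0.0)))
        d = ibs_distance(geno).values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        n = d.shape[0]
        for i, j, k in itertools.combinations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def brute_force_partition_objective(d2, k):
    """Minimum within-cluster sum of squares over all K-partitions."""
    n = d2.shape[0]

    def gen(items):
        if not items:
            yield []
            return
        head, rest = items[0], items[1:]
        for p in gen(rest):
            for i in range(len(p)):
                yield p[:i] + [p[i] + [head]] + p[i + 1:]
            yield [[head]] + p

    best = np.inf
    for part in gen(list(range(n))):
        if len(part) != k:
            continue
        obj = sum(d2[np.ix_(b, b)].sum() / (2 * len(b)) for b in part)
        best = min(best, obj)
    return best


def partition_objective(d2, labels):
    obj = 0.0
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        obj += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return obj


class TestWardCluster:
    def _from_points(self, pts):
        pts = np.asarray(pts, dtype=float).reshape(len(pts), -1)
        return DistanceMatrix(samples=[f"S{i}" for i in range(len(pts))],
                              values=squareform(pdist(pts)))

    def test_1d_example_two_clusters(self):
        d = self._from_points([0, 1, 10, 11])
        res = ward_cluster(d, 2)
        assert res.labels["S0"] == res.labels["S1"]
        assert res.labels["S2"] == res.labels["S3"]
        assert res.labels["S0"] != res.labels["S2"]

    def test_k_equals_n(self):
        d = self._from_points([0, 3, 7, 12])
        res = ward_cluster(d, 4)
        assert len(set(res.labels.values())) == 4

    def test_duplicated_sample_merges_first(self):
        d = self._from_points([0.0, 5.0, 5.0, 9.0])
        res = ward_cluster(d, 3)
        assert res.labels["S1"] == res.labels["S2"]
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_k_out_of_range(self):
        d = self._from_points([0, 1, 2])
        with pytest.raises(ValueError):
            ward_cluster(d, 5)

    def test_matches_brute_force_on_separated_points(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, 4))
            centers = rng.permutation(np.arange(k))[:, None] * 10.0
            assign = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
            pts = centers[assign] + rng.normal(0, 0.6, size=(n, 1))
            d = self._from_points(pts)
            res = ward_cluster(d, k)
            labels = np.array([res.labels[s] for s in d.samples])
            d2 = d.values**2
            assert partition_objective(d2, labels) == pytest.approx(
                brute_force_partition_objective(d2, k), abs=1e-9)


class TestPca:
    def test_two_point_geometry(self):
        calls = np.array([[0] * 10, [0] * 10, [2] * 10, [2] * 10])
        scores, eigvals = pca_genotypes(make_genotypes(calls), 2)
        pc1 = scores["PC1"].to_numpy()
        assert np.sign(pc1[0]) == np.sign(pc1[1]) != np.sign(pc1[2])
        assert np.var(pc1[:2]) == pytest.approx(0.0, abs=1e-20)

    def test_trace_identity(self):
        geno, _ = simulate_genotypes(SimConfig(n_lines=15, seed=4,
                                               marker=MarkerSpec(n_markers=100,
                                                                 missing_rate=0.0)))
        x = geno.calls.astype(float)
        x = x - x.mean(axis=0)
        _, eigvals = pca_genotypes(geno, 5)
        total_var = (x**2).sum() / (geno.n_samples - 1)
        assert eigvals.sum() == pytest.approx(total_var, rel=1e-8)

    def test_eigenvalues_non_increasing(self):
        geno, _ = simulate_genotypes(SimConfig(n_lines=15, seed=5))
        _, eigvals = pca_genotypes(geno, 5)
        assert (np.diff(eigvals) <= 1e-9).all()

    def test_n_components_truncated_with_warning(self):
        geno = make_genotypes([[0, 1, 2], [2, 1, 0], [0, 0, 0]])
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = pca_genotypes(geno, 3)
        assert scores.shape[1] < 3

    def test_low_fst_shows_less_separation(self):
        def ratio(fst):
            cfg = SimConfig(n_lines=30, seed=21,
                            marker=MarkerSpec(n_markers=300, k=2, fst=fst,
                                              missing_rate=0.0))
            geno, _ = simulate_genotypes(cfg)
            _, eigvals = pca_genotypes(geno, 5)
            return eigvals[0] / eigvals.mean()

        assert ratio(0.01) < ratio(0.3)


def align_labels(pred, truth, k):
    """Best label permutation match count (pred entries may be MIXED)."""
    best = 0
    for perm in itertools.permutations(range(1, k + 1)):
        mapping = dict(zip(range(1, k + 1), perm))
        hits = sum(1 for p, t in zip(pred, truth)
                   if p != MIXED and mapping[p] == t + 1)
        best = max(best, hits)
    return best


class TestAdmixture:
    def test_k1_degenerate(self):
        geno = make_genotypes([[0, 1, 2], [2, 1, 0], [1, 1, 1]])
        res = admixture_em(geno, 1)
        assert np.allclose(res.q.to_numpy(), 1.0)
        # pooled binomial loglik: p = 0.5 at every site here
        g = geno.calls
        expected = (g * np.log(0.5) + (2 - g) * np.log(0.5)).sum()
        expected += (g == 1).sum() * np.log(2.0)
        assert res.loglik == pytest.approx(expected, rel=1e-9)

    def test_two_diverged_populations_recovered(self):
        calls = np.vstack([np.zeros((5, 40)), np.full((5, 40), 2)]).astype(np.int8)
        res = admixture_em(make_genotypes(calls), 2, n_replicates=3, seed=1)
        q = res.q.to_numpy()
        first, second = q[:5].mean(axis=0), q[5:].mean(axis=0)
        # memberships recovered up to label permutation
        assert max(first[0], first[1]) > 0.99
        assert abs(first - second).max() > 0.98

    def test_sixty_pct_threshold(self):
        geno, _ = simulate_genotypes(SimConfig(n_lines=10, seed=6,
                                               marker=MarkerSpec(n_markers=80)))
        res = admixture_em(geno, 2, n_replicates=2, seed=0)
        q = res.q.to_numpy()
        for i, s in enumerate(res.samples):
            if q[i].max() >= 0.60:
                assert res.assignments[s] == int(np.argmax(q[i])) + 1
            else:
                assert res.assignments[s] == MIXED

    def test_loglik_monotone(self):
        geno, _ = simulate_genotypes(SimConfig(n_lines=15, seed=7,
                                               marker=MarkerSpec(n_markers=100)))
        res = admixture_em(geno, 3, n_replicates=1, seed=3, max_iter=200)
        traj = np.array(res.loglik_trajectory)
        assert (np.diff(traj) >= -1e-6).all()

    def test_k_bounds(self):
        geno = make_genotypes([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            admixture_em(geno, 0)
        with pytest.raises(ValueError):
            admixture_em(geno, 3)


class TestEvanno:
    def test_hand_worked_example(self):
        logliks = {k: [m - 10.0, m, m + 10.0]
                   for k, m in zip(range(1, 5), (-1000.0, -800.0, -790.0, -785.0))}
        table = evanno_delta_k(logliks)
        t = table.table.set_index("K")
        assert t.loc[2, "delta_k"] == pytest.approx(19.0)
        assert t.loc[3, "delta_k"] == pytest.approx(0.5)
        assert table.best_k == 2

    def test_linear_loglik_all_zero(self):
        logliks = {k: [-100.0 * k - 5, -100.0 * k + 5] for k in range(1, 5)}
        table = evanno_delta_k(logliks)
        interior = table.table.dropna(subset=["delta_k"])
        assert (interior["delta_k"].abs() < 1e-9).all()

    def test_single_interior_k(self):
        logliks = {1: [-10.0, -12.0], 2: [-5.0, -6.0], 3: [-4.0, -5.0]}
        table = evanno_delta_k(logliks)
        assert table.table["delta_k"].notna().sum() == 1
        assert table.best_k == 2

    def test_zero_sd_flagged(self):
        logliks = {1: [-10.0, -10.0], 2: [-5.0, -5.0], 3: [-4.0, -4.0]}
        with pytest.raises(ValueError):
            evanno_delta_k(logliks)

    def test_non_consecutive_k_rejected(self):
        with pytest.raises(ValueError):
            evanno_delta_k({1: [1.0, 2.0], 3: [1.0, 2.0], 4: [0.0, 1.0]})


class TestEndToEndRecovery:
    def test_ward_and_admixture_recover_subpopulations(self):
        hits_ward = hits_adm = total = 0
        for seed in range(5):
            cfg = SimConfig(n_lines=28, n_testers=2, seed=seed,
                            marker=MarkerSpec(n_markers=250, k=3, fst=0.3,
                                              admixture_alpha=0.05))
            geno, truth = simulate_genotypes(cfg)
            truth_labels = [truth.subpop_labels[s] for s in geno.samples]
            d = ibs_distance(geno)
            ward = ward_cluster(d, 3)
            pred_w = [ward.labels[s] for s in geno.samples]
            hits_ward += align_labels(pred_w, truth_labels, 3)
            adm = admixture_em(geno, 3, n_replicates=2, seed=seed, max_iter=500)
            pred_a = [adm.assignments[s] for s in geno.samples]
            hits_adm += align_labels(pred_a, truth_labels, 3)
            total += len(truth_labels)
        assert hits_ward / total >= 0.9
        assert hits_adm / total >= 0.9
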