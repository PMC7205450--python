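"""Density-peak states, principal-tree pseudotime, NB spline DE,
gene modules, and stage boundaries."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import ovatlas as ov
from ovatlas.iodata import ValidationError
from ovatlas.trajectory import (
    DensityPeakParams,
    _size_factors,
    densitypeak_cluster,
    build_principal_tree,
    branch_test,
    gene_modules_cutree,
    pseudotime_de_test,
    stage_boundaries,
)
from conftest import make_count_matrix


@pytest.fixture(scope="module")
def branched_embedding(branched_sim):
    """PCA embedding plus aligned truth for the branched simulation."""
    _, cm, gt, _ = branched_sim
    nm = ov.lognormalize(cm)
    hvgs, _ = ov.select_hvg(nm)
    sm = ov.scale_regress(nm)
    pca = ov.run_pca(sm, hvgs, n_pcs=10)
    return pca.embeddings[:, :8], nm, gt


def _brute_force_density_peak(X, d_c, n_centers):
    """Independent O(n^2) transcription of the published assignment rule."""
    n = len(X)
    D = np.linalg.norm(X[:, None] - X[None], axis=2)
    rho = np.exp(-((D / d_c) ** 2)).sum(axis=1) - 1
    order = np.argsort(-rho, kind="stable")
    delta = np.empty(n)
    nearest = np.full(n, -1)
    for pos, i in enumerate(order):
        if pos == 0:
            delta[i] = D[i].max()
        else:
            higher = order[:pos]
            j = higher[np.argmin(D[i, higher])]
            delta[i] = D[i, j]
            nearest[i] = j
    centers = np.argsort(-(rho * delta), kind="stable")[:n_centers]
    labels = np.full(n, -1)
    for lab, c in enumerate(np.sort(centers)):
        labels[c] = lab
    for i in order:
        if labels[i] == -1:
            labels[i] = labels[nearest[i]]
    return labels


class TestDensityPeak:
    def test_two_blobs_perfectly_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack(
            [rng.normal(size=(40, 2)), rng.normal(size=(40, 2)) + 12]
        )
        cl = densitypeak_cluster(X, DensityPeakParams(n_centers=2))
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([0, 1], 40)
        assert adjusted_rand_score(truth, cl.labels) == 1.0

    def test_single_center_single_label(self):
        X = np.random.default_rng(1).normal(size=(20, 3))
        cl = densitypeak_cluster(X, DensityPeakParams(n_centers=1))
        assert cl.n_clusters == 1

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        params = DensityPeakParams(d_c=0.8, n_centers=3)
        cl = densitypeak_cluster(X, params)
        oracle = _brute_force_density_peak(X, 0.8, 3)
        # same partition (label ids may permute)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(oracle, cl.labels) == 1.0

    def test_duplicate_points_jittered(self):
        X = np.zeros((10, 2))
        X[5:] = 1.0
        with pytest.warns(UserWarning, match="jitter"):
            cl = densitypeak_cluster(X, DensityPeakParams(n_centers=2))
        assert cl.n_clusters == 2


class TestPrincipalTree:
    def test_collinear_states_path_order(self):
        rng = np.random.default_rng(3)
        X = np.column_stack(
            [np.repeat([0.0, 5.0, 10.0], 20), np.zeros(60)]
        ) + rng.normal(scale=0.2, size=(60, 2))
        labels = np.repeat([0, 1, 2], 20)
        traj = build_principal_tree(X, labels, root_spec=0)
        assert len(traj.branch_points) == 0
        rho = spearmanr(traj.pseudotime, X[:, 0]).statistic
        assert rho > 0.95

    def test_y_shaped_lineage_recovered(self, branched_embedding):
        E, nm, gt = branched_embedding
        truth = gt.cells
        states = densitypeak_cluster(E, DensityPeakParams(n_centers=8))
        g = gt.genes
        roots = g[
            (g.role == "ramp") & (g.ramp_kind == "logistic") & (g.ramp_sign < 0)
        ].gene_id.tolist()
        traj = build_principal_tree(E, states.labels, root_spec=roots, nm=nm)
        assert len(traj.branch_points) >= 1
        committed = truth.branch.isin(["A", "B"]).to_numpy()
        tab = pd.crosstab(pd.Series(traj.branch), truth.branch)
        mapping = tab.idxmax(axis=1)
        acc = (
            pd.Series(traj.branch[committed]).map(mapping).to_numpy()
            == truth.branch[committed].to_numpy()
        ).mean()
        assert acc >= 0.9
        for br in ("A", "B"):
            m = (truth.branch == br).to_numpy()
            rho = abs(spearmanr(traj.pseudotime[m], truth.t[m]).statistic)
            assert rho >= 0.9

    def test_mst_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for trial in range(3):
            k = 6
            cent = rng.normal(size=(k, 3))
            X = np.repeat(cent, 3, axis=0) + rng.normal(scale=0.01, size=(3 * k, 3))
            labels = np.repeat(np.arange(k), 3)
            traj = build_principal_tree(X, labels, root_spec=0)
            total = sum(w for _, _, w in traj.tree_edges)
            D = np.linalg.norm(
                traj.centroids[:, None] - traj.centroids[None], axis=2
            )
            best = np.inf
            # enumerate all spanning trees via Pruefer sequences
            for seq in itertools.product(range(k), repeat=k - 2):
                degree = [1] * k
                for v in seq:
                    degree[v] += 1
                seq_list = list(seq)
                weight = 0.0
                deg = degree[:]
                import heapq

                leaves = [v for v in range(k) if deg[v] == 1]
                heapq.heapify(leaves)
                s = seq_list[:]
                for v in s:
                    leaf = heapq.heappop(leaves)
                    weight += D[leaf, v]
                    deg[v] -= 1
                    if deg[v] == 1:
                        heapq.heappush(leaves, v)
                u, v = heapq.heappop(leaves), heapq.heappop(leaves)
                weight += D[u, v]
                best = min(best, weight)
            assert total == pytest.approx(best, abs=1e-9)

    def test_root_marker_tie_raises(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((10, 2)) * 5])
        labels = np.repeat([0, 1], 10)
        arr = np.ones((20, 4), dtype=int)  # identical cells -> tied scores
        nm = ov.lognormalize(make_count_matrix(arr))
        with pytest.raises(ValidationError, match="tie"):
            build_principal_tree(X, labels, root_spec=["G0"], nm=nm)


@pytest.fixture(scope="module")
def de_fixture():
    """Branched sim restricted to program + baseline genes, truth ordering."""
    d = ov.default_branched_design(seed=1, n_cells=500)
    cm, gt, _ = ov.simulate_atlas(d)
    g = gt.genes
    genes = (
        g[g.role.isin(["ramp", "branch"])].gene_id.tolist()
        + g[g.role == "baseline"].gene_id.tolist()[:250]
    )
    idx = [cm.gene_ids.index(x) for x in genes]
    cms = cm.subset_genes(np.array(idx))
    sf = _size_factors(cm.counts.toarray())
    roles = g.set_index("gene_id").role
    return cms, gt, sf, roles


class TestPseudotimeDE:
    def test_planted_programs_detected(self, de_fixture):
        cms, gt, sf, roles = de_fixture
        res = pseudotime_de_test(
            cms, gt.cells.t.to_numpy(), min_cells=5, size_factors=sf
        )
        tab = res.table.set_index("gene_id")
        tab["role"] = roles.loc[tab.index]
        assert (tab[tab.role == "ramp"].q < 0.05).mean() >= 0.8
        sig = tab[tab.q < 0.05]
        assert (sig.role == "baseline").mean() <= 0.07

    def test_null_type_one_error_near_zero(self):
        from ovatlas.synthetic import LineageSpec

        d = ov.default_branched_design(
            seed=5,
            n_cells=300,
            lineage=LineageSpec(
                program_log2fc=0.0, branch_log2fc=0.0, marker_log2fc=0.0
            ),
        )
        cm, gt, _ = ov.simulate_atlas(d)
        cms = cm.subset_genes(np.arange(400))
        sf = _size_factors(cm.counts.toarray())
        res = pseudotime_de_test(
            cms, gt.cells.t.to_numpy(), min_cells=5, size_factors=sf
        )
        assert (res.table.q < 0.05).mean() <= 0.01
        # p-values conservative-to-uniform: type-I at p<0.05 stays <= nominal
        p = res.table.p.dropna()
        assert (p < 0.05).mean() <= 0.06

    def test_min_cells_filter(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(2.0, size=(50, 5)) + 1
        arr[:, 0] = 0
        arr[:3, 0] = 1  # expressed in 3 cells only
        cm = make_count_matrix(arr)
        res = pseudotime_de_test(cm, rng.uniform(0, 1, 50), min_cells=5)
        assert "G0" not in set(res.table.gene_id)

    def test_non_finite_pseudotime_raises(self):
        cm = make_count_matrix(np.ones((10, 3), dtype=int))
        with pytest.raises(ValidationError):
            pseudotime_de_test(cm, np.full(10, np.nan))


class TestBranchTest:
    def _traj(self, gt):
        class T:
            pass

        t = T()
        t.pseudotime = gt.cells.t.to_numpy()
        t.branch = gt.cells.branch.to_numpy()
        return t

    def test_planted_divergence_detected(self, de_fixture):
        cms, gt, sf, roles = de_fixture
        bt = branch_test(
            cms, self._traj(gt), ("A", "B"), min_cells=5, size_factors=sf
        ).set_index("gene_id")
        bt["role"] = roles.loc[bt.index]
        assert (bt[bt.role == "branch"].q < 0.05).mean() >= 0.8
        sig = bt[bt.q < 0.05]
        assert (sig.role != "branch").mean() <= 0.07

    def test_branch_label_swap_symmetric(self, de_fixture):
        cms, gt, sf, roles = de_fixture
        sub = cms.subset_genes(np.arange(40))
        a = branch_test(sub, self._traj(gt), ("A", "B"), size_factors=sf)
        b = branch_test(sub, self._traj(gt), ("B", "A"), size_factors=sf)
        assert np.allclose(a.p.to_numpy(), b.p.to_numpy(), atol=1e-6, equal_nan=True)

    def test_small_branch_raises(self, de_fixture):
        cms, gt, sf, _ = de_fixture
        bad = self._traj(gt)
        bad.branch = np.where(bad.branch == "A", "A", "pre")
        bad.branch[np.flatnonzero(bad.branch == "pre")[:2]] = "B"
        with pytest.raises(ValidationError):
            branch_test(cms, bad, ("A", "B"), min_cells=5)


class TestGeneModules:
    def _curves(self):
        grid = np.linspace(0, 1, 50)
        up = np.vstack([grid + 0.05 * np.sin(7 * grid + i) for i in range(6)])
        down = -up + 1
        curves = pd.DataFrame(
            np.vstack([up, down]),
            index=[f"u{i}" for i in range(6)] + [f"d{i}" for i in range(6)],
        )
        return curves

    def test_anticorrelated_families_separated(self):
        modules = gene_modules_cutree(self._curves(), k=2)
        up_mods = {modules[f"u{i}"] for i in range(6)}
        down_mods = {modules[f"d{i}"] for i in range(6)}
        assert len(up_mods) == 1 and len(down_mods) == 1
        assert up_mods != down_mods

    def test_singleton_modules(self):
        curves = self._curves()
        modules = gene_modules_cutree(curves, k=len(curves))
        assert len(set(modules.values())) == len(curves)

    def test_gene_order_invariance(self):
        curves = self._curves()
        m1 = gene_modules_cutree(curves, k=2)
        perm = curves.sample(frac=1.0, random_state=0)
        m2 = gene_modules_cutree(perm, k=2)
        same1 = {g for g in m1 if m1[g] == m1["u0"]}
        same2 = {g for g in m2 if m2[g] == m2["u0"]}
        assert same1 == same2

    def test_k_exceeds_genes_raises(self):
        with pytest.raises(ValidationError):
            gene_modules_cutree(self._curves(), k=100)


class TestStageBoundaries:
    def _staged_sim(self, reverse=False):
        rng = np.random.default_rng(0)
        n, g = 400, 60
        t = rng.uniform(0, 1, n)
        arr = rng.poisson(2.0, size=(n, g)) + 1
        early = t < 0.5
        arr[np.ix_(early, np.arange(10))] += 25
        arr[np.ix_(~early, np.arange(10, 20))] += 25
        cm = make_count_matrix(arr)
        nm = ov.lognormalize(cm)
        sets = {
            "stage8": [f"G{j}" for j in range(10)],
            "stage9": [f"G{j}" for j in range(10, 20)],
        }
        return (1 - t if reverse else t), nm, sets

    def test_boundary_near_planted_switch(self):
        t, nm, sets = self._staged_sim()
        res = stage_boundaries(t, nm, sets)
        assert res.stage.tolist() == ["stage8", "stage9"]
        boundary = res.end.iloc[0]
        assert abs(boundary - 0.5) <= 0.05

    def test_single_stage_full_interval(self):
        t, nm, sets = self._staged_sim()
        res = stage_boundaries(t, nm, {"only": sets["stage8"]})
        assert len(res) == 1
        assert res.start.iloc[0] == pytest.approx(t.min())
        assert res.end.iloc[0] == pytest.approx(t.max())

    def test_reversed_pseudotime_reverses_order(self):
        t, nm, sets = self._staged_sim(reverse=True)
        res = stage_boundaries(t, nm, {"stage9": sets["stage9"], "stage8": sets["stage8"]})
        boundary = res.end.iloc[0]
        assert abs(boundary - 0.5) <= 0.05

    def test_intervals_contiguous_ordered(self):
        t, nm, sets = self._staged_sim()
        res = stage_boundaries(t, nm, sets)
        assert (res.start.to_numpy()[1:] == res.end.to_numpy()[:-1]).all()
        assert (res.end.to_numpy() >= res.start.to_numpy()).all()
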