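"""COG occupancy, PCA, core/pan analytics, Heaps fit, MDS, k-means."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from congenerics import SimulationConfig, simulate_pangenome
from congenerics.genomics import (
    accumulation_curve,
    binary_distance,
    cog_occupancy,
    core_genome,
    embed_2d,
    fit_heaps,
    kmeans_silhouette,
    pca,
    transportome_profile,
)


def genes_df(rows):
    return pd.DataFrame(rows, columns=["genome_id", "gene_id", "length_bp",
                                       "cog_categories"])


class TestCogOccupancy:
    def test_single_category(self):
        genes = genes_df([("g1", "a", 300, "C"), ("g1", "b", 700, "C")])
        prof = cog_occupancy(genes)
        assert prof.loc["g1", "C"] == 1.0

    def test_equal_allotment_multi_category(self):
        genes = genes_df([("g1", "a", 300, "C"), ("g1", "b", 300, "C;T")])
        prof = cog_occupancy(genes)
        assert prof.loc["g1", "C"] == pytest.approx((300 + 150) / 600)
        assert prof.loc["g1", "T"] == pytest.approx(150 / 600)

    def test_empty_category_counts_as_nic(self):
        genes = genes_df([("g1", "a", 400, ""), ("g1", "b", 600, "J")])
        prof = cog_occupancy(genes)
        assert prof.loc["g1", "NIC"] == pytest.approx(0.4)

    def test_rows_sum_to_one_random_table(self):
        rng = np.random.default_rng(0)
        cats = list("CEGJKLT")
        rows = []
        for g in range(5):
            for i in range(40):
                k = rng.integers(0, 3)
                chosen = ";".join(rng.choice(cats, size=k, replace=False))
                rows.append((f"g{g}", f"g{g}_{i}",
                             int(rng.integers(100, 3000)), chosen))
        prof = cog_occupancy(genes_df(rows))
        np.testing.assert_allclose(prof.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_per_gene_oracle(self):
        """Independent per-gene accumulation with explicit dictionaries."""
        rng = np.random.default_rng(1)
        cats = list("CEGJT")
        rows = []
        for g in range(3):
            for i in range(25):
                k = int(rng.integers(0, 3))
                chosen = sorted(rng.choice(cats, size=k, replace=False))
                rows.append((f"g{g}", f"gene{g}_{i}",
                             int(rng.integers(100, 2000)), ";".join(chosen)))
        genes = genes_df(rows)
        prof = cog_occupancy(genes)

        for genome in ("g0", "g1", "g2"):
            acc: dict[str, float] = {}
            total = 0.0
            for _, r in genes[genes.genome_id == genome].iterrows():
                cset = [c for c in str(r.cog_categories).split(";") if c] or ["NIC"]
                total += r.length_bp
                for c in cset:
                    acc[c] = acc.get(c, 0.0) + r.length_bp / len(cset)
            for c, w in acc.items():
                assert prof.loc[genome, c] == pytest.approx(w / total)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            cog_occupancy(genes_df([]))
        with pytest.raises(ValueError):
            cog_occupancy(genes_df([("g1", "a", 0, "C")]))
        with pytest.raises(ValueError):
            cog_occupancy(genes_df([("g1", "a", 10, "C;zz")]))


class TestPCA:
    def test_collinear_rows_single_component(self):
        base = np.array([1.0, 2.0, 3.0])
        X = pd.DataFrame(np.outer([1, 2, 3, 4], base))
        res = pca(X, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(12, 6)))
        res = pca(X, n_components=4)
        gram = res.loadings.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-9)

    def test_scores_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 5))
        res = pca(pd.DataFrame(X), n_components=3)
        Xc = X - X.mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(np.cov(Xc, rowvar=False, ddof=0))
        order = np.argsort(eigvals)[::-1][:3]
        oracle = Xc @ eigvecs[:, order]
        np.testing.assert_allclose(np.abs(res.scores.to_numpy()),
                                   np.abs(oracle), atol=1e-9)
        total = np.trace(np.cov(Xc, rowvar=False, ddof=0))
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   eigvals[order] / total, atol=1e-9)

    def test_constant_matrix_all_zero_scores(self):
        X = pd.DataFrame(np.full((5, 4), 3.14))
        res = pca(X, n_components=2)
        np.testing.assert_allclose(res.scores.to_numpy(), 0.0, atol=1e-12)
        np.testing.assert_allclose(res.explained_variance_ratio, 0.0)

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(4)
        res = pca(pd.DataFrame(rng.normal(size=(15, 7))), n_components=5)
        evr = res.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()


class TestCoreGenome:
    @staticmethod
    def _matrix_with_presence(n_present, n_genomes=43):
        col = np.zeros(n_genomes, dtype=int)
        col[:n_present] = 1
        return pd.DataFrame({"grp": col, "anchor": np.ones(n_genomes, int)},
                            index=[f"g{i}" for i in range(n_genomes)])

    def test_present_in_41_of_43_is_core(self):
        assert "grp" in core_genome(self._matrix_with_presence(41), 0.95)

    def test_present_in_40_of_43_is_not_core(self):
        assert "grp" not in core_genome(self._matrix_with_presence(40), 0.95)

    def test_all_ones_everything_core(self):
        m = pd.DataFrame(np.ones((10, 5), dtype=int),
                         columns=[f"og{i}" for i in range(5)])
        assert core_genome(m) == [f"og{i}" for i in range(5)]

    def test_matches_exhaustive_counting(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.integers(0, 3, size=(12, 60)),
                         columns=[f"og{i}" for i in range(60)])
        m.iloc[:, 0] = 1  # avoid an all-zero genome pathology
        for prev in (0.5, 0.75, 0.95, 1.0):
            want = sorted(c for c in m.columns
                          if sum(1 for v in m[c] if v >= 1)
                          >= math.ceil(prev * len(m)))
            assert core_genome(m, prev) == want

    def test_prevalence_monotone(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.integers(0, 2, size=(20, 80)))
        m.iloc[:, 0] = 1
        m.columns = [f"og{i}" for i in range(80)]
        previous = None
        for prev in (0.3, 0.5, 0.7, 0.9, 1.0):
            current = set(core_genome(m, prev))
            if previous is not None:
                assert current <= previous
            previous = current

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            core_genome(pd.DataFrame())


class TestAccumulation:
    def test_identical_genomes(self):
        m = pd.DataFrame(np.ones((6, 9), dtype=int))
        curve = accumulation_curve(m, n_permutations=5, seed=0)
        np.testing.assert_allclose(curve["mean_new"],
                                   [9, 0, 0, 0, 0, 0])

    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.integers(0, 2, size=(5, 30)))
        curve = accumulation_curve(m, exhaustive=True)

        presence = m.to_numpy() >= 1
        sets = [frozenset(np.flatnonzero(row)) for row in presence]
        per_step = np.zeros(5)
        n_perm = 0
        for order in itertools.permutations(range(5)):
            seen: frozenset = frozenset()
            for step, g in enumerate(order):
                per_step[step] += len(sets[g] - seen)
                seen = seen | sets[g]
            n_perm += 1
        np.testing.assert_allclose(curve["mean_new"], per_step / n_perm,
                                   atol=1e-12)

    def test_exhaustive_step1_mean_is_average_genome_size(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.integers(0, 2, size=(5, 40)))
        curve = accumulation_curve(m, exhaustive=True)
        assert curve["mean_new"].iloc[0] == pytest.approx(
            (m.to_numpy() >= 1).sum(axis=1).mean())

    def test_total_new_equals_total_groups_every_permutation(self):
        cfg = SimulationConfig(seed=31)
        cfg.pangenome.n_genomes = 12
        cfg.pangenome.core_size = 30
        cfg.pangenome.shell_size = 60
        cfg.pangenome.cloud_kappa = 20.0
        m, _ = simulate_pangenome(cfg)
        n_groups = int(((m >= 1).any(axis=0)).sum())
        for seed in range(3):
            curve = accumulation_curve(m, n_permutations=1, seed=seed)
            assert curve["mean_new"].sum() == pytest.approx(n_groups)


class TestHeapsFit:
    def test_noiseless_recovery(self):
        g = np.arange(1, 101, dtype=float)
        curve = 1000.0 * g ** -0.9
        fit = fit_heaps(curve)
        assert fit.alpha == pytest.approx(0.9, abs=1e-6)
        assert fit.kappa == pytest.approx(1000.0, rel=1e-6)
        assert fit.openness

    def test_flat_curve_alpha_zero_open(self):
        fit = fit_heaps(np.full(30, 55.0))
        assert abs(fit.alpha) < 1e-6
        assert fit.openness

    def test_scale_equivariance(self):
        g = np.arange(1, 61, dtype=float)
        curve = 300.0 * g ** -0.7
        base = fit_heaps(curve)
        scaled = fit_heaps(10.0 * curve)
        assert scaled.alpha == pytest.approx(base.alpha, abs=1e-8)
        assert scaled.kappa == pytest.approx(10.0 * base.kappa, rel=1e-8)

    def test_closed_pan_genome_detected(self):
        g = np.arange(1, 101, dtype=float)
        fit = fit_heaps(500.0 * g ** -1.6)
        assert not fit.openness

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            fit_heaps(np.array([100.0, 0.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            fit_heaps(np.array([100.0, 5.0]))

    def test_planted_alpha_recovered(self):
        errs = []
        for seed in range(5):
            cfg = SimulationConfig(seed=100 + seed)
            cfg.pangenome.n_genomes = 200
            cfg.pangenome.shell_size = 0
            m, truth = simulate_pangenome(cfg)
            fit = fit_heaps(accumulation_curve(m, permute=False))
            errs.append(abs(fit.alpha - truth["cloud_alpha"]))
        assert np.mean(errs) <= 0.05


class TestBinaryDistance:
    def test_identical_and_disjoint(self):
        m = pd.DataFrame([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
                         index=["a", "b", "c"])
        d = binary_distance(m)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == 1.0
        assert (np.diag(d) == 0).all()

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.integers(0, 4, size=(8, 25)))
        m.iloc[:, 0] = 1
        d = binary_distance(m)
        for i in range(8):
            for j in range(8):
                a = {k for k in range(25) if m.iat[i, k] >= 1}
                b = {k for k in range(25) if m.iat[j, k] >= 1}
                want = 1.0 - len(a & b) / len(a | b)
                assert d.iat[i, j] == pytest.approx(want, abs=1e-12)

    def test_empty_genome_rejected(self):
        m = pd.DataFrame([[1, 1], [0, 0]])
        with pytest.raises(ValueError):
            binary_distance(m)


class TestEmbed2D:
    def test_equilateral_triangle(self):
        D = pd.DataFrame(1.0 - np.eye(3))
        coords = embed_2d(D).to_numpy()
        for i, j in ((0, 1), (0, 2), (1, 2)):
            assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
                1.0, abs=1e-9)

    def test_planar_configuration_recovered(self):
        from scipy.linalg import orthogonal_procrustes
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(12, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords = embed_2d(pd.DataFrame(D)).to_numpy()
        a = pts - pts.mean(axis=0)
        b = coords - coords.mean(axis=0)
        R, _ = orthogonal_procrustes(b, a)
        np.testing.assert_allclose(b @ R, a, atol=1e-6)

    def test_duplicated_rows_coincide(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1], [0, 1, 0]],
                         index=["a", "a2", "b"])
        coords = embed_2d(binary_distance(m))
        np.testing.assert_allclose(coords.loc["a"], coords.loc["a2"],
                                   atol=1e-8)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            embed_2d(pd.DataFrame(D))

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 2))
        D = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)))
        np.testing.assert_array_equal(embed_2d(D).to_numpy(),
                                      embed_2d(D).to_numpy())


class TestKMeansSilhouette:
    @staticmethod
    def _blobs(seed=12, n=20, sep=20.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(n, 2))
        b = rng.normal(size=(n, 2)) + sep
        return pd.DataFrame(np.vstack([a, b]))

    def test_two_planted_blobs(self):
        coords = self._blobs()
        res = kmeans_silhouette(coords, k_range=range(2, 6), seed=0)
        assert res.k == 2
        labels = res.labels.to_numpy()
        assert len(set(labels[:20])) == 1
        assert len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_silhouette_approaches_one_for_separated_blobs(self):
        coords = self._blobs(sep=100.0)
        res = kmeans_silhouette(coords, k_range=[2], seed=0)
        assert res.silhouettes[2] > 0.95

    def test_silhouette_matches_textbook_formula(self):
        coords = self._blobs(seed=13, n=10, sep=5.0)
        res = kmeans_silhouette(coords, k_range=[2, 3], seed=0)
        X = coords.to_numpy()
        labels = res.labels.to_numpy()
        n = len(X)
        dist = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        sils = []
        for i in range(n):
            own = [j for j in range(n) if labels[j] == labels[i] and j != i]
            if not own:
                sils.append(0.0)
                continue
            a_i = np.mean([dist[i, j] for j in own])
            b_i = min(np.mean([dist[i, j] for j in range(n)
                               if labels[j] == lab])
                      for lab in set(labels) if lab != labels[i])
            sils.append((b_i - a_i) / max(a_i, b_i))
        assert res.silhouettes[res.k] == pytest.approx(np.mean(sils),
                                                       abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kmeans_silhouette(pd.DataFrame([[0.0, 0.0], [1.0, 1.0]]), [2])


class TestTransportome:
    def test_single_class(self):
        out = transportome_profile({"a": "SC", "b": "SC"}, {"a"})
        assert out.loc["SC", "genome_share"] == 1.0
        assert out.loc["SC", "detected_share"] == 1.0

    def test_columns_sum_to_one(self):
        ann = {f"g{i}": cls for i, cls in
               enumerate(["AT", "AT", "SC", "SC", "SC", "CP", "EC"])}
        out = transportome_profile(ann, {"g0", "g2", "g3"})
        assert out["genome_share"].sum() == pytest.approx(1.0)
        assert out["detected_share"].sum() == pytest.approx(1.0)

    def test_planted_composition_recovered(self):
        ann = {}
        for i in range(6):
            ann[f"at{i}"] = "AT"
        for i in range(4):
            ann[f"sc{i}"] = "SC"
        out = transportome_profile(ann, {"at0", "at1", "sc0"})
        assert out.loc["AT", "genome_share"] == pytest.approx(0.6)
        assert out.loc["SC", "genome_share"] == pytest.approx(0.4)
        assert out.loc["AT", "detected_share"] == pytest.approx(2 / 3)
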