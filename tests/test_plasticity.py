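"""Genomic plasticity: compositional vectors, distance normalisation, the
exponential 16S-vs-proteome model, and the φ index."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import pearsonr

from metastruct import plasticity, synthfix
from metastruct.plasticity import (
    CompositionalVector,
    bray_curtis,
    count_kmers,
    cv_distance_matrix,
    fit_exponential,
    normalize_distances,
    phi_index,
    reduce_kmers,
    residual_matrix,
)


class TestCountKmers:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["AAAAA"], {"AAAAA": 1}),
            (["AAAAAA"], {"AAAAA": 2}),
            (["MKV"], {}),  # shorter than k
            (["MKVLAX", "MKVLA"], {"MKVLA": 2}),  # X-containing k-mer dropped
        ],
    )
    def test_window_counting(self, seqs, expected):
        assert count_kmers(seqs, k=5).counts == expected

    def test_frequencies_sum_to_one(self):
        vec = count_kmers(["MKVLAMKVLA"], k=5)
        assert sum(vec.normalized.values()) == pytest.approx(1.0)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            count_kmers(["AAAA"], k=0)


def _vector(gid, counts):
    return CompositionalVector(gid, counts)


class TestReduceKmers:
    def test_single_varying_kmer_ranks_first(self):
        vectors = [
            _vector(f"g{i}", {"AAAAA": 10, "CCCCC": 1 + 5 * i}) for i in range(6)
        ]
        red = reduce_kmers(vectors, n_sample=6, n_keep=2, seed=0)
        assert red.selected_kmers[0] == "CCCCC"

    def test_identical_vectors_fall_back_to_lexicographic(self, caplog):
        vectors = [_vector(f"g{i}", {"CCCCC": 2, "AAAAA": 1}) for i in range(4)]
        red = reduce_kmers(vectors, n_sample=4, n_keep=2, seed=0)
        assert red.selected_kmers == ["AAAAA", "CCCCC"]
        assert red.n_components == 0

    def test_planted_high_variance_kmers_recovered(self):
        rng = np.random.default_rng(7)
        planted = [f"PLNT{c}" for c in "ACDEFGHIKL"]
        background = [f"BKGD{c}" for c in "ACDEFGHIKLMNPQRSTVW"]
        vectors = []
        for i in range(50):
            counts = {k: 50 for k in background}
            for k in planted:
                counts[k] = int(rng.integers(0, 500))
            vectors.append(_vector(f"g{i}", counts))
        red = reduce_kmers(vectors, n_sample=50, n_keep=20, seed=1)
        assert set(planted) <= set(red.selected_kmers[:20])

    def test_n_sample_larger_than_population_rejected(self):
        with pytest.raises(ValueError):
            reduce_kmers([_vector("g", {"AAAAA": 1})], n_sample=2)


class TestBrayCurtis:
    def test_identical_vectors_distance_zero(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        assert bray_curtis([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_computed_half(self):
        assert bray_curtis([0.5, 0.5, 0], [0.5, 0, 0.5]) == pytest.approx(0.5)

    def test_all_zero_pair_fatal(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(0, 100), min_size=2, max_size=10),
        st.data(),
    )
    def test_symmetric_and_bounded(self, x, data):
        y = data.draw(
            st.lists(st.floats(0, 100), min_size=len(x), max_size=len(x))
        )
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x))
        assert -1e-12 <= d <= 1 + 1e-12

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(8), rng.random(8)
            assert bray_curtis(x, y) == pytest.approx(scipy_braycurtis(x, y))


class TestNormalizeDistances:
    def test_three_values_map_to_0_half_1(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        out = normalize_distances(d)
        iu = np.triu_indices(3, 1)
        assert sorted(out[iu]) == pytest.approx([0, 0.5, 1])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        d = rng.random((8, 8))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        iu = np.triu_indices(8, 1)
        out = normalize_distances(d)
        assert list(np.argsort(d[iu])) == list(np.argsort(out[iu]))

    def test_single_pair_fatal(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize_distances(np.array([[0.0, 0.5], [0.5, 0.0]]))


class TestFitExponential:
    A, B = 5e-6, 12.523

    def _matrices(self, n=15, noise=None, seed=0, a=None, b=None):
        a = self.A if a is None else a
        b = self.B if b is None else b
        rng = np.random.default_rng(seed)
        dcv = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        dcv[iu] = rng.uniform(0, 1, size=len(iu[0]))
        dcv = dcv + dcv.T
        d16 = a * np.exp(b * dcv)
        np.fill_diagonal(d16, 0)
        if noise is not None:
            d16[iu] *= rng.lognormal(0, noise, size=len(iu[0]))
            d16 = np.triu(d16, 1) + np.triu(d16, 1).T
        return dcv, d16

    def test_exact_data_recovers_coefficients_within_one_percent(self):
        dcv, d16 = self._matrices()
        model = fit_exponential(dcv, d16, seed=0)
        assert model.a == pytest.approx(self.A, rel=0.01)
        assert model.b == pytest.approx(self.B, rel=0.01)
        assert model.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_flat_data_gives_mean_and_zero_rate(self):
        x = np.linspace(0, 1, 50)
        y = np.full(50, 0.3)
        model = fit_exponential(x, y, seed=0)
        assert model.a == pytest.approx(0.3, rel=1e-4)
        assert model.b == pytest.approx(0.0, abs=1e-4)

    def test_noisy_data_recovers_within_ten_percent(self):
        # gentler truth curve: with a 6-decade dynamic range the prefactor
        # is an extrapolation and absolute-scale least squares cannot pin it
        dcv, d16 = self._matrices(n=20, noise=0.1, seed=5, a=0.01, b=3.0)
        model = fit_exponential(dcv, d16, seed=0)
        assert model.a == pytest.approx(0.01, rel=0.1)
        assert model.b == pytest.approx(3.0, rel=0.1)
        assert model.r_squared < 1.0

    def test_all_zero_observations_fatal(self):
        with pytest.raises(ValueError):
            fit_exponential(np.linspace(0, 1, 10), np.zeros(10))


class TestResidualMatrix:
    def test_on_curve_points_have_zero_residual_and_symmetry(self):
        dcv = np.array([[0, 0.2, 0.4], [0.2, 0, 0.6], [0.4, 0.6, 0]])
        d16 = 0.01 * np.exp(3.0 * dcv)
        np.fill_diagonal(d16, 0)
        model = fit_exponential(dcv, d16, seed=0)
        res = residual_matrix(model)
        iu = np.triu_indices(3, 1)
        assert np.allclose(res[iu], 0, atol=1e-8)
        assert np.allclose(res, res.T)
        # self-comparison evaluates to the prefactor a
        assert np.allclose(np.diag(res), model.a)

    def test_observed_below_curve_gives_positive_residual(self):
        dcv = np.array([[0, 0.5], [0.5, 0]])
        model = plasticity.DistanceModel(
            a=0.01, b=3.0, r_squared=1.0,
            d16_matrix=0.5 * 0.01 * np.exp(3.0 * dcv) * (1 - np.eye(2)),
            dcv_matrix=dcv,
        )
        res = residual_matrix(model)
        assert res[0, 1] > 0


class TestPhiIndex:
    def test_hand_minmax_of_row_means(self):
        # row means 0.1, 0.2, 0.4 -> phi 0, 1/3, 1
        res = np.array(
            [[9, 0.1, 0.1], [0.1, 9, 0.3], [0.3, 0.5, 9]]
        )
        phi = phi_index(res, ["a", "b", "c"])
        assert phi.phi["a"] == pytest.approx(0.0)
        assert phi.phi["b"] == pytest.approx(1 / 3)
        assert phi.phi["c"] == pytest.approx(1.0)

    def test_permuting_genomes_permutes_phi(self):
        rng = np.random.default_rng(1)
        res = rng.random((5, 5))
        ids = list("abcde")
        phi = phi_index(res, ids)
        perm = [3, 1, 4, 0, 2]
        phi_p = phi_index(res[np.ix_(perm, perm)], [ids[i] for i in perm])
        for name in ids:
            assert phi.phi[name] == pytest.approx(phi_p.phi[name])

    def test_identical_row_means_fatal(self):
        res = np.array([[0.5, 0.2], [0.2, 0.5]])  # symmetric 2x2: equal means
        with pytest.raises(ValueError, match="identical row means"):
            phi_index(res, ["a", "b"])

    def test_single_genome_fatal(self):
        with pytest.raises(ValueError):
            phi_index(np.array([[0.0]]), ["a"])


class TestPipeline:
    def test_phi_spans_unit_interval(self, small_sim):
        _, _, genomes, _ = small_sim
        phi, model, _ = plasticity.compute_plasticity(genomes, seed=0)
        values = list(phi.phi.values())
        assert min(values) == pytest.approx(0.0)
        assert max(values) == pytest.approx(1.0)

    def test_full_and_reduced_distances_agree(self, small_sim):
        """Reduced vectors keeping most variance reproduce full-vector
        Bray-Curtis structure (Pearson r > 0.9)."""
        _, _, genomes, _ = small_sim
        vectors = [
            plasticity.count_kmers(g.proteome, genome_id=g.genome_id)
            for g in genomes
        ]
        red = reduce_kmers(
            vectors, n_sample=len(vectors), variance_target=0.95,
            n_keep=len(vectors[0].counts) * 5, seed=0,
        )
        _, full = cv_distance_matrix(vectors)
        _, part = cv_distance_matrix(vectors, red.selected_kmers)
        iu = np.triu_indices(len(vectors), 1)
        r = pearsonr(full[iu], part[iu]).statistic
        assert r > 0.9
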