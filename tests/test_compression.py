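import numpy as np
import pytest
from scipy import stats

from pana.compression import (CompressionParams, build_plm, fit_gamma_cutoff,
                              select_components, variance_cutoff,
                              _centered_samples_by_genes, _eigenvalues,
                              _final_pca)
from pana.io import ExpressionMatrix, PathwayAnnotation
from pana.simulate import SimulationDesign, sep_profile, simulate


class TestGammaCutoff:
    def test_recovers_closed_form_quantile(self):
        """Fitted-gamma quantile vs the true quantile of a gamma sample."""
        rng = np.random.default_rng(5)
        v = rng.gamma(2.0, 1.0, 10_000)
        truth = stats.gamma.ppf(0.95, 2.0, scale=1.0)  # 4.7439
        for method in ("mle", "moments"):
            cut = fit_gamma_cutoff(v, 0.05, method)
            assert abs(cut - truth) / truth < 0.05, (method, cut)

    def test_median_at_alpha_half(self):
        rng = np.random.default_rng(6)
        v = rng.gamma(3.0, 2.0, 5000)
        cut = fit_gamma_cutoff(v, 0.5, "mle")
        shape, _, scale = stats.gamma.fit(v, floc=0)
        assert cut == pytest.approx(stats.gamma.ppf(0.5, shape, scale=scale))

    def test_smaller_alpha_larger_cutoff(self):
        rng = np.random.default_rng(7)
        v = rng.gamma(2.0, 1.0, 2000)
        cuts = [fit_gamma_cutoff(v, a, "mle") for a in (0.05, 0.01, 0.001)]
        assert cuts[0] < cuts[1] < cuts[2]

    def test_constant_matrix_is_degenerate(self):
        m = ExpressionMatrix(["a", "b"], ["s1", "s2", "s3"], np.ones((2, 3)))
        with pytest.raises(ValueError, match="degenerate gamma"):
            variance_cutoff(m, 0.05, np.random.default_rng(0))


class TestSelectComponents:
    def test_planted_rank_one_always_selected(self):
        d = SimulationDesign(gene_counts=(100,), profile_types=(5,),
                             inner_correlations=(1.0,), noise_s=0.001, seed=2)
        ds = simulate(d)
        sub = ds.matrix.submatrix(ds.annotation[next(iter(ds.annotation))])
        params = CompressionParams(alpha=0.05, n_boot=25, seed=2)
        h, freqs = select_components(sub, params, ds.matrix)
        assert h >= 1
        assert freqs[1] == 1.0

    def test_pure_noise_pathway_not_selected(self):
        """In a genome with real signal, a noise-only block yields h_f = 0."""
        zeros = 0
        for seed in range(10):
            d = SimulationDesign(gene_counts=(10, 100), profile_types=(1,),
                                 inner_correlations=(0.0, 0.8),
                                 noise_s=0.01, seed=seed)
            ds = simulate(d)
            noise_pid = next(p for p, (k, rho, g) in ds.truth.items()
                             if rho == 0.0 and g == 10)
            sub = ds.matrix.submatrix(ds.annotation[noise_pid])
            params = CompressionParams(alpha=0.05, n_boot=20, seed=seed)
            h, _ = select_components(sub, params, ds.matrix)
            zeros += (h == 0)
        assert zeros >= 9

    def test_single_repetition_frequencies_binary(self):
        d = SimulationDesign(gene_counts=(30,), profile_types=(2,),
                             inner_correlations=(0.8,), seed=3)
        ds = simulate(d)
        sub = ds.matrix.submatrix(ds.annotation[next(iter(ds.annotation))])
        params = CompressionParams(alpha=0.05, n_boot=1, seed=3)
        _, freqs = select_components(sub, params, ds.matrix)
        assert set(freqs.values()) <= {0.0, 1.0}

    def test_tiny_pathway_yields_zero(self):
        d = SimulationDesign(gene_counts=(10,), profile_types=(1,),
                             inner_correlations=(0.5,), seed=4)
        ds = simulate(d)
        params = CompressionParams(n_boot=5, seed=4)
        h, freqs = select_components(ds.matrix.values[:1], params, ds.matrix)
        assert h == 0 and freqs == {}


class TestBuildPlm:
    def test_pca_reconstruction_identity(self):
        rng = np.random.default_rng(8)
        sub = rng.standard_normal((7, 12))  # 7 genes x 12 samples
        h = 7
        scores, loadings, _ = _final_pca(sub, h)
        recon = scores @ loadings.T
        assert np.allclose(recon, _centered_samples_by_genes(sub), atol=1e-8)

    def test_eigenvalue_conservation(self):
        rng = np.random.default_rng(9)
        sub = rng.standard_normal((20, 15))
        w = _eigenvalues(sub)
        total = _centered_samples_by_genes(sub).var(axis=0, ddof=1).sum()
        assert w.sum() == pytest.approx(total, abs=1e-8)

    def test_profile_invariants(self, small_profile_set):
        ps = small_profile_set
        assert len(ps) > 0
        for p in ps.profiles:
            assert abs(p.scores.mean()) < 1e-8
            assert np.linalg.norm(p.loadings) == pytest.approx(1.0)
            # sign convention: dominant loading positive
            assert p.loadings[np.argmax(np.abs(p.loadings))] > 0

    def test_multi_component_pathway_scores_orthogonal(self):
        """A block with two planted patterns yields two orthogonal profiles."""
        rng = np.random.default_rng(10)
        m = 36
        block = np.vstack([
            np.tile(sep_profile(1, m), (20, 1)),
            np.tile(sep_profile(6, m), (20, 1)),
            np.zeros((160, m)),
        ]) + rng.normal(0, 0.1, (200, m))
        genes = [f"g{i}" for i in range(200)]
        matrix = ExpressionMatrix(genes, [f"s{j}" for j in range(m)], block)
        ann = PathwayAnnotation({"two_signals": set(genes[:40])})
        ps = build_plm(matrix, ann, CompressionParams(alpha=0.05, n_boot=30,
                                                      seed=10))
        assert len(ps) == 2
        s1, s2 = ps.profiles[0].scores, ps.profiles[1].scores
        assert abs(np.dot(s1, s2)) < 1e-8
        assert ps.profiles[0].eigenvalue > ps.profiles[1].eigenvalue

    def test_pathway_order_does_not_change_profiles(self, small_dataset):
        ds = small_dataset
        params = CompressionParams(alpha=0.05, n_boot=10, seed=11)
        fwd = build_plm(ds.matrix, ds.annotation, params)
        rev_ann = PathwayAnnotation(
            dict(reversed(list(ds.annotation.pathways.items()))))
        rev = build_plm(ds.matrix, rev_ann, params)
        a = {p.profile_id: p.scores for p in fwd.profiles}
        b = {p.profile_id: p.scores for p in rev.profiles}
        assert a.keys() == b.keys()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_unannotated_genes_ignored(self, small_dataset):
        ds = small_dataset
        ann = PathwayAnnotation({
            pid: set(g) | {"ghost_gene"}
            for pid, g in list(ds.annotation.pathways.items())[:5]})
        ps = build_plm(ds.matrix, ann, CompressionParams(n_boot=5, seed=1))
        for p in ps.profiles:
            assert "ghost_gene" not in p.gene_ids

    def test_empty_plm_raises(self):
        d = SimulationDesign(gene_counts=(2,), profile_types=(1, 2, 3),
                             inner_correlations=(0.0,), noise_s=0.01, seed=12)
        ds = simulate(d)
        with pytest.raises(ValueError, match="empty PLM"):
            build_plm(ds.matrix, ds.annotation,
                      CompressionParams(alpha=0.001, n_boot=20, seed=12))

    def test_plm_roundtrip(self, small_profile_set, tmp_path):
        from pana.compression import read_plm
        p = tmp_path / "plm.tsv"
        small_profile_set.write_plm(p)
        again = read_plm(p)
        assert again.profile_ids == small_profile_set.profile_ids
        assert np.allclose(again.plm, small_profile_set.plm)
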