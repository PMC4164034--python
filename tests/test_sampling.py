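import numpy as np
import pytest
from scipy import stats

from anatomap.geometry import make_sheet, offset_layer
from anatomap.kernels import KernelSpec
from anatomap.layers import place_neurons
from anatomap.mapping import MappingChain, MappingStep
from anatomap.sampling import (
    SamplerConfig,
    build_bin_grid,
    project_populations,
    sample_exact,
    sample_fast,
)


def make_chain(n_pre, n_post, kernel_pre, kernel_post, n_syn, seed=0, name="chain"):
    """Pre sheet below, post sheet above, synaptic layer between."""
    sl = make_sheet(1, 1, 8, 8, "sl")
    pre_l = offset_layer(sl, -0.5, "pre_l")
    post_l = offset_layer(sl, 0.5, "post_l")
    layers = {l.name: l for l in (sl, pre_l, post_l)}
    pre = place_neurons(pre_l, n_pre, seed=seed)
    post = place_neurons(post_l, n_post, seed=seed + 1)
    return MappingChain(
        name, layers, pre, post,
        [MappingStep("sl", "normal")], [MappingStep("sl", "normal")],
        kernel_pre=kernel_pre, kernel_post=kernel_post, n_synapses_per_pre=n_syn,
    )


def joint_counts(conn, n_post, n_bins):
    key = (conn.pre_id * n_post + conn.post_id) * n_bins + conn.bin_index
    return np.bincount(key, minlength=conn.n_pre * n_post * n_bins)


class TestProjection:
    def test_identity_like_chain_preserves_positions(self):
        chain = make_chain(10, 10, KernelSpec(), KernelSpec(), 1)
        proj = project_populations(chain, np.random.default_rng(0))
        # normal projection of parallel sheets preserves the chart position
        assert np.allclose(proj.pre_entry_uv, chain.pre_population.uv, atol=1e-9)
        assert proj.pre_alive.all() and proj.post_alive.all()

    def test_deterministic_given_seed(self):
        chain = make_chain(5, 5, KernelSpec(), KernelSpec(), 3)
        a = project_populations(chain, np.random.default_rng(3))
        b = project_populations(chain, np.random.default_rng(3))
        assert np.array_equal(a.pre_entry_uv, b.pre_entry_uv)


class TestBinGrid:
    def test_zero_threshold_registers_everywhere_positive(self):
        chain = make_chain(1, 4, KernelSpec(), KernelSpec(sigma=(0.2, 0.2)), 1)
        proj = project_populations(chain, np.random.default_rng(0))
        grid = build_bin_grid(
            chain.synaptic_layer, proj.post_entry_uv, chain.kernel_post,
            SamplerConfig(cu=8, cv=8, p0=0.0),
        )
        assert (grid.weights > 0).all()  # Gaussian is positive everywhere

    def test_threshold_near_one_keeps_only_peak_bins(self):
        chain = make_chain(1, 4, KernelSpec(), KernelSpec(sigma=(0.2, 0.2)), 1)
        proj = project_populations(chain, np.random.default_rng(0))
        grid = build_bin_grid(
            chain.synaptic_layer, proj.post_entry_uv, chain.kernel_post,
            SamplerConfig(cu=8, cv=8, p0=0.999999),
        )
        assert ((grid.weights > 0).sum(axis=0) == 1).all()

    def test_stored_weights_equal_direct_evaluation(self):
        from anatomap.kernels import evaluate_kernel

        chain = make_chain(1, 6, KernelSpec(), KernelSpec(sigma=(0.3, 0.2)), 1)
        proj = project_populations(chain, np.random.default_rng(0))
        cfg = SamplerConfig(cu=8, cv=8, p0=0.0)
        grid = build_bin_grid(chain.synaptic_layer, proj.post_entry_uv,
                              chain.kernel_post, cfg)
        centers = grid.bin_centers()
        for j in range(6):
            w = evaluate_kernel(chain.kernel_post, centers, proj.post_entry_uv[j])
            assert np.allclose(grid.weights[:, j], w)

    def test_raising_p0_shrinks_candidate_lists_monotonically(self):
        chain = make_chain(1, 8, KernelSpec(), KernelSpec(sigma=(0.15, 0.15)), 1)
        proj = project_populations(chain, np.random.default_rng(0))
        sizes = []
        for p0 in (0.0, 0.01, 0.1, 0.5):
            grid = build_bin_grid(
                chain.synaptic_layer, proj.post_entry_uv, chain.kernel_post,
                SamplerConfig(cu=8, cv=8, p0=p0),
            )
            sizes.append((grid.weights > 0).sum())
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestExactSampler:
    def test_concentrated_kernels_hit_single_shared_bin(self):
        k = KernelSpec(sigma=(0.01, 0.01))
        chain = make_chain(1, 1, k, k, 200, seed=4)
        conn = sample_exact(chain, SamplerConfig(cu=4, cv=4, seed=1))
        # pre and post enter at different chart points; the product mass
        # concentrates between them, but with sigma much smaller than a bin
        # all draws land in one bin and on the single post neuron
        assert len(np.unique(conn.bin_index)) == 1
        assert (conn.post_id == 0).all()

    def test_symmetric_posts_split_evenly(self):
        sl = make_sheet(1, 1, 8, 8, "sl")
        pre_l = offset_layer(sl, -0.5, "pre_l")
        post_l = offset_layer(sl, 0.5, "post_l")
        layers = {l.name: l for l in (sl, pre_l, post_l)}
        from anatomap.layers import NeuronPopulation, points_from_uv

        def pop_at(layer, uvs):
            tri, bary, ok = points_from_uv(layer, np.asarray(uvs, float))
            assert ok.all()
            return NeuronPopulation(
                layer=layer.name, size=len(tri), tri_index=tri, bary=bary,
                xyz=layer.bary_to_xyz(tri, bary), uv=layer.bary_to_uv(tri, bary),
            )

        pre = pop_at(pre_l, [[0.5, 0.5]])
        post = pop_at(post_l, [[0.25, 0.5], [0.75, 0.5]])  # symmetric about pre
        chain = MappingChain(
            "sym", layers, pre, post,
            [MappingStep("sl", "normal")], [MappingStep("sl", "normal")],
            kernel_pre=KernelSpec(sigma=(0.2, 0.2)),
            kernel_post=KernelSpec(sigma=(0.2, 0.2)),
            n_synapses_per_pre=10_000,
        )
        conn = sample_exact(chain, SamplerConfig(cu=16, cv=16, seed=2))
        n1 = int((conn.post_id == 1).sum())
        assert abs(n1 - 5000) < 4 * np.sqrt(10_000 * 0.25)

    def test_disjoint_supports_yield_zero_synapses(self):
        pre_k = KernelSpec(mu=(-0.4, 0.0), sigma=(0.03, 0.03))
        post_k = KernelSpec(mu=(0.4, 0.0), sigma=(0.03, 0.03))

        # boxcar-truncate both kernels so the product genuinely vanishes
        from anatomap.kernels import register_kernel

        def trunc(delta, params):
            mu = np.asarray(params["mu"])
            d = delta - mu
            w = np.exp(-(d**2).sum(axis=1) / (2 * 0.03**2))
            w[np.abs(d).max(axis=1) > 0.2] = 0.0
            return w

        register_kernel("trunc_gauss_test", trunc)
        sl = make_sheet(1, 1, 8, 8, "sl")
        pre_l = offset_layer(sl, -0.5, "pre_l")
        post_l = offset_layer(sl, 0.5, "post_l")
        layers = {l.name: l for l in (sl, pre_l, post_l)}
        from anatomap.layers import NeuronPopulation, points_from_uv

        def pop_at(layer, uvs):
            tri, bary, ok = points_from_uv(layer, np.asarray(uvs, float))
            return NeuronPopulation(
                layer=layer.name, size=len(tri), tri_index=tri, bary=bary,
                xyz=layer.bary_to_xyz(tri, bary), uv=layer.bary_to_uv(tri, bary),
            )

        chain = MappingChain(
            "disjoint", layers,
            pop_at(pre_l, [[0.5, 0.5]]), pop_at(post_l, [[0.5, 0.5]]),
            [MappingStep("sl", "normal")], [MappingStep("sl", "normal")],
            kernel_pre=KernelSpec("trunc_gauss_test", mu=(-0.4, 0.0), sigma=(0.03, 0.03)),
            kernel_post=KernelSpec("trunc_gauss_test", mu=(0.4, 0.0), sigma=(0.03, 0.03)),
            n_synapses_per_pre=50,
        )
        conn = sample_exact(chain, SamplerConfig(cu=16, cv=16, seed=3))
        assert len(conn) == 0


class TestFastSampler:
    def test_single_bin_pre_kernel_confines_synapses(self):
        pre_k = KernelSpec(sigma=(0.01, 0.01))  # far below one 4x4 bin
        chain = make_chain(1, 5, pre_k, KernelSpec(sigma=(0.5, 0.5)), 300, seed=7)
        conn = sample_fast(chain, SamplerConfig(cu=4, cv=4, p0=0, p1=0, seed=4))
        assert len(np.unique(conn.bin_index)) == 1

    def test_matches_exact_joint_at_zero_thresholds(self):
        """Accelerated and reference samplers draw from the same joint."""
        k = KernelSpec(sigma=(0.15, 0.15))
        chain = make_chain(5, 7, k, k, 4000, seed=2)
        cfg = lambda s: SamplerConfig(cu=16, cv=16, p0=0.0, p1=0.0, seed=s)
        je = joint_counts(sample_exact(chain, cfg(5)), 7, 256)
        jf = joint_counts(sample_fast(chain, cfg(6)), 7, 256)
        mask = (je + jf) >= 10
        k1 = np.sqrt(jf.sum() / je.sum())
        chi2 = ((k1 * je[mask] - jf[mask] / k1) ** 2 / (je[mask] + jf[mask])).sum()
        assert stats.chi2.sf(chi2, mask.sum() - 1) > 0.01

    def test_record_count_and_budget(self):
        k = KernelSpec(sigma=(0.2, 0.2))
        chain = make_chain(6, 4, k, k, 25, seed=8)
        conn = sample_fast(chain, SamplerConfig(cu=8, cv=8, seed=5))
        assert len(conn) == 6 * 25
        assert conn.fill_fraction == pytest.approx(150 / 24)

    def test_bit_identical_under_fixed_seed(self):
        k = KernelSpec(sigma=(0.2, 0.2))
        chain = make_chain(4, 4, k, k, 50, seed=9)
        a = sample_fast(chain, SamplerConfig(seed=11))
        b = sample_fast(chain, SamplerConfig(seed=11))
        for f in ("pre_id", "post_id", "bin_index", "syn_uv"):
            assert np.array_equal(getattr(a, f), getattr(b, f))

    def test_per_post_budget_swaps_roles(self):
        k = KernelSpec(sigma=(0.2, 0.2))
        chain = make_chain(3, 5, k, k, 40, seed=10)
        conn = sample_fast(chain, SamplerConfig(seed=12, per_post=True))
        assert len(conn) == 5 * 40
        counts = np.bincount(conn.post_id, minlength=5)
        assert (counts == 40).all()
        assert conn.n_pre == 3 and conn.n_post == 5

    def test_edge_marginal_matches_analytic_product_on_coarse_grid(self):
        """With one bin, the edge distribution is exactly the kernel product."""
        k_pre = KernelSpec(sigma=(0.3, 0.3))
        k_post = KernelSpec(sigma=(0.3, 0.3))
        chain = make_chain(1, 3, k_pre, k_post, 30_000, seed=13)
        cfg = SamplerConfig(cu=1, cv=1, p0=0, p1=0, seed=14)
        rng = np.random.default_rng(cfg.seed)
        proj = project_populations(chain, rng)
        conn = sample_fast(chain, cfg, rng, proj=proj)
        from anatomap.kernels import evaluate_kernel

        center = np.array([[0.5, 0.5]])
        w = np.array(
            [evaluate_kernel(k_post, center, proj.post_entry_uv[j])[0] for j in range(3)]
        )
        p = w / w.sum()
        counts = np.bincount(conn.post_id, minlength=3)
        chi2 = ((counts - p * len(conn)) ** 2 / (p * len(conn))).sum()
        assert stats.chi2.sf(chi2, 2) > 0.01
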