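import numpy as np
import pytest

from knockloc import simulate as sim
from knockloc.filtering import select
from knockloc.partition import Partition


@pytest.fixture(scope="module")
def variants():
    model = sim.synthetic_hmm(seed=0)
    return sim.variant_table(model)


class TestCausalPlacement:
    def test_default_architecture(self, variants):
        spec = sim.place_causal_clusters(variants, seed=1)
        assert spec.causal_idx.size == 30  # 6 clusters of 5
        assert np.unique(spec.cluster_of).size == 6
        pos = variants["pos"].to_numpy()
        for c in np.unique(spec.cluster_of):
            cpos = pos[spec.causal_idx[spec.cluster_of == c]]
            assert cpos.max() - cpos.min() < 100_000

    def test_effect_ratio_exact(self, variants):
        spec = sim.place_causal_clusters(variants, seed=2)
        mags = np.abs(spec.beta)
        assert mags.min() / mags.max() == pytest.approx(1.0 / 19.0, rel=1e-12)

    def test_unit_ratio_gives_equal_magnitudes(self, variants):
        spec = sim.place_causal_clusters(variants, effect_ratio=1.0, seed=3)
        assert np.allclose(np.abs(spec.beta), np.abs(spec.beta)[0])

    def test_empty_window_skipped_with_warning(self):
        import pandas as pd

        vt = pd.DataFrame({"pos": np.r_[np.arange(1, 51), 10_000_000]})
        with pytest.warns(UserWarning, match="no variants"):
            spec = sim.place_causal_clusters(
                vt, n_clusters=4, cluster_size=2, cluster_width_bp=100, seed=4
            )
        assert np.unique(spec.cluster_of).size < 4


class TestGaussianTrait:
    def test_zero_heritability_is_pure_noise(self, variants):
        model = sim.synthetic_hmm(seed=5)
        _, X = sim.simulate_genotypes(model, 3000, seed=6)
        spec = sim.place_causal_clusters(variants, seed=7, h2_causal=0.0)
        y = sim.simulate_gaussian_trait(X, spec, seed=8)
        cors = [
            abs(np.corrcoef(X[:, j], y)[0, 1]) for j in spec.causal_idx[:10]
        ]
        assert max(cors) < 0.06

    def test_realized_heritability_pinned(self, variants):
        model = sim.synthetic_hmm(seed=9)
        _, X = sim.simulate_genotypes(model, 5000, seed=10)
        spec = sim.place_causal_clusters(variants, seed=11, h2_causal=0.5)
        y = sim.simulate_gaussian_trait(X, spec, seed=12)
        g = sim._genetic_value(X, spec)
        assert g.var() / y.var() == pytest.approx(0.5, abs=0.02)

    def test_seeded_reproducibility(self, variants):
        model = sim.synthetic_hmm(seed=13)
        _, X = sim.simulate_genotypes(model, 500, seed=14)
        spec = sim.place_causal_clusters(variants, seed=15)
        y1 = sim.simulate_gaussian_trait(X, spec, seed=16)
        y2 = sim.simulate_gaussian_trait(X, spec, seed=16)
        assert np.array_equal(y1, y2)

    def test_invalid_heritability(self, variants):
        spec = sim.place_causal_clusters(variants, seed=17, h2_causal=1.5)
        with pytest.raises(ValueError):
            sim.simulate_gaussian_trait(np.zeros((10, 600)), spec, seed=18)


class TestProbitTrait:
    def test_case_fraction_tracks_threshold(self, variants):
        model = sim.synthetic_hmm(seed=19)
        _, X = sim.simulate_genotypes(model, 4000, seed=20)
        spec = sim.place_causal_clusters(variants, seed=21, family="probit")
        y, frac = sim.simulate_probit_trait(X, spec, 0.5, threshold=1.0, seed=22)
        from scipy.stats import norm

        assert frac == pytest.approx(norm.sf(1.0), abs=0.03)
        assert set(np.unique(y)) == {0.0, 1.0}

    def test_rare_case_regime(self, variants):
        # strong imbalance (~2% cases), the regime where marginal methods
        # struggle but the construction still yields both classes
        model = sim.synthetic_hmm(seed=23)
        _, X = sim.simulate_genotypes(model, 4000, seed=24)
        spec = sim.place_causal_clusters(variants, seed=25, family="probit")
        y, frac = sim.simulate_probit_trait(X, spec, 0.5, threshold=2.0, seed=26)
        assert 0.005 < frac < 0.06

    def test_degenerate_draw_raises(self, variants):
        model = sim.synthetic_hmm(seed=27)
        _, X = sim.simulate_genotypes(model, 50, seed=28)
        spec = sim.place_causal_clusters(variants, seed=29, family="probit")
        with pytest.raises(ValueError, match="threshold"):
            sim.simulate_probit_trait(X, spec, 0.5, threshold=10.0, seed=30)

    def test_zero_latent_heritability_independent_of_genotypes(self, variants):
        model = sim.synthetic_hmm(seed=31)
        _, X = sim.simulate_genotypes(model, 4000, seed=32)
        spec = sim.place_causal_clusters(variants, seed=33, family="probit")
        y, _ = sim.simulate_probit_trait(X, spec, 0.0, threshold=0.5, seed=34)
        cors = [abs(np.corrcoef(X[:, j], y)[0, 1]) for j in spec.causal_idx[:10]]
        assert max(cors) < 0.06


def _discovery_set(groups, positions, W, tau):
    part = Partition(np.asarray(groups), positions, 0.0)
    return select(np.asarray(W, dtype=float), tau, part, q=0.1,
                  with_local_fdr=False)


class TestScoring:
    def test_empty_discoveries(self, variants):
        spec = sim.place_causal_clusters(variants, seed=35)
        pos = variants["pos"].to_numpy()
        ds = _discovery_set(np.arange(1, 601), pos, [-1.0] * 600, np.inf)
        fdp, nt, nf = sim.evaluate_discoveries(ds, spec)
        assert (fdp, nt, nf) == (0.0, 0, 0)
        assert sim.evaluate_locus_detection(ds, spec) == 0.0

    def test_exact_causal_singleton_is_true(self, variants):
        spec = sim.place_causal_clusters(variants, seed=36)
        pos = variants["pos"].to_numpy()
        W = np.full(600, -1.0)
        W[spec.causal_idx[0]] = 5.0
        ds = _discovery_set(np.arange(1, 601), pos, W, 5.0)
        fdp, nt, nf = sim.evaluate_discoveries(ds, spec)
        assert (fdp, nt, nf) == (0.0, 1, 0)

    def test_fdp_matches_brute_force_set_intersection(self, variants):
        pos = variants["pos"].to_numpy()
        rng = np.random.default_rng(37)
        spec = sim.place_causal_clusters(variants, seed=38)
        causal = set(spec.causal_idx.tolist())
        for _ in range(20):
            groups = np.repeat(np.arange(1, 61), 10)
            W = rng.standard_normal(60)
            tau = 0.5
            ds = _discovery_set(groups, pos, W, tau)
            fdp, nt, nf = sim.evaluate_discoveries(ds, spec)
            truth = [
                bool(causal & set(range(int(r.first_idx), int(r.last_idx) + 1)))
                for _, r in ds.table.iterrows()
            ]
            assert nt == sum(truth) and nf == len(truth) - sum(truth)
            assert fdp == pytest.approx(nf / max(1, len(truth)))

    def test_locus_detection_margin_arithmetic(self):
        import pandas as pd

        vt = pd.DataFrame({"pos": np.arange(1, 201) * 1000})
        spec = sim.place_causal_clusters(
            vt, n_clusters=1, cluster_size=1, cluster_width_bp=1000, seed=39
        )
        causal_pos = vt["pos"].to_numpy()[spec.causal_idx[0]]
        # a discovery 50 kb away from the causal variant
        far_idx = spec.causal_idx[0] + 50
        groups = np.arange(1, 201)
        W = np.full(200, -1.0)
        W[far_idx] = 3.0
        ds = _discovery_set(groups, vt["pos"].to_numpy(), W, 3.0)
        assert sim.evaluate_locus_detection(ds, spec, margin_bp=100_000) == 1.0
        assert sim.evaluate_locus_detection(ds, spec, margin_bp=10_000) == 0.0
        # a discovery covering the causal variant is detected at margin 0
        W2 = np.full(200, -1.0)
        W2[spec.causal_idx[0]] = 3.0
        ds2 = _discovery_set(groups, vt["pos"].to_numpy(), W2, 3.0)
        assert sim.evaluate_locus_detection(ds2, spec, margin_bp=0) == 1.0


class TestSyntheticModel:
    def test_model_satisfies_invariants(self):
        model = sim.synthetic_hmm(p=50, K=4, seed=40)
        assert model.p == 50 and model.K == 4
        assert np.allclose(model.alpha.sum(axis=1), 1.0)
        assert model.r[0] == 1.0

    def test_genotypes_are_allele_counts(self):
        model = sim.synthetic_hmm(p=20, K=3, seed=41)
        H, X = sim.simulate_genotypes(model, 50, seed=42)
        assert H.shape == (100, 20) and X.shape == (50, 20)
        assert np.array_equal(X, H[0::2] + H[1::2])
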