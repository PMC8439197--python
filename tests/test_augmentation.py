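"""Perturbation sampling, parameter shifting, Mahalanobis-preserving
reconstruction and the end-to-end augmentation pipeline."""

import numpy as np
import pytest

import gmmda.augmentation as aug_module
from gmmda import (
    GmmdaError,
    MixtureParams,
    PerturbationSample,
    PhantomSpec,
    generate_phantom,
    VARIANCE_FLOOR,
    VariationRanges,
    augment,
    augmenting_iterator,
    class_map,
    default_ranges,
    dice,
    fit_gmm,
    mahalanobis_distances,
    perturb_params,
    posteriors,
    prepare_for_gmm,
    reconstruct,
    sample_perturbation,
)

from conftest import volume_from_values
from test_gmm import random_params


def zero_ranges(K=3):
    return VariationRanges(s_mu=np.zeros(K), s_var=np.zeros(K))


def scalar_loop_reconstruct(values, params, new_params, probs):
    """Independent per-voxel scalar oracle of the remapping equations."""
    out = np.empty(len(values))
    for n, v in enumerate(values):
        acc = 0.0
        for k in range(params.K):
            d = (v - params.mu[k]) / np.sqrt(params.var[k])
            v_k = new_params.mu[k] + d * np.sqrt(new_params.var[k])
            acc += probs[n, k] * v_k
        out[n] = acc
    return out


class TestSampling:
    def test_zero_ranges_give_exactly_zero_offsets(self):
        params = MixtureParams(pi=(1 / 3,) * 3, mu=(0.2, 0.5, 0.8), var=(0.01,) * 3)
        q = sample_perturbation(zero_ranges(), params, 123)
        assert np.all(q.q_mu == 0.0) and np.all(q.q_var == 0.0)

    def test_uniform_support_and_moments(self):
        params = MixtureParams(pi=(1.0,), mu=(0.5,), var=(0.01,))
        ranges = VariationRanges(s_mu=(0.06,), s_var=(0.001,))
        n = 100_000
        draws = np.array(
            [sample_perturbation(ranges, params, s).q_mu[0] for s in range(n)]
        )
        a = 0.06
        assert draws.min() > -a and draws.max() < a
        assert abs(draws.mean()) < 3 * (a / np.sqrt(3)) / np.sqrt(n)
        assert abs(draws.std() - a / np.sqrt(3)) < 3 * a / np.sqrt(n)

    def test_seed_determinism(self):
        params = random_params(np.random.default_rng(1))
        ranges = default_ranges()
        q1 = sample_perturbation(ranges, params, 77)
        q2 = sample_perturbation(ranges, params, 77)
        assert np.array_equal(q1.q_mu, q2.q_mu) and np.array_equal(q1.q_var, q2.q_var)

    def test_variance_offset_respects_floor(self):
        # component variance below every possible negative draw magnitude:
        # resampling cannot succeed, so the draw is clamped to the floor
        params = MixtureParams(pi=(1.0,), mu=(0.5,), var=(2e-6,))
        ranges = VariationRanges(s_mu=(0.0,), s_var=(0.5,))
        for seed in range(50):
            q = sample_perturbation(ranges, params, seed)
            assert params.var[0] + q.q_var[0] >= VARIANCE_FLOOR - 1e-18


class TestPerturbParams:
    def test_zero_offsets_are_identity(self):
        params = random_params(np.random.default_rng(2))
        q = PerturbationSample(q_mu=np.zeros(3), q_var=np.zeros(3), seed=0)
        out = perturb_params(params, q)
        assert np.array_equal(out.mu, params.mu)
        assert np.array_equal(out.var, params.var)
        assert np.array_equal(out.pi, params.pi)

    def test_componentwise_addition_preserving_identity(self):
        params = MixtureParams(pi=(1 / 3,) * 3, mu=(0.2, 0.5, 0.8), var=(0.01,) * 3)
        q = PerturbationSample(
            q_mu=np.array([0.03, -0.06, 0.08]), q_var=np.zeros(3), seed=0
        )
        out = perturb_params(params, q)
        assert np.allclose(out.mu, (0.23, 0.44, 0.88))
        # large offsets may re-order means; component identity is kept
        q_big = PerturbationSample(
            q_mu=np.array([0.5, 0.0, -0.5]), q_var=np.zeros(3), seed=0
        )
        shifted = perturb_params(params, q_big)
        assert np.allclose(shifted.mu, (0.7, 0.5, 0.3))  # not re-sorted

    def test_variance_floor_enforced(self):
        params = MixtureParams(pi=(1.0,), mu=(0.5,), var=(0.001,))
        q = PerturbationSample(q_mu=np.zeros(1), q_var=np.array([-0.002]), seed=0)
        assert perturb_params(params, q).var[0] == VARIANCE_FLOOR


class TestReconstruct:
    def test_noop_identity(self, clean_phantom):
        vol = prepare_for_gmm(clean_phantom[0])
        params, _ = fit_gmm(vol)
        post = posteriors(vol, params)
        out = reconstruct(vol, params, params, post)
        assert np.max(np.abs(out.data - vol.data)) < 1e-9

    def test_single_component_closed_form(self):
        params = MixtureParams(pi=(1.0,), mu=(0.5,), var=(0.01,))
        new = MixtureParams(pi=(1.0,), mu=(0.3,), var=(0.05**2,))
        vol = volume_from_values([0.6])  # d = (0.6-0.5)/0.1 = 1
        out = reconstruct(vol, params, new, posteriors(vol, params))
        assert out.masked_values[0] == pytest.approx(0.35, abs=1e-12)

    def test_symmetric_cancellation(self):
        params = MixtureParams(pi=(0.5, 0.5), mu=(0.2, 0.8), var=(0.01, 0.01))
        new = MixtureParams(pi=(0.5, 0.5), mu=(0.3, 0.7), var=(0.01, 0.01))
        vol = volume_from_values([0.5])  # posteriors (0.5, 0.5), d = (3, -3)
        out = reconstruct(vol, params, new, posteriors(vol, params))
        assert out.masked_values[0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(5)
        params = random_params(rng)
        q = sample_perturbation(default_ranges(), params, 13)
        new = perturb_params(params, q)
        values = rng.uniform(0, 1, 500)
        vol = volume_from_values(values)
        post = posteriors(vol, params)
        out = reconstruct(vol, params, new, post)
        expected = scalar_loop_reconstruct(values, params, new, post.probs)
        assert np.max(np.abs(out.masked_values - expected)) < 1e-10

    def test_affine_map_for_single_component(self):
        params = MixtureParams(pi=(1.0,), mu=(0.4,), var=(0.01,))
        new = MixtureParams(pi=(1.0,), mu=(0.6,), var=(0.04,))
        values = np.linspace(0, 1, 101)
        vol = volume_from_values(values)
        out = reconstruct(vol, params, new, posteriors(vol, params)).masked_values
        slope = np.sqrt(new.var[0] / params.var[0])
        assert np.allclose(out, new.mu[0] + slope * (values - params.mu[0]), atol=1e-12)

    def test_pure_voxels_keep_mahalanobis_distance(self, clean_phantom):
        vol = prepare_for_gmm(clean_phantom[0])
        params, _ = fit_gmm(vol)
        post = posteriors(vol, params)
        for seed in range(20):
            q = sample_perturbation(default_ranges(), params, seed)
            new = perturb_params(params, q)
            out = reconstruct(vol, params, new, post)
            d_old = mahalanobis_distances(vol, params)
            d_new = mahalanobis_distances(out, new)
            for k in range(3):
                pure = post.probs[:, k] >= 1 - 1e-6
                assert pure.any()
                assert np.max(np.abs(d_new[pure, k] - d_old[pure, k])) < 1e-6

    def test_mask_mismatch_rejected(self):
        params = MixtureParams(pi=(1.0,), mu=(0.5,), var=(0.01,))
        vol = volume_from_values([0.4, 0.6])
        other = volume_from_values([0.4, 0.6, 0.7])
        with pytest.raises(GmmdaError):
            reconstruct(vol, params, params, posteriors(other, params))

    def test_clip_flag_bounds_output(self):
        params = MixtureParams(pi=(1.0,), mu=(0.5,), var=(0.01,))
        new = MixtureParams(pi=(1.0,), mu=(0.9,), var=(0.04,))
        vol = volume_from_values(np.linspace(0.01, 1, 50))
        out = reconstruct(vol, params, new, posteriors(vol, params), clip=True)
        assert out.data.max() <= 1.0 and out.data.min() >= 0.0


class TestAugmentPipeline:
    def test_zero_ranges_reproduce_preprocessed_input(self, clean_phantom):
        vol = clean_phantom[0]
        variant = augment(vol, zero_ranges(), rng_seed=99)[0]
        expected = prepare_for_gmm(vol)
        assert np.max(np.abs(variant.volume.data - expected.data)) < 1e-9

    def test_refit_recovers_perturbed_means(self, clean_phantom):
        variant = augment(clean_phantom[0], default_ranges(), rng_seed=3)[0]
        refit, _ = fit_gmm(variant.volume)
        target = np.sort(variant.perturbed_params.mu)
        assert np.all(np.abs(refit.mu - target) < 0.015)

    def test_variants_distinct_and_bit_reproducible(self, clean_phantom):
        first = augment(clean_phantom[0], default_ranges(), rng_seed=5, n_variants=5)
        again = augment(clean_phantom[0], default_ranges(), rng_seed=5, n_variants=5)
        for a, b in zip(first, again):
            assert np.array_equal(a.volume.data, b.volume.data)
        for i in range(5):
            for j in range(i + 1, 5):
                assert not np.array_equal(first[i].volume.data, first[j].volume.data)

    def test_variant_i_independent_of_n_variants(self, clean_phantom):
        short = augment(clean_phantom[0], default_ranges(), rng_seed=5, n_variants=2)
        long = augment(clean_phantom[0], default_ranges(), rng_seed=5, n_variants=5)
        assert np.array_equal(short[0].volume.data, long[0].volume.data)
        assert np.array_equal(short[1].volume.data, long[1].volume.data)

    def test_structure_preserved_under_default_ranges(self, clean_phantom):
        vol = prepare_for_gmm(clean_phantom[0])
        params, _ = fit_gmm(vol)
        post = posteriors(vol, params)
        before = class_map(post)
        for seed in range(20):
            q = sample_perturbation(default_ranges(), params, seed)
            new = perturb_params(params, q)
            out = reconstruct(vol, params, new, post)
            refit, _ = fit_gmm(out)
            after = class_map(posteriors(out, refit))
            for k in (1, 2, 3):
                assert dice(before, after, k) >= 0.98

    def test_provenance_serialization(self, clean_phantom, tmp_path):
        variant = augment(clean_phantom[0], default_ranges(), rng_seed=1)[0]
        path = tmp_path / "prov.json"
        variant.write_provenance(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["perturbation"]["q_mu"] == variant.perturbation.q_mu.tolist()
        assert payload["perturbed_params"]["mu"] == variant.perturbed_params.mu.tolist()


class TestAugmentingIterator:
    def test_empty_sequence_yields_empty_stream(self):
        assert list(augmenting_iterator([], default_ranges(), rng_seed=0)) == []

    def test_fit_cache_contract(self, clean_phantom, monkeypatch):
        calls = {"n": 0}
        real = aug_module.fit_gmm

        def counting_fit(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(aug_module, "fit_gmm", counting_fit)
        vol_a = clean_phantom[0]
        vol_b, _ = generate_phantom(PhantomSpec(grid_shape=(24, 24, 24), seed=12))
        stream = augmenting_iterator([vol_a, vol_b], default_ranges(), rng_seed=2)
        for _ in range(10):
            next(stream)
        assert calls["n"] == 2

    def test_same_seed_gives_identical_streams(self, clean_phantom):
        ranges = default_ranges()
        s1 = augmenting_iterator([clean_phantom[0]], ranges, rng_seed=8)
        s2 = augmenting_iterator([clean_phantom[0]], ranges, rng_seed=8)
        for _ in range(4):
            assert np.array_equal(next(s1).volume.data, next(s2).volume.data)
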