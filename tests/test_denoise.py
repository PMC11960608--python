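import numpy as np
import pytest
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

from relpatlak.denoise import (CompositeSet, ConventionalKernelSmoother,
                               DeepKernelSmoother, DenoiseConfig, apply_kernel,
                               build_conventional_kernel, denoise_dynamic,
                               kernel_objective, load_kernel_model,
                               make_composites, save_kernel_model,
                               train_deep_kernel)
from relpatlak.phantom import (DynamicImage, late_schedule, simulate_dynamic)

FAST = DenoiseConfig(k=20, window=5, iters=40, lr=1e-3, seed=0,
                     batch_size=1024)


@pytest.fixture(scope="module")
def noisy_small(small_spec_module, feng_module):
    return simulate_dynamic(small_spec_module, feng_module, late_schedule(),
                            noise_scale=1.0, seed=21)


@pytest.fixture(scope="module")
def small_spec_module():
    from relpatlak.phantom import PhantomConfig, build_phantom
    return build_phantom(PhantomConfig(shape=(20, 20, 40)))


@pytest.fixture(scope="module")
def feng_module():
    from relpatlak.kinetics import InputFunction
    return InputFunction.feng()


@pytest.fixture(scope="module")
def composites(noisy_small):
    return make_composites(noisy_small)


@pytest.fixture(scope="module")
def conv_kernel(composites):
    return build_conventional_kernel(composites, k=FAST.k, window=FAST.window)


# ---------------------------------------------------------------------- #
# composites

def test_make_composites_identity_for_four_frames(noisy_small):
    Z = make_composites(noisy_small, nz=4)
    assert Z.nz == 4
    for m in range(4):
        assert np.allclose(Z.frames[m], noisy_small.data[..., m], rtol=1e-14)
    assert np.allclose(Z.mean_image, noisy_small.data.mean(axis=-1))


def test_make_composites_grouping():
    sched = late_schedule(40.0, 8, 2.5)
    data = np.arange(8.0)[None, None, None, :] * np.ones((2, 2, 2, 8))
    img = DynamicImage(data=data, schedule=sched)
    Z = make_composites(img, nz=4)
    assert Z.nz == 4
    assert np.allclose(Z.frames[0], 0.5)   # mean of frames 0, 1
    assert np.allclose(Z.frames[3], 6.5)
    with pytest.raises(ValueError):
        make_composites(img, nz=3)          # 8 not divisible by 3
    with pytest.raises(ValueError):
        make_composites(img, nz=1)


def test_composite_set_validation():
    with pytest.raises(ValueError):
        CompositeSet(frames=[np.zeros((2, 2, 2))], mean_image=np.zeros((2, 2, 2)))
    with pytest.raises(ValueError):
        CompositeSet(frames=[np.zeros((2, 2, 2)), np.zeros((3, 2, 2))],
                     mean_image=np.zeros((2, 2, 2)))


# ---------------------------------------------------------------------- #
# conventional kernel

def test_kernel_rows_are_stochastic(conv_kernel):
    assert np.allclose(conv_kernel.weights.sum(axis=1), 1.0)
    assert conv_kernel.weights.min() >= 0.0
    assert conv_kernel.neighbor_index.shape == (conv_kernel.rows.size, FAST.k)


def test_apply_kernel_preserves_constants(conv_kernel):
    const = np.full(conv_kernel.shape, 3.7)
    assert np.allclose(apply_kernel(conv_kernel, const), 3.7)


def test_apply_kernel_is_linear(conv_kernel):
    rng = np.random.default_rng(2)
    a = rng.normal(size=conv_kernel.shape)
    b = rng.normal(size=conv_kernel.shape)
    lhs = apply_kernel(conv_kernel, 2.0 * a - 3.0 * b)
    rhs = 2.0 * apply_kernel(conv_kernel, a) - 3.0 * apply_kernel(conv_kernel, b)
    assert np.allclose(lhs, rhs, atol=1e-10)
    with pytest.raises(ValueError):
        apply_kernel(conv_kernel, np.zeros((2, 2, 2)))


def test_k1_kernel_is_identity(composites):
    # the single nearest neighbor in feature space is the voxel itself
    model = build_conventional_kernel(composites, k=1, window=3)
    vol = composites.frames[0]
    assert np.allclose(apply_kernel(model, vol), vol)


def test_kernel_respects_region_boundaries(small_spec_module, feng_module):
    # on noise-free composites, features separate organs exactly, so the
    # kernel average of the noise-free volume stays (near) noise-free
    img = simulate_dynamic(small_spec_module, feng_module, late_schedule(),
                           noise_scale=0.0)
    Z = make_composites(img)
    model = build_conventional_kernel(Z, k=FAST.k, window=FAST.window)
    out = apply_kernel(model, img.data[..., -1])
    err = np.abs(out - img.data[..., -1])
    assert np.median(err) < 1e-6 * img.data[..., -1].max()


def test_conventional_kernel_validation(composites):
    with pytest.raises(ValueError):
        build_conventional_kernel(composites, k=0)
    with pytest.raises(ValueError):
        build_conventional_kernel(composites, k=10, sigma=0.0)
    with pytest.raises(ValueError):
        build_conventional_kernel(composites, k=1000, window=3)


# ---------------------------------------------------------------------- #
# deep kernel

def test_deep_kernel_descends_and_beats_conventional(composites, conv_kernel):
    model = train_deep_kernel(composites, FAST)
    hist = model.config["loss_history"]
    assert model.trained and len(hist) == FAST.iters
    assert min(hist) < hist[0]
    assert (kernel_objective(model, composites)
            < kernel_objective(conv_kernel, composites))


def test_deep_kernel_deterministic(composites):
    a = train_deep_kernel(composites, FAST)
    b = train_deep_kernel(composites, FAST)
    assert np.array_equal(a.weights, b.weights)
    assert all(np.array_equal(a.theta[k], b.theta[k]) for k in a.theta)


def test_deep_kernel_initial_state_matches_conventional(composites,
                                                        conv_kernel):
    # zero iterations: W2 = 0 keeps the feature map the identity, so the
    # operator is exactly the conventional kernel
    cfg = DenoiseConfig(k=FAST.k, window=FAST.window, iters=0, seed=0)
    model = train_deep_kernel(composites, cfg)
    assert np.array_equal(model.neighbor_index, conv_kernel.neighbor_index)
    assert np.allclose(model.weights, conv_kernel.weights, atol=1e-12)


def test_time_constant_composites_give_zero_objective():
    # when every composite frame equals the mean image, any row-stochastic
    # kernel that respects region boundaries reproduces z_a exactly
    rng = np.random.default_rng(4)
    vol = np.repeat(rng.uniform(1.0, 10.0, size=(6, 6, 1)), 6, axis=2)
    frames = [vol.copy() for _ in range(4)]
    Z = CompositeSet(frames=frames, mean_image=vol.copy())
    # k = 3: along z every voxel has >= 3 feature-identical window candidates
    model = build_conventional_kernel(Z, k=3, window=3)
    assert kernel_objective(model, Z) < 1e-18 * float((vol ** 2).sum())


def test_denoise_dynamic_reduces_noise(noisy_small, small_spec_module,
                                       composites, feng_module):
    model = train_deep_kernel(composites, FAST)
    den = denoise_dynamic(noisy_small, model)
    liver = small_spec_module.labels == small_spec_module.label_of("liver")
    before = noisy_small.data[liver, -1].std()
    after = den.data[liver, -1].std()
    assert after < before


# ---------------------------------------------------------------------- #
# serialization

def test_kernel_model_round_trip(tmp_path, composites):
    model = train_deep_kernel(composites, FAST)
    path = tmp_path / "kernel.npz"
    save_kernel_model(model, str(path))
    loaded = load_kernel_model(str(path))
    assert loaded.shape == model.shape and loaded.k == model.k
    assert loaded.trained
    assert np.array_equal(loaded.weights, model.weights)
    assert np.array_equal(loaded.rows, model.rows)
    assert all(np.array_equal(loaded.theta[k], model.theta[k])
               for k in model.theta)


# ---------------------------------------------------------------------- #
# estimator interface

def test_smoother_estimators(noisy_small):
    conv = ConventionalKernelSmoother(k=FAST.k, window=FAST.window)
    assert clone(conv).get_params()["k"] == FAST.k
    with pytest.raises(NotFittedError):
        conv.transform(noisy_small)
    conv.fit(noisy_small)
    out = conv.transform(noisy_small)
    assert isinstance(out, type(noisy_small)) and out.data.shape == noisy_small.data.shape

    deep = DeepKernelSmoother(k=FAST.k, window=FAST.window, iters=FAST.iters,
                              batch_size=FAST.batch_size, random_state=0)
    den = deep.fit_transform(noisy_small)
    assert den.data.shape == noisy_small.data.shape
    assert deep.objective_ < conv.objective_
    assert len(deep.loss_history_) == FAST.iters
    # 3-D arrays pass through apply_kernel
    vol = deep.transform(noisy_small.data[..., 0])
    assert vol.shape == noisy_small.shape
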