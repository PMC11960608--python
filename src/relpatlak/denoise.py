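"""Self-supervised kernel denoising for dynamic PET.

A denoised volume is a row-stochastic neighbor average

    x_denoised = K(theta; Z) x_noise,

where the kernel matrix K is built from composite late-frame images
Z = {z_m} (here the nz = 4 five-minute frames of the short scan).  The
conventional kernel uses fixed Gaussian weights on z-scored composite
features; the deep kernel passes the per-voxel feature vector through a
small trainable residual map and learns its parameters self-supervised,
minimizing

    sum_m || z_a - K(theta; Z) z_m ||^2

with the mean image z_a of the composites as the clean training label.
No population pretraining is involved: the kernel is trained per scan.

The trainer is a hand-derived analytic backpropagation through the Gaussian
k-NN softmax and the two-layer feature map, optimized with Adam.  Neighbors
are found once from the raw z-scored features inside a spatial search window
and stay frozen during training, so the operator keeps a fixed topology and
only the weights are learned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .kinetics import InputFunction
from .patlak import ParametricImage, default_mask, fit_parametric
from .phantom import DynamicImage

__all__ = [
    "CompositeSet",
    "KernelModel",
    "DenoiseConfig",
    "make_composites",
    "build_conventional_kernel",
    "train_deep_kernel",
    "apply_kernel",
    "kernel_objective",
    "denoise_parametric",
    "denoise_dynamic",
    "save_kernel_model",
    "load_kernel_model",
    "ConventionalKernelSmoother",
    "DeepKernelSmoother",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositeSet:
    """Composite late frames z_1..z_nz and their mean image z_a."""

    frames: list
    mean_image: np.ndarray

    def __post_init__(self):
        if len(self.frames) < 2:
            raise ValueError("need at least 2 composite frames")
        shapes = {f.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValueError("composite frames must share a shape")

    @property
    def nz(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames[0].shape


@dataclass
class DenoiseConfig:
    """Settings of the kernel denoiser (defaults follow the short-scan
    protocol: k = 200 neighbors, 300 iterations, learning rate 1e-3)."""

    k: int = 200
    window: int = 9
    sigma: float = 1.0
    iters: int = 300
    lr: float = 1e-3
    seed: int = 0
    nz: int = 4
    hidden: int = 16
    batch_size: int = 4096
    post_smooth_parametric: bool = False


@dataclass
class KernelModel:
    """Frozen row-stochastic neighbor-averaging operator.

    Rows are the voxels the kernel acts on (linear indices into the
    flattened volume); every other voxel is passed through unchanged.
    """

    shape: tuple[int, int, int]
    rows: np.ndarray            # (n,) linear voxel indices
    neighbor_index: np.ndarray  # (n, k) linear voxel indices
    weights: np.ndarray         # (n, k), rows sum to 1
    k: int
    trained: bool = False
    theta: dict | None = None
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------- #
# composites

def make_composites(img: DynamicImage, nz: int = 4) -> CompositeSet:
    """Group the dynamic frames into nz contiguous, equal composites.

    With the 4x5-min late schedule and nz = 4 the composites are the frames
    themselves; coarser nz averages contiguous groups (duration-weighted).
    """
    if nz < 2:
        raise ValueError("nz must be >= 2")
    n = img.n_frames
    if n < nz or n % nz != 0:
        raise ValueError(f"{n} frames cannot be grouped into {nz} composites")
    group = n // nz
    dur = img.schedule.durations
    frames = []
    for m in range(nz):
        sl = slice(m * group, (m + 1) * group)
        d = dur[sl]
        frames.append((img.data[..., sl] * d).sum(axis=-1) / d.sum())
    mean_image = np.mean(frames, axis=0)
    return CompositeSet(frames=frames, mean_image=mean_image)


# ---------------------------------------------------------------------- #
# neighbor search

def _zscored_features(Z: CompositeSet, mask: np.ndarray) -> np.ndarray:
    """Per-voxel feature = its nz composite values, z-scored per composite
    over the mask; returned flattened as (n_voxels, nz) float64."""
    stack = np.stack([f.astype(np.float64) for f in Z.frames], axis=-1)
    ref = stack[mask]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    sd[sd == 0] = 1.0
    feats = (stack - mu) / sd
    return feats.reshape(-1, Z.nz)


def _window_offsets(window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    r = window // 2
    g = np.arange(-r, r + 1)
    return np.stack(np.meshgrid(g, g, g, indexing="ij"), -1).reshape(-1, 3)


def _knn_search(feats: np.ndarray, shape: tuple, rows: np.ndarray,
                k: int, window: int, chunk: int = 4096) -> np.ndarray:
    """k nearest neighbors (feature distance) within a spatial window.

    Window coordinates are clamped at the volume edge.  Returns linear
    neighbor indices, shape (len(rows), k).
    """
    offs = _window_offsets(window)
    if k > offs.shape[0]:
        raise ValueError(f"k={k} exceeds the {window}^3 search window")
    shape_arr = np.asarray(shape)
    coords = np.stack(np.unravel_index(rows, shape), axis=-1)
    f32 = feats.astype(np.float32)
    out = np.empty((rows.size, k), dtype=np.int64)
    for c0 in range(0, rows.size, chunk):
        cc = coords[c0:c0 + chunk]
        cand = cc[:, None, :] + offs[None, :, :]
        np.clip(cand, 0, shape_arr - 1, out=cand)
        lin = np.ravel_multi_index(
            (cand[..., 0], cand[..., 1], cand[..., 2]), shape)
        diff = f32[lin] - f32[rows[c0:c0 + chunk], None, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        part = np.argpartition(d2, k - 1, axis=1)[:, :k]
        out[c0:c0 + chunk] = np.take_along_axis(lin, part, axis=1)
    return out


def _gaussian_weights(fi: np.ndarray, fj: np.ndarray, sigma: float,
                      nz: int) -> np.ndarray:
    """Row-normalized Gaussian weights from feature distances.

    The squared distance is scaled by the feature dimension so sigma is
    in per-component z-score units.
    """
    d2 = ((fi[:, None, :] - fj) ** 2).sum(axis=-1)
    s = -d2 / (2.0 * sigma ** 2 * nz)
    s -= s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)
    return w


# ---------------------------------------------------------------------- #
# conventional kernel

def build_conventional_kernel(Z: CompositeSet, k: int = 200,
                              sigma: float = 1.0, window: int = 9,
                              mask: np.ndarray | None = None) -> KernelModel:
    """Fixed Gaussian k-NN kernel on z-scored composite features."""
    if k < 1 or sigma <= 0:
        raise ValueError("require k >= 1 and sigma > 0")
    if mask is None:
        mask = Z.mean_image > 0.01 * Z.mean_image.max()
    rows = np.flatnonzero(mask.ravel())
    feats = _zscored_features(Z, mask)
    nb = _knn_search(feats, Z.shape, rows, k, window)
    weights = np.empty(nb.shape, dtype=np.float64)
    chunk = 8192
    for c0 in range(0, rows.size, chunk):
        sl = slice(c0, c0 + chunk)
        weights[sl] = _gaussian_weights(feats[rows[sl]], feats[nb[sl]],
                                        sigma, Z.nz)
    return KernelModel(shape=Z.shape, rows=rows, neighbor_index=nb,
                       weights=weights, k=k, trained=False,
                       config={"k": k, "sigma": sigma, "window": window})


# ---------------------------------------------------------------------- #
# deep kernel

def _forward_features(V: np.ndarray, theta: dict) -> tuple[np.ndarray, np.ndarray]:
    """Residual two-layer feature map f = v + tanh(v W1 + b1) W2 + b2."""
    a1 = np.tanh(V @ theta["W1"] + theta["b1"])
    return V + a1 @ theta["W2"] + theta["b2"], a1


def _init_theta(nz: int, hidden: int, rng: np.random.Generator) -> dict:
    # W2 = 0 makes the initial map the identity, so training starts from
    # exactly the conventional kernel and can only improve the objective
    return {
        "W1": rng.normal(0.0, 0.5 / np.sqrt(nz), size=(nz, hidden)),
        "b1": np.zeros(hidden),
        "W2": np.zeros((hidden, nz)),
        "b2": np.zeros(nz),
    }


def _batch_loss_and_grad(theta, V, rows, nb, batch_idx, z_flat, za_flat,
                         sigma, nz, scale):
    """Eq.-style objective on a row minibatch and its gradient w.r.t. theta.

    Backpropagates through the Gaussian softmax weights and the residual
    feature map; gradients flow both to each row voxel and to its neighbors.
    """
    F, a1 = _forward_features(V, theta)
    rb = rows[batch_idx]
    nbb = nb[batch_idx]                      # (b, k)
    fi = F[rb][:, None, :]                   # (b, 1, nz)
    fj = F[nbb]                              # (b, k, nz)
    diff = fi - fj
    d2 = (diff ** 2).sum(axis=-1)
    s = -d2 / (2.0 * sigma ** 2 * nz)
    s -= s.max(axis=1, keepdims=True)
    w = np.exp(s)
    w /= w.sum(axis=1, keepdims=True)        # (b, k)

    b = rb.size
    norm = b * z_flat.shape[0] * scale
    loss = 0.0
    G = np.zeros_like(w)                     # dL/dw
    for zm in z_flat:                        # z_flat: (nz, n_voxels)
        pred = (w * zm[nbb]).sum(axis=1)
        r = za_flat[rb] - pred
        loss += (r ** 2).sum() / norm
        dpred = -2.0 * r / norm
        G += dpred[:, None] * zm[nbb]
    ds = w * (G - (G * w).sum(axis=1, keepdims=True))
    dd2 = ds * (-1.0 / (2.0 * sigma ** 2 * nz))
    dfi = (2.0 * dd2[:, :, None] * diff).sum(axis=1)   # (b, nz)
    dfj = -2.0 * dd2[:, :, None] * diff                # (b, k, nz)

    dF = np.zeros_like(F)
    np.add.at(dF, rb, dfi)
    flat_nb = nbb.ravel()
    dfj_flat = dfj.reshape(-1, nz)
    for c in range(nz):
        dF[:, c] += np.bincount(flat_nb, weights=dfj_flat[:, c],
                                minlength=F.shape[0])

    grads = {
        "W2": a1.T @ dF,
        "b2": dF.sum(axis=0),
    }
    da1 = dF @ theta["W2"].T
    dh1 = da1 * (1.0 - a1 ** 2)
    grads["W1"] = V.T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    return loss, grads


def train_deep_kernel(Z: CompositeSet, config: DenoiseConfig | None = None,
                      mask: np.ndarray | None = None) -> KernelModel:
    """Self-supervised deep-kernel training.

    Learns the residual feature map whose induced Gaussian k-NN kernel
    minimizes sum_m ||z_a - K z_m||^2 over the masked voxels; the parameters
    with the lowest running objective are kept and frozen into the returned
    operator.  Fully seeded and deterministic.
    """
    config = config or DenoiseConfig()
    if mask is None:
        mask = Z.mean_image > 0.01 * Z.mean_image.max()
    rows = np.flatnonzero(mask.ravel())
    feats = _zscored_features(Z, mask)
    nb = _knn_search(feats, Z.shape, rows, config.k, config.window)

    rng = np.random.default_rng(config.seed)
    theta = _init_theta(Z.nz, config.hidden, rng)
    z_flat = np.stack([f.reshape(-1).astype(np.float64) for f in Z.frames])
    za_flat = Z.mean_image.reshape(-1).astype(np.float64)
    scale = float(np.mean(za_flat[rows] ** 2)) + 1e-12

    m = {kk: np.zeros_like(v) for kk, v in theta.items()}
    v = {kk: np.zeros_like(vv) for kk, vv in theta.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    batch = min(config.batch_size, rows.size)
    best_loss = np.inf
    best_theta = {kk: vv.copy() for kk, vv in theta.items()}
    history = []
    for it in range(config.iters):
        idx = rng.choice(rows.size, size=batch, replace=False)
        loss, grads = _batch_loss_and_grad(theta, feats, rows, nb, idx,
                                           z_flat, za_flat, config.sigma,
                                           Z.nz, scale)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at iteration {it}")
        history.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_theta = {kk: vv.copy() for kk, vv in theta.items()}
        for kk in theta:
            m[kk] = beta1 * m[kk] + (1 - beta1) * grads[kk]
            v[kk] = beta2 * v[kk] + (1 - beta2) * grads[kk] ** 2
            mh = m[kk] / (1 - beta1 ** (it + 1))
            vh = v[kk] / (1 - beta2 ** (it + 1))
            theta[kk] -= config.lr * mh / (np.sqrt(vh) + eps)

    F, _ = _forward_features(feats, best_theta)
    weights = np.empty(nb.shape, dtype=np.float64)
    chunk = 8192
    for c0 in range(0, rows.size, chunk):
        sl = slice(c0, c0 + chunk)
        weights[sl] = _gaussian_weights(F[rows[sl]], F[nb[sl]],
                                        config.sigma, Z.nz)
    model = KernelModel(shape=Z.shape, rows=rows, neighbor_index=nb,
                        weights=weights, k=config.k, trained=True,
                        theta=best_theta, config=asdict(config))
    model.config["loss_history"] = history
    return model


# ---------------------------------------------------------------------- #
# application

def apply_kernel(model: KernelModel, vol: np.ndarray) -> np.ndarray:
    """Apply the row-stochastic kernel; linear, constant-preserving."""
    if vol.shape != model.shape:
        raise ValueError("volume geometry does not match the kernel model")
    src = vol.reshape(-1).astype(np.float64)
    out = src.copy()
    out[model.rows] = (model.weights * src[model.neighbor_index]).sum(axis=1)
    return out.reshape(vol.shape)


def kernel_objective(model: KernelModel, Z: CompositeSet) -> float:
    """Self-supervised objective sum_m ||z_a - K z_m||^2 over model rows."""
    za = Z.mean_image.reshape(-1)[model.rows]
    total = 0.0
    for f in Z.frames:
        zf = f.reshape(-1)
        pred = (model.weights * zf[model.neighbor_index]).sum(axis=1)
        total += float(((za - pred) ** 2).sum())
    return total


def denoise_dynamic(img: DynamicImage, model: KernelModel) -> DynamicImage:
    """Apply the trained kernel to every dynamic frame."""
    frames = [apply_kernel(model, img.data[..., i])
              for i in range(img.n_frames)]
    return DynamicImage(data=np.stack(frames, axis=-1),
                        schedule=img.schedule, voxel_mm=img.voxel_mm)


def denoise_parametric(img: DynamicImage, f: InputFunction, t_star: float,
                       method: str = "relative",
                       config: DenoiseConfig | None = None,
                       mask: np.ndarray | None = None) -> ParametricImage:
    """Deep-kernel denoising pipeline for parametric imaging.

    make_composites -> train_deep_kernel -> apply to each dynamic frame ->
    voxelwise Patlak fit.  When config.post_smooth_parametric is true the
    kernel is additionally applied to the slope/intercept maps.
    """
    config = config or DenoiseConfig()
    if mask is None:
        mask = default_mask(img)
    Z = make_composites(img, config.nz)
    model = train_deep_kernel(Z, config, mask=mask)
    den = denoise_dynamic(img, model)
    pimg = fit_parametric(den, f, t_star, method=method, mask=mask)
    if config.post_smooth_parametric:
        pimg = ParametricImage(
            slope_vol=apply_kernel(model, pimg.slope_vol),
            intercept_vol=apply_kernel(model, pimg.intercept_vol),
            method=pimg.method, t_star=pimg.t_star, mask=pimg.mask)
    return pimg


# ---------------------------------------------------------------------- #
# serialization: npz payload + JSON header

def save_kernel_model(model: KernelModel, path: str):
    arrays = {
        "rows": model.rows,
        "neighbor_index": model.neighbor_index,
        "weights": model.weights,
    }
    if model.theta is not None:
        for kk, vv in model.theta.items():
            arrays[f"theta_{kk}"] = vv
    header = {
        "shape": list(model.shape),
        "k": model.k,
        "trained": model.trained,
        "config": {kk: vv for kk, vv in model.config.items()
                   if kk != "loss_history"},
    }
    arrays["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_kernel_model(path: str) -> KernelModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        theta = {kk[6:]: data[kk] for kk in data.files
                 if kk.startswith("theta_")}
        return KernelModel(shape=tuple(header["shape"]), rows=data["rows"],
                           neighbor_index=data["neighbor_index"],
                           weights=data["weights"], k=header["k"],
                           trained=header["trained"],
                           theta=theta or None, config=header["config"])


# ---------------------------------------------------------------------- #
# estimator interface

class _KernelSmootherBase(BaseEstimator):
    def _composites(self, X) -> CompositeSet:
        if isinstance(X, CompositeSet):
            return X
        if isinstance(X, DynamicImage):
            return make_composites(X, self.nz)
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("expected a CompositeSet, DynamicImage or "
                             "4-D array (x, y, z, frame)")
        frames = [X[..., i] for i in range(X.shape[-1])]
        return CompositeSet(frames=frames, mean_image=np.mean(frames, axis=0))

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "model_")
        if isinstance(X, DynamicImage):
            return denoise_dynamic(X, self.model_)
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            return apply_kernel(self.model_, X)
        return np.stack([apply_kernel(self.model_, X[..., i])
                         for i in range(X.shape[-1])], axis=-1)

    def fit_transform(self, X, y=None, **kw):
        return self.fit(X, y, **kw).transform(X)


class ConventionalKernelSmoother(_KernelSmootherBase):
    """Fixed Gaussian k-NN kernel smoother (the conventional kernel method)."""

    def __init__(self, k: int = 200, window: int = 9, sigma: float = 1.0,
                 nz: int = 4):
        self.k = k
        self.window = window
        self.sigma = sigma
        self.nz = nz

    def fit(self, X, y=None, *, mask: np.ndarray | None = None):
        Z = self._composites(X)
        self.model_ = build_conventional_kernel(Z, k=self.k,
                                                sigma=self.sigma,
                                                window=self.window, mask=mask)
        self.objective_ = kernel_objective(self.model_, Z)
        return self


class DeepKernelSmoother(_KernelSmootherBase):
    """Self-supervised deep-kernel smoother trained per scan."""

    def __init__(self, k: int = 200, window: int = 9, sigma: float = 1.0,
                 nz: int = 4, iters: int = 300, lr: float = 1e-3,
                 hidden: int = 16, batch_size: int = 4096,
                 random_state: int = 0):
        self.k = k
        self.window = window
        self.sigma = sigma
        self.nz = nz
        self.iters = iters
        self.lr = lr
        self.hidden = hidden
        self.batch_size = batch_size
        self.random_state = random_state

    def _config(self) -> DenoiseConfig:
        return DenoiseConfig(k=self.k, window=self.window, sigma=self.sigma,
                             iters=self.iters, lr=self.lr, seed=self.random_state,
                             nz=self.nz, hidden=self.hidden,
                             batch_size=self.batch_size)

    def fit(self, X, y=None, *, mask: np.ndarray | None = None):
        Z = self._composites(X)
        self.model_ = train_deep_kernel(Z, self._config(), mask=mask)
        self.loss_history_ = list(self.model_.config.get("loss_history", []))
        self.objective_ = kernel_objective(self.model_, Z)
        return self
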