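"""Implicit neural representation machinery.

A coordinate MLP with Gaussian random Fourier feature (GRFF) positional
encoding represents the reference CBCT volume (spatial INR), and nine small
coordinate MLPs of a scalar time input represent the time-varying weights of
the principal motion components (temporal INRs).

Everything here is plain numpy with hand-written backward passes: the networks
are small dense stacks, so explicit matmul backprop plus Adam is all that is
needed, and it keeps training fully deterministic under a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "swish", "swish_grad", "GRFFEncoder", "MLP", "Adam",
    "SpatialINR", "TemporalINR", "SCALED_PRESET", "FULL_PRESET",
]


from scipy.special import expit


def swish(y):
    """Swish activation y * sigmoid(y)."""
    y = np.asarray(y)
    return y * expit(y)


def swish_grad(y):
    """d/dy of swish: sigmoid(y) * (1 + y * (1 - sigmoid(y)))."""
    s = expit(y)
    return s * (1.0 + y * (1.0 - s))


def relu(y):
    return np.maximum(y, 0.0)


def relu_grad(y):
    return (y > 0.0).astype(y.dtype)


_ACTIVATIONS = {"swish": (swish, swish_grad), "relu": (relu, relu_grad)}


class GRFFEncoder:
    """Gaussian random Fourier feature encoding.

    gamma(x) = [sin(2 pi B x), cos(2 pi B x)] with B ~ N(0, sigma_b^2),
    B of shape (n_features, in_dim).  B is frozen after construction; the
    output dimension is 2 * n_features.
    """

    def __init__(self, in_dim, n_features=128, sigma_b=2.5, seed=0):
        rng = np.random.default_rng(seed)
        self.B = rng.normal(0.0, sigma_b, size=(n_features, in_dim)).astype(np.float32)
        self.in_dim = int(in_dim)
        self.n_features = int(n_features)
        self.sigma_b = float(sigma_b)
        self.seed = int(seed)

    @property
    def out_dim(self):
        return 2 * self.n_features

    def encode(self, x):
        """x: (N, in_dim) -> (N, 2*n_features)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 1:
            x = x[:, None]
        phase = 2.0 * np.pi * (x @ self.B.T)
        return np.concatenate([np.sin(phase), np.cos(phase)], axis=1)


class MLP:
    """Dense multi-layer perceptron with explicit forward/backward.

    ``sizes`` lists layer widths including input and output, e.g.
    ``[256, 64, 64, 64, 1]``.  The activation follows every layer but the
    last, whose output is linear (unbounded, sign-free).
    """

    def __init__(self, sizes, seed=0, activation="swish", final_scale=1.0):
        rng = np.random.default_rng(seed)
        self.sizes = list(int(s) for s in sizes)
        self.activation = activation
        self.W, self.b = [], []
        for i, (n_in, n_out) in enumerate(zip(self.sizes[:-1], self.sizes[1:])):
            scale = np.sqrt(2.0 / n_in)
            if i == len(self.sizes) - 2:
                scale *= final_scale
            self.W.append(rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32))
            self.b.append(np.zeros(n_out, dtype=np.float32))

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        return self.W + self.b

    def set_params(self, params):
        n = len(self.W)
        self.W = [np.asarray(p, dtype=np.float32) for p in params[:n]]
        self.b = [np.asarray(p, dtype=np.float32) for p in params[n:]]

    # -- forward / backward -------------------------------------------------
    def forward(self, x, want_cache=False):
        """x: (N, sizes[0]).  Returns output or (output, cache)."""
        act, _ = _ACTIVATIONS[self.activation]
        a = np.asarray(x, dtype=np.float32)
        cache = {"inputs": [], "pre": []}
        n_layers = len(self.W)
        for i in range(n_layers):
            cache["inputs"].append(a)
            z = a @ self.W[i] + self.b[i]
            if i < n_layers - 1:
                cache["pre"].append(z)
                a = act(z)
            else:
                a = z
        if want_cache:
            return a, cache
        return a

    def backward(self, cache, dy, want_dx=False):
        """Backprop dy = dL/d(output); returns (grads, dx).

        ``grads`` is ordered like :meth:`params` (weights then biases).
        ``dx`` (the input gradient) is skipped unless requested — the
        encoder inputs are constants during training.
        """
        _, dact = _ACTIVATIONS[self.activation]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        d = np.asarray(dy, dtype=np.float32)
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                d = d * dact(cache["pre"][i])
            a_in = cache["inputs"][i]
            gW[i] = a_in.T @ d
            gb[i] = d.sum(axis=0)
            if i > 0 or want_dx:
                d = d @ self.W[i].T
        return gW + gb, (d if want_dx else None)


class Adam:
    """Adaptive-moment gradient descent over a list of parameter arrays."""

    def __init__(self, params, lr=0.002, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.lr0 = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float32) for p in params]
        self.t = 0

    def set_lr_fraction(self, frac, floor=0.02):
        """Cosine decay of the initial learning rate as ``frac`` goes 0 -> 1."""
        self.lr = self.lr0 * (floor + (1.0 - floor)
                              * 0.5 * (1.0 + np.cos(np.pi * min(frac, 1.0))))

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g.astype(np.float32, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


# Architecture presets.  The full preset follows the published network sizes
# (spatial: 4 layers x 256 neurons; temporal: 256/100/100; 128 Fourier
# features); the scaled preset keeps the same topology at desk-scale widths
# for CPU runs.
FULL_PRESET = {
    "spatial_hidden": (256, 256, 256),
    "temporal_hidden": (256, 100, 100),
    "n_features": 128,
    "sigma_spatial": 2.5,   # phantom-study encoder width (sigma=4 preset: patient)
    "sigma_temporal": 2.5,
}
SCALED_PRESET = {
    "spatial_hidden": (64, 64, 64),
    "temporal_hidden": (64, 32, 32),
    "n_features": 64,
    "sigma_spatial": 2.5,
    "sigma_temporal": 2.5,
}


class SpatialINR:
    """Coordinate MLP mapping encoded 3-D positions to attenuation.

    Input coordinates are world positions (mm) normalized to [-1, 1]^3 over a
    fixed physical bounding box, so that the same network can be queried on
    any grid over that box (arbitrary-resolution inference).
    """

    def __init__(self, box_center, box_half, preset=SCALED_PRESET, seed=0,
                 activation="swish", output_scale=0.02):
        self.box_center = np.asarray(box_center, dtype=np.float64)
        self.box_half = np.asarray(box_half, dtype=np.float64)
        self.encoder = GRFFEncoder(3, preset["n_features"],
                                   preset["sigma_spatial"], seed=seed)
        sizes = [self.encoder.out_dim, *preset["spatial_hidden"], 1]
        self.mlp = MLP(sizes, seed=seed + 1, activation=activation,
                       final_scale=0.1)
        # the network learns values of order one; a fixed physical scale
        # (soft-tissue attenuation, mm^-1) maps them to attenuation
        self.output_scale = float(output_scale)
        self.preset = dict(preset)
        self.seed = int(seed)

    def normalize(self, pts_mm):
        return (np.asarray(pts_mm) - self.box_center) / self.box_half

    def encode_points(self, pts_mm):
        """Frozen GRFF features of world points; cacheable across training
        iterations when the query grid is fixed."""
        return self.encoder.encode(self.normalize(pts_mm).astype(np.float32))

    def eval_encoded(self, enc, want_cache=False):
        """Evaluate from precomputed encoder features."""
        if want_cache:
            out, cache = self.mlp.forward(enc, want_cache=True)
            return out[:, 0] * self.output_scale, cache
        return self.mlp.forward(enc)[:, 0] * self.output_scale

    def eval_points(self, pts_mm, want_cache=False):
        """pts_mm: (N, 3) world mm -> (N,) attenuation values."""
        return self.eval_encoded(self.encode_points(pts_mm),
                                 want_cache=want_cache)

    def eval_grid(self, shape, spacing, origin=None, want_cache=False):
        from .volume import centered_grid
        shape = tuple(int(s) for s in shape)
        spacing = np.broadcast_to(np.asarray(spacing, float), (3,))
        if origin is None:
            origin = centered_grid(shape, spacing)
        axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([a.ravel() for a in g], axis=1)
        if want_cache:
            vals, cache = self.eval_points(pts, want_cache=True)
            return vals.reshape(shape), cache
        return self.eval_points(pts).reshape(shape)

    def backward(self, cache, dvals):
        """dvals: (N,) dL/d(attenuation) -> parameter gradients."""
        dy = np.asarray(dvals).reshape(-1, 1) * self.output_scale
        grads, _ = self.mlp.backward(cache, dy)
        return grads


class TemporalINR:
    """Nine independent sub-MLPs of normalized time t in [0, 1].

    Sub-MLP (dim, n) outputs the weight of principal motion component n along
    Cartesian direction dim.  Each sub-MLP has its own parameters; they share
    one frozen GRFF time encoder.  Final layers start at zero so training
    begins from the mean-motion state.
    """

    N_TRACKS = 9

    def __init__(self, preset=SCALED_PRESET, seed=100, activation="swish"):
        self.encoder = GRFFEncoder(1, preset["n_features"],
                                   preset["sigma_temporal"], seed=seed)
        sizes = [self.encoder.out_dim, *preset["temporal_hidden"], 1]
        self.mlps = [MLP(sizes, seed=seed + 1 + i, activation=activation)
                     for i in range(self.N_TRACKS)]
        for m in self.mlps:      # zero final layer: w(t) == 0 at init
            m.W[-1][:] = 0.0
        self.preset = dict(preset)
        self.seed = int(seed)

    def eval_times(self, times, want_cache=False):
        """times: (T,) in [0, 1] -> (T, 9) weights."""
        t = np.asarray(times, dtype=np.float32).reshape(-1, 1)
        if np.any(t < -1e-9) or np.any(t > 1 + 1e-9):
            raise ValueError("temporal inputs must lie in [0, 1]")
        enc = self.encoder.encode(t)
        outs, caches = [], []
        for m in self.mlps:
            if want_cache:
                o, c = m.forward(enc, want_cache=True)
                caches.append(c)
            else:
                o = m.forward(enc)
            outs.append(o[:, 0])
        w = np.stack(outs, axis=1)
        if want_cache:
            return w, caches
        return w

    def backward(self, caches, dw):
        """dw: (T, 9) -> list of per-sub-MLP gradient lists (concatenated)."""
        grads = []
        for i, (m, c) in enumerate(zip(self.mlps, caches)):
            g, _ = m.backward(c, dw[:, i].reshape(-1, 1))
            grads.extend(g)
        return grads

    def params(self):
        out = []
        for m in self.mlps:
            out.extend(m.params())
        return out
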