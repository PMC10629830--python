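"""Stacked single-hidden-layer spatiotemporal prediction networks.

Each *stack* is a three-layer convolutional network: an input layer, a
hidden layer of ``J`` convolutional units with rectified-linear activation,

    H_j = relu(b_j + sum_i U_i * W_ji),            (strided, valid)

and a linear prediction head with kernels of temporal depth one,

    Vhat_k = c_k + sum_j H_j * M_kj,

trained so that Vhat matches the input one time-step into the future. When
the hidden layer is spatially strided (stack 1), the head operates on the
zero-dilated hidden activity — a fractionally-strided convolution — so that
the prediction regains the input's spatial size. Stacks are trained
greedily, bottom-up: the hidden activity of a trained stack is the input of
the next, and gradients never cross stack boundaries.

The loss for one stack is

    E = mean((Vhat - V)^2) + lambda * (sum|W| + sum|M|),

minimised with Adam (beta1=0.9, beta2=0.999) on minibatches of 32 clips.
All gradients are computed by hand-written backpropagation through the two
convolution primitives in :mod:`predstack.conv`; the implementation is pure
numpy and is validated against numerical differentiation in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conv import (
    conv3d,
    conv3d_grad_w,
    conv_output_shape,
    conv_transpose3d,
    conv_transpose3d_grad_h,
    conv_transpose3d_grad_m,
    conv_windows,
)

__all__ = [
    "StackSpec",
    "StackWeights",
    "PredictionLoss",
    "HierarchicalModel",
    "TrainingDivergence",
    "hidden_layer_shape",
    "receptive_extent",
    "conv_forward",
    "predict_future",
    "future_target",
    "prediction_loss",
    "init_weights",
    "Adam",
    "PredictionObjective",
    "train_stack",
    "train_hierarchy",
    "full_scale_specs",
    "miniature_specs",
]


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log


@dataclass(frozen=True)
class StackSpec:
    """Architecture of one stack.

    ``input_shape`` is (Y, X, T, I); ``kernel`` is (ky, kx, kt); ``stride``
    is (sy, sx, st). The prediction head always has as many output channels
    as there are input channels and temporal depth one.
    """

    index: int
    input_shape: tuple
    conv_units: int
    kernel: tuple
    stride: tuple = (1, 1, 1)
    learning_rate: float = 1e-4
    l1_strength: float = 1e-6

    def __post_init__(self):
        y, x, t, i = self.input_shape
        for name, n, k in zip("yxt", (y, x, t), self.kernel):
            if k > n:
                raise ValueError(
                    f"stack {self.index}: kernel exceeds input along {name!r} ({k} > {n})"
                )
        sy, sx, st = self.stride
        # the dilated head must regain the input size exactly
        if (y - self.kernel[0]) % sy or (x - self.kernel[1]) % sx:
            raise ValueError(
                f"stack {self.index}: spatial size minus kernel must be divisible "
                f"by the stride for the prediction head to match the input"
            )

    @property
    def in_channels(self):
        return self.input_shape[3]

    @property
    def out_channels(self):
        return self.in_channels

    @property
    def hidden_shape(self):
        yx_t = conv_output_shape(self.input_shape[:3], self.kernel, self.stride)
        return (*yx_t, self.conv_units)


@dataclass
class StackWeights:
    """Learned parameters of one stack.

    w : (J, I, ky, kx, kt) input kernels; b : (J,) hidden biases;
    m : (K, J, ky, kx) head kernels (temporal depth 1); c : (K,) head biases.
    """

    w: np.ndarray
    b: np.ndarray
    m: np.ndarray
    c: np.ndarray

    def check_finite(self):
        for name in ("w", "b", "m", "c"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in weights field {name!r}")

    def copy(self):
        return StackWeights(self.w.copy(), self.b.copy(), self.m.copy(), self.c.copy())


@dataclass
class PredictionLoss:
    mse_term: float
    l1_term: float

    @property
    def total(self):
        return self.mse_term + self.l1_term


def hidden_layer_shape(spec: StackSpec):
    """Hidden-layer shape (yh, xh, th, J) and the unit count yh*xh*J.

    The unit count multiplies the two spatial dimensions by the number of
    convolutional units; time is excluded (a unit replicated over time is
    still one unit).
    """
    shape = spec.hidden_shape
    yh, xh, th, j = shape
    if min(yh, xh, th) < 1:
        raise ValueError(f"stack {spec.index}: non-positive hidden dimension {shape}")
    return shape, yh * xh * j


def receptive_extent(specs):
    """Spatiotemporal extent (ey, ex, et) of a unit at the top listed stack.

    E_1 = kernel_1 and E_z = E_{z-1} + (kernel_z - 1) * prod(strides below),
    applied per axis.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one spec")
    ext = np.array(specs[0].kernel, dtype=int)
    jump = np.array(specs[0].stride, dtype=int)
    for spec in specs[1:]:
        ext = ext + (np.array(spec.kernel) - 1) * jump
        jump = jump * np.array(spec.stride)
    return tuple(int(e) for e in ext)


def init_weights(spec: StackSpec, rng) -> StackWeights:
    """Fan-in-scaled uniform initialization, zero biases."""
    j, i = spec.conv_units, spec.in_channels
    ky, kx, kt = spec.kernel
    lim_w = 1.0 / np.sqrt(i * ky * kx * kt)
    w = rng.uniform(-lim_w, lim_w, size=(j, i, ky, kx, kt))
    lim_m = 1.0 / np.sqrt(j * ky * kx)
    m = rng.uniform(-lim_m, lim_m, size=(spec.out_channels, j, ky, kx))
    return StackWeights(
        w=w,
        b=np.zeros(j),
        m=m,
        c=np.zeros(spec.out_channels),
    )


def _check_input(u, spec):
    expect = (spec.input_shape[0], spec.input_shape[1], spec.input_shape[2], spec.in_channels)
    got = u.shape[1:]
    for ax, (e, g) in enumerate(zip(expect, got)):
        if e != g:
            names = ("y", "x", "t", "channel")
            raise ValueError(
                f"stack {spec.index}: input axis {names[ax]!r} has size {g}, expected {e}"
            )


def conv_forward(u, spec: StackSpec, weights: StackWeights, windows=None,
                 return_pre=False):
    """Hidden activity H = relu(b + conv(U, W)) with the spec's stride.

    ``u`` is (n, y, x, t, i). Returns (n, yh, xh, th, j), all entries >= 0.
    """
    _check_input(u, spec)
    # conv3d expects (out_c, in_c, ...) which is exactly how w is stored: (j, i, ...)
    pre = conv3d(u, weights.w, spec.stride, windows=windows) + weights.b
    h = np.maximum(pre, 0.0)
    if return_pre:
        return h, pre
    return h


def predict_future(h, spec: StackSpec, weights: StackWeights):
    """Linear prediction head (fractionally-strided when the stride is > 1).

    Output spatial size is (yh-1)*sy + ky, which equals the input size for
    any spec accepted by :class:`StackSpec`. The temporal size equals the
    hidden temporal size; step t is the estimate of input frame t + kt.
    """
    vhat = conv_transpose3d(h, weights.m, spec.stride)
    return vhat + weights.c


def future_target(u, spec: StackSpec):
    """The prediction target: the input one step ahead of each window.

    The hidden window at time t spans input frames t .. t+kt-1, so the
    target of head step t is frame t+kt. The last hidden step has no
    target; callers compare ``predict_future(...)[..., :T-kt, :]`` with
    this array.
    """
    kt = spec.kernel[2]
    return u[:, :, :, kt:, :]


def prediction_loss(vhat, target, weights: StackWeights, lam) -> PredictionLoss:
    """Mean-squared prediction error plus L1 weight penalty.

    ``vhat`` and ``target`` must be congruent; the mse term is the mean over
    all compared elements, the l1 term is lambda * (sum|W| + sum|M|).
    """
    if vhat.shape != target.shape:
        raise ValueError(f"shape mismatch: {vhat.shape} vs {target.shape}")
    if not (np.all(np.isfinite(vhat)) and np.all(np.isfinite(target))):
        raise ValueError("non-finite values in prediction or target")
    mse = float(np.mean((vhat - target) ** 2))
    l1 = float(lam * (np.abs(weights.w).sum() + np.abs(weights.m).sum()))
    return PredictionLoss(mse_term=mse, l1_term=l1)


class Adam:
    """Adam optimizer over a dict of named arrays (beta1=0.9, beta2=0.999)."""

    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            m = self.m.setdefault(k, np.zeros_like(p))
            v = self.v.setdefault(k, np.zeros_like(p))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class PredictionObjective:
    """One-step-ahead prediction loss (the model's native objective)."""

    name = "prediction"
    uses_head = True

    def loss_and_grads(self, u, spec, weights, windows=None, rng=None):
        kt = spec.kernel[2]
        t_cmp = spec.input_shape[2] - kt
        if windows is None:
            windows = conv_windows(u, spec.kernel, spec.stride)
        h, pre = conv_forward(u, spec, weights, windows=windows, return_pre=True)
        vhat = predict_future(h, spec, weights)
        target = future_target(u, spec)
        vcmp = vhat[:, :, :, :t_cmp, :]
        resid = vcmp - target
        mse = float(np.mean(resid ** 2))
        lam = spec.l1_strength
        l1 = float(lam * (np.abs(weights.w).sum() + np.abs(weights.m).sum()))

        dvhat = np.zeros_like(vhat)
        dvhat[:, :, :, :t_cmp, :] = (2.0 / resid.size) * resid
        dc = dvhat.sum(axis=(0, 1, 2, 3))
        dm = conv_transpose3d_grad_m(h, dvhat, weights.m.shape[2:], spec.stride)
        dh = conv_transpose3d_grad_h(dvhat, weights.m, spec.stride, h.shape[1:3])
        dpre = dh * (pre > 0)
        db = dpre.sum(axis=(0, 1, 2, 3))
        dw = conv3d_grad_w(u, dpre, spec.kernel, spec.stride, windows=windows)
        dw += lam * np.sign(weights.w)
        dm += lam * np.sign(weights.m)
        terms = {"loss": mse + l1, "mse_term": mse, "l1_term": l1}
        return terms, {"w": dw, "b": db, "m": dm, "c": dc}

    def validation_score(self, u, spec, weights, batch=32):
        """Validation prediction error (the mse term only), batched."""
        kt = spec.kernel[2]
        t_cmp = spec.input_shape[2] - kt
        num = 0.0
        count = 0
        for lo in range(0, u.shape[0], batch):
            ub = u[lo : lo + batch]
            h = conv_forward(ub, spec, weights)
            vhat = predict_future(h, spec, weights)[:, :, :, :t_cmp, :]
            target = future_target(ub, spec)
            num += float(((vhat - target) ** 2).sum())
            count += vhat.size
        return num / count


_WINDOW_CACHE_LIMIT = 2 * 1024 ** 3  # bytes


def train_stack(
    train_u,
    spec: StackSpec,
    seed=0,
    objective=None,
    n_iter=1000,
    batch_size=32,
    val_u=None,
    val_every=1,
    val_window=50,
    init=None,
    dtype=np.float32,
):
    """Train one stack with Adam on minibatches.

    ``train_u``/``val_u`` are (n, y, x, t, i) arrays of clips (or of the
    hidden activity of the stack below). "Iterations" are optimizer update
    steps. The clip order is shuffled once and minibatches are contiguous
    slices of that order, with the batch sequence reshuffled every epoch;
    this lets the convolution windows of the whole training set be
    materialized a single time (when they fit in ``_WINDOW_CACHE_LIMIT``)
    and sliced by view thereafter. Training arithmetic runs in ``dtype``
    (float32 by default); the returned weights are float64.

    Returns ``(weights, log)``: the log records the training loss per
    iteration and the validation prediction error every ``val_every``
    iterations, and ``log['val_score']`` is the mean validation error over
    the final ``val_window`` evaluations.
    """
    if objective is None:
        objective = PredictionObjective()
    rng = np.random.default_rng(seed)
    weights = init.copy() if init is not None else init_weights(spec, rng)
    for name in ("w", "b", "m", "c"):
        setattr(weights, name, getattr(weights, name).astype(dtype))
    opt = Adam(spec.learning_rate)
    n = train_u.shape[0]
    order = rng.permutation(n)
    u_all = np.ascontiguousarray(train_u[order], dtype=dtype)
    if val_u is not None:
        val_u = val_u.astype(dtype)
    win_bytes = (
        n * np.prod(spec.hidden_shape[:3]) * spec.in_channels
        * np.prod(spec.kernel) * np.dtype(dtype).itemsize
    )
    win_all = (
        conv_windows(u_all, spec.kernel, spec.stride)
        if win_bytes <= _WINDOW_CACHE_LIMIT
        else None
    )
    take = min(batch_size, n)
    n_batches = max(1, n // take)
    batch_order = rng.permutation(n_batches)
    pos = 0
    log = {"iter": [], "train_loss": [], "train_terms": [], "val_mse": []}
    params = {"w": weights.w, "b": weights.b, "m": weights.m, "c": weights.c}
    if not objective.uses_head:
        params = {k: params[k] for k in ("w", "b")}
    for it in range(n_iter):
        if pos >= n_batches:
            batch_order = rng.permutation(n_batches)
            pos = 0
        lo = batch_order[pos] * take
        pos += 1
        ub = u_all[lo : lo + take]
        windows = (
            win_all[lo : lo + take]
            if win_all is not None
            else conv_windows(ub, spec.kernel, spec.stride)
        )
        terms, grads = objective.loss_and_grads(
            ub, spec, weights, windows=windows, rng=rng
        )
        if not np.isfinite(terms["loss"]):
            raise TrainingDivergence(
                f"stack {spec.index}: loss diverged at iteration {it}", log=log
            )
        opt.step(params, {k: grads[k] for k in params})
        log["iter"].append(it)
        log["train_loss"].append(float(terms["loss"]))
        log["train_terms"].append(
            {k: float(v) for k, v in terms.items() if k != "loss"}
        )
        if val_u is not None and it % val_every == 0:
            log["val_mse"].append(objective.validation_score(val_u, spec, weights))
    if log["val_mse"]:
        tail = log["val_mse"][-val_window:]
        log["val_score"] = float(np.mean(tail))
    for name in ("w", "b", "m", "c"):
        setattr(weights, name, getattr(weights, name).astype(np.float64))
    weights.check_finite()
    return weights, log


@dataclass
class HierarchicalModel:
    """An ordered set of trained stacks acting as one feedforward network."""

    specs: list
    weights: list
    logs: list = field(default_factory=list)
    objective: str = "prediction"

    def __post_init__(self):
        for lower, upper in zip(self.specs[:-1], self.specs[1:]):
            if lower.hidden_shape != upper.input_shape:
                raise ValueError(
                    f"stack {upper.index} input shape {upper.input_shape} does not "
                    f"match stack {lower.index} hidden shape {lower.hidden_shape}"
                )

    @property
    def n_stacks(self):
        return len(self.specs)

    def forward(self, u, n_stacks=None, return_all=False, batch=None):
        """Hidden activity after ``n_stacks`` stacks (default: all).

        ``u`` is (n, y, x, t, c) at the stack-1 input resolution. With
        ``return_all`` a list of per-stack hidden activities is returned.
        """
        if n_stacks is None:
            n_stacks = self.n_stacks
        outs = []
        h = u
        for spec, wts in zip(self.specs[:n_stacks], self.weights[:n_stacks]):
            if batch is None:
                h = _forward_free(h, spec, wts)
            else:
                h = np.concatenate(
                    [
                        _forward_free(h[lo : lo + batch], spec, wts)
                        for lo in range(0, h.shape[0], batch)
                    ]
                )
            outs.append(h)
        return outs if return_all else h


def _forward_free(u, spec, weights):
    """conv_forward without the input-shape check (any spatial/temporal size).

    Used to probe the trained network with stimuli whose size differs from
    the training clips; only kernel feasibility is required.
    """
    pre = conv3d(u, weights.w, spec.stride) + weights.b
    return np.maximum(pre, 0.0)


def respec(spec: StackSpec, **changes) -> StackSpec:
    from dataclasses import replace

    return replace(spec, **changes)


def train_hierarchy(
    train_clips,
    specs,
    seed=0,
    val_clips=None,
    lambda_grid=None,
    n_iter=1000,
    batch_size=32,
    objective_factory=None,
    val_window=50,
    val_every=1,
    dtype=np.float32,
):
    """Greedy bottom-up training of a hierarchy.

    ``train_clips`` is (n, y, x, t, 1). For stacks >= 2, if ``lambda_grid``
    is given (a list of L1 strengths), each candidate is trained and the one
    with the lowest validation prediction error (mean over the final
    ``val_window`` evaluations) is kept; stack 1 always uses its spec's
    l1_strength directly. Gradients never cross stack boundaries: each
    stack sees only the fixed hidden activity of the one below.
    """
    if objective_factory is None:
        objective_factory = lambda spec: PredictionObjective()  # noqa: E731
    u = train_clips
    uv = val_clips
    trained_w, logs = [], []
    for depth, spec in enumerate(specs):
        candidates = [spec]
        if lambda_grid is not None and depth > 0:
            candidates = [respec(spec, l1_strength=lam) for lam in lambda_grid]
        best = None
        for cand in candidates:
            wts, log = train_stack(
                u,
                cand,
                seed=seed + depth,
                objective=objective_factory(cand),
                n_iter=n_iter,
                batch_size=batch_size,
                val_u=uv,
                val_window=val_window,
                val_every=val_every,
                dtype=dtype,
            )
            score = log.get("val_score", log["train_loss"][-1])
            log["l1_strength"] = cand.l1_strength
            if best is None or score < best[0]:
                best = (score, cand, wts, log)
        _, spec_used, wts, log = best
        trained_w.append(wts)
        logs.append(log)
        specs = list(specs)
        specs[depth] = spec_used
        # hidden activity of this stack feeds the next one
        if depth + 1 < len(specs):
            u = _batched_hidden(u, spec_used, wts, batch_size)
            if uv is not None:
                uv = _batched_hidden(uv, spec_used, wts, batch_size)
    obj_name = objective_factory(specs[0]).name
    return HierarchicalModel(specs=list(specs), weights=trained_w, logs=logs,
                             objective=obj_name)


def _batched_hidden(u, spec, weights, batch):
    return np.concatenate(
        [
            conv_forward(u[lo : lo + batch], spec, weights)
            for lo in range(0, u.shape[0], max(1, batch))
        ]
    )


def full_scale_specs():
    """The four full-scale stack specifications used for natural movies.

    Stack 1 sees 181x181x20 single-channel clips with a 21x21x5 kernel and a
    (10, 10, 1) stride; stacks 2-4 use 3x3x5 kernels at stride 1 with 100,
    200 and 400 units. Learning rates are 1e-2 for stack 1 and 1e-4 above;
    L1 strengths default to 10^-4.5 (stack 1) and 10^-6 (above).
    """
    specs = []
    shape = (181, 181, 20, 1)
    units = (50, 100, 200, 400)
    for z, j in enumerate(units, start=1):
        if z == 1:
            spec = StackSpec(
                index=1,
                input_shape=shape,
                conv_units=j,
                kernel=(21, 21, 5),
                stride=(10, 10, 1),
                learning_rate=1e-2,
                l1_strength=10 ** -4.5,
            )
        else:
            spec = StackSpec(
                index=z,
                input_shape=shape,
                conv_units=j,
                kernel=(3, 3, 5),
                stride=(1, 1, 1),
                learning_rate=1e-4,
                l1_strength=1e-6,
            )
        specs.append(spec)
        shape = spec.hidden_shape
    return specs


def miniature_specs(side=64, clip_len=20, units=(8, 16)):
    """A two-stack miniature used throughout the tests and benchmarks.

    Same construction as the full model, scaled to 64x64 synthetic movies:
    stack 1 has a 16x16x4 kernel at stride (6, 6, 1) and stack 2 a 6x6x3
    kernel at stride 1. The stack-1 kernel is kept large enough (256
    pixels) that a Gabor fitted to an unstructured slice of that size
    rarely reaches the 0.4 correlation criterion, mirroring the 21x21
    kernels of the full model. Learning rates are scaled up for the short
    (hundreds of iterations) training runs the miniature is meant for.
    """
    s1 = StackSpec(
        index=1,
        input_shape=(side, side, clip_len, 1),
        conv_units=units[0],
        kernel=(16, 16, 4),
        stride=(6, 6, 1),
        learning_rate=1e-2,
        l1_strength=10 ** -4.5,
    )
    specs = [s1]
    shape = s1.hidden_shape
    for z, j in enumerate(units[1:], start=2):
        spec = StackSpec(
            index=z,
            input_shape=shape,
            conv_units=j,
            kernel=(6, 6, 3),
            stride=(1, 1, 1),
            learning_rate=1e-3,
            l1_strength=1e-6,
        )
        specs.append(spec)
        shape = spec.hidden_shape
    return specs
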