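"""Alternative training objectives and perturbation controls.

Three manipulations isolate what one-step-ahead prediction contributes to
learned tuning:

* a *sparse autoencoder* objective — the same architecture reconstructs the
  input at the current time-step instead of predicting the next one, with
  an L1 penalty on the hidden activity;
* a *slowness* objective — the hidden layer minimizes the mean-squared
  difference between consecutive time-steps of its (batch-normalized)
  activity while decorrelating channels, with no prediction head at all;
* *weight shuffling* — the entries of each trained input kernel are
  randomly permuted across space and time, preserving the value multiset
  but destroying its arrangement.

Frame shuffling of the training clips lives in
:func:`predstack.video.frame_shuffle`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conv import conv3d_grad_w, conv_transpose3d_grad_h, conv_transpose3d_grad_m, conv_windows
from .model import (
    HierarchicalModel,
    StackSpec,
    conv_forward,
    predict_future,
    train_hierarchy,
)

__all__ = [
    "SlownessLoss",
    "AutoencoderLoss",
    "slowness_loss",
    "autoencoder_loss",
    "SlownessObjective",
    "AutoencoderObjective",
    "shuffle_weights",
    "unshuffle_weights",
    "train_control_hierarchy",
]

_BN_EPS = 1e-5
_JITTER = 1e-4


@dataclass
class SlownessLoss:
    temporal_term: float
    decorrelation_term: float
    l1_weight_term: float

    @property
    def total(self):
        return self.temporal_term + self.decorrelation_term + self.l1_weight_term


@dataclass
class AutoencoderLoss:
    reconstruction_term: float
    activity_l1_term: float
    weight_l1_term: float

    @property
    def total(self):
        return self.reconstruction_term + self.activity_l1_term + self.weight_l1_term


def _batchnorm(h, eps=_BN_EPS):
    """Normalize each channel over the batch and all positions/time-steps."""
    mu = h.mean(axis=(0, 1, 2, 3), keepdims=True)
    var = h.var(axis=(0, 1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    return (h - mu) * inv, inv


def slowness_loss(h, w, lam, rng=None, jitter=_JITTER, batchnorm=True):
    """Evaluate the slowness cost on hidden activity ``h`` (n, yh, xh, th, j).

    temporal_term: mean squared difference between consecutive time-steps,
    normalized by n * j * yh * xh * (th - 1). decorrelation_term: mean
    absolute Pearson correlation (over flattened space-time, per clip)
    across all unordered channel pairs, normalized by 2 / (n * j * (j-1)).
    A small uniform jitter on (0, 1e-4) is added before the correlations to
    avoid zero-variance division. ``w`` enters only through lam * sum|w|.
    """
    n, yh, xh, th, j = h.shape
    if j < 2:
        raise ValueError("decorrelation term needs at least 2 channels")
    if rng is None:
        rng = np.random.default_rng(0)
    hn = _batchnorm(h)[0] if batchnorm else h
    dif = np.diff(hn, axis=3)
    temporal = float((dif ** 2).sum() / (n * j * yh * xh * (th - 1)))
    z = hn + rng.uniform(0.0, jitter, size=hn.shape)
    z = z.transpose(0, 4, 1, 2, 3).reshape(n, j, -1)
    z = z - z.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(z, axis=2, keepdims=True)
    c = z / norms
    decor = 0.0
    for ni in range(n):
        r = c[ni] @ c[ni].T
        decor += np.abs(r[np.triu_indices(j, k=1)]).sum()
    decor = float(2.0 * decor / (n * j * (j - 1)))
    l1 = float(lam * np.abs(w).sum())
    return SlownessLoss(temporal, decor, l1)


def autoencoder_loss(uhat, u_now, h, w, m, lam1, lam2):
    """Evaluate the sparse-autoencoder cost.

    ``uhat`` is the head output aligned with ``u_now`` (the input at the
    current time-step of each window). reconstruction_term is the mean
    squared error; activity_l1_term is lam1 * mean|H|; weight_l1_term is
    lam2 * (sum|W| + sum|M|).
    """
    if uhat.shape != u_now.shape:
        raise ValueError(f"shape mismatch: {uhat.shape} vs {u_now.shape}")
    if not (np.all(np.isfinite(uhat)) and np.all(np.isfinite(u_now))):
        raise ValueError("non-finite values in reconstruction or target")
    rec = float(np.mean((uhat - u_now) ** 2))
    act = float(lam1 * np.mean(np.abs(h)))
    wt = float(lam2 * (np.abs(w).sum() + np.abs(m).sum()))
    return AutoencoderLoss(rec, act, wt)


class AutoencoderObjective:
    """Reconstruct the current input with sparse hidden activity.

    Head step t estimates input frame t + kt - 1 (the most recent frame of
    its window), so every hidden step has a target.
    """

    name = "autoencoder"
    uses_head = True

    def __init__(self, lam1=1e-4):
        self.lam1 = lam1

    def _target(self, u, spec):
        kt = spec.kernel[2]
        return u[:, :, :, kt - 1 :, :]

    def loss_and_grads(self, u, spec, weights, windows=None, rng=None):
        if windows is None:
            windows = conv_windows(u, spec.kernel, spec.stride)
        h, pre = conv_forward(u, spec, weights, windows=windows, return_pre=True)
        uhat = predict_future(h, spec, weights)
        target = self._target(u, spec)
        resid = uhat - target
        lam1, lam2 = self.lam1, spec.l1_strength
        loss = autoencoder_loss(uhat, target, h, weights.w, weights.m, lam1, lam2)

        dv = (2.0 / resid.size) * resid
        dc = dv.sum(axis=(0, 1, 2, 3))
        dm = conv_transpose3d_grad_m(h, dv, weights.m.shape[2:], spec.stride)
        dh = conv_transpose3d_grad_h(dv, weights.m, spec.stride, h.shape[1:3])
        dh += (lam1 / h.size) * np.sign(h)
        dpre = dh * (pre > 0)
        db = dpre.sum(axis=(0, 1, 2, 3))
        dw = conv3d_grad_w(u, dpre, spec.kernel, spec.stride, windows=windows)
        dw += lam2 * np.sign(weights.w)
        dm += lam2 * np.sign(weights.m)
        terms = {
            "loss": loss.total,
            "reconstruction_term": loss.reconstruction_term,
            "activity_l1_term": loss.activity_l1_term,
            "weight_l1_term": loss.weight_l1_term,
        }
        return terms, {"w": dw, "b": db, "m": dm, "c": dc}

    def validation_score(self, u, spec, weights, batch=32):
        num, count = 0.0, 0
        for lo in range(0, u.shape[0], batch):
            ub = u[lo : lo + batch]
            h = conv_forward(ub, spec, weights)
            uhat = predict_future(h, spec, weights)
            target = self._target(ub, spec)
            num += float(((uhat - target) ** 2).sum())
            count += uhat.size
        return num / count


class SlownessObjective:
    """Slowly varying, decorrelated hidden activity; no prediction head."""

    name = "slowness"
    uses_head = False

    def __init__(self, jitter=_JITTER):
        self.jitter = jitter

    def loss_and_grads(self, u, spec, weights, windows=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        if windows is None:
            windows = conv_windows(u, spec.kernel, spec.stride)
        h, pre = conv_forward(u, spec, weights, windows=windows, return_pre=True)
        n, yh, xh, th, j = h.shape
        if j < 2:
            raise ValueError("decorrelation term needs at least 2 channels")
        lam = spec.l1_strength

        mu = h.mean(axis=(0, 1, 2, 3), keepdims=True)
        var = h.var(axis=(0, 1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        hn = (h - mu) * inv

        # --- temporal smoothness term ---
        dif = np.diff(hn, axis=3)
        denom_t = n * j * yh * xh * (th - 1)
        temporal = float((dif ** 2).sum() / denom_t)
        dhn = np.zeros_like(hn)
        g = (2.0 / denom_t) * dif
        dhn[:, :, :, 1:, :] += g
        dhn[:, :, :, :-1, :] -= g

        # --- decorrelation term (unit-normalized rows -> Pearson) ---
        z = hn + rng.uniform(0.0, self.jitter, size=hn.shape)
        zf = z.transpose(0, 4, 1, 2, 3).reshape(n, j, -1)
        zc = zf - zf.mean(axis=2, keepdims=True)
        norms = np.linalg.norm(zc, axis=2, keepdims=True)
        c = zc / norms
        coef = 2.0 / (n * j * (j - 1))
        decor = 0.0
        dzf = np.empty_like(zf)
        for ni in range(n):
            r = c[ni] @ c[ni].T
            decor += np.abs(r[np.triu_indices(j, k=1)]).sum()
            s = np.sign(r)
            np.fill_diagonal(s, 0.0)
            dc_rows = coef * (s @ c[ni])
            # back through row normalization then centering
            dz = (dc_rows - c[ni] * (c[ni] * dc_rows).sum(axis=1, keepdims=True))
            dz /= norms[ni]
            dz -= dz.mean(axis=1, keepdims=True)
            dzf[ni] = dz
        decor = float(coef * decor)
        dhn += dzf.reshape(n, j, yh, xh, th).transpose(0, 2, 3, 4, 1)

        # --- batchnorm backward (per channel over batch/space/time) ---
        cnt = n * yh * xh * th
        mean_d = dhn.mean(axis=(0, 1, 2, 3), keepdims=True)
        mean_dh = (dhn * hn).mean(axis=(0, 1, 2, 3), keepdims=True)
        dh = inv * (dhn - mean_d - hn * mean_dh)

        dpre = dh * (pre > 0)
        db = dpre.sum(axis=(0, 1, 2, 3))
        dw = conv3d_grad_w(u, dpre, spec.kernel, spec.stride, windows=windows)
        dw += lam * np.sign(weights.w)
        l1 = float(lam * np.abs(weights.w).sum())
        terms = {
            "loss": temporal + decor + l1,
            "temporal_term": temporal,
            "decorrelation_term": decor,
            "l1_weight_term": l1,
        }
        return terms, {"w": dw, "b": db}

    def validation_score(self, u, spec, weights, batch=32):
        scores = []
        for lo in range(0, u.shape[0], batch):
            h = conv_forward(u[lo : lo + batch], spec, weights)
            loss = slowness_loss(h, weights.w, 0.0,
                                 rng=np.random.default_rng(0), jitter=self.jitter)
            scores.append(loss.temporal_term + loss.decorrelation_term)
        return float(np.mean(scores))


def shuffle_weights(model: HierarchicalModel, seed=0):
    """Permute each input kernel's entries across space and time.

    Returns ``(shuffled_model, permutations)``; biases and head kernels are
    untouched and the multiset of weight values is preserved exactly.
    ``permutations[z][j, i]`` records the flat permutation applied to the
    (j, i) kernel of stack z, so the perturbation can be undone with
    :func:`unshuffle_weights`.
    """
    rng = np.random.default_rng(seed)
    new_weights, perms = [], []
    for wts in model.weights:
        w = wts.w.copy()
        j, i = w.shape[:2]
        ksize = w[0, 0].size
        stack_perms = np.empty((j, i, ksize), dtype=np.intp)
        for jj in range(j):
            for ii in range(i):
                perm = rng.permutation(ksize)
                stack_perms[jj, ii] = perm
                w[jj, ii] = w[jj, ii].ravel()[perm].reshape(w[jj, ii].shape)
        perms.append(stack_perms)
        new = wts.copy()
        new.w = w
        new_weights.append(new)
    shuffled = HierarchicalModel(
        specs=list(model.specs), weights=new_weights, logs=list(model.logs),
        objective=model.objective,
    )
    return shuffled, perms


def unshuffle_weights(model: HierarchicalModel, perms):
    """Invert :func:`shuffle_weights` given its recorded permutations."""
    new_weights = []
    for wts, stack_perms in zip(model.weights, perms):
        w = wts.w.copy()
        j, i = w.shape[:2]
        for jj in range(j):
            for ii in range(i):
                inv = np.argsort(stack_perms[jj, ii])
                w[jj, ii] = w[jj, ii].ravel()[inv].reshape(w[jj, ii].shape)
        new = wts.copy()
        new.w = w
        new_weights.append(new)
    return HierarchicalModel(
        specs=list(model.specs), weights=new_weights, logs=list(model.logs),
        objective=model.objective,
    )


def train_control_hierarchy(
    train_clips,
    specs,
    objective="slowness",
    seed=0,
    val_clips=None,
    n_iter=1000,
    batch_size=32,
    lam1=1e-4,
):
    """Train a hierarchy with the plumbing of the standard model but a
    control objective swapped in (``"slowness"`` or ``"autoencoder"``).

    The control objectives cannot rank L1 strengths by prediction error, so
    each spec's own l1_strength is used directly (no grid search).
    """
    if objective == "slowness":
        factory = lambda spec: SlownessObjective()  # noqa: E731
    elif objective == "autoencoder":
        factory = lambda spec: AutoencoderObjective(lam1=lam1)  # noqa: E731
    else:
        raise ValueError(f"unknown control objective {objective!r}")
    return train_hierarchy(
        train_clips,
        specs,
        seed=seed,
        val_clips=val_clips,
        lambda_grid=None,
        n_iter=n_iter,
        batch_size=batch_size,
        objective_factory=factory,
    )
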