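"""Desk-scale benchmark study: a two-stack miniature on synthetic movies.

The full-scale model trains on ~1305 clips of 181x181 wildlife footage for
1000 iterations per stack; that is out of reach for a test suite, so the
package defines one fixed miniature study whose conditions are used by the
test-suite and the reproduction script alike:

* movies: 60 synthetic 64x64x20 clips of 1/f-textured rigid translation
  (every clip moves; per-component speeds up to 3 px/frame, 30% of clips
  pan horizontally only), split 90/10 into train/validation;
* model: two stacks with 8 and 16 convolutional units (16x16x4 kernel,
  stride (6,6,1), then 6x6x3 at stride 1), trained 300 iterations per
  stack with the standard optimizer settings (Adam, minibatch 32).

The natural yardstick for one-step prediction on translating movies is the
copy-last-frame baseline; rigid motion makes it beatable, and a trained
stack should land below it.
"""

from __future__ import annotations

import numpy as np

from .model import future_target, miniature_specs, train_hierarchy, train_stack
from .video import frame_shuffle, split_train_validation, synth_movies

__all__ = [
    "benchmark_clips",
    "train_benchmark_model",
    "train_frame_shuffled_stack1",
    "copy_last_baseline",
    "BENCH_N_CLIPS",
    "BENCH_SIDE",
    "BENCH_ITERS",
]

BENCH_N_CLIPS = 60
BENCH_SIDE = 64
BENCH_ITERS = 300


def benchmark_clips(seed=0, n_clips=BENCH_N_CLIPS):
    """The miniature study's movies: all-translating synthetic clips."""
    cs = synth_movies(n_clips, seed=seed, side=BENCH_SIDE, frac_static=0.0)
    return split_train_validation(cs, seed=seed)


def train_benchmark_model(seed=0, n_iter=BENCH_ITERS, clips=None):
    """Train the two-stack miniature; returns (model, train_u, val_u)."""
    cs = clips if clips is not None else benchmark_clips(seed=seed)
    tr = cs.subset("train").to_array()
    va = cs.subset("validation").to_array()
    specs = miniature_specs(side=BENCH_SIDE)
    model = train_hierarchy(tr, specs, seed=seed, val_clips=va, n_iter=n_iter,
                            val_every=5)
    return model, tr, va


def train_frame_shuffled_stack1(seed=0, n_iter=BENCH_ITERS, clips=None):
    """Stack 1 trained on the same movies with frame order shuffled."""
    cs = clips if clips is not None else benchmark_clips(seed=seed)
    fs = frame_shuffle(cs, seed=seed)
    tr = fs.subset("train").to_array()
    va = fs.subset("validation").to_array()
    spec = miniature_specs(side=BENCH_SIDE)[0]
    weights, log = train_stack(tr, spec, seed=seed, n_iter=n_iter, val_u=va,
                               val_every=10)
    return weights, log


def copy_last_baseline(u, spec):
    """One-step prediction error of simply repeating the last seen frame."""
    kt = spec.kernel[2]
    target = future_target(u, spec)
    return float(np.mean((u[:, :, :, kt - 1 : -1, :] - target) ** 2))
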