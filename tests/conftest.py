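"""Shared fixtures: the trained miniature model and its characterization.

These are session-scoped because training the two-stack miniature and
running the grating protocol are the expensive steps shared by several
qualitative tests.
"""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the handbuilt helpers


@pytest.fixture(scope="session")
def bench_clips():
    from predstack.benchmark import benchmark_clips

    return benchmark_clips(seed=0)


@pytest.fixture(scope="session")
def bench_model(bench_clips):
    from predstack.benchmark import train_benchmark_model

    model, tr, va = train_benchmark_model(seed=0, clips=bench_clips)
    return {"model": model, "train": tr, "val": va}


@pytest.fixture(scope="session")
def bench_frame_shuffled(bench_clips):
    from predstack.benchmark import train_frame_shuffled_stack1

    weights, log = train_frame_shuffled_stack1(seed=0, clips=bench_clips)
    return weights


@pytest.fixture(scope="session")
def bench_characterization(bench_model):
    from predstack.physiology import characterize_stack

    model = bench_model["model"]
    return {z: characterize_stack(model, z, seed=0) for z in (1, 2)}
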