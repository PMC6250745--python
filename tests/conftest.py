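"""Shared fixtures: the synthetic tracking benchmark and calibrated models.

The benchmark conditions used across the suite: the 30x56 hardware
worked-example network with a 15x15 connection field, beta/k = 100, 15
iterations per difference frame, and default synthetic scenes (120x224
native frames, 16-px bright square moving at (2.0, 0.7) px/frame over a
noisy background, seeds 1-3).
"""

from __future__ import annotations

import numpy as np
import pytest

from canntrack import (
    SyntheticSceneConfig,
    generate_synthetic_video,
    plan_full_mapping,
)
from canntrack.cli import (
    RunConfig,
    _prepare,
    _seed_for_box,
    build_quantized_pipeline,
)

BENCHMARK_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def bench_cfg() -> RunConfig:
    return RunConfig(grid_height=30, grid_width=56)


@pytest.fixture(scope="session")
def bench_video():
    return generate_synthetic_video(SyntheticSceneConfig(seed=1))


@pytest.fixture(scope="session")
def bench_setup(bench_cfg, bench_video):
    """Stimuli, initial state, placement and sliced pipeline for seed 1."""
    seq, gt = bench_video
    stimuli, scale = _prepare(bench_cfg, seq.frames)
    state0 = _seed_for_box(bench_cfg, tuple(gt.boxes[0]), scale)
    placement = plan_full_mapping(bench_cfg.grid(), bench_cfg.kernel(),
                                  bench_cfg.constraints())
    pipeline = build_quantized_pipeline(
        bench_cfg, stimuli, state0, placement.slice_plan.col_slices)
    return {
        "stimuli": stimuli,
        "scale": scale,
        "state0": state0,
        "placement": placement,
        "pipeline": pipeline,
        "gt": gt,
        "frames": seq.frames,
    }


@pytest.fixture(scope="session")
def unsliced_pipeline(bench_cfg, bench_setup):
    """Single-slice pipeline (same calibration path, no column partition)."""
    return build_quantized_pipeline(
        bench_cfg, bench_setup["stimuli"], bench_setup["state0"])


@pytest.fixture(scope="session")
def benchmark_argmax_agreement(bench_cfg):
    """(n_agree, n_frames) of quantized-vs-float argmax over the benchmark
    scenes (seeds 1-3), using the sliced hardware pipeline."""
    from canntrack.core import build_interaction_kernel, run_frame

    stencil = build_interaction_kernel(bench_cfg.grid(), bench_cfg.kernel())
    placement = plan_full_mapping(bench_cfg.grid(), bench_cfg.kernel(),
                                  bench_cfg.constraints())
    agree = total = 0
    for seed in BENCHMARK_SEEDS:
        seq, gt = generate_synthetic_video(SyntheticSceneConfig(seed=seed))
        stimuli, scale = _prepare(bench_cfg, seq.frames)
        state0 = _seed_for_box(bench_cfg, tuple(gt.boxes[0]), scale)
        pipe = build_quantized_pipeline(bench_cfg, stimuli, state0,
                                        placement.slice_plan.col_slices)
        st = state0
        r_int = pipe.quantize_rate(st.r)
        for stim in stimuli:
            st = run_frame(st, stim, bench_cfg.params(), stencil)
            r_int = pipe.run_frame(r_int, pipe.quantize_stimulus(stim))
            agree += int(np.argmax(st.r) == np.argmax(r_int))
            total += 1
    return agree, total
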