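"""Fixed-point pipeline: scaling chain rule, LUTs, calibration, fidelity."""

import numpy as np
import pytest
from dataclasses import replace

from canntrack.cli import RunConfig, build_quantized_pipeline
from canntrack.core import build_interaction_kernel, run_frame
from canntrack.errors import CalibrationError, ScalingError
from canntrack.quantizer import (
    CalibrationStats,
    FixedPointSpec,
    QuantizedPipeline,
    ScalingChain,
    build_inhibition_lut,
    propagate_scaling,
    quantize_array,
    solve_feedback_scaling,
    trace_scaling_ratio,
)

SPEC8 = FixedPointSpec()


class TestQuantizeArray:
    def test_clipping_to_signed_range(self):
        assert quantize_array(200.0, 1.0, 8) == 127
        assert quantize_array(-200.0, 1.0, 8) == -128

    def test_integers_pass_through(self):
        x = np.array([-5, 0, 3, 100])
        assert np.array_equal(quantize_array(x, 1.0, 8), x)

    def test_rounding_half_away_from_zero(self):
        assert quantize_array(0.005, 100.0, 8) == 1
        assert quantize_array(-0.005, 100.0, 8) == -1

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ScalingError):
            quantize_array(1.0, 0.0, 8)


class TestScalingChainRule:
    def test_multiply_rule(self):
        assert propagate_scaling(4.0, 8.0, 2.0, "multiply") == 16.0

    def test_identity(self):
        assert propagate_scaling(1.0, 1.0, 1.0, "multiply") == 1.0

    def test_add_requires_matching_scales(self):
        assert propagate_scaling(6.0, 6.0, 3.0, "add") == 2.0
        with pytest.raises(ScalingError):
            propagate_scaling(6.0, 7.0, 1.0, "add")


class TestInhibitionLut:
    LUT = build_inhibition_lut(k=0.5, rho_sum=2.0, rho_s=50.0, spec=SPEC8)

    def test_zero_entry_is_zero(self):
        assert self.LUT[0] == 0

    def test_monotone_non_increasing(self):
        assert np.all(np.diff(self.LUT[1:]) <= 0)

    def test_small_indices_saturate_at_output_max(self):
        # 50 / (0.5 * i/2) saturates 8-bit output for small i
        assert self.LUT[1] == 127

    def test_entries_match_reciprocal(self):
        i = 100
        expect = round(50.0 / (0.5 * (i / 2.0)))
        assert self.LUT[i] == expect


def _toy_stats(**over):
    base = dict(max_r=0.1, max_V1=60.0, max_partial=40.0, max_stim=30.0,
                max_V=80.0, max_V2=6400.0, max_sum=50000.0, max_s=3e-4,
                max_weight=50.0)
    base.update(over)
    return CalibrationStats(**base)


class TestFeedbackScaling:
    def test_loop_closes_exactly(self):
        from canntrack.core import DynamicsParams

        chain = solve_feedback_scaling(SPEC8, DynamicsParams(beta=50, k=0.5),
                                       _toy_stats())
        assert chain.closure_residual() == 0.0

    def test_doubled_range_doubles_truncation_factor(self):
        """A calibration range 2x wider needs exactly one more halving in the
        stage's equivalent scaling factor rho_F = 2**f / alpha (an extra
        right-shift once the LUT index range is exhausted)."""
        from canntrack.core import DynamicsParams

        p = DynamicsParams(beta=50, k=0.5)
        c1 = solve_feedback_scaling(SPEC8, p, _toy_stats())
        c2 = solve_feedback_scaling(SPEC8, p, _toy_stats(max_V=160.0))
        rho_F1 = c1.rho_V1 / c1.rho_V
        rho_F2 = c2.rho_V1 / c2.rho_V
        assert rho_F2 == pytest.approx(2.0 * rho_F1, rel=1e-12)
        # and once the 10-bit index span is exhausted the shift itself grows
        c3 = solve_feedback_scaling(SPEC8, p, _toy_stats(max_V=300.0))
        c4 = solve_feedback_scaling(SPEC8, p, _toy_stats(max_V=600.0))
        assert c4.shifts[1] == c3.shifts[1] + 1

    def test_degenerate_calibration_rejected(self):
        from canntrack.core import DynamicsParams

        with pytest.raises(CalibrationError):
            solve_feedback_scaling(SPEC8, DynamicsParams(beta=50, k=0.5),
                                   _toy_stats(max_r=0.0))

    def test_json_round_trip(self):
        from canntrack.core import DynamicsParams

        chain = solve_feedback_scaling(SPEC8, DynamicsParams(beta=50, k=0.5),
                                       _toy_stats())
        back = ScalingChain.from_json(chain.to_json())
        assert back.shifts == chain.shifts
        assert back.rho_r == chain.rho_r
        assert np.array_equal(back.inhib_lut, chain.inhib_lut)


class TestPipelineBehavior:
    def test_zero_state_and_stimulus_stay_zero(self, bench_cfg, unsliced_pipeline):
        z = np.zeros(bench_cfg.grid().shape, dtype=np.int64)
        r, aux = unsliced_pipeline.quantized_step(z, z)
        assert np.all(r == 0) and aux["s"] == 0

    def test_single_step_tracks_float_within_lsb_budget(
            self, bench_cfg, bench_setup, unsliced_pipeline):
        """De-quantized one-step output matches the float step to within a
        few LSB of accumulated per-operation rounding."""
        pipe = unsliced_pipeline
        st = bench_setup["state0"]
        stim = bench_setup["stimuli"][0]
        stencil = build_interaction_kernel(bench_cfg.grid(), bench_cfg.kernel())
        float_next = run_frame(st, stim, bench_cfg.params(), stencil)
        r_int = pipe.quantize_rate(st.r)
        r_int = pipe.run_frame(r_int, pipe.quantize_stimulus(stim))
        err = np.abs(r_int - pipe.chain.rho_r * float_next.r).max()
        assert err <= 6.0  # LSB on the integer rate scale

    def test_dequantized_ratio_bounded_no_drift(
            self, bench_cfg, bench_setup, unsliced_pipeline):
        pipe = unsliced_pipeline
        st = bench_setup["state0"]
        stencil = build_interaction_kernel(bench_cfg.grid(), bench_cfg.kernel())
        r_int = pipe.quantize_rate(st.r)
        floats, ints = [], []
        for stim in bench_setup["stimuli"][:10]:
            st = run_frame(st, stim, bench_cfg.params(), stencil)
            r_int = pipe.run_frame(r_int, pipe.quantize_stimulus(stim))
            floats.append(st.r)
            ints.append(r_int)
        rep = trace_scaling_ratio(floats, ints, pipe.chain)
        assert rep["max_deviation"] < 0.2

    def test_broken_chain_diverges_geometrically(self, bench_cfg, bench_setup):
        """Negative control: one truncation factor off by 2x destroys the
        constant-scaling restriction and the rate mass collapses."""
        good = bench_setup["pipeline"].chain
        bad_shifts = list(good.shifts)
        bad_shifts[4] += 1  # rho_F doubled at the firing-rate step
        bad = replace(good, shifts=tuple(bad_shifts))
        pipe = QuantizedPipeline(bench_cfg.grid(), bench_cfg.kernel(),
                                 bench_cfg.params(), bad)
        st = bench_setup["state0"]
        stencil = build_interaction_kernel(bench_cfg.grid(), bench_cfg.kernel())
        r_int = pipe.quantize_rate(st.r)
        floats, ints = [], []
        for stim in bench_setup["stimuli"][:5]:
            st = run_frame(st, stim, bench_cfg.params(), stencil)
            r_int = pipe.run_frame(r_int, pipe.quantize_stimulus(stim))
            floats.append(st.r)
            ints.append(r_int)
        rep = trace_scaling_ratio(floats, ints, bad)
        assert rep["ratios"][-1] < 0.1  # healthy chains stay within 20%

    def test_no_explosion_or_vanishing_200_iterations(
            self, bench_cfg, bench_setup, unsliced_pipeline):
        pipe = unsliced_pipeline
        r = pipe.quantize_rate(bench_setup["state0"].r)
        zero = np.zeros(bench_cfg.grid().shape, dtype=np.int64)
        init = np.abs(r).sum()
        for _ in range(200):
            r, _ = pipe.quantized_step(r, zero)
            mass = np.abs(r).sum()
            assert 0.5 * init <= mass <= 2.0 * init

    def test_saturation_below_one_percent(self, bench_setup):
        pipe = bench_setup["pipeline"]
        r = pipe.quantize_rate(bench_setup["state0"].r)
        for stim in bench_setup["stimuli"][:5]:
            r = pipe.run_frame(r, pipe.quantize_stimulus(stim))
        for step, rate in pipe.saturation_rates().items():
            assert rate < 0.01, step

    def test_wider_words_never_degrade(self, bench_cfg, bench_setup):
        """Mean |r_int/rho_r - r_float| is non-increasing as the I/O width
        grows 8 -> 12 -> 16 bits."""
        stencil = build_interaction_kernel(bench_cfg.grid(), bench_cfg.kernel())
        errs = []
        for io, lut_in in [(8, 10), (12, 14), (16, 18)]:
            cfg = RunConfig(grid_height=30, grid_width=56, io_bits=io,
                            accum_bits=40, lut_in_bits=lut_in, lut_out_bits=io)
            pipe = build_quantized_pipeline(cfg, bench_setup["stimuli"],
                                            bench_setup["state0"])
            st = bench_setup["state0"]
            r_int = pipe.quantize_rate(st.r)
            tot = 0.0
            for stim in bench_setup["stimuli"][:5]:
                st = run_frame(st, stim, cfg.params(), stencil)
                r_int = pipe.run_frame(r_int, pipe.quantize_stimulus(stim))
                tot += np.abs(r_int / pipe.chain.rho_r - st.r).mean()
            errs.append(tot)
        assert errs[0] >= errs[1] >= errs[2]

    def test_quantized_argmax_matches_float_on_benchmark(
            self, benchmark_argmax_agreement):
        """Per-frame argmax of the sliced integer pipeline matches the float
        model on at least 90% of the synthetic benchmark frames."""
        agree, total = benchmark_argmax_agreement
        assert agree / total >= 0.9
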