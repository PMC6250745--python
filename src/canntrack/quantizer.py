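"""Fixed-point emulation of the five-step pipeline with a scaling chain rule.

Integer hardware cannot carry floating-point state, so every signal s is
represented by an integer ``round(rho_s * s)`` with a per-signal scaling
factor rho.  Scales propagate through the pipeline by a chain rule:
products multiply scales, sums require equal operand scales, and each
truncation / LUT stage divides by its equivalent factor rho_F (realized
here as arithmetic right-shifts, i.e. powers of two).  Because the firing
rate feeds back into the next iteration, the composed scale around the
recurrent loop must equal exactly 1 (constant-scaling restriction) —
otherwise the integer state explodes or vanishes geometrically.

The five execution steps of one iteration:

    1. recurrent input   V1 = sum_CF (beta*J) r        (VMM, per column slice)
    2. membrane potential V = ReLU(sum partials + V_ext)  (VVA + ReLU LUT)
    3. potential squared  V2 = V * V                    (VVM)
    4. inhibition factor  s = 1 / (k * sum V2)          (VVA + Lat_Acc + nonlinear LUT)
    5. firing rate        r = V2 * s                    (VS)

Accumulation is wide (24-bit by default); results are truncated to a
10-bit LUT index and the LUT emits 8-bit outputs.  beta is folded into the
stored weights and k into the inhibition LUT, so neither has a standalone
integer representation.

Hardware sums 8-bit *partial* potentials (one per contributing column
slice) in step 2, so the reference pipeline truncates each slice's partial
before summing; the column partition is therefore part of the quantized
model (a single slice covering the grid reproduces the unsliced variant).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import correlate

from .core import (
    DynamicsParams,
    GridSpec,
    KernelSpec,
    NetworkState,
    build_interaction_kernel,
    firing_rate,
    recurrent_input,
)
from .errors import (
    AccumulatorOverflowError,
    CalibrationError,
    ConfigurationError,
    ScalingError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FixedPointSpec",
    "ScalingChain",
    "CalibrationStats",
    "quantize_array",
    "propagate_scaling",
    "build_inhibition_lut",
    "calibrate_float_ranges",
    "solve_feedback_scaling",
    "QuantizedPipeline",
    "trace_scaling_ratio",
]


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedPointSpec:
    """Bit widths of the fixed-point datapath (defaults: 8/24/10/8)."""

    io_bits: int = 8
    accum_bits: int = 24
    lut_in_bits: int = 10
    lut_out_bits: int = 8

    def __post_init__(self) -> None:
        if not (self.io_bits <= self.lut_in_bits <= self.accum_bits):
            raise ConfigurationError("need io_bits <= lut_in_bits <= accum_bits")

    @property
    def io_max(self) -> int:
        return 2 ** (self.io_bits - 1) - 1

    @property
    def io_min(self) -> int:
        return -(2 ** (self.io_bits - 1))

    @property
    def accum_limit(self) -> int:
        return 2 ** (self.accum_bits - 1)

    @property
    def lut_idx_max(self) -> int:
        """Signed LUT index ceiling."""
        return 2 ** (self.lut_in_bits - 1) - 1

    @property
    def lut_idx_min(self) -> int:
        return -(2 ** (self.lut_in_bits - 1))

    @property
    def lut_size(self) -> int:
        return 2**self.lut_in_bits


@dataclass
class ScalingChain:
    """Solved per-signal scales, per-step right-shifts, and LUT gains.

    Each truncation/LUT stage has an equivalent scaling factor
    ``rho_F = 2**f / alpha``: the power-of-two part is the arithmetic
    right-shift of the wide accumulator down to the LUT index, and the
    non-power-of-two remainder ``alpha`` (in (0, 1]) is folded into the LUT
    contents so every signal can use the full I/O range.

    Invariant (closed loop): ``alpha5 * rho_s * rho_V2 / 2**f5 == rho_r``
    exactly, so the firing rate re-enters step 1 on the same scale it left
    step 5.
    """

    rho_J: float
    rho_ext: float
    rho_r: float
    rho_V1: float
    rho_V: float
    rho_V2: float
    rho_sum: float
    rho_s: float
    shifts: tuple[int, int, int, int, int]  # f1..f5
    lut_gains: tuple[float, float, float, float]  # alpha for steps 1, 2, 3, 5
    inhib_lut: np.ndarray = field(repr=False)

    def closure_residual(self) -> float:
        """Relative deviation of the composed loop scale from 1."""
        return abs(
            self.lut_gains[3] * self.rho_s * self.rho_V2 / 2 ** self.shifts[4]
            / self.rho_r - 1.0
        )

    def verify_closed_loop(self) -> None:
        if self.closure_residual() > 1e-12:
            raise ScalingError(
                f"feedback scaling not closed: residual {self.closure_residual():.3e}"
            )

    # -- JSON sidecar ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["inhib_lut"] = self.inhib_lut.tolist()
        d["shifts"] = list(self.shifts)
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ScalingChain":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        d = json.loads(text)
        d["inhib_lut"] = np.asarray(d["inhib_lut"], dtype=np.int64)
        d["shifts"] = tuple(d["shifts"])
        return cls(**d)


# --------------------------------------------------------------------------
# Elementary quantization operations
# --------------------------------------------------------------------------

def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (the fixed rounding rule)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantize_array(x: np.ndarray | float, rho: float, bits: int) -> np.ndarray:
    """round(rho * x) clipped to the signed range of ``bits``.

    Saturation is defined behavior (clipping keeps the data in range, e.g.
    [-128, 127] at 8 bits); it is counted and logged, never raised.
    """
    if rho <= 0:
        raise ScalingError("scaling factor must be positive")
    lo, hi = -(2 ** (bits - 1)), 2 ** (bits - 1) - 1
    q = _round_half_away(np.asarray(x, dtype=float) * rho)
    n_sat = int(np.count_nonzero((q < lo) | (q > hi)))
    if n_sat:
        logger.debug("quantize_array: %d values saturated at %d bits", n_sat, bits)
    return np.clip(q, lo, hi).astype(np.int64)


def propagate_scaling(
    rho_x: float, rho_y: float, rho_F: float, op_kind: str
) -> float:
    """Output scale of a multiply/add stage followed by truncation+LUT.

    multiply: rho_z = rho_x * rho_y / rho_F
    add:      rho_z = rho / rho_F, requiring rho_x == rho_y == rho
    """
    if op_kind == "multiply":
        return rho_x * rho_y / rho_F
    if op_kind == "add":
        if not math.isclose(rho_x, rho_y, rel_tol=1e-12):
            raise ScalingError(
                f"addends must share one scale, got {rho_x} vs {rho_y}"
            )
        return rho_x / rho_F
    raise ScalingError(f"unknown op_kind {op_kind!r}")


def build_inhibition_lut(
    k: float, rho_sum: float, rho_s: float, spec: FixedPointSpec,
    midpoint: bool = False,
) -> np.ndarray:
    """LUT computing the inhibition factor s = 1/(k * sum V^2) in hardware.

    Index i is the truncated integer sum on scale ``rho_sum``; the entry is
    the quantized s on scale ``rho_s``.  Entry 0 is defined as 0: with the
    "+1" of the continuous model dropped, zero activity would divide by
    zero, and an all-zero network must stay all-zero.  With ``midpoint``
    the entries are evaluated at i + 1/2, the unbiased representative of a
    floor-truncated index.
    """
    if k <= 0:
        raise ConfigurationError("k must be positive")
    i = np.arange(1, spec.lut_size, dtype=float) + (0.5 if midpoint else 0.0)
    vals = _round_half_away(rho_s / (k * (i / rho_sum)))
    out_hi = 2 ** (spec.lut_out_bits - 1) - 1
    lut = np.empty(spec.lut_size, dtype=np.int64)
    lut[0] = 0
    lut[1:] = np.clip(vals, 0, out_hi).astype(np.int64)
    return lut


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------

@dataclass
class CalibrationStats:
    """Value ranges from a floating-point dry run (maxima of |signal|).

    ``max_partial`` is the largest per-column-slice partial recurrent input;
    the 8-bit I/O constrains each partial (and the stimulus) individually,
    while their sum lives in the wide accumulator, so the partial scale can
    be finer than the total-V1 range would allow.
    """

    max_r: float
    max_V1: float
    max_partial: float
    max_stim: float
    max_V: float
    max_V2: float
    max_sum: float
    max_s: float
    max_weight: float  # max |beta * J|


def calibrate_float_ranges(
    stimuli: list[np.ndarray],
    init_state: NetworkState,
    grid: GridSpec,
    kernel: KernelSpec,
    params: DynamicsParams,
    stencil: np.ndarray | None = None,
    quiescent_iters: int = 30,
    col_slices: list[tuple[int, int]] | None = None,
) -> CalibrationStats:
    """Run the float model over calibration stimuli and record signal ranges.

    ``quiescent_iters`` appends a zero-stimulus segment: a tracker must also
    hold its bump through stimulus-free frames, and that regime has the
    smallest potentials — hence the largest inhibition factor — so leaving
    it out of calibration would under-range the inhibition LUT.
    """
    if stencil is None:
        stencil = build_interaction_kernel(grid, kernel)
    if quiescent_iters > 0:
        n_per_frame = max(params.n_iter, 1)
        stimuli = list(stimuli) + [np.zeros(grid.shape)] * (
            (quiescent_iters + n_per_frame - 1) // n_per_frame
        )
    masks = (_column_masks(grid, col_slices) if col_slices and len(col_slices) > 1
             else None)
    st = CalibrationStats(
        max_r=float(np.abs(init_state.r).max()),
        max_V1=0.0,
        max_partial=0.0,
        max_stim=max((float(np.abs(s).max()) for s in stimuli), default=0.0),
        max_V=float(np.abs(init_state.V).max()),
        max_V2=float((init_state.V**2).max()),
        max_sum=float((init_state.V**2).sum()),
        max_s=init_state.s_inh,
        max_weight=float(params.beta * stencil.max()),
    )
    state = init_state
    for stim in stimuli:
        for _ in range(params.n_iter):
            V1 = recurrent_input(state.r, stencil, params.beta)
            V = np.maximum(0.0, V1 + stim)
            r = firing_rate(V, params.k)
            total = float((V * V).sum())
            s = 1.0 / (params.k * total) if total > 0 else 0.0
            st.max_V1 = max(st.max_V1, float(np.abs(V1).max()))
            if masks is not None:
                st.max_partial = max(
                    st.max_partial,
                    max(float(np.abs(recurrent_input(state.r * m, stencil,
                                                     params.beta)).max())
                        for m in masks),
                )
            st.max_V = max(st.max_V, float(V.max()))
            st.max_V2 = max(st.max_V2, float((V * V).max()))
            st.max_sum = max(st.max_sum, total)
            st.max_s = max(st.max_s, s)
            st.max_r = max(st.max_r, float(r.max()))
            state = NetworkState(V=V, r=r, s_inh=s)
    if masks is None:
        st.max_partial = st.max_V1
    return st


def _min_shift(scale_in: float, max_val: float, limit: float) -> int:
    """Smallest f >= 0 with (scale_in / 2**f) * max_val <= limit."""
    if max_val <= 0:
        return 0
    f = math.ceil(math.log2(scale_in * max_val / limit)) if scale_in * max_val > limit else 0
    return max(0, f)


def _stage(scale_in: float, max_val: float, spec: FixedPointSpec,
           headroom: float) -> tuple[int, float, float]:
    """Shift + LUT gain of one linear stage: (f, alpha, scale_out).

    The shift brings the accumulator into the LUT index range; the LUT gain
    alpha <= 1 then stretches the observed range onto the full I/O span, so
    ``scale_out ~= headroom * io_max / max_val`` regardless of where the
    power-of-two ladder lands.
    """
    if max_val <= 0:
        return 0, 1.0, scale_in
    f = _min_shift(scale_in, max_val, float(spec.lut_idx_max))
    idx_scale = scale_in / 2**f
    alpha = min(1.0, headroom * spec.io_max / (idx_scale * max_val))
    return f, alpha, alpha * idx_scale


def solve_feedback_scaling(
    spec: FixedPointSpec,
    params: DynamicsParams,
    calib: CalibrationStats,
    target_rho_r: float | None = None,
    headroom: float = 0.95,
) -> ScalingChain:
    """Choose shifts, LUT gains and scales so the loop scale closes exactly.

    Per-step truncations are powers of two (arithmetic right-shifts,
    matching the 24-to-10-bit hardware truncation); non-power-of-two scale
    corrections are folded into the LUT contents (a gain alpha <= 1 for the
    linear/ReLU stages, and the free real scale rho_s of the inhibition
    LUT).  Scales are chosen so each signal's calibration range fills the
    I/O span with a (1 - headroom) safety margin, and the composed scale
    around the feedback loop equals 1 exactly.
    """
    io_max = float(spec.io_max)
    if calib.max_r <= 0 or calib.max_weight <= 0:
        raise CalibrationError("calibration ranges degenerate (zero activity)")
    if calib.max_s <= 0:
        raise CalibrationError("inhibition factor never observed (step 4)")
    rho_r_target = (target_rho_r if target_rho_r is not None
                    else headroom * io_max / calib.max_r)
    rho_J = io_max / calib.max_weight

    # step 1: accumulate rho_J*rho_r; each 8-bit output is one slice's
    # partial, and the stimulus is added on the same scale in step 2
    m1 = max(calib.max_partial, calib.max_stim)
    f1, a1, rho_V1 = _stage(rho_J * rho_r_target, m1, spec, headroom)
    rho_ext = rho_V1

    # step 2: sum partials + stimulus, ReLU
    f2, a2, rho_V = _stage(rho_V1, calib.max_V, spec, headroom)

    # step 3: square
    f3, a3, rho_V2 = _stage(rho_V * rho_V, calib.max_V2, spec, headroom)

    # step 4: global sum to an unsigned LUT index (no gain: the nonlinear
    # LUT contents absorb all remaining scale freedom)
    f4 = _min_shift(rho_V2, calib.max_sum, float(spec.lut_size - 1))
    rho_sum = rho_V2 / 2**f4
    # generous headroom on the inhibition factor: a clipped s breaks the
    # divisive feedback that stabilizes the bump (runaway collapse), while
    # its quantization error is a global factor on r and never moves the
    # argmax, so the extra margin costs nothing where it matters
    rho_s = 0.5 * headroom * io_max / calib.max_s

    # step 5: close the loop exactly through the last LUT gain
    f5 = _min_shift(rho_s * rho_V2, calib.max_r, float(spec.lut_idx_max))
    a5 = rho_r_target * 2**f5 / (rho_s * rho_V2)
    if a5 > 1.0:
        # not enough accumulator resolution to reach the target; settle on
        # the largest closing scale instead
        a5 = 1.0
    rho_r = a5 * rho_s * rho_V2 / 2**f5

    chain = ScalingChain(
        rho_J=rho_J,
        rho_ext=rho_ext,
        rho_r=rho_r,
        rho_V1=rho_V1,
        rho_V=rho_V,
        rho_V2=rho_V2,
        rho_sum=rho_sum,
        rho_s=rho_s,
        shifts=(f1, f2, f3, f4, f5),
        lut_gains=(a1, a2, a3, a5),
        inhib_lut=build_inhibition_lut(params.k, rho_sum, rho_s, spec,
                                       midpoint=f4 > 0),
    )
    chain.verify_closed_loop()
    return chain


# --------------------------------------------------------------------------
# Integer pipeline
# --------------------------------------------------------------------------

def _column_masks(grid: GridSpec, col_slices: list[tuple[int, int]]) -> list[np.ndarray]:
    masks = []
    for start, width in col_slices:
        m = np.zeros(grid.shape)
        m[:, start : start + width] = 1.0
        masks.append(m)
    return masks


class QuantizedPipeline:
    """Direct integer execution of the five-step pipeline.

    ``col_slices`` is the step-1 column partition (list of (start, width));
    each slice's partial recurrent input is truncated to I/O width before
    the step-2 sum, exactly as the sliced hardware mapping does.  The
    default is a single slice spanning the grid.
    """

    def __init__(
        self,
        grid: GridSpec,
        kernel: KernelSpec,
        params: DynamicsParams,
        chain: ScalingChain,
        spec: FixedPointSpec = FixedPointSpec(),
        col_slices: list[tuple[int, int]] | None = None,
    ) -> None:
        self.grid = grid
        self.kernel = kernel
        self.params = params
        self.chain = chain
        self.spec = spec
        self.col_slices = col_slices or [(0, grid.width)]
        stencil = build_interaction_kernel(grid, kernel)
        # beta folded into the stored weights
        self.weights_int = quantize_array(params.beta * stencil, chain.rho_J, spec.io_bits)
        self._masks = _column_masks(grid, self.col_slices)
        self.saturation_counts: dict[str, int] = {f"step{i}": 0 for i in (1, 2, 3, 4, 5)}
        self.value_counts: dict[str, int] = {f"step{i}": 0 for i in (1, 2, 3, 4, 5)}

    # -- helpers -----------------------------------------------------------
    def _check_accum(self, acc: np.ndarray | int, where: str) -> None:
        m = int(np.max(np.abs(acc)))
        if m >= self.spec.accum_limit:
            raise AccumulatorOverflowError(
                f"{where}: |accumulator| {m} exceeds {self.spec.accum_bits} bits"
            )

    def _lut_linear(self, acc: np.ndarray, shift: int, gain: float, step: str,
                    relu: bool) -> np.ndarray:
        """Truncate (right shift) to LUT index, apply the (scaled) linear LUT.

        The table entry for index i is evaluated at the midpoint i + 1/2 of
        the truncation bin (index 0 stays 0): the floor of the arithmetic
        shift otherwise biases every stage low by half an index, which
        slowly bleeds the bump mass out of the feedback loop.
        """
        idx = acc >> shift
        idx = np.clip(idx, self.spec.lut_idx_min, self.spec.lut_idx_max)
        if relu:
            idx = np.maximum(idx, 0)
        mid = 0.5 if shift > 0 else 0.0
        scaled = np.where(
            idx == 0, 0, _round_half_away((idx + mid) * gain)
        ).astype(np.int64)
        out_hi = 2 ** (self.spec.lut_out_bits - 1) - 1
        out_lo = -(2 ** (self.spec.lut_out_bits - 1))
        out = np.clip(scaled, out_lo, out_hi)
        self.saturation_counts[step] += int(np.count_nonzero(out != scaled))
        self.value_counts[step] += int(np.asarray(idx).size)
        return out.astype(np.int64)

    def _recurrent_partials(self, r_int: np.ndarray) -> list[np.ndarray]:
        """Per-column-slice integer partial potentials, truncated to I/O width."""
        f1 = self.chain.shifts[0]
        partials = []
        for mask in self._masks:
            acc = np.rint(
                correlate(r_int.astype(float) * mask, self.weights_int.astype(float),
                          mode="wrap")
            ).astype(np.int64)
            self._check_accum(acc, "step1 VMM")
            partials.append(self._lut_linear(acc, f1, self.chain.lut_gains[0], "step1", relu=False))
        return partials

    # -- the five steps ----------------------------------------------------
    def quantized_step(
        self, r_int: np.ndarray, stim_int: np.ndarray
    ) -> tuple[np.ndarray, dict[str, np.ndarray | int]]:
        """One integer iteration; returns (next r_int, intermediate signals)."""
        f1, f2, f3, f4, f5 = self.chain.shifts
        # step 1: per-slice recurrent partials (8-bit each)
        partials = self._recurrent_partials(r_int)
        # step 2: integrate partials + external stimulus, ReLU
        acc2 = np.sum(partials, axis=0, dtype=np.int64) + stim_int
        self._check_accum(acc2, "step2 VVA")
        V_int = self._lut_linear(acc2, f2, self.chain.lut_gains[1], "step2", relu=True)
        # step 3: square
        acc3 = V_int * V_int
        self._check_accum(acc3, "step3 VVM")
        V2_int = self._lut_linear(acc3, f3, self.chain.lut_gains[2], "step3", relu=False)
        # step 4: global sum -> unsigned LUT index -> inhibition factor
        S = int(V2_int.sum())
        self._check_accum(S, "step4 Lat_Acc")
        idx = min(max(S >> f4, 0), self.spec.lut_size - 1)
        s_int = int(self.chain.inhib_lut[idx])
        self.value_counts["step4"] += 1
        self.saturation_counts["step4"] += int((S >> f4) > self.spec.lut_size - 1)
        # step 5: scale squared potentials by the inhibition factor
        acc5 = s_int * V2_int
        self._check_accum(acc5, "step5 VS")
        r_next = self._lut_linear(acc5, f5, self.chain.lut_gains[3], "step5", relu=False)
        aux = {"partials": partials, "V": V_int, "V2": V2_int, "s": s_int}
        return r_next, aux

    def run_frame(
        self, r_int: np.ndarray, stim_int: np.ndarray, n_iter: int | None = None
    ) -> np.ndarray:
        for _ in range(self.params.n_iter if n_iter is None else n_iter):
            r_int, _ = self.quantized_step(r_int, stim_int)
        return r_int

    # -- boundary conversions ---------------------------------------------
    def quantize_rate(self, r: np.ndarray) -> np.ndarray:
        return quantize_array(r, self.chain.rho_r, self.spec.io_bits)

    def quantize_stimulus(self, stim: np.ndarray) -> np.ndarray:
        return quantize_array(stim, self.chain.rho_ext, self.spec.io_bits)

    def dequantize_rate(self, r_int: np.ndarray) -> np.ndarray:
        return r_int.astype(float) / self.chain.rho_r

    def saturation_rates(self) -> dict[str, float]:
        return {
            k: (self.saturation_counts[k] / self.value_counts[k]
                if self.value_counts[k] else 0.0)
            for k in self.saturation_counts
        }


def check_saturation(pipeline: QuantizedPipeline, limit: float = 0.01) -> None:
    """Raise CalibrationError if any step saturates more than ``limit``."""
    for step, rate in pipeline.saturation_rates().items():
        if rate > limit:
            raise CalibrationError(
                f"{step}: saturation rate {rate:.2%} exceeds {limit:.0%}"
            )


# --------------------------------------------------------------------------
# Diagnostics
# --------------------------------------------------------------------------

def trace_scaling_ratio(
    float_traj: list[np.ndarray],
    int_traj: list[np.ndarray],
    chain: ScalingChain,
) -> dict[str, object]:
    """Per-iteration ratio of integer to scaled-float firing-rate mass.

    A healthy chain keeps the ratio fluctuating around 1 (rounding noise);
    a broken loop scale makes it drift geometrically.  Returns the ratio
    series plus its mean and maximum absolute deviation from 1.
    """
    ratios = []
    for rf, ri in zip(float_traj, int_traj):
        denom = chain.rho_r * float(np.abs(rf).sum())
        ratios.append(float(np.abs(ri).sum()) / denom if denom > 0 else np.nan)
    arr = np.asarray(ratios)
    ok = arr[np.isfinite(arr)]
    return {
        "ratios": arr,
        "mean": float(ok.mean()) if ok.size else np.nan,
        "max_deviation": float(np.abs(ok - 1.0).max()) if ok.size else np.nan,
    }
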