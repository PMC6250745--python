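# Methods

## Model and discretization

The tracker is a two-dimensional continuous attractor neural network: rate
neurons on a toroidal `H x W` grid with translation-invariant Gaussian
excitation and divisive global inhibition. The continuous-time membrane
equation is discretized with unit time constant and unit step (`tau = 1`,
`dt = 1`), giving the per-iteration update

    V(x, t+1) = ReLU( beta * (J * r)(x, t) + V_ext(x, t) )
    r(x, t+1) = V^2(x, t+1) / (k * sum V^2(x, t+1))

The `1 +` term of the continuous inhibition denominator is dropped, which
makes the all-zero state singular; the package defines `r = 0` when
`sum V^2 = 0` (the quiescent network stays quiescent; in hardware the same
convention is entry 0 of the inhibition LUT). For any nonzero state the
identity `sum r = 1/k` holds exactly, and the potential trajectory depends
on `beta` and `k` only through `beta/k`.

Synapses are pruned to an `R x R` connection field (CF) around each neuron;
distances are minimum-image Euclidean on the torus, so the bump remains
stable across the wrap-around boundary. The ReLU matters because stimuli
are *signed* frame differences: recurrent input and rates are non-negative,
so without signed stimuli the clip would be vacuous.

## Parameters

| parameter | default | meaning / rationale |
| --- | --- | --- |
| `H x W` | 96x128 (tracking), 30x56 (hardware example) | neuron grid; video is resized to it |
| `R` | 15 | CF side; accuracy saturates for large R, 15 keeps connections few |
| `a` | 2.0 neurons | Gaussian range. Never published for this model; chosen so that (i) the 15x15 CF holds >99.9% of kernel mass (half-width 3.5a) and (ii) the 8-bit readout can resolve the argmax: near the peak, adjacent-neuron rate differences scale as `u/a^2` (u = sub-cell offset of the true peak), so a broad kernel makes the argmax numerically ill-conditioned at fixed-point precision |
| `J0` | `2*pi*a^2` | pure normalization making the peak synaptic weight 1.0; only `beta/k` and the stimulus gain are dynamically meaningful |
| `beta`, `k` | 50, 0.5 (`beta/k = 100`) | recurrent gain and inhibition strength; published per-video ratios range 100-900 |
| `n_iter` | 15 | iterations of the update per difference frame |
| `stimulus.gain` | 0.25 | scale of difference-frame injection. The published configuration fixes only `beta/k`, leaving the absolute stimulus scale free; 0.25 keeps the drive comparable to (but below) the bump's self-sustained amplitude, so the bump follows motion without being torn apart |

Tracking initialization is not specified beyond "ground truth of the first
frame": the package seeds `V` with a stencil-shaped bump (peak `beta/k`,
the amplitude a self-sustained bump settles to) at the first ground-truth
center, so tracking starts from an already-formed attractor state. The
emitted box keeps the first frame's width/height (fixed-scale tracker) and
the center comes from the argmax neuron, ties broken row-major.

## Fixed-point emulation

Every signal `s` is carried as `round(rho_s * s)`. Scales obey the chain
rule: products multiply scales, sums require equal operand scales, and each
truncation/LUT stage divides by its equivalent factor `rho_F = 2^f / alpha`
— `f` an arithmetic right-shift of the 24-bit accumulator down to the
10-bit LUT index, and `alpha <= 1` the non-power-of-two remainder folded
into the LUT contents. The feedback constraint is exact:
`alpha_5 * rho_s * rho_V2 / 2^f5 == rho_r`, so the firing rate re-enters
step 1 on the scale it left step 5. Without this the integer state grows or
decays geometrically (the package's negative-control test breaks one shift
by 2x and watches the rate mass collapse).

Calibration runs the float model over a few difference frames *plus a
zero-stimulus segment* and records per-signal ranges. The quiescent segment
is essential: with no stimulus the potentials are smallest and the
inhibition factor `s = 1/(k sum V^2)` largest, and a clipped `s` destroys
the divisive feedback that stabilizes the bump (a saturating inhibition
factor under-normalizes, the bump shrinks, `s` needs to grow further — a
runaway collapse). For the same reason `rho_s` gets 2x extra headroom; the
quantization error of `s` is a *global* factor on `r` and cannot move the
argmax, so the margin is free where accuracy matters.

Numerical conventions, fixed once:

- rounding is half-away-from-zero; truncation is the floor of the
  arithmetic right shift;
- linear/ReLU LUT entries are evaluated at the truncation-bin midpoint
  (`i + 1/2`, entry 0 stays 0) — the unbiased representative of a floored
  index. Plain `i` biases every stage low by half an index and measurably
  bleeds bump mass around the loop;
- the step-1 partial scale is set by the largest *per-slice* partial, not
  the total recurrent input: each 8-bit partial is range-limited
  individually while their sum lives in the wide accumulator;
- saturation clips and is counted, never raised; calibration rejects a
  configuration whose dry run saturates any step above 1%;
- `beta` is folded into the stored weights and `k` into the inhibition LUT.

Because the hardware sums 8-bit per-column-slice partials in step 2, the
reference integer pipeline truncates each slice's partial before summing —
the column partition is part of the quantized model, and the mapped
simulator is bit-exact against it by construction, not approximately.

## Mapping

A functional core offers 256 fan-ins, 256 fan-outs, a 256x256 8-bit synapse
array (usable as two 128x256 dynamic vector banks), one of five dendrite
ops (VMM, VVM, VVA <= 128 vectors, VS, VB) and soma transforms (truncation +
LUT, lateral accumulation, packet emission). The planner:

1. cuts the grid into column slices of width
   `w = min(floor(fan_in / H), (R-1)/2)`, snapped down to a divisor of `W`
   (a grid that fits one core entirely is left unsliced);
2. cuts each slice's affected span (`w + R - 1` columns, capped at `W`)
   into the smallest number of equal row bands whose outputs fit the
   fan-out;
3. assigns one VMM core per (column slice x row band), vector cores over
   `ceil(N / fan_out)` equal neuron groups for steps 2-5, duplicating
   steps 2 and 3 (two operand copies for squaring; squared potential feeds
   both inhibition and delay) and replicating the inhibition core once per
   firing-rate core;
4. shares inputs within chains (row bands of one slice, the two copies,
   the inhibition replicas) by adjacent-multicast relay, so no producer
   exceeds its fan-out; inter-step traffic is point-to-point.

The planner is a pure function of (grid, kernel, constraints). Validation
checks fan limits per core — for vector ops the binding limits are the
per-vector length (<= 256) and vector count (<= 128), since operands stream
through the dynamic synapse banks rather than the axon. Total core count is
non-decreasing in grid area within families of slice-aligned widths; widths
whose only small divisors are awkward (e.g. near-prime `W`) cost extra
cores, so the planner's generalization to arbitrary sizes is validated only
against the fully specified 30x56 example.

## Behavioral simulator

Phase-accurate, not cycle-accurate: each iteration is five global
compute-then-communicate phases; clock frequency and phase latency are
hardware properties outside the software model. Cores hold ping-pong
operand banks (a phase never reads the bank it is being written; asserted
at runtime), packets deliver into the inactive bank, and AMC registers
re-emit received payloads down the configured chain. The central
correctness property — checked as a test, integer for integer over 300
iterations — is equivalence with the direct quantized pipeline.

## Synthetic data

The generator renders a bright object (square or Gaussian blob) over a
darker noisy background with linear, sinusoidal, or random-walk motion;
boxes follow the commanded trajectory exactly and the whole scene is a pure
function of its config (seed included). Defaults: 120x224 frames, 16-px
object at intensity 200 over background 40, noise sigma 5 (contrast 32x
noise), speed (2.0, 0.7) px/frame from a start at (0.35 W, 0.45 H).

The start and speed are deliberately *generic*: a centered start with
axis-aligned motion on an integer-ratio downscale pins the object center
exactly onto a resize-cell boundary for the entire sequence, which makes
the top-two firing rates differ by less than one 8-bit quantization step on
every frame — a measure-zero knife-edge geometry that no real video
exhibits, and one that would make any finite-precision argmax comparison a
coin flip by construction.

What the generator does not emulate: appearance change, scale change,
rotation, background clutter and distractor objects, illumination shifts,
motion blur. Tests passing on this material show the dynamics, the
quantization, and the mapping are implemented correctly; they do not
predict accuracy on natural video, where difference-frame trackers are
known to trail edges and struggle with nearby distractors.

## Evaluation

Center error is the Euclidean distance between box centers; overlap is the
intersection-over-union of axis-aligned boxes with continuous areas (no
rasterization). The success plot is the survival function of the overlap
distribution, so its area equals the mean overlap exactly — the package
computes AUC as the mean and cross-checks the trapezoid integral within
half a threshold step. Protocols: OPE (one pass from the first-frame
truth), TRE (20 evenly spaced segment starts), SRE (8 shifts of 10% of the
box size plus scalings x{0.8, 0.9, 1.1, 1.2}); protocol scores average over
runs. Box centers are `(x + w/2, y + h/2)`; the OTB 1-based file origin is
converted to 0-based internally.

## Problem sizes

The test suite and the acceptance script run the 30x56 worked-example
network (1680 neurons, 73 cores) with 15 iterations per frame on 20-30
frame synthetic sequences, and grids up to 12x12 for the all-pairs brute-
force kernel oracle. These sizes exercise every code path (slicing, copies,
AMC chains, LUT saturation) while keeping the whole suite under a minute.

## Known limitations

- The bump trails the object's leading edge (difference-signal drive), so
  center error carries a systematic offset of roughly half the object size
  even when tracking is otherwise perfect.
- Fixed-scale boxes: no scale or rotation estimation.
- One object: a second moving stimulus will capture or split the bump.
- The planner refuses `H > fan_in` (no multi-row input splitting) and
  models routing as reachability, not hop latency or congestion.
- Published large-grid core counts (50x70 and 40x60 networks) are not
  reproduced: the slicing generalization beyond the worked example is
  under-determined, and those figures are treated as diagnostics.
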