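# canntrack

Object tracking with a continuous attractor neural network (CANN), plus the
full tool chain needed to run that tracker on fan-in/fan-out-constrained
many-core neural-network hardware: fixed-point quantization with a
constant-restricted scaling chain rule, a deterministic core-slicing mapper,
and a behavioral simulator of the mapped network that is bit-exact against
the direct integer pipeline. Tracking quality is scored with the standard
OTB-style metrics (center error, overlap, precision/success plots, AUC)
under the OPE / TRE / SRE protocols.

## Who this is for

Researchers working on neuromorphic or many-core accelerators who need a
software-complete, testable reference of an attractor-dynamics tracker —
from video in, to per-core integer execution, to tracking scores out —
without access to the physical chip. Everything runs on synthetic video
generated by the package, so no external datasets are required.

## The model

Neurons sit on an `H x W` toroidal grid. Membrane potential `V` and firing
rate `r` evolve per iteration as

    V(x, t+1) = ReLU( beta * sum_{x' in CF(x)} J(x, x') r(x', t) + V_ext(x, t) )
    r(x, t+1) = V^2(x, t+1) / ( k * sum_x' V^2(x', t+1) )

with the Gaussian interaction

    J(x, x') = J0 / (2 pi a^2) * exp( -|x - x'|^2 / (2 a^2) )

pruned to an `R x R` connection field (CF) around each neuron (distance is
minimum-image on the torus). The divisive term is global inhibition: for any
nonzero state, `sum r = 1/k` exactly, which keeps a localized bump of
activity stable. Frame differences of the (resized) input video are injected
as `V_ext`; the bump then follows the moving object, and the argmax neuron
is the predicted location. Each difference frame drives 15 iterations.
Only the ratio `beta/k` affects the potential trajectory; the split merely
rescales rates.

For hardware execution the pipeline is cut into five per-iteration steps
(recurrent input -> membrane potential -> squared potential -> inhibition
factor -> firing rate), quantized to 8-bit I/O with 24-bit accumulation and
10-bit LUT indices, and placed onto cores with 256 fan-ins/fan-outs and a
256x256 synapse array. The scaling chain rule tracks a scale factor per
signal through every multiply/add/truncate stage; the composed scale around
the recurrent loop is forced to exactly 1, which is what prevents integer
state explosion or vanishing.

## Worked example

Generate a synthetic sequence, track it with the float reference and with
the simulated mapped hardware, and plan the chip mapping:

```
$ canntrack synth --out demo_seq --seed 7 --frames 20 --height 120 --width 224
wrote 20 frames to demo_seq

$ printf 'grid:\n  height: 30\n  width: 56\n' > demo.yaml
$ canntrack track demo_seq --config demo.yaml --out demo_run
AUC 0.462  mean center error 5.77 px

$ canntrack track demo_seq --config demo.yaml --mode mapped --out demo_run_mapped
AUC 0.462  mean center error 5.77 px
```

The AUC (area under the success plot, equal to the mean box overlap) and the
mean center error in native pixels are identical between the float run and
the mapped run on this sequence: the 8-bit pipeline predicts the same boxes.
The residual ~5.8 px offset against ground truth is the method's known edge
sensitivity — frame differencing highlights the moving object's leading
edge, not its center.

```
$ canntrack plan --height 30 --width 56 --cf 15
Step  Functionality            Operation       Fan-in  Fan-out  Cores
---------------------------------------------------------------------
1     recurrent input          VMM                210      210     24
2     membrane potential       VVA                960      240     14
3     potential squared        VVM                480      240     14
4-1   inhibition factor        VVA + Lat_Acc     1680        1      7
4-2   potential delay          VB                 240      240      7
5     firing rate              VS                 241      240      7
---------------------------------------------------------------------
Total                                                           73
```

73 functional cores carry the whole 30x56 tracker: 8 column slices x 3 row
slices of VMM for the recurrent input, and vector cores (with the listed
copies) for the remaining steps.

## Library layout

| module | contents |
| --- | --- |
| `canntrack.core` | float reference dynamics, kernel, bump readout, tracking loop |
| `canntrack.data_io` | OTB folder I/O, synthetic scene generator, resize + frame differencing |
| `canntrack.quantizer` | scaling chain solver, LUT construction, integer five-step pipeline |
| `canntrack.mapper` | column/row slicing, placement, resource report, validation |
| `canntrack.chip_sim` | phase-by-phase core simulator with ping-pong buffers and AMC routing |
| `canntrack.evaluation` | center error, overlap, precision/success curves, OPE/TRE/SRE |
| `canntrack.cli` | `canntrack synth / track / plan / eval / chipsim`, run configuration |

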