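"""Behavioral simulator of the many-core fabric executing a placement.

Each functional core is modeled with the published operation semantics:
a dendrite doing one of VMM / VVM / VVA / VS / VB into wide accumulators,
and a soma that truncates the accumulator to a LUT index, applies a
table-lookup nonlinearity (ReLU or the inhibition reciprocal), optionally
laterally accumulates to a scalar, and emits routing packets.  Data moves
between cores as packets delivered into ping-pong buffers: a core never
reads the bank being written in the same phase (asserted at runtime).
Adjacent-multicast (AMC) chains re-emit received payloads to a configured
next hop, which is how copies and input-sharing groups receive identical
data without exceeding any producer's fan-out.

One iteration of the dynamics is five global phases (compute + communicate
rounds); timing is phase-accurate, not cycle-accurate — clock frequency and
phase latency are hardware properties outside the software model.

The central correctness property: for any validated placement, the mapped
run equals the direct integer pipeline of :mod:`canntrack.quantizer`
integer-for-integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import GridSpec, KernelSpec, toroidal_offset_distance
from .errors import ConfigurationError, RoutingError
from .mapper import CoreAssignment, Placement
from .quantizer import FixedPointSpec, QuantizedPipeline, ScalingChain

logger = logging.getLogger(__name__)

__all__ = [
    "Packet",
    "CoreInstance",
    "ChipSimulator",
    "exec_dendrite",
    "exec_soma",
    "run_mapped_network",
]

_STEP_PHASE = {"1": 1, "2": 2, "3": 3, "4-1": 4, "4-2": 4, "5": 5}


@dataclass
class Packet:
    """One routed write: payload values into a destination buffer region."""

    dest: str
    slot: int
    offsets: np.ndarray
    values: np.ndarray
    scalar: bool = False


@dataclass
class CoreInstance:
    """Runtime state of one core: op config, weights, ping-pong banks."""

    assignment: CoreAssignment
    phase: int
    shift: int
    lut: str  # "linear" | "relu" | "inhib" | "none"
    lat_acc: bool
    gain: float = 1.0
    weights: np.ndarray | None = None  # (n_in, n_out) for VMM
    amc_next: str | None = None
    # two banks of operand vectors (+ scalar slot for VS)
    banks: list[np.ndarray] = field(default_factory=list)
    scalar_banks: list[int] = field(default_factory=lambda: [0, 0])
    read_bank: int = 0
    out_plan: list[tuple[str, int, np.ndarray, np.ndarray, bool]] = field(default_factory=list)
    # (dest, slot, dest_offsets, src_offsets, scalar) — dest None = external output

    def write_bank(self) -> int:
        return 1 - self.read_bank


def exec_dendrite(op: str, vectors: np.ndarray, scalar: int | None,
                  weights: np.ndarray | None) -> np.ndarray:
    """Dendrite semantics into a wide accumulator vector.

    VMM multiplies the (single) input vector with the static weight matrix —
    physically 16 MAC groups of 16 columns sharing one axon value per cycle,
    which is timing, not arithmetic.  VVM is the elementwise product of two
    stored vectors, VVA the elementwise sum of up to 128, VS scales a stored
    vector by the axon scalar, and VB copies.
    """
    if op == "VMM":
        return vectors[0] @ weights
    if op == "VVM":
        if vectors.shape[0] != 2:
            raise ConfigurationError("VVM requires exactly 2 vectors")
        return vectors[0] * vectors[1]
    if op == "VVA":
        if vectors.shape[0] > 128:
            raise ConfigurationError("VVA supports at most 128 vectors")
        return vectors.sum(axis=0)
    if op == "VS":
        return scalar * vectors[0]
    if op == "VB":
        return vectors[0].copy()
    raise ConfigurationError(f"unknown dendrite op {op!r}")


def exec_soma(
    acc: np.ndarray,
    shift: int,
    lut: str,
    lat_acc: bool,
    spec: FixedPointSpec,
    inhib_lut: np.ndarray | None = None,
    gain: float = 1.0,
) -> np.ndarray:
    """Soma semantics: (Lat_Acc) -> truncate to LUT index -> LUT -> outputs.

    ``gain`` is the non-power-of-two part of the stage's equivalent scaling
    factor, folded into the linear/ReLU LUT contents by the calibration.
    """
    if lat_acc:
        acc = np.asarray([acc.sum()])  # y_j = x_j + y_{j-1}, final scalar
    idx = acc >> shift
    if lut == "none":
        return idx
    if lut == "inhib":
        if inhib_lut is None:
            raise ConfigurationError("inhibition core without a LUT table")
        idx = np.clip(idx, 0, spec.lut_size - 1)
        return inhib_lut[idx]
    idx = np.clip(idx, spec.lut_idx_min, spec.lut_idx_max)
    if lut == "relu":
        idx = np.maximum(idx, 0)
    # table entries evaluated at the bin midpoint (index 0 stays 0), the
    # unbiased representative of a floor-truncated accumulator
    mid = 0.5 if shift > 0 else 0.0
    x = (idx + mid) * gain
    scaled = np.where(idx == 0, 0,
                      np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)
    out_hi = 2 ** (spec.lut_out_bits - 1) - 1
    out_lo = -(2 ** (spec.lut_out_bits - 1))
    return np.clip(scaled, out_lo, out_hi)


# --------------------------------------------------------------------------
# Compilation: placement + scaling chain -> runnable core instances
# --------------------------------------------------------------------------

def _vmm_weights(core: CoreAssignment, grid: tuple[int, int], R: int,
                 weights_int: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Static weight submatrix and the global input/output neuron ids."""
    H, W = grid
    h = (R - 1) // 2
    cstart, cw = core.in_cols
    rstart, rh = core.out_rows
    sstart, span = core.span_cols
    in_rows = np.repeat(np.arange(H), cw)
    in_cols = np.tile(np.arange(cstart, cstart + cw), H)
    out_rows = np.repeat(np.arange(rstart, rstart + rh), span)
    out_cols = np.tile((sstart + np.arange(span)) % W, rh)
    in_ids = in_rows * W + in_cols
    out_ids = out_rows * W + out_cols

    dr = out_rows[None, :] - in_rows[:, None]
    dc = out_cols[None, :] - in_cols[:, None]
    gs = GridSpec(H, W)
    dr = np.minimum(np.abs(dr), H - np.abs(dr))
    dc = np.minimum(np.abs(dc), W - np.abs(dc))
    mat = np.zeros((len(in_ids), len(out_ids)), dtype=np.int64)
    inside = (dr <= h) & (dc <= h)
    mat[inside] = weights_int[dr[inside] + h, dc[inside] + h]
    return mat, in_ids, out_ids


class ChipSimulator:
    """Execute a placement phase-by-phase on simulated cores."""

    def __init__(
        self,
        placement: Placement,
        chain: ScalingChain,
        weights_int: np.ndarray,
        spec: FixedPointSpec = FixedPointSpec(),
    ) -> None:
        self.placement = placement
        self.chain = chain
        self.spec = spec
        self.H, self.W = placement.grid
        self.n_phases = 0
        self._trace = logger.isEnabledFor(logging.DEBUG)
        self._build(weights_int)

    # -- construction ------------------------------------------------------
    def _build(self, weights_int: np.ndarray) -> None:
        pl, chain = self.placement, self.chain
        f1, f2, f3, f4, f5 = chain.shifts
        H, W = self.H, self.W
        n_contrib = pl.slice_plan.n_contrib
        col_starts = np.array([s for s, _ in pl.slice_plan.col_slices])
        w = pl.slice_plan.col_slices[0][1]
        n_col = len(pl.slice_plan.col_slices)
        groups = pl.groups
        group_of = np.empty(H * W, dtype=int)
        for g, (start, cnt) in enumerate(groups):
            group_of[start : start + cnt] = g

        amc_next: dict[str, str] = {}
        for chain_ids in pl.amc_chains:
            for a, b in zip(chain_ids[:-1], chain_ids[1:]):
                amc_next[a] = b

        a1, a2, a3, a5 = chain.lut_gains
        step_cfg = {
            "1": (f1, "linear", False, a1),
            "2": (f2, "relu", False, a2),
            "3": (f3, "linear", False, a3),
            "4-1": (f4, "inhib", True, 1.0),
            "4-2": (0, "none", False, 1.0),
            "5": (f5, "linear", False, a5),
        }
        self.cores: dict[str, CoreInstance] = {}
        self._s1_inputs: dict[str, np.ndarray] = {}  # head core -> input ids
        for a in pl.cores:
            shift, lut, lat, gain = step_cfg[a.step]
            inst = CoreInstance(
                assignment=a, phase=_STEP_PHASE[a.step], shift=shift, lut=lut,
                lat_acc=lat, gain=gain, amc_next=amc_next.get(a.core_id),
            )
            n_slots = a.n_vectors
            vlen = max(a.vector_len, 1)
            inst.banks = [np.zeros((n_slots, vlen), dtype=np.int64) for _ in range(2)]
            self.cores[a.core_id] = inst

        # --- step-1 cores: weights + output deliveries to step-2 heads ----
        for a in pl.cores:
            if a.step != "1":
                continue
            inst = self.cores[a.core_id]
            mat, in_ids, out_ids = _vmm_weights(a, pl.grid, pl.R, weights_int)
            inst.weights = mat
            self._s1_inputs[a.core_id] = in_ids
            # slot of slice j among the contributors of each output column
            j = a.col_slice
            out_cols = out_ids % W
            slots = self._contrib_slot(j, out_cols, w, n_col, (pl.R - 1) // 2)
            if np.any(slots >= n_contrib):
                raise RoutingError(
                    f"{a.core_id}: contributor slot exceeds the {n_contrib} "
                    "operand slots of step 2"
                )
            dests = group_of[out_ids]
            for g in np.unique(dests):
                for s in range(n_contrib):
                    sel = (dests == g) & (slots == s)
                    if not np.any(sel):
                        continue
                    inst.out_plan.append((
                        f"s2_g{g}_c0", s,
                        out_ids[sel] - groups[g][0],
                        np.flatnonzero(sel),
                        False,
                    ))

        # --- vector-step deliveries ---------------------------------------
        n_vec = len(groups)
        for g, (start, cnt) in enumerate(groups):
            sel_all = np.arange(cnt)
            # step 2 copies feed the two operand slots of the step-3 head
            self.cores[f"s2_g{g}_c0"].out_plan.append(
                (f"s3_g{g}_c0", 0, sel_all, sel_all, False))
            self.cores[f"s2_g{g}_c1"].out_plan.append(
                (f"s3_g{g}_c0", 1, sel_all, sel_all, False))
            # step-3 copy 0 -> inhibition chain head (vector slot g);
            # copy 1 -> delay core
            self.cores[f"s3_g{g}_c0"].out_plan.append(
                (f"s41_g0", g, sel_all, sel_all, False))
            self.cores[f"s3_g{g}_c1"].out_plan.append(
                (f"s42_g{g}", 0, sel_all, sel_all, False))
            # delay -> firing-rate vector; inhibition -> firing-rate scalar
            self.cores[f"s42_g{g}"].out_plan.append(
                (f"s5_g{g}", 0, sel_all, sel_all, False))
            self.cores[f"s41_g{g}"].out_plan.append(
                (f"s5_g{g}", 0, np.zeros(1, dtype=int), np.zeros(1, dtype=int), True))
            # firing rate -> step-1 chain heads + external readout
            ids = np.arange(start, start + cnt)
            cols = ids % W
            slice_of = np.searchsorted(col_starts, cols, side="right") - 1
            for j in np.unique(slice_of):
                head = f"s1_j{j}_k0"
                sel = np.flatnonzero(slice_of == j)
                dest_pos = np.searchsorted(self._s1_inputs[head], ids[sel])
                self.cores[f"s5_g{g}"].out_plan.append(
                    (head, 0, dest_pos, sel, False))

    @staticmethod
    def _contrib_slot(j: int, out_cols: np.ndarray, w: int, n_col: int,
                      h: int) -> np.ndarray:
        """Ordinal of slice j among the contributing slices of each column.

        A column c receives partials from the slices touching columns
        [c - h, c + h]; they form a contiguous run on the column-slice ring
        starting at the slice of column c - h.  The slot is j's position in
        that run, which is unique per (column, contributing slice).
        """
        if n_col == 1:
            return np.zeros(len(out_cols), dtype=int)
        lo = (out_cols - h) // w  # slice of the leftmost affected column
        return (j - lo) % n_col

    # -- execution ---------------------------------------------------------
    def _deliver(self, pkt: Packet, phase: int) -> None:
        inst = self.cores.get(pkt.dest)
        if inst is None:
            raise RoutingError(f"packet to unconfigured core {pkt.dest}")
        bank = inst.write_bank()
        if inst.phase == phase and bank == inst.read_bank:
            raise RoutingError(
                f"ping-pong violation: write to active bank of {pkt.dest} in phase {phase}"
            )
        if pkt.scalar:
            inst.scalar_banks[bank] = int(pkt.values[0])
        else:
            buf = inst.banks[bank]
            if pkt.slot >= buf.shape[0] or np.any(pkt.offsets >= buf.shape[1]):
                raise RoutingError(f"write past bank capacity of {pkt.dest}")
            buf[pkt.slot, pkt.offsets] = pkt.values
        # AMC relay: re-emit the payload to the configured adjacent core
        if inst.amc_next is not None:
            self._deliver(
                Packet(inst.amc_next, pkt.slot, pkt.offsets, pkt.values, pkt.scalar),
                phase,
            )

    def inject(self, core_id: str, slot: int, values: np.ndarray,
               offsets: np.ndarray | None = None) -> None:
        """External write (initial state / stimulus) into a core's next bank."""
        values = np.asarray(values, dtype=np.int64)
        if offsets is None:
            offsets = np.arange(len(values))
        self._deliver(Packet(core_id, slot, offsets, values), phase=0)

    def _run_phase(self, phase: int, external: dict[str, np.ndarray]) -> None:
        packets: list[Packet] = []
        for cid, inst in self.cores.items():
            if inst.phase != phase:
                continue
            # swap ping-pong banks: read what was written since last compute
            inst.read_bank = 1 - inst.read_bank
            a = inst.assignment
            vectors = inst.banks[inst.read_bank][:, : max(a.vector_len, 1)]
            scalar = inst.scalar_banks[inst.read_bank]
            acc = exec_dendrite(a.dendrite_op, vectors, scalar, inst.weights)
            if a.step == "4-2":
                out = acc  # pure delay, no soma transform
            else:
                out = exec_soma(acc, inst.shift, inst.lut, inst.lat_acc,
                                self.spec, self.chain.inhib_lut, inst.gain)
            # clear the now-consumed bank for the next round
            inst.banks[inst.read_bank][:] = 0
            inst.scalar_banks[inst.read_bank] = 0
            if self._trace:
                logger.debug("phase %d core %s op %s checksum %d",
                             phase, cid, a.dendrite_op, int(out.sum()))
            for dest, slot, doff, soff, is_scalar in inst.out_plan:
                packets.append(Packet(dest, slot, doff, out[soff], is_scalar))
            if a.step == "5":
                external[cid] = out.copy()
        for pkt in packets:
            self._deliver(pkt, phase)
        self.n_phases += 1

    def run(
        self,
        stimuli_int: list[np.ndarray],
        r0_int: np.ndarray,
        n_iter: int,
    ) -> list[np.ndarray]:
        """Execute n_iter iterations (5 phases each) per stimulus frame.

        Returns the assembled H x W integer firing-rate grid after every
        iteration (len(stimuli) * n_iter grids).
        """
        pl = self.placement
        n_contrib = pl.slice_plan.n_contrib
        # initial firing rate into the step-1 chains (as a pre-run delivery)
        flat0 = r0_int.reshape(-1)
        for j in range(len(pl.slice_plan.col_slices)):
            head = f"s1_j{j}_k0"
            ids = self._s1_inputs[head]
            self.inject(head, 0, flat0[ids])
        out: list[np.ndarray] = []
        for stim in stimuli_int:
            stim_flat = stim.reshape(-1)
            for _ in range(n_iter):
                # stimulus lands in the last operand slot of the step-2 chains
                for g, (start, cnt) in enumerate(pl.groups):
                    self.inject(f"s2_g{g}_c0", n_contrib,
                                stim_flat[start : start + cnt])
                ext: dict[str, np.ndarray] = {}
                for phase in range(1, 6):
                    self._run_phase(phase, ext)
                grid = np.zeros(self.H * self.W, dtype=np.int64)
                for g, (start, cnt) in enumerate(pl.groups):
                    grid[start : start + cnt] = ext[f"s5_g{g}"]
                out.append(grid.reshape(self.H, self.W))
        return out


def run_mapped_network(
    placement: Placement,
    pipeline: QuantizedPipeline,
    stimuli_int: list[np.ndarray],
    r0_int: np.ndarray,
    n_iter: int | None = None,
) -> list[np.ndarray]:
    """Convenience wrapper: simulate ``placement`` with ``pipeline``'s
    calibration (weights, shifts, LUT) on integer stimuli."""
    sim = ChipSimulator(placement, pipeline.chain, pipeline.weights_int,
                        pipeline.spec)
    return sim.run(stimuli_int, r0_int,
                   pipeline.params.n_iter if n_iter is None else n_iter)
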