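"""Deterministic planner mapping the network onto fan-in/fan-out-limited cores.

A functional core (FunC) is a self-contained compute unit with 256 fan-ins,
256 fan-outs, and a 256x256 8-bit synapse array.  The recurrent-input
vector-matrix multiply of step 1 exceeds a single core for any realistic
grid, so the planner partitions the grid into column-wise input slices
(width limited jointly by the grid height and the fan-in budget) and, per
slice, row-wise output slices (so the affected span of w + R - 1 columns
fits the fan-out budget).  Vector steps 2-5 split the neuron population
into equal groups of at most fan_out neurons.  Copies: steps 2 and 3 are
duplicated x2 (the squaring step consumes two operand vectors and the
squared potential feeds both the inhibition and the delay path), and the
inhibition step is replicated once per firing-rate core.

The planner is a pure function of (grid, kernel, constraints): same inputs,
bit-identical plan.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .core import GridSpec, KernelSpec
from .errors import PlanningError

__all__ = [
    "CoreConstraints",
    "CoreAssignment",
    "SlicePlan",
    "Placement",
    "ResourceReport",
    "plan_column_slices",
    "plan_row_slices",
    "plan_full_mapping",
    "resource_report",
    "validate_placement",
]


@dataclass(frozen=True)
class CoreConstraints:
    """Per-core resource limits of the many-core fabric."""

    fan_in: int = 256
    fan_out: int = 256
    synapse_rows: int = 256
    synapse_cols: int = 256
    vva_max_vectors: int = 128
    mac_groups: int = 16
    mac_group_cols: int = 16

    def __post_init__(self) -> None:
        if min(self.fan_in, self.fan_out, self.synapse_rows, self.synapse_cols,
               self.vva_max_vectors) < 1:
            raise PlanningError("core constraints must be positive")


@dataclass
class CoreAssignment:
    """One core of the placement: role, op, fan counts, and geometry."""

    core_id: str
    step: str                 # "1", "2", "3", "4-1", "4-2", "5"
    role: str
    dendrite_op: str          # VMM | VVM | VVA | VS | VB
    soma_ops: tuple[str, ...]
    fan_in: int
    fan_out: int
    copy_index: int = 0
    n_vectors: int = 1        # operand vectors held in dynamic synapse banks
    vector_len: int = 0
    # step-1 geometry
    col_slice: int | None = None
    row_slice: int | None = None
    in_cols: tuple[int, int] | None = None    # (start, width)
    out_rows: tuple[int, int] | None = None   # (start, height)
    span_cols: tuple[int, int] | None = None  # (start, width), columns mod W
    # vector-step geometry
    neuron_range: tuple[int, int] | None = None  # (start, count), flat row-major


@dataclass
class SlicePlan:
    col_slices: list[tuple[int, int]]
    row_slices: list[tuple[int, int]]
    span_width: int
    n_contrib: int  # column-slice contributions per neuron


@dataclass
class Placement:
    grid: tuple[int, int]
    R: int
    constraints: CoreConstraints
    slice_plan: SlicePlan
    cores: list[CoreAssignment]
    amc_chains: list[list[str]]
    p2p_edges: list[tuple[str, str]]
    groups: list[tuple[int, int]]  # vector-step neuron ranges (start, count)

    def cores_by_step(self) -> dict[str, list[CoreAssignment]]:
        out: dict[str, list[CoreAssignment]] = {}
        for c in self.cores:
            out.setdefault(c.step, []).append(c)
        return out

    def core(self, core_id: str) -> CoreAssignment:
        for c in self.cores:
            if c.core_id == core_id:
                return c
        raise KeyError(core_id)

    # -- JSON --------------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "grid": list(self.grid),
            "R": self.R,
            "constraints": asdict(self.constraints),
            "slice_plan": asdict(self.slice_plan),
            "cores": [asdict(c) for c in self.cores],
            "amc_chains": self.amc_chains,
            "p2p_edges": [list(e) for e in self.p2p_edges],
            "groups": [list(g) for g in self.groups],
        }
        text = json.dumps(d, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "Placement":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        d = json.loads(text)

        def _tup(v):
            return tuple(v) if v is not None else None

        cores = []
        for cd in d["cores"]:
            cd = dict(cd)
            for key in ("soma_ops", "in_cols", "out_rows", "span_cols", "neuron_range"):
                cd[key] = _tup(cd.get(key))
            cores.append(CoreAssignment(**cd))
        sp = d["slice_plan"]
        return cls(
            grid=tuple(d["grid"]),
            R=d["R"],
            constraints=CoreConstraints(**d["constraints"]),
            slice_plan=SlicePlan(
                col_slices=[tuple(s) for s in sp["col_slices"]],
                row_slices=[tuple(s) for s in sp["row_slices"]],
                span_width=sp["span_width"],
                n_contrib=sp["n_contrib"],
            ),
            cores=cores,
            amc_chains=d["amc_chains"],
            p2p_edges=[tuple(e) for e in d["p2p_edges"]],
            groups=[tuple(g) for g in d["groups"]],
        )


@dataclass
class ResourceReport:
    rows: list[dict]
    total: int

    def to_text(self) -> str:
        header = f"{'Step':<5} {'Functionality':<24} {'Operation':<14} {'Fan-in':>7} {'Fan-out':>8} {'Cores':>6}"
        lines = [header, "-" * len(header)]
        for r in self.rows:
            lines.append(
                f"{r['step']:<5} {r['functionality']:<24} {r['operation']:<14} "
                f"{r['fan_in']:>7} {r['fan_out']:>8} {r['n_cores']:>6}"
            )
        lines.append("-" * len(header))
        lines.append(f"{'Total':<52} {self.total:>13}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# Slicing rules
# --------------------------------------------------------------------------

def _largest_divisor_at_most(n: int, limit: int) -> int:
    for d in range(min(limit, n), 0, -1):
        if n % d == 0:
            return d
    return 0


def plan_column_slices(
    H: int, W: int, R: int, constraints: CoreConstraints = CoreConstraints()
) -> list[tuple[int, int]]:
    """Column-wise input slices for step 1.

    If the whole grid fits a single core's fan-in and fan-out, no slicing is
    needed.  Otherwise the slice width is ``min(floor(fan_in/H), (R-1)/2)``
    — capped by the fan-in budget per column of H neurons, and by the CF
    half-width so each slice affects only itself and its two neighbors —
    snapped down to the largest divisor of W.
    """
    if R % 2 == 0:
        raise PlanningError(f"CF size R must be odd, got {R}")
    if H > constraints.fan_in:
        raise PlanningError(
            f"grid height {H} exceeds the per-core fan-in {constraints.fan_in}; "
            "multi-row input splitting is unsupported"
        )
    if H * W <= constraints.fan_in and H * W <= constraints.fan_out:
        return [(0, W)]
    w_cap = min(constraints.fan_in // H, max((R - 1) // 2, 1))
    w = _largest_divisor_at_most(W, w_cap)
    if w < 1:
        raise PlanningError(f"no valid slice width for W={W} under cap {w_cap}")
    return [(i * w, w) for i in range(W // w)]


def plan_row_slices(
    H: int, w: int, R: int,
    constraints: CoreConstraints = CoreConstraints(),
    W: int | None = None,
) -> list[tuple[int, int]]:
    """Row-wise output slices per column slice.

    A width-w input slice affects a span of w + R - 1 columns (capped at the
    grid width); the smallest divisor of H whose row bands keep
    ``(H / n) * span <= fan_out`` outputs per core is used.
    """
    span = w + R - 1 if W is None else min(w + R - 1, W)
    for n in range(1, H + 1):
        if H % n == 0 and (H // n) * span <= constraints.fan_out:
            h = H // n
            return [(i * h, h) for i in range(n)]
    raise PlanningError(
        f"cannot split H={H} rows so that row-band x span {span} fits "
        f"fan-out {constraints.fan_out}"
    )


def _vector_groups(n_neurons: int, fan_out: int) -> list[tuple[int, int]]:
    """Split N neurons into ceil(N/fan_out) near-equal contiguous groups."""
    n_cores = math.ceil(n_neurons / fan_out)
    base, rem = divmod(n_neurons, n_cores)
    groups, start = [], 0
    for g in range(n_cores):
        cnt = base + (1 if g < rem else 0)
        groups.append((start, cnt))
        start += cnt
    return groups


# --------------------------------------------------------------------------
# Full mapping
# --------------------------------------------------------------------------

def plan_full_mapping(
    grid: GridSpec,
    kernel: KernelSpec,
    constraints: CoreConstraints = CoreConstraints(),
) -> Placement:
    """Place the five-step schedule onto cores and build the routing plan."""
    H, W, R = grid.height, grid.width, kernel.R
    col_slices = plan_column_slices(H, W, R, constraints)
    w = col_slices[0][1]
    row_slices = plan_row_slices(H, w, R, constraints, W=W)
    span = min(w + R - 1, W)
    n_col, n_row = len(col_slices), len(row_slices)
    n_contrib = min(math.ceil((R - 1) / w) + 1 if w else 1, n_col)
    N = grid.n_neurons
    groups = _vector_groups(N, constraints.fan_out)
    n_vec = len(groups)

    cores: list[CoreAssignment] = []
    chains: list[list[str]] = []
    edges: list[tuple[str, str]] = []

    # step 1: one VMM core per (column slice x row slice); the n_row cores of
    # one column slice share the same inputs through an AMC chain.
    for j, (cstart, cw) in enumerate(col_slices):
        chain = []
        for k, (rstart, rh) in enumerate(row_slices):
            cid = f"s1_j{j}_k{k}"
            chain.append(cid)
            cores.append(CoreAssignment(
                core_id=cid, step="1", role="recurrent input",
                dendrite_op="VMM", soma_ops=("LUT_Fun", "Out_Trans"),
                fan_in=H * cw, fan_out=rh * span,
                col_slice=j, row_slice=k,
                in_cols=(cstart, cw), out_rows=(rstart, rh),
                span_cols=((cstart - (R - 1) // 2) % W if span < W else 0, span),
                vector_len=H * cw,
            ))
        if len(chain) > 1:
            chains.append(chain)

    # steps 2..5: vector cores over equal neuron groups
    for g, (start, cnt) in enumerate(groups):
        s2 = []
        for c in range(2):
            cid = f"s2_g{g}_c{c}"
            s2.append(cid)
            cores.append(CoreAssignment(
                core_id=cid, step="2", role="membrane potential",
                dendrite_op="VVA", soma_ops=("LUT_Fun", "Out_Trans"),
                fan_in=cnt * (n_contrib + 1), fan_out=cnt, copy_index=c,
                n_vectors=n_contrib + 1, vector_len=cnt, neuron_range=(start, cnt),
            ))
        if len(s2) > 1:
            chains.append(s2)
        s3 = []
        for c in range(2):
            cid = f"s3_g{g}_c{c}"
            s3.append(cid)
            cores.append(CoreAssignment(
                core_id=cid, step="3", role="potential squared",
                dendrite_op="VVM", soma_ops=("LUT_Fun", "Out_Trans"),
                fan_in=cnt * 2, fan_out=cnt, copy_index=c,
                n_vectors=2, vector_len=cnt, neuron_range=(start, cnt),
            ))
        if len(s3) > 1:
            chains.append(s3)
        edges += [(s2[0], s3[0]), (s2[1], s3[0])]

    s41 = []
    for g, (start, cnt) in enumerate(groups):
        cid = f"s41_g{g}"
        s41.append(cid)
        cores.append(CoreAssignment(
            core_id=cid, step="4-1", role="inhibition factor",
            dendrite_op="VVA", soma_ops=("Lat_Acc", "LUT_Fun", "Out_Trans"),
            fan_in=N, fan_out=1, copy_index=g,
            n_vectors=n_vec, vector_len=max(c for _, c in groups),
            neuron_range=(0, N),
        ))
    if len(s41) > 1:
        chains.append(s41)

    for g, (start, cnt) in enumerate(groups):
        cores.append(CoreAssignment(
            core_id=f"s42_g{g}", step="4-2", role="potential delay",
            dendrite_op="VB", soma_ops=("Out_Trans",),
            fan_in=cnt, fan_out=cnt, n_vectors=1, vector_len=cnt,
            neuron_range=(start, cnt),
        ))
        cores.append(CoreAssignment(
            core_id=f"s5_g{g}", step="5", role="firing rate",
            dendrite_op="VS", soma_ops=("LUT_Fun", "Out_Trans"),
            fan_in=cnt + 1, fan_out=cnt, n_vectors=1, vector_len=cnt,
            neuron_range=(start, cnt),
        ))
        edges += [
            (f"s3_g{g}_c0", s41[0]),
            (f"s3_g{g}_c1", f"s42_g{g}"),
            (f"s41_g{g}", f"s5_g{g}"),
            (f"s42_g{g}", f"s5_g{g}"),
        ]

    # inter-step edges at core granularity: step-1 -> step-2 heads and
    # step-5 -> step-1 chain heads (element routing is derived from geometry)
    for j in range(n_col):
        for k in range(n_row):
            for g in range(n_vec):
                edges.append((f"s1_j{j}_k{k}", f"s2_g{g}_c0"))
        for g in range(n_vec):
            edges.append((f"s5_g{g}", f"s1_j{j}_k0"))

    placement = Placement(
        grid=(H, W), R=R, constraints=constraints,
        slice_plan=SlicePlan(col_slices, row_slices, span, n_contrib),
        cores=cores, amc_chains=chains, p2p_edges=edges, groups=groups,
    )
    violations = validate_placement(placement, constraints)
    if violations:
        raise PlanningError("infeasible placement: " + "; ".join(violations))
    return placement


# --------------------------------------------------------------------------
# Accounting & validation
# --------------------------------------------------------------------------

_STEP_ORDER = ["1", "2", "3", "4-1", "4-2", "5"]


def resource_report(placement: Placement) -> ResourceReport:
    """Per-step core counts and fan figures, plus the total."""
    by_step = placement.cores_by_step()
    rows = []
    for step in _STEP_ORDER:
        cs = by_step.get(step, [])
        if not cs:
            continue
        rows.append({
            "step": step,
            "functionality": cs[0].role,
            "operation": " + ".join(
                [cs[0].dendrite_op] + [op for op in cs[0].soma_ops if op == "Lat_Acc"]
            ),
            "fan_in": cs[0].fan_in,
            "fan_out": cs[0].fan_out,
            "n_cores": len(cs),
        })
    return ResourceReport(rows=rows, total=sum(r["n_cores"] for r in rows))


def validate_placement(
    placement: Placement, constraints: CoreConstraints | None = None
) -> list[str]:
    """Check every core against the fabric limits; violations are data.

    VMM cores buffer their inputs in the 256-entry axon and store static
    weights in the synapse array, so their fan-in/fan-out are checked
    directly.  Element-wise vector cores stream operands through the dynamic
    synapse banks (128 vectors x 256 entries), so the per-vector length and
    the vector count are the binding limits, not the summed fan-in.
    """
    cons = constraints or placement.constraints
    out: list[str] = []
    for c in placement.cores:
        if c.dendrite_op == "VMM":
            if c.fan_in > cons.fan_in:
                out.append(f"{c.core_id}: fan-in {c.fan_in} > {cons.fan_in}")
            if c.fan_in > cons.synapse_rows or c.fan_out > cons.synapse_cols:
                out.append(f"{c.core_id}: weights {c.fan_in}x{c.fan_out} exceed synapse array")
        else:
            if c.vector_len > cons.synapse_cols:
                out.append(f"{c.core_id}: vector length {c.vector_len} > {cons.synapse_cols}")
            if c.n_vectors > cons.vva_max_vectors:
                out.append(f"{c.core_id}: {c.n_vectors} vectors > {cons.vva_max_vectors}")
            if c.dendrite_op == "VVM" and c.n_vectors != 2:
                out.append(f"{c.core_id}: VVM requires exactly 2 vectors")
            if c.n_vectors * c.vector_len > 2 * cons.vva_max_vectors * cons.synapse_cols:
                out.append(f"{c.core_id}: dynamic vectors exceed synapse capacity")
        if c.fan_out > cons.fan_out:
            out.append(f"{c.core_id}: fan-out {c.fan_out} > {cons.fan_out}")
    return out
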