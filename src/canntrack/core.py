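"""Discretized continuous-attractor network (CANN) tracking dynamics.

A CANN is a recurrent grid of rate neurons with translation-invariant
Gaussian excitation and divisive global inhibition.  Its stable activity
"bump" encodes a 2-D position; injecting frame-difference stimuli makes the
bump follow a moving object.  This module is the floating-point reference
implementation of the discretized dynamics

    V(x, t+1) = ReLU( beta * sum_{x' in CF(x)} J(x, x') r(x', t) + V_ext(x, t) )
    r(x, t+1) = V^2(x, t+1) / (k * sum_x' V^2(x', t+1))

with the interaction kernel restricted to an R x R connection field (CF)
around each neuron and toroidal (wrap-around) boundary conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "KernelSpec",
    "DynamicsParams",
    "NetworkState",
    "build_interaction_kernel",
    "firing_rate",
    "update_potential",
    "step",
    "run_frame",
    "predict_location",
    "seed_state",
    "track_sequence",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Neuron grid geometry.

    The grid is toroidal: the topmost and bottommost rows (and leftmost /
    rightmost columns) are adjacent, which keeps the bump stable at the
    boundary.
    """

    height: int
    width: int
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ConfigurationError("grid dimensions must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_neurons(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian interaction kernel with a local connection field.

    Parameters
    ----------
    J0 : peak interaction scale; the maximum synaptic weight is
        ``J0 / (2 pi a^2)`` between a neuron and itself.
    a : Gaussian interaction range in neuron-grid units.
    R : side length of the square connection field (odd).  Synapses to
        neurons outside the R x R window centered on each neuron are pruned.
    """

    J0: float
    a: float
    R: int

    def __post_init__(self) -> None:
        if self.J0 <= 0 or self.a <= 0:
            raise ConfigurationError("J0 and a must be positive")
        if self.R < 1 or self.R % 2 == 0:
            raise ConfigurationError(f"CF size R must be a positive odd integer, got {self.R}")

    @property
    def peak(self) -> float:
        """Maximum interaction J0 / (2 pi a^2)."""
        return self.J0 / (2.0 * np.pi * self.a**2)


@dataclass(frozen=True)
class DynamicsParams:
    """Global dynamics parameters.

    ``tau`` is fixed to 1 by the discretization (one iteration = one unit of
    the continuous time constant) and is not configurable.  Only the ratio
    ``beta / k`` affects the membrane-potential trajectory; the individual
    values rescale the firing rates uniformly.
    """

    beta: float
    k: float
    n_iter: int = 15
    tau: float = field(default=1.0, init=False)

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.k <= 0:
            raise ConfigurationError("beta and k must be positive")
        if self.n_iter < 0:
            raise ConfigurationError("n_iter must be >= 0")


@dataclass
class NetworkState:
    """Membrane potentials V, firing rates r, and the last inhibition factor.

    Invariants: V >= 0 and r >= 0 elementwise; whenever V is not identically
    zero, ``r.sum() == 1/k`` (algebraic identity of the simplified rate
    equation).  ``s_inh`` is ``1 / (k * sum V^2)`` from the last iteration,
    or 0 for an all-zero V.
    """

    V: np.ndarray
    r: np.ndarray
    s_inh: float = 0.0

    @classmethod
    def zeros(cls, grid: GridSpec) -> "NetworkState":
        return cls(V=np.zeros(grid.shape), r=np.zeros(grid.shape), s_inh=0.0)


# A stimulus frame is a signed H x W array of external inputs (one value per
# neuron, from frame differencing).  Plain ndarrays are used throughout.


# --------------------------------------------------------------------------
# Kernel construction
# --------------------------------------------------------------------------

def toroidal_offset_distance(dr: int, dc: int, grid: GridSpec) -> float:
    """Minimum-image Euclidean distance of an offset on the torus."""
    h, w = grid.shape
    dr = min(abs(dr), h - abs(dr)) if grid.toroidal else abs(dr)
    dc = min(abs(dc), w - abs(dc)) if grid.toroidal else abs(dc)
    return float(np.hypot(dr, dc))


def build_interaction_kernel(grid: GridSpec, kernel: KernelSpec) -> np.ndarray:
    """Build the R x R weight stencil J(x, x') for offsets within the CF.

    Entry ``[h + dr, h + dc]`` (h = (R-1)/2) holds the weight from the neuron
    at offset (dr, dc); the center entry is the self-interaction
    ``J0 / (2 pi a^2)``.  Offsets outside the stencil are implicitly zero
    (the pruned remote connections).
    """
    if kernel.R > min(grid.height, grid.width):
        raise ConfigurationError(
            f"CF size R={kernel.R} exceeds grid dimension {min(grid.shape)}"
        )
    h = (kernel.R - 1) // 2
    stencil = np.empty((kernel.R, kernel.R), dtype=float)
    for dr in range(-h, h + 1):
        for dc in range(-h, h + 1):
            d = toroidal_offset_distance(dr, dc, grid)
            stencil[h + dr, h + dc] = kernel.peak * np.exp(-(d**2) / (2.0 * kernel.a**2))
    return stencil


# --------------------------------------------------------------------------
# One iteration of the difference equation
# --------------------------------------------------------------------------

def firing_rate(V: np.ndarray, k: float) -> np.ndarray:
    """Divisively normalized rates r = V^2 / (k * sum V^2).

    The simplified denominator drops the "+1" of the continuous model, so an
    all-zero V is singular; by convention the rates are then all zero (the
    quiescent start state).  For any nonzero V, ``r.sum() == 1/k``.
    """
    V2 = V * V
    total = V2.sum()
    if total == 0.0:
        return np.zeros_like(V)
    return V2 / (k * total)


def recurrent_input(r: np.ndarray, stencil: np.ndarray, beta: float) -> np.ndarray:
    """beta * sum_{x' in CF} J(x, x') r(x') with toroidal wrap."""
    return beta * correlate(r, stencil, mode="wrap")


def update_potential(
    r: np.ndarray, V_ext: np.ndarray, stencil: np.ndarray, beta: float
) -> np.ndarray:
    """V(x) = ReLU(beta * (J (*) r)(x) + V_ext(x)), CF wrapped toroidally."""
    if r.shape != V_ext.shape:
        raise InputError(f"shape mismatch: r {r.shape} vs V_ext {V_ext.shape}")
    return np.maximum(0.0, recurrent_input(r, stencil, beta) + V_ext)


def step(
    state: NetworkState,
    stim: np.ndarray,
    params: DynamicsParams,
    stencil: np.ndarray,
) -> NetworkState:
    """One iteration: {r(t), V_ext(t)} -> V(t+1) -> r(t+1)."""
    V = update_potential(state.r, stim, stencil, params.beta)
    r = firing_rate(V, params.k)
    total = float((V * V).sum())
    s_inh = 1.0 / (params.k * total) if total > 0 else 0.0
    return NetworkState(V=V, r=r, s_inh=s_inh)


def run_frame(
    state: NetworkState,
    stim: np.ndarray,
    params: DynamicsParams,
    stencil: np.ndarray,
) -> NetworkState:
    """Apply ``step`` n_iter times with the stimulus held constant.

    One difference frame drives several iterations of the difference
    equation (15 by default); the external stimulus is indexed per frame,
    not per iteration.
    """
    for _ in range(params.n_iter):
        state = step(state, stim, params, stencil)
    return state


# --------------------------------------------------------------------------
# Readout
# --------------------------------------------------------------------------

def predict_location(
    r: np.ndarray, prev: tuple[int, int] | None = None
) -> tuple[int, int]:
    """(row, col) of the maximum firing rate; the bump center.

    Ties break to the smallest row, then smallest column (row-major first
    occurrence).  An all-zero rate map carries no information: the previous
    location is returned if supplied, else the grid center, with a warning.
    """
    if not np.all(np.isfinite(r)):
        raise InputError("firing-rate map contains non-finite values")
    if np.all(r == 0):
        if prev is not None:
            logger.warning("all-zero firing rates; keeping previous location %s", prev)
            return prev
        center = (r.shape[0] // 2, r.shape[1] // 2)
        logger.warning("all-zero firing rates and no history; returning grid center %s", center)
        return center
    flat = int(np.argmax(r))
    return (flat // r.shape[1], flat % r.shape[1])


def seed_state(
    grid: GridSpec,
    kernel: KernelSpec,
    params: DynamicsParams,
    center: tuple[int, int],
    stencil: np.ndarray | None = None,
) -> NetworkState:
    """Initial state: a kernel-shaped potential bump at ``center``.

    The bump copies the interaction stencil's shape with peak value
    ``(beta/k) * stencil_center`` — the amplitude a self-sustained bump
    settles to — so tracking starts from an already-formed attractor state.
    """
    if stencil is None:
        stencil = build_interaction_kernel(grid, kernel)
    V = np.zeros(grid.shape)
    h = (kernel.R - 1) // 2
    scale = (params.beta / params.k) * 1.0  # peak = beta/k * (stencil/stencil_center) peak
    rows = (np.arange(-h, h + 1) + center[0]) % grid.height
    cols = (np.arange(-h, h + 1) + center[1]) % grid.width
    V[np.ix_(rows, cols)] = scale * (stencil / stencil[h, h])
    r = firing_rate(V, params.k)
    total = float((V * V).sum())
    return NetworkState(V=V, r=r, s_inh=1.0 / (params.k * total) if total > 0 else 0.0)


# --------------------------------------------------------------------------
# Sequence-level tracking
# --------------------------------------------------------------------------

def grid_to_native(loc: tuple[float, float], scale: tuple[float, float]) -> tuple[float, float]:
    """Map a (row, col) grid location to native-pixel (x, y) center coords."""
    sr, sc = scale
    row, col = loc
    return ((col + 0.5) * sc - 0.5, (row + 0.5) * sr - 0.5)


def native_to_grid(xy: tuple[float, float], scale: tuple[float, float],
                   grid: GridSpec) -> tuple[int, int]:
    """Map a native-pixel (x, y) center to the nearest (row, col) neuron."""
    sr, sc = scale
    x, y = xy
    row = int(np.clip(round((y + 0.5) / sr - 0.5), 0, grid.height - 1))
    col = int(np.clip(round((x + 0.5) / sc - 0.5), 0, grid.width - 1))
    return (row, col)


def track_sequence(
    stimuli: list[np.ndarray],
    init_box: tuple[float, float, float, float],
    grid: GridSpec,
    kernel: KernelSpec,
    params: DynamicsParams,
    scale: tuple[float, float] = (1.0, 1.0),
    stencil: np.ndarray | None = None,
    step_fn=None,
) -> np.ndarray:
    """Track through a stimulus sequence; returns per-frame boxes.

    The state is initialized with a kernel-shaped bump at the first-frame
    ground-truth center (mapped to grid coordinates).  Each stimulus frame
    drives ``n_iter`` iterations, the bump center is read out, mapped back
    to native pixel coordinates, and emitted as a box that keeps the initial
    box's width and height (fixed-scale tracker).

    Returns an array of shape (len(stimuli) + 1, 4) of (x, y, w, h) boxes in
    native coordinates; row 0 is the initial box.

    ``step_fn``, if given, replaces the float per-frame update: it is called
    as ``step_fn(state, stim)`` and must return a state-like object with an
    ``r`` attribute (used by the fixed-point and mapped backends).
    """
    if len(stimuli) == 0:
        raise InputError("empty stimulus sequence")
    x0, y0, w0, h0 = init_box
    cx, cy = x0 + w0 / 2.0, y0 + h0 / 2.0
    loc = native_to_grid((cx, cy), scale, grid)
    if stencil is None:
        stencil = build_interaction_kernel(grid, kernel)
    state = seed_state(grid, kernel, params, loc, stencil)

    boxes = np.empty((len(stimuli) + 1, 4), dtype=float)
    boxes[0] = init_box
    for t, stim in enumerate(stimuli, start=1):
        if stim.shape != grid.shape:
            raise InputError(f"stimulus shape {stim.shape} does not match grid {grid.shape}")
        if step_fn is None:
            state = run_frame(state, stim, params, stencil)
        else:
            state = step_fn(state, stim)
        loc = predict_location(state.r, prev=loc)
        px, py = grid_to_native(loc, scale)
        boxes[t] = (px - w0 / 2.0, py - h0 / 2.0, w0, h0)
    return boxes
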