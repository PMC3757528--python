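"""Target-signal construction and the one-pass least-squares readout.

Training the network means solving W A = Z for the dendrite-to-soma weights
W, where A (M x K) holds the dendritic activations and Z (N x K) the desired
soma signal. The minimum-norm least-squares solution is W = Z A+ (Moore-
Penrose pseudoinverse); a small ridge keeps the solve well-posed when A is
rank-deficient, as happens with sparse spike input. Training is a single
pass — there are no learning rates or iterations.

Because output spikes are sparse, a bare spike train makes a poor regression
target: the target spike is widened into a square pulse (default 10 steps of
unit amplitude) and displaced past the end of the input pattern (default 10
steps) so the dendritic responses have time to peak. The firing threshold is
then set at a fraction (default 25%) of the target amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import linalg

from .io import SpikeRaster, SKIMModel
from .kernels import sample_kernel_bank
from .network import dendritic_activations, init_input_weights, summed_input

__all__ = [
    "TargetSignal",
    "build_target",
    "solve_batch",
    "IncrementalSolver",
    "solve_incremental",
    "choose_threshold",
    "train",
    "training_residual",
]


def _merge_windows(windows: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    ws = sorted((int(a), int(b)) for a, b in windows if b > a)
    merged: list[tuple[int, int]] = []
    for a, b in ws:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


@dataclass
class TargetSignal:
    """Analog soma target Z: ``amplitude`` inside spike windows, 0 outside."""

    values: np.ndarray
    spike_windows: list  # per output: list of (start, end) half-open intervals
    amplitude: float

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))

    @property
    def n_outputs(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def build_target(
    pattern_end_times,
    K: int,
    width: int = 10,
    delay: int = 10,
    amplitude: float = 1.0,
) -> TargetSignal:
    """Build the widened, delayed square-pulse target from pattern end times.

    For each end time ``e`` the window ``[e + delay, e + delay + width)`` is
    set to ``amplitude``; overlapping windows merge and windows are clipped
    at ``K``. ``pattern_end_times`` may be a flat list (one output) or a list
    of lists (one per output neuron).
    """
    if width < 1 or delay < 0:
        raise ValueError("require width >= 1 and delay >= 0")
    ends = list(pattern_end_times)
    nested = len(ends) > 0 and isinstance(ends[0], (list, tuple, np.ndarray))
    per_output = [list(e) for e in ends] if nested else [ends]
    N = len(per_output)
    Z = np.zeros((N, K))
    all_windows = []
    for n, es in enumerate(per_output):
        windows = _merge_windows(
            (min(e + delay, K), min(e + delay + width, K)) for e in es
        )
        windows = [(a, b) for a, b in windows if b > a]
        for a, b in windows:
            Z[n, a:b] = amplitude
        all_windows.append(windows)
    return TargetSignal(values=Z, spike_windows=all_windows, amplitude=amplitude)


def _as_matrix(Z) -> np.ndarray:
    if isinstance(Z, TargetSignal):
        return Z.values
    return np.atleast_2d(np.asarray(Z, dtype=float))


def solve_batch(
    A: np.ndarray,
    Z,
    ridge: float = 1e-8,
    sv_cutoff: Optional[float] = None,
) -> np.ndarray:
    """Solve the output weights W minimizing ||W A - Z||_F^2 + ridge ||W||_F^2.

    Computed by a QR/SVD least-squares factorization of the (optionally
    ridge-augmented) design, never by forming normal equations. At
    ``ridge=0`` this is exactly the pseudoinverse solution W = Z A+
    (minimum-norm). ``sv_cutoff`` optionally discards singular values below
    the given fraction of the largest (rank-truncated pseudoinverse).

    Warns when there are fewer samples than dendrites (K < M): the system is
    underdetermined and the minimum-norm solution is returned.
    """
    A = np.asarray(A, dtype=float)
    Zm = _as_matrix(Z)
    if A.ndim != 2:
        raise ValueError("A must be 2-D (M x K)")
    M, K = A.shape
    if Zm.shape[1] != K:
        raise ValueError(f"A has K={K} columns but Z has {Zm.shape[1]}")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if K < M:
        warnings.warn(
            f"underdetermined system: K={K} samples < M={M} dendrites; "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    if sv_cutoff is not None:
        Wt, *_ = linalg.lstsq(A.T, Zm.T, cond=sv_cutoff, lapack_driver="gelsd")
        return Wt.T
    if ridge == 0:
        Wt, *_ = linalg.lstsq(A.T, Zm.T, lapack_driver="gelsd")
        return Wt.T
    # Ridge via the augmented system [A.T; sqrt(ridge) I] — unique solution,
    # solved with column-pivoted QR (fast, stable).
    aug = np.vstack([A.T, np.sqrt(ridge) * np.eye(M)])
    rhs = np.vstack([Zm.T, np.zeros((M, Zm.shape[0]))])
    Wt, *_ = linalg.lstsq(aug, rhs, lapack_driver="gelsy")
    return Wt.T


class IncrementalSolver:
    """Recursive least-squares accumulation of the readout weights.

    Maintains the inverse regularized Gram matrix P = (A A.T + ridge I)^-1
    by rank-one (Sherman-Morrison) updates together with the cross moment
    C = Z A.T, one (a_t, z_t) sample at a time; ``solve()`` returns W = C P,
    identical (to rounding) to the batch solution on the concatenated data.
    Suitable for online learning or data too large to hold as one matrix.
    """

    def __init__(self, n_dendrites: int, n_outputs: int = 1, ridge: float = 1e-8):
        if ridge <= 0:
            raise ValueError("incremental solving requires ridge > 0")
        self.M = n_dendrites
        self.N = n_outputs
        self.ridge = ridge
        self.P = np.eye(n_dendrites) / ridge
        self.C = np.zeros((n_outputs, n_dendrites))
        self.n_seen = 0

    def update(self, a: np.ndarray, z) -> None:
        a = np.asarray(a, dtype=float).ravel()
        z = np.atleast_1d(np.asarray(z, dtype=float)).ravel()
        if a.shape != (self.M,) or z.shape != (self.N,):
            raise ValueError(
                f"sample dims ({a.shape[0]}, {z.shape[0]}) drifted from "
                f"(M={self.M}, N={self.N})"
            )
        Pa = self.P @ a
        self.P -= np.outer(Pa, Pa) / (1.0 + a @ Pa)
        self.C += np.outer(z, a)
        self.n_seen += 1

    def solve(self) -> np.ndarray:
        return self.C @ self.P


def solve_incremental(stream, ridge: float = 1e-8) -> np.ndarray:
    """Solve W from a stream of (a_t, z_t) pairs via recursive least squares.

    Equivalent to :func:`solve_batch` on the stacked data; the order of the
    samples does not matter.
    """
    solver = None
    for a, z in stream:
        a = np.asarray(a, dtype=float).ravel()
        z = np.atleast_1d(np.asarray(z, dtype=float)).ravel()
        if solver is None:
            solver = IncrementalSolver(len(a), len(z), ridge=ridge)
        solver.update(a, z)
    if solver is None:
        raise ValueError("stream contained no samples")
    return solver.solve()


def choose_threshold(amplitude: float, fraction: float = 0.25) -> float:
    """Firing threshold as a fraction of the target spike amplitude.

    A threshold at 25% of the amplitude detects more reliably than the
    half-amplitude one might expect, because sparse targets keep the solved
    soma excursions small.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if not amplitude > 0:
        raise ValueError("amplitude must be positive")
    return fraction * amplitude


def training_residual(W: np.ndarray, A: np.ndarray, Z) -> float:
    """Frobenius norm of the regression residual ||W A - Z||_F."""
    return float(np.linalg.norm(np.atleast_2d(W) @ A - _as_matrix(Z)))


def derive_seeds(seed: int, n: int) -> list[int]:
    """Split one integer seed into n independent child seeds (< 2**31)."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def train(
    raster: SpikeRaster,
    pattern_end_times,
    M: int = 100,
    family: str = "alpha",
    t_max: int = 200,
    k: float = 5.0,
    compression: str = "logistic",
    ts_mode: str = "uniform",
    weight_low: float = -0.5,
    weight_high: float = 0.5,
    ridge: float = 1e-8,
    target_width: int = 10,
    target_delay: int = 10,
    target_amplitude: float = 1.0,
    threshold_fraction: float = 0.25,
    order: str = "filter_then_nonlinearity",
    seed: int = 0,
    sv_cutoff: Optional[float] = None,
    return_internals: bool = False,
):
    """Synthesize a complete network from a training raster in one pass.

    Draws the fixed random input weights and kernel bank, runs the forward
    projection to get activations A, builds the widened target Z from the
    pattern end times, solves W = Z A+ (ridge-stabilized), and sets the
    firing threshold. Deterministic given ``seed``.

    ``sv_cutoff`` switches the solve to a rank-truncated pseudoinverse
    (singular values below the given fraction of the largest are dropped).
    Recommended when heavily over-provisioning dendrites before pruning: on
    a rank-deficient bank the minimum-norm solution loads large opposing
    weights onto noise directions, which makes |weight| useless as an
    importance signal; truncation restores it.

    Returns the :class:`~skimnet.io.SKIMModel`; with ``return_internals``
    also the tuple (A, target).
    """
    w_seed, k_seed = derive_seeds(seed, 2)
    w1 = init_input_weights(raster.n_channels, M, weight_low, weight_high, seed=w_seed)
    kernels = sample_kernel_bank(
        M, family=family, t_max=t_max, seed=k_seed, k=k,
        compression=compression, ts_mode=ts_mode,
    )
    u = summed_input(raster, w1)
    A = dendritic_activations(u, kernels, order=order)
    target = build_target(
        pattern_end_times, raster.n_steps, width=target_width,
        delay=target_delay, amplitude=target_amplitude,
    )
    W = solve_batch(A, target, ridge=ridge, sv_cutoff=sv_cutoff)
    model = SKIMModel(
        L=raster.n_channels, M=M, N=target.n_outputs,
        input_weights=w1, kernels=kernels, output_weights=W,
        threshold=choose_threshold(target_amplitude, threshold_fraction),
        target_amplitude=target_amplitude, seed=seed, dt=raster.dt,
    )
    if return_internals:
        return model, A, target
    return model
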