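"""Forward pass of the two-layer network.

Input spikes are projected through fixed random weights onto M dendritic
branches; each branch convolves its summed input with its synaptic kernel
and compresses the result, giving the activation matrix A (M x K). A linear
soma weights the branches and the output neuron spikes on rising threshold
crossings of the soma potential.

The whole pass is a pure function of (raster, model): all randomness lives
in the model construction.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal

from .io import SpikeRaster, SKIMModel
from .kernels import KernelSpec, compress, truncated_response

__all__ = [
    "init_input_weights",
    "summed_input",
    "dendritic_activations",
    "soma",
    "threshold_spikes",
    "forward",
]


def init_input_weights(
    L: int, M: int, low: float = -0.5, high: float = 0.5, seed: int = 0
) -> np.ndarray:
    """Fixed random first-layer weights, i.i.d. Uniform(low, high), shape (M, L).

    These are never trained; only the dendrite-to-soma weights are solved.
    """
    if L <= 0 or M <= 0:
        raise ValueError("L and M must be positive")
    if not low < high:
        raise ValueError("require low < high")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=(M, L))


def summed_input(raster: SpikeRaster, input_weights: np.ndarray) -> np.ndarray:
    """Weighted spike sum u[j, t] = sum_i w1[j, i] * x[i, t], shape (M, K).

    Zero wherever no input spikes occur; simultaneous spikes superpose.
    """
    input_weights = np.asarray(input_weights)
    if input_weights.ndim != 2 or input_weights.shape[1] != raster.n_channels:
        raise ValueError(
            f"input_weights shape {input_weights.shape} incompatible with "
            f"L={raster.n_channels}"
        )
    M = input_weights.shape[0]
    u = np.zeros((M, raster.n_steps))
    if raster.events:
        ev = np.array(sorted(raster.events), dtype=np.intp)
        times, chans = ev[:, 0], ev[:, 1]
        # scatter-add handles multiple channels spiking at the same step
        np.add.at(u.T, times, input_weights[:, chans].T)
    return u


def dendritic_activations(
    u: np.ndarray,
    kernels: Sequence[KernelSpec],
    order: str = "filter_then_nonlinearity",
) -> np.ndarray:
    """Kernel-filtered, compressed dendritic activations A, shape (M, K).

    Default order convolves each dendrite's summed input with its truncated
    impulse response (individual spike responses superpose linearly) and
    compresses the sum — overlapping responses are then jointly compressed,
    which is what gives the synapse history-dependent (depressive)
    adaptation. The alternate order ``nonlinearity_then_filter`` compresses
    each scaled impulse response independently before superposition; it is
    supported for comparison but scales every event independently and loses
    that adaptation.
    """
    u = np.asarray(u, dtype=float)
    M, K = u.shape
    if len(kernels) != M:
        raise ValueError(f"expected {M} kernels, got {len(kernels)}")
    if order not in ("filter_then_nonlinearity", "nonlinearity_then_filter"):
        raise ValueError(f"unknown order {order!r}")
    A = np.empty((M, K))
    if order == "filter_then_nonlinearity":
        for j, spec in enumerate(kernels):
            h = truncated_response(spec)
            v = signal.fftconvolve(u[j], h)[:K] if len(h) > 1 else u[j] * h[0]
            A[j] = compress(v, spec.k, spec.compression)
    else:
        for j, spec in enumerate(kernels):
            h = truncated_response(spec)
            v = np.zeros(K)
            for t0 in np.nonzero(u[j])[0]:
                seg = min(len(h), K - t0)
                v[t0:t0 + seg] += compress(u[j, t0] * h[:seg], spec.k, spec.compression)
            A[j] = v
    return A


def soma(A: np.ndarray, output_weights: np.ndarray) -> np.ndarray:
    """Pre-threshold soma potentials y = w2 @ A, shape (N, K). Purely linear."""
    A = np.asarray(A)
    output_weights = np.asarray(output_weights)
    if output_weights.ndim != 2 or output_weights.shape[1] != A.shape[0]:
        raise ValueError(
            f"output_weights shape {output_weights.shape} incompatible with "
            f"M={A.shape[0]}"
        )
    return output_weights @ A


def threshold_spikes(y: np.ndarray, theta: float, dt: float = 1.0) -> SpikeRaster:
    """Emit one output spike per rising crossing of the threshold.

    A spike occurs at each timestep where y goes from below theta to at or
    above it; a sustained supra-threshold plateau yields a single spike at
    its onset (closely spaced recognitions merge into one event). A trace
    already above threshold at t=0 spikes at t=0.
    """
    if not theta > 0:
        raise ValueError("theta must be positive")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    above = y >= theta
    prev = np.concatenate([np.zeros((y.shape[0], 1), dtype=bool), above[:, :-1]], axis=1)
    rising = above & ~prev
    chans, times = np.nonzero(rising)
    events = frozenset(zip(times.tolist(), chans.tolist()))
    return SpikeRaster(n_channels=y.shape[0], n_steps=y.shape[1], events=events, dt=dt)


def _forward_with_reset(raster: SpikeRaster, model: SKIMModel):
    """Stepwise forward pass that zeroes all dendritic state at firing steps.

    Pending kernel contributions from past spikes are kept in a ring buffer
    per dendrite and cleared whenever any output fires (hyperpolarization).
    Quadratic-ish and loop-heavy; intended for small problems.
    """
    u = summed_input(raster, model.input_weights)
    M, K = u.shape
    hs = [truncated_response(spec) for spec in model.kernels]
    width = max(len(h) for h in hs)
    H = np.zeros((M, width))
    for j, h in enumerate(hs):
        H[j, : len(h)] = h
    pending = np.zeros((M, width))  # pending[:, i] = contribution at step t+i
    A = np.empty((M, K))
    y = np.empty((model.N, K))
    fired_prev = np.zeros(model.N, dtype=bool)
    events = set()
    for t in range(K):
        col = u[:, t]
        if np.any(col):
            pending += col[:, None] * H
        v_t = pending[:, 0].copy()
        a_t = np.array(
            [compress(v_t[j], model.kernels[j].k, model.kernels[j].compression)
             for j in range(M)]
        )
        A[:, t] = a_t
        y_t = model.output_weights @ a_t
        y[:, t] = y_t
        above = y_t >= model.threshold
        rising = above & ~fired_prev
        for n in np.nonzero(rising)[0]:
            events.add((t, int(n)))
        if rising.any():
            pending[:] = 0.0  # reset: all dendritic potentials forced to zero
        fired_prev = above
        pending[:, :-1] = pending[:, 1:]
        pending[:, -1] = 0.0
    out = SpikeRaster(n_channels=model.N, n_steps=K, events=frozenset(events),
                      dt=model.dt)
    return out, y, A


def forward(
    raster: SpikeRaster,
    model: SKIMModel,
    order: str = "filter_then_nonlinearity",
    reset: bool = False,
    return_trace: bool = False,
):
    """Run the full forward pass: raster -> output spike raster.

    With ``reset=True`` the simulation runs stepwise and zeroes all dendritic
    potentials whenever an output fires; default is the fast vectorized pass
    (resetting has shown no significant effect in practice and is off by
    default). Returns the output raster, plus (soma trace, activations) when
    ``return_trace`` is set.
    """
    if raster.n_channels != model.L:
        raise ValueError(f"raster has {raster.n_channels} channels, model expects {model.L}")
    if reset:
        out, y, A = _forward_with_reset(raster, model)
    else:
        u = summed_input(raster, model.input_weights)
        A = dendritic_activations(u, model.kernels, order=order)
        y = soma(A, model.output_weights)
        out = threshold_spikes(y, model.threshold, dt=model.dt)
    return (out, y, A) if return_trace else out
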