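"""Weight-concentration analysis and synaptic pruning.

The solved dendritic weights are strongly concentrated: in a typical
detection network roughly a quarter of the dendrites carry half of the
total |weight| mass, and half carry about 80%. Low-weight dendrites can
therefore be pruned with little loss — provided the remaining weights are
re-solved, since dropping regressors leaves the old solution non-optimal.

Two strategies:

- two-pass: over-provision (e.g. 10x), train, keep the largest-|weight|
  dendrites, re-solve. The pruned network is typically better than a
  same-size network trained once, because the kept dendrites are the best
  of a much larger random draw.
- iterative: train at the target size, repeatedly replace the lowest-weight
  dendrites with fresh random ones and re-solve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import SpikeRaster, SKIMModel
from .kernels import sample_kernel_bank
from .network import dendritic_activations, summed_input
from .solver import TargetSignal, _as_matrix, derive_seeds, solve_batch

__all__ = [
    "ConcentrationCurve",
    "weight_concentration",
    "dendrite_importance",
    "prune_two_pass",
    "prune_iterative",
]


@dataclass(frozen=True)
class ConcentrationCurve:
    """Cumulative share of total |weight| mass vs. dendrite rank.

    ``fractions[r-1]`` is the share held by the r largest-|weight|
    dendrites; non-decreasing, concave, ending at 1.
    """

    fractions: tuple

    def share_at(self, rank: int) -> float:
        """Cumulative share held by the top ``rank`` dendrites."""
        if not 1 <= rank <= len(self.fractions):
            raise ValueError(f"rank {rank} outside [1, {len(self.fractions)}]")
        return self.fractions[rank - 1]

    def share_at_fraction(self, q: float) -> float:
        """Share held by the top fraction ``q`` of dendrites (e.g. 0.25)."""
        rank = max(1, int(round(q * len(self.fractions))))
        return self.share_at(rank)


def weight_concentration(
    output_weights: np.ndarray, output_index: Optional[int] = 0
) -> ConcentrationCurve:
    """Sorted cumulative |weight| share per dendrite for one output neuron.

    ``output_index=None`` aggregates |weights| across all outputs (the
    importance used for pruning in multi-output networks).
    """
    W = np.atleast_2d(np.asarray(output_weights, dtype=float))
    mags = np.abs(W).sum(axis=0) if output_index is None else np.abs(W[output_index])
    total = mags.sum()
    if total == 0:
        raise ValueError("all-zero weight row: concentration undefined")
    cum = np.cumsum(np.sort(mags)[::-1]) / total
    return ConcentrationCurve(fractions=tuple(float(v) for v in cum))


def dendrite_importance(model: SKIMModel) -> np.ndarray:
    """Summed |output weight| per dendrite across output neurons."""
    return np.abs(model.output_weights).sum(axis=0)


def _resolve(model: SKIMModel, raster: SpikeRaster, target, keep_idx, ridge: float):
    """Subset the dendrites, recompute activations, re-solve the readout."""
    keep_idx = np.asarray(sorted(keep_idx), dtype=np.intp)
    w1 = model.input_weights[keep_idx]
    kernels = [model.kernels[j] for j in keep_idx]
    u = summed_input(raster, w1)
    A = dendritic_activations(u, kernels)
    W = solve_batch(A, target, ridge=ridge)
    pruned = SKIMModel(
        L=model.L, M=len(keep_idx), N=model.N,
        input_weights=w1, kernels=kernels, output_weights=W,
        threshold=model.threshold, target_amplitude=model.target_amplitude,
        seed=model.seed, dt=model.dt,
    )
    return pruned, A


def prune_two_pass(
    model: SKIMModel,
    raster: SpikeRaster,
    target,
    keep: int,
    ridge: float = 1e-8,
) -> SKIMModel:
    """Keep the ``keep`` largest-|weight| dendrites and re-solve the readout.

    Importance is the summed |output weight| across output neurons. The
    dropped dendrites' input weights and kernels are removed outright; the
    re-solve on the same training data is mandatory.
    """
    if not 1 <= keep <= model.M:
        raise ValueError(f"keep must lie in [1, {model.M}]")
    order = np.argsort(dendrite_importance(model))[::-1]
    pruned, _ = _resolve(model, raster, target, order[:keep], ridge)
    return pruned


def prune_iterative(
    model: SKIMModel,
    raster: SpikeRaster,
    target,
    n_replace: int,
    iterations: int,
    seed: int = 0,
    ridge: float = 1e-8,
    weight_low: float = -0.5,
    weight_high: float = 0.5,
    t_max: int = 200,
) -> SKIMModel:
    """Iteratively replace the lowest-weight dendrites with fresh random ones.

    Each round drops the ``n_replace`` dendrites of smallest importance,
    draws that many fresh random dendrites (new input-weight rows and new
    kernels from the same family as the model's bank), and re-solves. The
    final model keeps the model's size. Deterministic per ``seed``.
    """
    n_keep = model.M
    if not 0 <= n_replace < n_keep:
        raise ValueError("require 0 <= n_replace < M")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    family = model.kernels[0].family
    k = model.kernels[0].k
    compression = model.kernels[0].compression
    current = model
    seeds = derive_seeds(seed, 2 * iterations)
    for it in range(iterations):
        w_seed, k_seed = seeds[2 * it], seeds[2 * it + 1]
        order = np.argsort(dendrite_importance(current))[::-1]
        kept = order[: n_keep - n_replace] if n_replace else order
        w1_kept = current.input_weights[kept]
        kernels_kept = [current.kernels[j] for j in kept]
        if n_replace:
            rng = np.random.default_rng(w_seed)
            w1_new = rng.uniform(weight_low, weight_high, size=(n_replace, model.L))
            kernels_new = sample_kernel_bank(
                n_replace, family=family, t_max=t_max, seed=k_seed,
                k=k, compression=compression,
            )
            w1 = np.vstack([w1_kept, w1_new])
            kernels = kernels_kept + kernels_new
        else:
            w1, kernels = w1_kept, kernels_kept
        u = summed_input(raster, w1)
        A = dendritic_activations(u, kernels)
        W = solve_batch(A, target, ridge=ridge)
        current = SKIMModel(
            L=model.L, M=n_keep, N=model.N,
            input_weights=w1, kernels=kernels, output_weights=W,
            threshold=model.threshold, target_amplitude=model.target_amplitude,
            seed=model.seed, dt=model.dt,
        )
    return current
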