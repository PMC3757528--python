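"""Synthetic spatio-temporal pattern-recognition tasks.

The benchmark task: a fixed multichannel spike pattern (default nine spikes
across five channels in a nominal 200-step window) is embedded repeatedly in
a long sequence as a Poisson process, on top of independent Poisson noise
spikes of roughly equal number. The network must spike when — and only when
— the pattern has just been presented. Presentations may overlap each other
and the noise; spike collisions resolve by OR (the raster is binary).

Per-presentation time warping and spike jitter are opt-in transforms; by
default every presentation is an exact copy of the pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io import SpikeRaster

__all__ = [
    "PatternSpec",
    "EmbeddedSequence",
    "make_pattern",
    "embed_pattern",
    "time_warp",
    "jitter",
]


@dataclass(frozen=True)
class PatternSpec:
    """A fixed spatio-temporal spike pattern.

    ``spikes`` is a tuple of (channel, offset) pairs with offsets in
    ``[0, duration)``; channels may carry zero, one, or several spikes.
    """

    n_channels: int
    spikes: tuple
    duration: int
    seed: int = 0

    def __post_init__(self):
        spikes = tuple(sorted((int(c), int(o)) for c, o in self.spikes))
        if len(spikes) == 0:
            raise ValueError("pattern must contain at least one spike")
        if len(set(spikes)) != len(spikes):
            raise ValueError("duplicate (channel, offset) in pattern")
        for c, o in spikes:
            if not (0 <= c < self.n_channels):
                raise ValueError(f"channel {c} outside [0, {self.n_channels})")
            if not (0 <= o < self.duration):
                raise ValueError(f"offset {o} outside [0, {self.duration})")
        object.__setattr__(self, "spikes", spikes)

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)


@dataclass
class EmbeddedSequence:
    """A long spike sequence with ground-truth pattern presentations.

    ``presentation_end_times[i]`` is the functional end of the i-th embedded
    copy — one step past its last spike — sorted ascending; this is the time
    the input sequence ends and hence the anchor for the training target.
    ``nominal_end_times`` holds start + duration (the end of the nominal
    pattern window) for reference. Spike counts are the numbers drawn before
    OR-merging collisions.
    """

    raster: SpikeRaster
    presentation_end_times: list = field(default_factory=list)
    n_noise_spikes: int = 0
    n_pattern_spikes: int = 0
    nominal_end_times: list = field(default_factory=list)


def make_pattern(
    L: int = 5,
    n_spikes: int = 9,
    duration: int = 200,
    seed: int = 0,
    per_channel_range: Optional[tuple[int, int]] = None,
) -> PatternSpec:
    """Draw a random pattern: n_spikes distinct (channel, offset) cells.

    Placement is uniform over the L x duration grid without duplicates.
    ``per_channel_range=(lo, hi)`` optionally constrains every channel to
    carry between lo and hi spikes (e.g. (1, 3) for one-to-three spikes per
    channel), drawn by rejection on the channel counts.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be >= 1")
    if n_spikes > L * duration:
        raise ValueError(f"cannot place {n_spikes} distinct spikes on a "
                         f"{L}x{duration} grid")
    rng = np.random.default_rng(seed)
    if per_channel_range is None:
        flat = rng.choice(L * duration, size=n_spikes, replace=False)
        spikes = tuple((int(i // duration), int(i % duration)) for i in flat)
    else:
        lo, hi = per_channel_range
        if not (0 <= lo <= hi) or lo * L > n_spikes or hi * L < n_spikes:
            raise ValueError(f"per-channel range ({lo},{hi}) infeasible for "
                             f"{n_spikes} spikes on {L} channels")
        while True:  # rejection on the per-channel counts
            counts = rng.integers(lo, hi + 1, size=L)
            if counts.sum() == n_spikes:
                break
        spikes = []
        for c in range(L):
            offs = rng.choice(duration, size=int(counts[c]), replace=False)
            spikes.extend((c, int(o)) for o in offs)
        spikes = tuple(spikes)
    return PatternSpec(n_channels=L, spikes=spikes, duration=duration, seed=seed)


def embed_pattern(
    pattern: PatternSpec,
    K: int,
    presentation_rate: float = 580e-5,
    noise_ratio: float = 1.0,
    seed: int = 0,
    warp_range: Optional[tuple[float, float]] = None,
    jitter_sd: float = 0.0,
) -> EmbeddedSequence:
    """Embed Poisson-distributed pattern copies among Poisson noise spikes.

    Presentation start times form a Poisson process of ``presentation_rate``
    per timestep (count ~ Poisson(rate * K), starts uniform on
    ``[0, K - duration]``); overlapping copies are permitted and merge by OR.
    Independent noise spikes are added uniformly over channels and time with
    expected total ``noise_ratio`` times the expected number of pattern
    spikes (the default makes noise and pattern spikes roughly equal in
    number). When ``warp_range=(lo, hi)`` each presentation is time-warped
    by an independent Uniform(lo, hi) factor; ``jitter_sd`` adds Gaussian
    jitter to each presented spike. Ground-truth end times are returned.
    """
    if K < pattern.duration:
        raise ValueError("sequence shorter than the pattern")
    if noise_ratio < 0 or presentation_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    n_pres = int(rng.poisson(presentation_rate * K))
    max_dur = pattern.duration
    if warp_range is not None:
        max_dur = int(np.ceil(pattern.duration * max(warp_range)))
    starts = np.sort(rng.integers(0, max(K - max_dur, 0) + 1, size=n_pres))
    events = set()
    end_times = []
    nominal_ends = []
    n_pattern_spikes = 0
    for s in starts:
        p = pattern
        if warp_range is not None:
            p = time_warp(p, rng.uniform(*warp_range))
        if jitter_sd > 0:
            p = jitter(p, jitter_sd, seed=int(rng.integers(2 ** 31)))
        for c, o in p.spikes:
            events.add((int(s + o), c))
        n_pattern_spikes += p.n_spikes
        # the input sequence ends with its last spike, which anchors the
        # target ("the output spike follows the end of the input sequence")
        end_times.append(int(s + max(o for _, o in p.spikes) + 1))
        nominal_ends.append(int(s + p.duration))
    expected_pattern = presentation_rate * K * pattern.n_spikes
    n_noise = int(rng.poisson(noise_ratio * expected_pattern))
    noise_t = rng.integers(0, K, size=n_noise)
    noise_c = rng.integers(0, pattern.n_channels, size=n_noise)
    events.update(zip(noise_t.tolist(), noise_c.tolist()))
    raster = SpikeRaster(n_channels=pattern.n_channels, n_steps=K,
                         events=frozenset(events))
    return EmbeddedSequence(
        raster=raster,
        presentation_end_times=sorted(end_times),
        n_noise_spikes=n_noise,
        n_pattern_spikes=n_pattern_spikes,
        nominal_end_times=sorted(nominal_ends),
    )


def _dedupe(spikes, duration: int) -> tuple:
    """Resolve per-channel offset collisions by nudging to a free slot."""
    out = set()
    for c, o in spikes:
        o = int(np.clip(o, 0, duration - 1))
        step = 1
        while (c, o) in out:
            o2 = o + step
            if 0 <= o2 < duration and (c, o2) not in out:
                o = o2
                break
            step = -step if step > 0 else -(step - 1)
            if abs(step) > 2 * duration:
                raise ValueError("channel full; cannot place spike")
        out.add((c, o))
    return tuple(sorted(out))


def time_warp(pattern: PatternSpec, factor: float) -> PatternSpec:
    """Uniformly rescale the pattern in time (cadence change).

    Offsets and duration scale by ``factor`` with rounding to the timestep
    grid; channel identities and spike count are preserved (grid collisions
    after rounding are nudged to the nearest free offset).
    """
    if not factor > 0:
        raise ValueError("factor must be > 0")
    new_dur = max(1, int(round(pattern.duration * factor)))
    scaled = [(c, int(round(o * factor))) for c, o in pattern.spikes]
    return replace(pattern, spikes=_dedupe(scaled, new_dur), duration=new_dur)


def jitter(pattern: PatternSpec, sd: float, seed: int = 0) -> PatternSpec:
    """Perturb each spike offset by rounded zero-mean Gaussian noise.

    Offsets are clipped to ``[0, duration)``; collisions nudge to a free
    slot so the spike count is preserved. ``sd=0`` is the identity.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return pattern
    rng = np.random.default_rng(seed)
    moved = [
        (c, int(round(o + rng.normal(0.0, sd)))) for c, o in pattern.spikes
    ]
    return replace(pattern, spikes=_dedupe(moved, pattern.duration))
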