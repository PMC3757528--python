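"""Spike event containers and file I/O.

Spike data are discrete-time event lists: a spike is a ``(timestep, channel)``
pair on an integer time grid, 0-based in both coordinates. The physical
duration of a timestep (``dt``, in ms) is carried as metadata only — all
computation happens on the grid.

Interchange format for spikes is CSV with header ``timestep,channel``;
trained networks are stored as HDF5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .kernels import KernelSpec

MODEL_FORMAT_VERSION = 1

__all__ = [
    "SpikeRaster",
    "SKIMModel",
    "read_raster",
    "write_raster",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SpikeRaster:
    """A multichannel spike train on a discrete time grid.

    Parameters
    ----------
    n_channels : int
        Number of channels (``L`` for network inputs, ``N`` for outputs).
    n_steps : int
        Number of timesteps ``K``; events live on ``[0, n_steps)``.
    events : frozenset of (int, int)
        Set of ``(timestep, channel)`` pairs. At most one spike per cell —
        the raster is binary.
    dt : float
        Milliseconds per timestep (metadata only).
    """

    n_channels: int
    n_steps: int
    events: frozenset = field(default_factory=frozenset)
    dt: float = 1.0

    def __post_init__(self):
        if self.n_channels <= 0 or self.n_steps <= 0:
            raise ValueError("n_channels and n_steps must be positive")
        events = frozenset((int(t), int(c)) for t, c in self.events)
        for t, c in events:
            if not (0 <= t < self.n_steps):
                raise ValueError(
                    f"event timestep {t} outside [0, {self.n_steps})"
                )
            if not (0 <= c < self.n_channels):
                raise ValueError(
                    f"event channel {c} outside [0, {self.n_channels})"
                )
        object.__setattr__(self, "events", events)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_dense(self) -> np.ndarray:
        """Return the raster as a dense (n_channels, n_steps) 0/1 array."""
        x = np.zeros((self.n_channels, self.n_steps))
        if self.events:
            ev = np.array(sorted(self.events), dtype=np.intp)
            x[ev[:, 1], ev[:, 0]] = 1.0
        return x

    @classmethod
    def from_dense(cls, x: np.ndarray, dt: float = 1.0) -> "SpikeRaster":
        """Build a raster from a (n_channels, n_steps) array; nonzero = spike."""
        x = np.asarray(x)
        chans, times = np.nonzero(x)
        events = frozenset(zip(times.tolist(), chans.tolist()))
        return cls(n_channels=x.shape[0], n_steps=x.shape[1], events=events, dt=dt)

    def restrict(self, n_steps: int) -> "SpikeRaster":
        """Drop events at or after ``n_steps`` (used for causality checks)."""
        kept = frozenset((t, c) for t, c in self.events if t < n_steps)
        return replace(self, n_steps=n_steps, events=kept)


@dataclass
class SKIMModel:
    """A fully synthesized two-layer spiking network.

    The first layer projects ``L`` input channels onto ``M`` dendritic
    branches through fixed random weights ``input_weights`` (w1); each
    branch filters its summed input with a synaptic kernel and a compressive
    nonlinearity. The soma of each of ``N`` output neurons sums the branches
    through the solved weights ``output_weights`` (w2) and spikes when the
    potential crosses ``threshold``.
    """

    L: int
    M: int
    N: int
    input_weights: np.ndarray
    kernels: Sequence[KernelSpec]
    output_weights: np.ndarray
    threshold: float
    target_amplitude: float = 1.0
    seed: int = 0
    dt: float = 1.0

    def __post_init__(self):
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.output_weights = np.asarray(self.output_weights, dtype=float)
        self.kernels = list(self.kernels)
        if self.input_weights.shape != (self.M, self.L):
            raise ValueError(
                f"input_weights shape {self.input_weights.shape} != ({self.M}, {self.L})"
            )
        if self.output_weights.shape != (self.N, self.M):
            raise ValueError(
                f"output_weights shape {self.output_weights.shape} != ({self.N}, {self.M})"
            )
        if len(self.kernels) != self.M:
            raise ValueError(f"expected {self.M} kernels, got {len(self.kernels)}")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")


def read_raster(path, n_channels: int, n_steps: int, dt: float = 1.0) -> SpikeRaster:
    """Read a spike raster from a ``timestep,channel`` CSV.

    Duplicate rows collapse to a single event (the raster is a set).
    Malformed rows raise a :class:`ValueError` naming the offending line;
    events outside the declared bounds raise as well.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty file, expected 'timestep,channel' header") from exc
    if list(df.columns[:2]) != ["timestep", "channel"]:
        raise ValueError(
            f"{path}: expected header 'timestep,channel', got {list(df.columns)}"
        )
    events = set()
    for i, (t_raw, c_raw) in enumerate(zip(df["timestep"], df["channel"])):
        # +2: 1-based line numbers and one header line.
        line = i + 2
        try:
            t, c = int(t_raw), int(c_raw)
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed row at line {line}: {t_raw!r},{c_raw!r}"
            ) from exc
        if not (0 <= t < n_steps) or not (0 <= c < n_channels):
            raise ValueError(
                f"{path}: line {line}: event ({t},{c}) outside declared bounds "
                f"K={n_steps}, L={n_channels}"
            )
        events.add((t, c))
    return SpikeRaster(n_channels=n_channels, n_steps=n_steps,
                       events=frozenset(events), dt=dt)


def write_raster(raster: SpikeRaster, path) -> None:
    """Write a raster as CSV sorted by (timestep, channel)."""
    ev = sorted(raster.events)
    df = pd.DataFrame(ev, columns=["timestep", "channel"], dtype=int)
    df.to_csv(path, index=False)


def _kernel_table(kernels: Sequence[KernelSpec]):
    """Pack kernel specs into parallel arrays for HDF5 storage."""
    fam = np.array([k.family for k in kernels], dtype=h5py.string_dtype())
    comp = np.array([k.compression for k in kernels], dtype=h5py.string_dtype())
    num = np.array(
        [[k.ts, k.delay, k.omega, k.sigma, k.k, float(k.truncation)] for k in kernels]
    )
    return fam, comp, num


def save_model(model: SKIMModel, path) -> None:
    """Serialize a model to HDF5 (weights as datasets, scalars as attributes)."""
    for k in model.kernels:
        if k.family == "custom":
            raise ValueError("custom (tabulated) kernels are not serializable")
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = MODEL_FORMAT_VERSION
        for name in ("L", "M", "N", "seed"):
            f.attrs[name] = int(getattr(model, name))
        for name in ("threshold", "target_amplitude", "dt"):
            f.attrs[name] = float(getattr(model, name))
        f.create_dataset("input_weights", data=model.input_weights)
        f.create_dataset("output_weights", data=model.output_weights)
        fam, comp, num = _kernel_table(model.kernels)
        f.create_dataset("kernel_family", data=fam)
        f.create_dataset("kernel_compression", data=comp)
        f.create_dataset("kernel_params", data=num)


def load_model(path) -> SKIMModel:
    """Load a model written by :func:`save_model`; round-trips bit-exactly."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version is None or int(version) != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported model format version {version!r}"
            )
        required = ("input_weights", "output_weights", "kernel_family",
                    "kernel_compression", "kernel_params")
        for name in required:
            if name not in f:
                raise ValueError(f"{path}: missing dataset {name!r}")
        fam = [s.decode() if isinstance(s, bytes) else s for s in f["kernel_family"][:]]
        comp = [s.decode() if isinstance(s, bytes) else s for s in f["kernel_compression"][:]]
        num = f["kernel_params"][:]
        kernels = [
            KernelSpec(
                family=fam[j], ts=num[j, 0], delay=num[j, 1], omega=num[j, 2],
                sigma=num[j, 3], k=num[j, 4], compression=comp[j],
                truncation=int(num[j, 5]),
            )
            for j in range(len(fam))
        ]
        return SKIMModel(
            L=int(f.attrs["L"]), M=int(f.attrs["M"]), N=int(f.attrs["N"]),
            input_weights=f["input_weights"][:],
            kernels=kernels,
            output_weights=f["output_weights"][:],
            threshold=float(f.attrs["threshold"]),
            target_amplitude=float(f.attrs["target_amplitude"]),
            seed=int(f.attrs["seed"]),
            dt=float(f.attrs["dt"]),
        )
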