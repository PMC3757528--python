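"""Synaptic kernel impulse responses and compressive nonlinearities.

A synaptic kernel converts a presynaptic spike (a unit impulse on the time
grid) into a continuous signal that persists, giving the network memory of
past spikes. Supported families, written for a spike at t=0:

- ``leaky``            r(t) = exp(-t/ts)                 (leaky integration)
- ``alpha``            r(t) = (t/ts) * exp(-t/ts)        (peaks at t=ts, value 1/e)
- ``resonant``         r(t) = exp(-t/ts) * sin(omega*t)  (damped resonance)
- ``delayed_alpha``    alpha shifted right by ``delay``; zero before it
- ``delayed_gaussian`` exp(-(t-delay)^2 / (2 sigma^2)) for t >= delay, else 0
- ``custom``           a tabulated response

The linear response is followed by a compressive nonlinearity (logistic or
tanh, both rescaled to be odd with range (-0.5, 0.5)); compression of the
*summed* response is what gives a dendrite its depressive adaptation — a
second spike landing on the tail of a first is compressed more strongly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

FAMILIES = ("leaky", "alpha", "resonant", "delayed_alpha", "delayed_gaussian", "custom")
COMPRESSIONS = ("logistic", "tanh", "none")

#: Truncation horizon in time constants for exponential-tailed kernels.
#: At 20*ts the alpha kernel's dropped tail holds ~4e-8 of its L1 mass and
#: its magnitude is ~1e-7 of the peak.
_TAIL_TCONSTS = 20.0
_TAIL_SIGMAS = 8.0

__all__ = [
    "KernelSpec",
    "impulse_response",
    "compress",
    "kernel_fwhm",
    "preferred_delay",
    "sample_kernel_bank",
    "load_custom_kernel",
    "FAMILIES",
    "COMPRESSIONS",
]


def _default_truncation(family: str, ts: float, delay: float, sigma: float) -> int:
    if family == "delayed_gaussian":
        return max(1, int(np.ceil(delay + _TAIL_SIGMAS * sigma)))
    return max(1, int(np.ceil(delay + _TAIL_TCONSTS * ts)))


@dataclass(frozen=True)
class KernelSpec:
    """One dendrite's synaptic kernel: family, shape parameters, compression.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    ts : float
        Time constant in timesteps (families with an exponential factor).
    delay : float
        Synaptic/dendritic delay in timesteps (0 for undelayed families).
    omega : float
        Angular frequency per timestep (``resonant`` only).
    sigma : float
        Gaussian width in timesteps (``delayed_gaussian`` only).
    k : float
        Compression gain.
    compression : str
        One of :data:`COMPRESSIONS`.
    truncation : int, optional
        Support length in timesteps used when convolving; defaults to a
        horizon past which the response is negligible (< 1e-6 of peak).
    custom_table : ndarray, optional
        Tabulated impulse response (``custom`` only).
    """

    family: str
    ts: float = 0.0
    delay: float = 0.0
    omega: float = 0.0
    sigma: float = 0.0
    k: float = 5.0
    compression: str = "logistic"
    truncation: Optional[int] = None
    custom_table: Optional[tuple] = field(default=None, repr=False)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.compression not in COMPRESSIONS:
            raise ValueError(f"unknown compression {self.compression!r}")
        if self.family in ("leaky", "alpha", "resonant", "delayed_alpha") and not self.ts > 0:
            raise ValueError(f"{self.family} kernel requires ts > 0")
        if self.family == "delayed_gaussian" and not self.sigma > 0:
            raise ValueError("delayed_gaussian kernel requires sigma > 0")
        if self.family == "resonant" and not self.omega > 0:
            raise ValueError("resonant kernel requires omega > 0")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        if not self.k > 0:
            raise ValueError("compression gain k must be > 0")
        if self.family == "custom":
            if self.custom_table is None or len(self.custom_table) == 0:
                raise ValueError("custom kernel requires a non-empty custom_table")
            object.__setattr__(self, "custom_table", tuple(float(v) for v in self.custom_table))
            if self.truncation is None:
                object.__setattr__(self, "truncation", len(self.custom_table))
        elif self.truncation is None:
            object.__setattr__(
                self,
                "truncation",
                _default_truncation(self.family, self.ts, self.delay, self.sigma),
            )
        if self.truncation < 1:
            raise ValueError("truncation must be >= 1")

    def response_at(self, t) -> np.ndarray:
        """Evaluate the uncompressed response at (possibly fractional) times t.

        Vectorized over ``t``; zero for t < 0 and, for delayed families,
        for t < delay (causality).
        """
        t = np.asarray(t, dtype=float)
        fam = self.family
        if fam == "custom":
            table = np.asarray(self.custom_table)
            idx = np.round(t).astype(int)
            ok = (idx >= 0) & (idx < len(table))
            out = np.zeros_like(t)
            out[ok] = table[idx[ok]]
            return out
        shifted = t - self.delay
        with np.errstate(over="ignore"):
            if fam == "leaky":
                out = np.exp(-t / self.ts)
            elif fam == "alpha":
                out = (t / self.ts) * np.exp(-t / self.ts)
            elif fam == "resonant":
                out = np.exp(-t / self.ts) * np.sin(self.omega * t)
            elif fam == "delayed_alpha":
                out = (shifted / self.ts) * np.exp(-shifted / self.ts)
            elif fam == "delayed_gaussian":
                out = np.exp(-(shifted ** 2) / (2.0 * self.sigma ** 2))
        out = np.where((t < 0) | (shifted < 0) if fam.startswith("delayed") else (t < 0),
                       0.0, out)
        return out


def impulse_response(spec: KernelSpec, length: int) -> np.ndarray:
    """The kernel's linear response to a unit spike at step 0, before compression.

    Sampled at integer timesteps ``0 .. length-1``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    return spec.response_at(np.arange(length, dtype=float))


def truncated_response(spec: KernelSpec) -> np.ndarray:
    """Impulse response sampled over the kernel's finite support."""
    return impulse_response(spec, spec.truncation)


def compress(v, k: float = 5.0, kind: str = "logistic"):
    """Compressive nonlinearity applied to a dendritic potential.

    ``logistic``: 1/(1+exp(-k*v)) - 0.5; ``tanh``: tanh(k*v)/2; ``none``: v.
    The bounded kinds are odd, strictly increasing, and map into (-0.5, 0.5).
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    v = np.asarray(v, dtype=float)
    if kind == "logistic":
        out = 1.0 / (1.0 + np.exp(-k * v)) - 0.5
    elif kind == "tanh":
        out = np.tanh(k * v) / 2.0
    elif kind == "none":
        return v.copy() if v.ndim else float(v)
    else:
        raise ValueError(f"unknown compression {kind!r}")
    # keep the open interval (-0.5, 0.5) open in float64: deep saturation
    # would otherwise round to exactly +/-0.5
    lim = np.nextafter(0.5, 0.0)
    out = np.clip(out, -lim, lim)
    return out if out.ndim else float(out)


def _refined_peak(spec: KernelSpec) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Locate the global maximum of the uncompressed response.

    Returns (t_peak, peak_value, grid, values) where the grid spans the
    kernel's support at 1e-3-timestep resolution near the optimum.
    """
    horizon = float(spec.truncation)
    grid = np.linspace(0.0, horizon, 4096)
    vals = spec.response_at(grid)
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: -spec.response_at(t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    t_peak, peak = float(res.x), float(-res.fun)
    # Flat-topped or boundary peaks (e.g. leaky at t=0) fall back to the grid.
    if peak < vals[i]:
        t_peak, peak = float(grid[i]), float(vals[i])
    return t_peak, peak, grid, vals


def _check_unimodal(vals: np.ndarray) -> bool:
    """True when the sampled response rises (possibly trivially) then falls."""
    d = np.diff(vals)
    sign = np.sign(np.where(np.abs(d) < 1e-12, 0.0, d))
    sign = sign[sign != 0]
    if len(sign) == 0:
        return False
    changes = np.count_nonzero(np.diff(sign))
    return changes <= 1


def kernel_fwhm(spec: KernelSpec) -> float:
    """Full width at half maximum of the uncompressed impulse response.

    Found by bracketing the two half-peak crossings on a fine grid and
    bisecting; accurate to well under 1e-2 timestep. Kernels without a
    single maximum over their support (e.g. the damped resonance) are
    rejected. A response that is already at its peak at t=0 (leaky
    integration) has its left crossing pinned at 0.
    """
    t_peak, peak, grid, vals = _refined_peak(spec)
    if not _check_unimodal(vals):
        raise ValueError(
            f"{spec.family} kernel response is not unimodal; FWHM undefined"
        )
    half = peak / 2.0

    def f(t):
        return float(spec.response_at(t)) - half

    # Left crossing: last grid point below half before the peak.
    left_mask = (grid < t_peak) & (vals < half)
    if left_mask.any():
        lo = grid[left_mask][-1]
        hi = min(t_peak, lo + (grid[1] - grid[0]) * 2)
        left = optimize.brentq(f, lo, hi, xtol=1e-6)
    else:
        left = 0.0
    # Right crossing: first grid point below half after the peak.
    right_mask = (grid > t_peak) & (vals < half)
    if not right_mask.any():
        raise ValueError("response never falls to half maximum within support")
    hi = grid[right_mask][0]
    lo = max(t_peak, hi - (grid[1] - grid[0]) * 2)
    right = optimize.brentq(f, lo, hi, xtol=1e-6)
    return right - left


def preferred_delay(spec: KernelSpec) -> float:
    """Time of maximum amplitude of the uncompressed impulse response.

    The peak of a kernel's spike response sets the preferred delay of that
    neural pathway (an alpha kernel peaks at its time constant; a delayed
    alpha at delay + ts).
    """
    t_peak, _, _, _ = _refined_peak(spec)
    return t_peak


def load_custom_kernel(path, k: float = 5.0, compression: str = "logistic") -> KernelSpec:
    """Load a tabulated impulse response from a two-column CSV.

    Expected header ``timestep,value``; timesteps must run 0, 1, 2, ... with
    no gaps.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if list(df.columns[:2]) != ["timestep", "value"]:
        raise ValueError(f"{path}: expected header 'timestep,value'")
    steps = df["timestep"].to_numpy()
    if not np.array_equal(steps, np.arange(len(steps))):
        raise ValueError(f"{path}: timesteps must be consecutive from 0")
    return KernelSpec("custom", custom_table=tuple(df["value"].astype(float)),
                      k=k, compression=compression)


def sample_kernel_bank(
    M: int,
    family: str = "alpha",
    t_max: int = 200,
    seed: int = 0,
    k: float = 5.0,
    compression: str = "logistic",
    ts_mode: str = "uniform",
    shape_param: Optional[float] = None,
) -> list[KernelSpec]:
    """Draw a bank of M random kernels spanning a pattern of length ``t_max``.

    For ``alpha``/``leaky``/``resonant`` the time constant is drawn
    ts ~ Uniform(1, t_max/2) (``ts_mode='uniform'``), spreading kernel
    memories over the pattern duration; ``ts_mode='heuristic'`` instead
    fixes every ts at t_max/2, the rule of thumb for the longest interval
    that must be remembered. Delayed families draw delay ~ Uniform(0, t_max)
    with a fixed shape parameter (``shape_param``; defaults: ts = t_max/10
    for ``delayed_alpha``, sigma = t_max/20 for ``delayed_gaussian``).
    Resonant kernels additionally draw omega ~ Uniform(pi/t_max, 10*pi/t_max),
    i.e. periods between a fifth of and twice the pattern length.
    Deterministic given ``seed``.
    """
    if M < 1 or t_max < 2:
        raise ValueError("require M >= 1 and t_max >= 2")
    if family not in FAMILIES or family == "custom":
        raise ValueError(f"cannot sample a bank of family {family!r}")
    rng = np.random.default_rng(seed)
    common = dict(k=k, compression=compression)
    bank = []
    for _ in range(M):
        if family in ("leaky", "alpha", "resonant"):
            if ts_mode == "uniform":
                ts = rng.uniform(1.0, t_max / 2.0)
            elif ts_mode == "heuristic":
                ts = t_max / 2.0
            else:
                raise ValueError(f"unknown ts_mode {ts_mode!r}")
            if family == "resonant":
                omega = rng.uniform(np.pi / t_max, 10.0 * np.pi / t_max)
                bank.append(KernelSpec(family, ts=ts, omega=omega, **common))
            else:
                bank.append(KernelSpec(family, ts=ts, **common))
        else:
            delay = rng.uniform(0.0, float(t_max))
            if family == "delayed_alpha":
                ts = shape_param if shape_param is not None else t_max / 10.0
                bank.append(KernelSpec(family, ts=ts, delay=delay, **common))
            else:
                sigma = shape_param if shape_param is not None else t_max / 20.0
                bank.append(KernelSpec(family, sigma=sigma, delay=delay, **common))
    return bank
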