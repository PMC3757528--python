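# Methods

## Model and assumptions

`skimnet` synthesizes feed-forward two-layer spiking networks for
spatio-temporal spike-pattern detection. The design rests on three
assumptions:

1. **Random projection suffices.** The input-to-dendrite weights are drawn
   once from `U(weight_low, weight_high)` (default `(−0.5, 0.5)`) and never
   trained. Diversity across dendrites comes from these weights and from
   randomly parameterized synaptic kernels; only the dendrite-to-soma
   readout is solved.
2. **Kernels provide memory.** A spike is an instantaneous event; the
   synaptic kernel converts it into a signal that persists for a time of
   order the kernel's time constant. A pattern spanning `t_max` timesteps is
   only detectable if kernel memories reach back that far, so the bank's
   time constants are sampled relative to `t_max`.
3. **The readout is linear and the problem convex.** Given the activation
   matrix `A` and target `Z`, the weights minimize
   `‖WA − Z‖²_F + ridge·‖W‖²_F`, solved by a QR/SVD least-squares
   factorization in a single pass. There are no learning rates, epochs, or
   local minima.

All computation happens on an integer time grid; `dt` (ms per step, default
1.0) is metadata only.

## Tunable parameters

| Parameter | Default | Meaning and rationale |
| --- | --- | --- |
| `n_dendrites` (M) | 100 | Hidden dimension. 100 suffices for the 5-channel toy task; detection quality saturates well below M = K. |
| `kernel` | `alpha` | `(t/τ_s)e^{−t/τ_s}`: rises then decays, peaking at `t = τ_s` with value `1/e` — the standard postsynaptic-current shape. Alternatives: `leaky`, `resonant`, `delayed_alpha`, `delayed_gaussian`, `custom`. |
| `t_max` | 200 steps | Longest interval to be remembered (the nominal pattern duration). Alpha/leaky/resonant time constants are drawn `τ_s ~ U(1, t_max/2)`; `ts_mode="heuristic"` instead fixes all at `t_max/2`. Delayed kernels draw `ΔT ~ U(0, t_max)` with a fixed shape parameter (`τ_s = t_max/10` for delayed alpha, `σ = t_max/20` for the delayed Gaussian). |
| `k`, `compression` | 5, `logistic` | Gain and form of the compressive nonlinearity `1/(1+e^{−kv}) − 0.5` (odd, bounded in `(−0.5, 0.5)`). Compression of the *summed* kernel response is what produces depressive adaptation: a spike arriving on the tail of an earlier one contributes less. |
| `ridge` | 1e−8 | Numerical stabilizer only — small enough that the solution is the pseudoinverse one for any well-posed system, but keeps rank-deficient activations (sparse spikes) solvable. `ridge=0` selects the exact minimum-norm pseudoinverse. |
| `sv_cutoff` | off | Rank-truncated pseudoinverse: singular values below this fraction of the largest are dropped. Used when heavily over-provisioning dendrites before pruning (see below). |
| `target_width`, `target_delay`, `target_amplitude` | 10, 10, 1.0 | The training target per presentation is a square pulse of this height and width, starting `delay` steps after the pattern's last input spike, so the slow dendritic responses have time to peak and the sparse target carries enough energy to steer the regression. |
| `threshold_fraction` | 0.25 | Firing threshold as a fraction of the target amplitude. The least-squares soma underswings its nominal target on hard tasks, so a quarter-amplitude threshold detects far more reliably than the intuitive half. |
| `order` | `filter_then_nonlinearity` | Compress the filtered sum (default) or each scaled impulse before superposition. The alternate order scales every event independently, which removes spike-history adaptation (its responses superpose exactly additively — verified in the test suite). |
| `reset` | off | Zero all dendritic state when an output fires, via a step-wise simulation. Kept available for soma-reset experiments; it has no effect on the solved weights. |

## Presentation end times and targets

A pattern occupies a nominal window (default 200 steps) but its information
ends with its **last spike**. The generator therefore reports each
presentation's end time as one step past its last spike (the nominal window
end is kept separately), and the training target is anchored there. This
matters: anchoring targets to the nominal window end instead leaves the
target up to tens of steps past the last evidence and measurably degrades
detection.

## The synthetic task

`make_pattern` draws a fixed pattern (default: 9 spikes uniformly placed on
a 5 × 200 grid; an optional per-channel count constraint, e.g. 1–3 spikes on
every channel, is available). `embed_pattern` plants copies at Poisson times
(default expectation 580 per 10⁵ steps — presentations frequently overlap at
this density) and adds uniform Poisson noise spikes with expected count
equal to `noise_ratio` times the expected pattern-spike count (default 1.0:
noise ≈ signal). Collisions resolve by OR; the raster is binary. Optional
per-presentation transforms: uniform time warping (e.g. factors in
0.76–1.24) and Gaussian spike jitter, both preserving spike counts by
nudging rounding collisions to adjacent free steps.

What the generator does **not** emulate: real sensory encodings (cochlear
or otherwise), rate-coded or bursting inputs, correlated noise, multiple
distractor patterns, or drift in the pattern itself. Passing tests
demonstrate the synthesis machinery works under the stated statistical
conditions, not performance on any natural dataset.

## Scoring

Detection in a continuous stream is scored per presentation, the analog of
per-utterance scoring in a classification task: each presentation
contributes a window of the nominal pattern length (default 200 steps)
centered on its trained target pulse; overlapping windows merge. A window
containing at least one output spike is a true positive, otherwise a false
negative. The complement is tiled into windows of the same length — only
full-length tiles are scored — and each tile with a spike is a false
positive. The scalar error is `FN/#positive + FP/#negative ∈ [0, 2]`. The
alternative reading that divides by *detected* true-positive/true-negative
counts is available (`interpretation="detected"`) but is undefined when
nothing is detected, so the ground-truth denominators are the default.

## Numerical choices

- **Kernel truncation.** Convolution uses a finite support of
  `ΔT + 20·τ_s` steps (`ΔT + 8·σ` for the delayed Gaussian), beyond which
  the response magnitude is `< 10⁻⁶` of the peak and the dropped tail holds
  `< 10⁻⁴` of the L1 mass.
- **Delayed Gaussian is causal.** `r(t) = e^{−(t−ΔT)²/(2σ²)}` for
  `t ≥ ΔT`, identically zero before — a half-Gaussian whose half-height
  width is `σ√(2 ln 2)`.
- **FWHM and preferred delay** are computed on the continuous-time kernel:
  a 4096-point grid over the support brackets the peak (refined by bounded
  minimization) and the two half-height crossings (refined by Brent's
  method to ≪ 10⁻² steps). Kernels without a single maximum (the damped
  resonance) are rejected for FWHM; the preferred delay (response argmax)
  is defined for all.
- **Compression saturation.** In float64, deep saturation of the logistic
  or tanh would round to exactly ±0.5; outputs are clamped to the largest
  double strictly inside the open interval so the bound `|a| < 0.5` is
  exact.
- **Spike semantics.** One output spike per rising threshold crossing; a
  sustained supra-threshold plateau is one event at its onset, and a trace
  already above threshold at `t = 0` spikes at `t = 0`.
- **Incremental solver.** Recursive least squares on
  `P = (AAᵀ + ridge·I)⁻¹` via rank-one Sherman–Morrison updates plus the
  cross-moment `C = ZAᵀ`; `W = CP` matches the batch solution to rounding,
  independent of sample order. Requires `ridge > 0` for the initial state
  `P₀ = I/ridge`.

## Pruning

The solved weight mass concentrates on a minority of dendrites, so
low-weight dendrites can be removed — but the remaining weights **must be
re-solved**, since dropping regressors leaves the old coefficients
non-optimal. Dendrite importance is the summed `|w⁽²⁾|` across output
neurons (scale-fair for multi-output networks).

One subtlety, found empirically and reproducible in this package's tests:
when the bank is heavily over-provisioned (e.g. 1000 dendrites on a
5-channel task) the activation matrix has a soft, gapless singular spectrum,
and a minimum-norm (or tiny-ridge) solution places its largest weights on
noise-amplifying directions. Magnitude ranking from such a solve is
anti-selective — keeping the top 100 of 1000 then fits *worse* than a fresh
100-dendrite network. Solving the over-provisioned network with the
rank-truncated pseudoinverse (`sv_cutoff ≈ 10⁻³`; the outcome is insensitive
across 10⁻²–10⁻⁴) makes the magnitudes meaningful again, and two-pass
pruning then beats the once-trained same-size network, as intended. The
iterative strategy (replace the lowest-weight dendrites with fresh random
ones and re-solve, for several rounds) does not need the cutoff, since it
discards from the bottom of the ranking where the distortion is minor.

## Design choices on open points

- Event-list CSV (header `timestep,channel`, 0-based) is the interchange
  format; dense matrices are internal. Models are HDF5 with named datasets
  and a format version.
- The forward pass is implemented as per-dendrite convolution with the
  truncated kernel; by linearity it equals per-spike superposition (tested
  against a literal bookkeeping implementation).
- Mixed-sign synaptic weights are the default; a single-polarity network is
  obtained by restricting the weight range (e.g. `weight_low=0`).
- The scikit-learn estimator (`SKIM`) is the primary interface; module
  functions (`train`, `forward`, `prune_two_pass`, …) expose the same
  pipeline for scripting, and the `skim` CLI wraps both for shell use.

## Problem sizes used in the test suite

Unit and property tests run on 10⁴-step sequences with 8–60 dendrites. The
acceptance-style checks use the full 10⁵-step, ~580-presentation
configuration with 80–100 dendrites (10 instantiations), and the pruning
comparison over-provisions 1000 dendrites on 2×10⁴-step sequences
(10 seeds) — chosen so the whole suite completes in a couple of minutes.

## Known limitations

- Detection quality varies substantially with the random pattern draw:
  patterns whose informative spikes span the full nominal window press
  against the kernel bank's memory (`τ_s ≤ t_max/2`), and some draws leave
  channels silent. Held-out errors on the standard task cluster around
  0.1–0.3 across seeds; the test suite's end-to-end check reports the
  per-seed spread.
- The dendritic feature space is spanned by (channels × kernel family), so
  adding dendrites beyond a few hundred yields strongly collinear features
  and diminishing returns.
- Thresholding is memoryless (no refractory period); closely spaced
  recognitions merge into one output event.
- Continuous-time (floating-timestamp) event streams and address-event
  hardware formats are out of scope; recurrent or cascaded topologies are
  not modeled.
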