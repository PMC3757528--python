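"""Scikit-learn-style estimator wrapping network synthesis end to end.

``SKIM`` is a detector for spatio-temporal spike patterns: ``fit`` draws the
fixed random projection and kernel bank and solves the linear readout in a
single least-squares pass; ``decision_function`` returns the analog soma
potential and ``predict`` the thresholded output spike raster. It follows
the scikit-learn estimator protocol (``get_params``/``set_params``, fitted
attributes with a trailing underscore) so it composes with pipelines and
parameter search, although its inputs are spike rasters rather than tabular
samples.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from . import solver
from .evaluation import error_metric, match_detections, windows_from_end_times
from .io import SKIMModel, SpikeRaster
from .network import forward

__all__ = ["SKIM"]


def _as_raster(X) -> SpikeRaster:
    if isinstance(X, SpikeRaster):
        return X
    return SpikeRaster.from_dense(np.asarray(X))


class SKIM(BaseEstimator):
    """Two-layer spiking pattern detector solved by pseudoinverse.

    Parameters
    ----------
    n_dendrites : int
        Hidden dimension M — number of dendritic branches.
    kernel : str
        Synaptic kernel family (``alpha``, ``leaky``, ``resonant``,
        ``delayed_alpha``, ``delayed_gaussian``).
    t_max : int
        Longest interval (timesteps) over which spikes must be remembered;
        sets the range of the random kernel time constants / delays.
    k : float
        Gain of the compressive nonlinearity.
    compression : str
        ``logistic`` (default), ``tanh`` or ``none``.
    ts_mode : str
        ``uniform``: time constants ~ U(1, t_max/2); ``heuristic``: all
        fixed at t_max/2.
    weight_low, weight_high : float
        Range of the fixed random input weights. Restricting the range to
        one sign (e.g. 0..0.5) gives a single-polarity network.
    ridge : float
        Tikhonov stabilizer for the least-squares solve; 0 for the plain
        pseudoinverse.
    sv_cutoff : float, optional
        Drop singular values below this fraction of the largest during the
        solve (rank-truncated pseudoinverse). Use when over-provisioning
        dendrites ahead of magnitude pruning, where the minimum-norm
        solution would otherwise put its largest weights on noise
        directions.
    target_width, target_delay : int
        The training target for each pattern presentation is a square pulse
        of this width, this many steps after the pattern's end.
    target_amplitude : float
        Pulse height of the training target.
    threshold_fraction : float
        Firing threshold as a fraction of the target amplitude.
    order : str
        ``filter_then_nonlinearity`` (default) or the reduced-power
        alternative ``nonlinearity_then_filter``.
    reset : bool
        Zero all dendritic state when an output fires (stepwise simulation;
        slow, default off).
    random_state : int, optional
        Seed for the random projection and kernel bank; ``None`` means 0.

    Attributes
    ----------
    model_ : SKIMModel
        The complete synthesized network.
    input_weights_ : ndarray of shape (M, L)
    output_weights_ : ndarray of shape (N, M)
    kernels_ : list of KernelSpec
    threshold_ : float
    n_features_in_ : int
        Number of input channels L.
    """

    def __init__(
        self,
        n_dendrites: int = 100,
        kernel: str = "alpha",
        t_max: int = 200,
        k: float = 5.0,
        compression: str = "logistic",
        ts_mode: str = "uniform",
        weight_low: float = -0.5,
        weight_high: float = 0.5,
        ridge: float = 1e-8,
        sv_cutoff: Optional[float] = None,
        target_width: int = 10,
        target_delay: int = 10,
        target_amplitude: float = 1.0,
        threshold_fraction: float = 0.25,
        order: str = "filter_then_nonlinearity",
        reset: bool = False,
        random_state: Optional[int] = None,
    ):
        self.n_dendrites = n_dendrites
        self.kernel = kernel
        self.t_max = t_max
        self.k = k
        self.compression = compression
        self.ts_mode = ts_mode
        self.weight_low = weight_low
        self.weight_high = weight_high
        self.ridge = ridge
        self.sv_cutoff = sv_cutoff
        self.target_width = target_width
        self.target_delay = target_delay
        self.target_amplitude = target_amplitude
        self.threshold_fraction = threshold_fraction
        self.order = order
        self.reset = reset
        self.random_state = random_state

    def fit(self, X, y):
        """Synthesize the network from a training raster.

        Parameters
        ----------
        X : SpikeRaster or array of shape (L, K)
            Input spike train.
        y : sequence of int, or sequence of sequences
            End timestep of every embedded pattern presentation (one list
            per output neuron for multi-output detectors).
        """
        raster = _as_raster(X)
        seed = 0 if self.random_state is None else int(self.random_state)
        self.model_, self._A, self._target = solver.train(
            raster, y,
            M=self.n_dendrites, family=self.kernel, t_max=self.t_max,
            k=self.k, compression=self.compression, ts_mode=self.ts_mode,
            weight_low=self.weight_low, weight_high=self.weight_high,
            ridge=self.ridge, sv_cutoff=self.sv_cutoff,
            target_width=self.target_width,
            target_delay=self.target_delay,
            target_amplitude=self.target_amplitude,
            threshold_fraction=self.threshold_fraction,
            order=self.order, seed=seed, return_internals=True,
        )
        self.input_weights_ = self.model_.input_weights
        self.output_weights_ = self.model_.output_weights
        self.kernels_ = self.model_.kernels
        self.threshold_ = self.model_.threshold
        self.n_features_in_ = self.model_.L
        return self

    def _check_fitted(self) -> SKIMModel:
        if not hasattr(self, "model_"):
            raise AttributeError("this SKIM instance is not fitted yet")
        return self.model_

    def decision_function(self, X) -> np.ndarray:
        """Pre-threshold soma potentials, shape (N, K)."""
        model = self._check_fitted()
        _, y, _ = forward(_as_raster(X), model, order=self.order,
                          reset=self.reset, return_trace=True)
        return y

    def predict(self, X) -> SpikeRaster:
        """Thresholded output spike raster (one channel per output neuron)."""
        model = self._check_fitted()
        return forward(_as_raster(X), model, order=self.order, reset=self.reset)

    def training_residual(self) -> float:
        """Frobenius residual ||W A - Z|| on the data last passed to fit."""
        self._check_fitted()
        return solver.training_residual(
            self.output_weights_, self._A, self._target
        )

    def score(self, X, y) -> float:
        """1 - error/2 where error = miss rate + false-alarm rate.

        ``y`` holds the ground-truth pattern end times of ``X``; detection
        windows run from each pattern end to the end of its target pulse.
        Returns 1.0 for perfect detection, 0.0 for the worst case.
        """
        raster = _as_raster(X)
        out = self.predict(raster)
        ends = list(y)
        nested = len(ends) > 0 and isinstance(ends[0], (list, tuple, np.ndarray))
        per_output = [list(e) for e in ends] if nested else [ends]
        errs = []
        for n, es in enumerate(per_output):
            windows = windows_from_end_times(
                es, raster.n_steps, delay=self.target_delay,
                width=self.target_width,
            )
            counts = match_detections(out, windows, raster.n_steps, channel=n)
            errs.append(error_metric(counts))
        return 1.0 - float(np.mean(errs)) / 2.0

    def detection_error(self, X, y) -> float:
        """Miss rate + false-alarm rate on windowed detections (0 = perfect)."""
        return 2.0 * (1.0 - self.score(X, y))
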