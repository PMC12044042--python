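"""Canonical double-gamma hemodynamic response function and convolution.

BOLD responds to neural events with a delayed, dispersed impulse response.
The canonical model is a difference of two gamma densities: a positive
response peaking around 6 s and a smaller undershoot peaking around 16 s.
Stimulus features are convolved with this kernel and truncated to the
length of the measured BOLD series before any model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.stats import gamma as _gamma

from .data import FeatureTimeSeries


@dataclass(frozen=True)
class HRFKernel:
    """A sampled hemodynamic impulse response.

    ``samples[i]`` is the kernel amplitude at ``t = i * dt`` seconds; the
    kernel is scaled so that its maximum equals 1.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("kernel contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        object.__setattr__(self, "samples", arr)

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) * self.dt

    def to_csv(self, path) -> None:
        import pandas as pd

        t = np.arange(self.samples.size) * self.dt
        pd.DataFrame({"t": t, "h": self.samples}).to_csv(path, index=False)


def canonical_hrf(
    dt: float = 1.0,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
) -> HRFKernel:
    """Sample the canonical double-gamma HRF on ``[0, duration]``.

    h(t) = Gamma(t; peak_delay/peak_disp, peak_disp)
           - ratio * Gamma(t; undershoot_delay/undershoot_disp, undershoot_disp),

    where Gamma(.; a, s) is the gamma probability density with shape ``a``
    and scale ``s``.  The sampled kernel is normalized to unit peak.

    Parameters
    ----------
    dt
        Sampling interval in seconds (the BOLD repetition time for a
        design-matrix kernel).
    duration
        Kernel support in seconds; the kernel has ``floor(duration/dt) + 1``
        samples.
    peak_delay, peak_disp
        Delay (mode-controlling shape x scale product) and dispersion of the
        positive lobe, in seconds.
    undershoot_delay, undershoot_disp
        Same for the negative undershoot.
    ratio
        Relative amplitude of the undershoot.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if peak_disp <= 0 or undershoot_disp <= 0:
        raise ValueError("dispersions must be positive")
    if duration < peak_delay:
        raise ValueError("duration must be at least peak_delay")
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    h = _gamma.pdf(t, a=peak_delay / peak_disp, scale=peak_disp)
    h = h - ratio * _gamma.pdf(
        t, a=undershoot_delay / undershoot_disp, scale=undershoot_disp
    )
    h = h / h.max()
    return HRFKernel(samples=h, dt=dt)


def convolve_truncate(
    features: FeatureTimeSeries | np.ndarray,
    kernel: HRFKernel,
    n_timepoints: int | None = None,
) -> FeatureTimeSeries:
    """Causally convolve every feature column with the HRF and truncate.

    The full causal convolution of each column with ``kernel.samples`` is
    computed and the first ``n_timepoints`` rows are kept, matching the
    length of the measured BOLD series.  The operation is linear in the
    input and the output at time ``t`` depends only on inputs at times
    ``<= t``.
    """
    if isinstance(features, FeatureTimeSeries):
        X = features.data
        dt = features.dt
        if abs(dt - kernel.dt) > 1e-9:
            raise ValueError(
                f"feature sampling interval {dt} differs from kernel dt "
                f"{kernel.dt}; resample the features to the BOLD rate first"
            )
    else:
        X = np.asarray(features, dtype=float)
        dt = kernel.dt
    if X.ndim != 2:
        raise ValueError("features must be 2-D (time x feature)")
    if n_timepoints is None:
        n_timepoints = X.shape[0]
    if n_timepoints > X.shape[0]:
        raise ValueError(
            f"n_timepoints={n_timepoints} exceeds available length {X.shape[0]}"
        )
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be positive")
    conv = _signal.convolve(X, kernel.samples[:, None], mode="full", method="auto")
    return FeatureTimeSeries(data=conv[:n_timepoints], dt=dt)
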