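"""Fluorescence recovery after photobleaching (FRAP).

Intracellular diffusion coupling among astroglial processes is probed by
bleaching dye in a line scan and measuring how fast fluorescence recovers
once the shutter re-opens.  The recovery "rate" is the initial slope of the
normalised recovery (over the first 20% of the recovery window by default;
an exponential-fit estimator is available behind a switch), reported both
absolutely and as a percentage of a reference recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ..errors import InputError
from .linescan import LineScan

__all__ = ["FrapResult", "compute_frap_rate"]


@dataclass
class FrapResult:
    rate: float                  # 1/ms, initial slope of normalised recovery
    rate_percent_of_reference: float | None
    baseline: float
    method: str
    converged: bool


def _as_curve(trace) -> np.ndarray:
    if isinstance(trace, LineScan):
        return trace.intensity.mean(axis=1)
    curve = np.asarray(trace, dtype=float)
    if curve.ndim != 1 or len(curve) < 4:
        raise InputError("recovery trace must be a 1D array of >= 4 samples")
    return curve


def compute_frap_rate(
    trace,
    bleach_interval: tuple[int, int],
    sample_period: float = 1.0,
    reference_rate: float | None = None,
    method: str = "initial_slope",
    initial_fraction: float = 0.2,
) -> FrapResult:
    """FRAP recovery rate relative to an optional reference.

    trace: LineScan (averaged over the line) or 1D recovery curve.
    bleach_interval: [start, stop) sample indices of the shutter-closed /
    bleach period; recovery is measured from ``stop`` onward, normalised to
    the pre-bleach baseline.
    sample_period: ms per sample.
    """
    curve = _as_curve(trace)
    b0, b1 = bleach_interval
    if not (0 < b0 < b1 < len(curve)):
        raise InputError("bleach interval must lie inside the trace")
    baseline = float(curve[:b0].mean())
    if baseline <= 0:
        raise InputError("non-positive pre-bleach baseline")
    recovery = curve[b1:] / baseline
    if len(recovery) < 3:
        raise InputError("no recovery segment after the bleach interval")
    t = np.arange(len(recovery)) * sample_period
    if method == "initial_slope":
        n = max(3, int(np.ceil(initial_fraction * len(recovery))))
        seg_t, seg_y = t[:n], recovery[:n]
        slope = float(np.polyfit(seg_t, seg_y, 1)[0])
        converged = True
    elif method == "exponential":
        y_inf0 = float(recovery[-max(3, len(recovery) // 5):].mean())
        y00 = float(recovery[0])
        tau0 = max(t[-1] / 3.0, sample_period)

        def model(t, y_inf, dy, tau):
            return y_inf - dy * np.exp(-t / tau)

        try:
            popt, _ = optimize.curve_fit(
                model, t, recovery, p0=(y_inf0, y_inf0 - y00, tau0),
                maxfev=10000,
            )
            slope = float(popt[1] / popt[2])  # initial slope dy/tau
            converged = True
        except RuntimeError:
            slope = float("nan")
            converged = False
    else:
        raise InputError(f"unknown FRAP method {method!r}")
    percent = None
    if reference_rate is not None:
        if reference_rate == 0:
            raise InputError("reference rate must be nonzero")
        percent = 100.0 * slope / reference_rate
    return FrapResult(
        rate=slope,
        rate_percent_of_reference=percent,
        baseline=baseline,
        method=method,
        converged=converged,
    )
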