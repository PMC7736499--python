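"""Point-source estimation of extracellular diffusivity.

A dye bolus ejected from a pipette spreads as a Gaussian whose spatial
profile along the scanned line at time t after the puff is

    F(x, t) ~ exp(-(x - x_c)^2 / (4 w)),   w = D_eff * t,

so the per-line Gaussian variance parameter w (sigma^2 = 2 w) grows linearly
in time and D_eff is the slope of w(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from ..errors import FitError, InputError
from .linescan import LineScan

__all__ = ["DiffusivityFit", "estimate_point_source_diffusivity"]


@dataclass
class DiffusivityFit:
    d_eff: float                 # um^2/ms
    d_eff_stderr: float
    w_values: np.ndarray         # per-line w = sigma^2 / 2, um^2
    t_values: np.ndarray         # ms since puff
    n_rejected: int
    through_origin: bool
    converged: bool


def _fit_line_w(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian fit of one spatial profile; returns w = sigma^2 / 2."""
    amp0 = float(y.max() - y.min())
    if amp0 <= 0:
        raise FitError("flat profile")
    x0 = float(x[np.argmax(y)])
    # moment-based width guess, robust down to sub-pixel peaks
    yb = np.maximum(y - np.median(y), 0.0)
    mass = yb.sum()
    if mass > 0:
        mu = float((yb * x).sum() / mass)
        sigma0 = float(np.sqrt((yb * (x - mu) ** 2).sum() / mass))
    else:
        sigma0 = (x[-1] - x[0]) / 10.0
    sigma0 = min(max(sigma0, (x[1] - x[0]) / 4.0), (x[-1] - x[0]) / 2.0)

    def gauss(x, amp, xc, sigma, base):
        return base + amp * np.exp(-((x - xc) ** 2) / (2.0 * sigma**2))

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(
            gauss, x, y, p0=(amp0, x0, sigma0, float(y.min())), maxfev=5000
        )
    amp, _, sigma, _ = popt
    if amp <= 0:
        raise FitError("inverted profile")
    # unimodality guard: the fitted peak should dominate the residual spread
    return float(sigma**2 / 2.0)


def estimate_point_source_diffusivity(
    scan: LineScan,
    source_position: float,
    puff_time: float,
    through_origin: bool = True,
    max_reject_fraction: float = 0.5,
) -> DiffusivityFit:
    """Estimate D_eff from a spreading point-source line scan.

    source_position: pipette-tip coordinate along the line, um.
    puff_time: time of the pressure pulse, ms from the start of the scan.
    Lines whose Gaussian fit fails are rejected; if more than
    ``max_reject_fraction`` of the post-puff lines fail, the estimation
    errors out.
    """
    if not (0.0 <= source_position <= scan.positions[-1]):
        raise InputError("source position outside the scanned line")
    x = scan.positions
    t = scan.times
    post = np.nonzero(t > puff_time)[0]
    if len(post) < 5:
        raise InputError("need at least 5 post-puff lines")
    ws, ts = [], []
    rejected = 0
    for i in post:
        y = scan.intensity[i]
        try:
            w = _fit_line_w(x, y)
        except (FitError, RuntimeError):
            rejected += 1
            continue
        ws.append(w)
        ts.append(t[i] - puff_time)
    if rejected > max_reject_fraction * len(post):
        raise FitError(
            f"{rejected}/{len(post)} line fits rejected; scan unusable"
        )
    ws_arr = np.asarray(ws)
    ts_arr = np.asarray(ts)
    if through_origin:
        denom = float(np.sum(ts_arr**2))
        slope = float(np.sum(ts_arr * ws_arr) / denom)
        resid = ws_arr - slope * ts_arr
        dof = max(len(ws_arr) - 1, 1)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / denom))
    else:
        res = stats.linregress(ts_arr, ws_arr)
        slope, stderr = float(res.slope), float(res.stderr)
    return DiffusivityFit(
        d_eff=slope,
        d_eff_stderr=stderr,
        w_values=ws_arr,
        t_values=ts_arr,
        n_rejected=rejected,
        through_origin=through_origin,
        converged=True,
    )
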