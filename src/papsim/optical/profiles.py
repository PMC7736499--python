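"""Gaussian spatial-profile fitting and iGluSnFR dF/F0 profiles.

The spatial spread of an uncaging-evoked glutamate-sensor transient is read
out as the full width at half maximum (FWHM) of a Gaussian fitted to the
dF/F0 profile along the scanned line; FWHM = 2*sqrt(2 ln 2) * sigma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ..errors import FitError, InputError
from .linescan import LineScan

__all__ = [
    "FWHM_PER_SIGMA",
    "GaussianProfileFit",
    "iglusnfr_profile",
    "fit_profile_fwhm",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class GaussianProfileFit:
    center: float      # um
    sigma: float       # um
    amplitude: float
    baseline: float
    residual_rms: float
    converged: bool

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise FitError("Gaussian fit produced non-positive sigma")

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma


def iglusnfr_profile(
    scan: LineScan,
    pre_window: tuple[int, int],
    post_window: tuple[int, int],
    f0_floor: float = 0.0,
) -> np.ndarray:
    """Time-averaged (F - F0) / F0 per pixel.

    pre_window and post_window are [start, stop) line index ranges; the pre
    window samples the baseline profile F0(x), the post window the evoked
    profile F(x).  Pixels whose F0 does not exceed ``f0_floor`` are masked to
    NaN with a warning; an all-masked profile is an error.
    """
    p0, p1 = pre_window
    q0, q1 = post_window
    n = scan.n_lines
    if not (0 <= p0 < p1 <= n and 0 <= q0 < q1 <= n):
        raise InputError("windows must lie within the scan")
    if max(p0, q0) < min(p1, q1):
        raise InputError("pre and post windows must be disjoint")
    f0 = scan.intensity[p0:p1].mean(axis=0)
    f = scan.intensity[q0:q1].mean(axis=0)
    bad = f0 <= f0_floor
    if bad.all():
        raise InputError("baseline F0 non-positive at every pixel")
    if bad.any():
        import warnings

        warnings.warn(
            f"masking {int(bad.sum())} pixels with non-positive baseline F0",
            stacklevel=2,
        )
    out = np.full(scan.n_pixels, np.nan)
    ok = ~bad
    out[ok] = (f[ok] - f0[ok]) / f0[ok]
    return out


def _gauss(x, amp, center, sigma, baseline):
    return baseline + amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def fit_profile_fwhm(
    profile: np.ndarray,
    positions: np.ndarray | None = None,
    pixel_pitch: float = 1.0,
    center: float | None = None,
    fit_baseline: bool = True,
) -> GaussianProfileFit:
    """Fit a Gaussian to a single-peaked spatial profile.

    ``center`` fixes the Gaussian at the uncaging-spot position (the default
    protocol); pass None to leave the centre free (QC use).
    """
    y = np.asarray(profile, dtype=float)
    ok = np.isfinite(y)
    if positions is None:
        positions = np.arange(len(y)) * pixel_pitch
    x = np.asarray(positions, dtype=float)[ok]
    y = y[ok]
    if len(y) < 5:
        raise InputError("need at least 5 finite profile points")
    amp0 = float(y.max() - y.min())
    if amp0 <= 0 or not np.isfinite(amp0):
        raise FitError("flat profile: no peak to fit")
    # single-dominant-peak guard: the maximum must clearly exceed the edges
    edge = max(y[0], y[-1])
    if y.max() - edge < 0.2 * amp0:
        raise FitError("profile peak is not dominant (flat or edge-peaked)")
    x0 = float(x[np.argmax(y)]) if center is None else float(center)
    sigma0 = max((x[-1] - x[0]) / 10.0, 1e-6)
    base0 = float(np.percentile(y, 10)) if fit_baseline else 0.0
    try:
        if center is None and fit_baseline:
            popt, _ = optimize.curve_fit(
                _gauss, x, y, p0=(amp0, x0, sigma0, base0), maxfev=20000
            )
            amp, xc, sigma, base = popt
        elif center is None:
            f = lambda x, amp, xc, s: _gauss(x, amp, xc, s, 0.0)
            popt, _ = optimize.curve_fit(
                f, x, y, p0=(amp0, x0, sigma0), maxfev=20000
            )
            amp, xc, sigma = popt
            base = 0.0
        elif fit_baseline:
            f = lambda x, amp, s, b: _gauss(x, amp, x0, s, b)
            popt, _ = optimize.curve_fit(
                f, x, y, p0=(amp0, sigma0, base0), maxfev=20000
            )
            amp, sigma, base = popt
            xc = x0
        else:
            f = lambda x, amp, s: _gauss(x, amp, x0, s, 0.0)
            popt, _ = optimize.curve_fit(f, x, y, p0=(amp0, sigma0), maxfev=20000)
            amp, sigma = popt
            xc = x0
            base = 0.0
    except RuntimeError as exc:
        raise FitError(f"Gaussian profile fit did not converge: {exc}") from exc
    resid = y - _gauss(x, amp, xc, abs(sigma), base)
    return GaussianProfileFit(
        center=float(xc),
        sigma=float(abs(sigma)),
        amplitude=float(amp),
        baseline=float(base),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=True,
    )
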