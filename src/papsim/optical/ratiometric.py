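"""Ratiometric (FRET) glutamate-sensor responses.

The immobilised sensor reports glutamate through the donor/acceptor emission
ratio R = ECFP/Venus; the response is dR(t) = R(t) - <R_baseline>.
"""

from __future__ import annotations

import numpy as np

from ..errors import InputError

__all__ = ["ratiometric_response", "fit_saturation_binding"]


def ratiometric_response(
    donor: np.ndarray,
    acceptor: np.ndarray,
    baseline_window: tuple[int, int] | None = None,
    mask_zero_acceptor: bool = True,
) -> np.ndarray:
    """dR trace with R = donor / acceptor.

    baseline_window: [start, stop) sample range defining the baseline mean
    (defaults to the first quarter of the trace).  Zero-acceptor samples are
    masked to NaN (or raise, if mask_zero_acceptor is False).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape or donor.ndim != 1:
        raise InputError("donor and acceptor must be matching 1D traces")
    bad = acceptor <= 0
    if bad.any() and not mask_zero_acceptor:
        raise InputError("acceptor trace contains non-positive samples")
    r = np.full_like(donor, np.nan)
    r[~bad] = donor[~bad] / acceptor[~bad]
    if baseline_window is None:
        baseline_window = (0, max(1, len(r) // 4))
    s0, s1 = baseline_window
    base = np.nanmean(r[s0:s1])
    if not np.isfinite(base):
        raise InputError("baseline window contains no valid ratio samples")
    return r - base


def fit_saturation_binding(concentrations, responses):
    """Half-saturation constant from a titration: dR = dR_max * c / (c + Kd)."""
    from scipy import optimize

    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(c) < 3:
        raise InputError("need at least 3 titration points")

    def hill1(c, rmax, kd):
        return rmax * c / (c + kd)

    popt, _ = optimize.curve_fit(
        hill1, c, y, p0=(float(y.max()), float(np.median(c))), maxfev=10000
    )
    return {"r_max": float(popt[0]), "kd": float(popt[1])}
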