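"""Astroglial volume-fraction (VF) readout and its decay after LTP induction.

The VF of dye-filled perisynaptic astroglial processes within a region of
interest is read out as the background-corrected ROI fluorescence normalised
to the somatic fluorescence, where the dye fills 100% of the tissue volume:

    VF = (F_roi - F_bg) / (F_soma - F_bg)

After LTP induction the normalised VF relaxes exponentially to a steady
state:

    VF(t) = VF_ss + (1 - VF_ss) * exp(-t / tau)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ..errors import FitError, InputError

__all__ = ["compute_vf", "VFTrace", "VFDecayFit", "fit_vf_decay"]


def compute_vf(f_roi, f_soma, background=0.0):
    """Somatic-normalised volume fraction; scale-invariant in the inputs."""
    f_roi = np.asarray(f_roi, dtype=float)
    f_soma = np.asarray(f_soma, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(f_soma <= background):
        raise InputError(
            "somatic fluorescence must exceed background for VF normalisation"
        )
    return (f_roi - background) / (f_soma - background)


@dataclass
class VFTrace:
    """Relative VF time series, normalised to pre-induction mean = 1."""

    times: np.ndarray   # minutes, induction onset at t = 0
    values: np.ndarray  # dimensionless; readout noise may exceed 1 transiently
    condition: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InputError("times and values must be matching 1D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise InputError("times must be strictly increasing")


def _model(t, vf_ss, tau):
    return vf_ss + (1.0 - vf_ss) * np.exp(-t / tau)


@dataclass
class VFDecayFit:
    vf_ss: float
    tau: float                      # minutes
    vf_ss_stderr: float
    tau_stderr: float
    residual_rms: float
    identifiable: bool
    n_points: int

    def confidence_interval(self, z: float = 1.96) -> dict:
        return {
            "vf_ss": (self.vf_ss - z * self.vf_ss_stderr,
                      self.vf_ss + z * self.vf_ss_stderr),
            "tau": (self.tau - z * self.tau_stderr,
                    self.tau + z * self.tau_stderr),
        }


def fit_vf_decay(trace: VFTrace) -> VFDecayFit:
    """Least-squares fit of VF(t) = VF_ss + (1 - VF_ss) exp(-t/tau).

    A non-decaying trace is flagged unidentifiable: tau is returned as nan
    and VF_ss as the trace mean.
    """
    t, v = trace.times, trace.values
    post = t >= 0
    if post.sum() < 5:
        raise InputError("need at least 5 post-onset time points")
    t, v = t[post], v[post]
    drop = 1.0 - v[-max(3, len(v) // 5):].mean()
    noise = np.std(np.diff(v)) / np.sqrt(2.0)
    if drop <= max(2.0 * noise / np.sqrt(len(v)), 1e-12):
        return VFDecayFit(
            vf_ss=float(v.mean()),
            tau=float("nan"),
            vf_ss_stderr=float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            tau_stderr=float("nan"),
            residual_rms=float(np.sqrt(np.mean((v - v.mean()) ** 2))),
            identifiable=False,
            n_points=len(v),
        )
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    p0 = (max(min(v[-1], 1.0), 1e-3), max(span / 3.0, 1e-3))
    try:
        popt, pcov = optimize.curve_fit(
            _model, t, v, p0=p0, maxfev=20000,
            bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"VF decay fit failed: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    resid = v - _model(t, *popt)
    return VFDecayFit(
        vf_ss=float(popt[0]),
        tau=float(popt[1]),
        vf_ss_stderr=float(perr[0]),
        tau_stderr=float(perr[1]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        identifiable=True,
        n_points=len(v),
    )
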