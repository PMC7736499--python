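"""MK801 cross-talk quantification and spillover arithmetic.

The use-dependent NMDAR blocker MK801 only blocks channels that open; if
NMDARs of a silent pathway become blocked while only the other (active)
pathway is stimulated, they must have been activated by glutamate escaping
from active synapses.  The cross-talk fraction is the relative reduction of
the silent pathway's NMDAR EPSC when its stimulation resumes.

Companion arithmetic: the per-discharge activation probability p solves
(1 - p)^n = 1 - f under independent discharges; density-scaled
nearest-neighbour distance d0 * p^(-1/3) for a subsampled synapse
population; and the extracellular-space increase produced by a fractional
loss of astroglial volume, (dVF * VF_astro) / ECS.  Release-statistics
helpers: paired-pulse ratio, 1/CV^2, and the MK801 trial-decay constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ..errors import FitError, InputError
from .epsc import EPSCSeries

__all__ = [
    "crosstalk_fraction",
    "per_discharge_probability",
    "subsample_nn_distance",
    "ecs_increase",
    "paired_pulse_ratio",
    "inv_cv_squared",
    "MK801Decay",
    "mk801_block_rate",
    "SpilloverEstimate",
]


@dataclass(frozen=True)
class SpilloverEstimate:
    """Cross-talk bookkeeping for one experiment."""

    cumulative_fraction: float      # f, fraction of silent-pool NMDARs blocked
    discharge_count: int            # n
    per_discharge_probability: float
    subsample_fraction: float | None = None
    scaled_distance_um: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.cumulative_fraction < 1.0):
            raise InputError("cumulative fraction must be in [0, 1)")
        if self.discharge_count < 1:
            raise InputError("discharge count must be >= 1")
        if not (
            0.0 <= self.per_discharge_probability <= self.cumulative_fraction
        ):
            raise InputError("per-discharge probability must be in [0, f]")


def crosstalk_fraction(
    series: EPSCSeries,
    pathway: str = "silent",
    min_trials: int = 3,
) -> float:
    """Percent of the pathway's NMDARs cross-activated during its pause.

    100 * (1 - mean(resumed) / mean(nmdar_baseline)); invariant to amplitude
    rescaling.
    """
    base = series.amplitudes(pathway, "nmdar_baseline")
    resumed = series.amplitudes(pathway, "resumed")
    if len(base) < min_trials or len(resumed) < min_trials:
        raise InputError(
            f"need >= {min_trials} trials in both nmdar_baseline and resumed"
        )
    base_mean = base.mean()
    if base_mean <= 0:
        raise InputError("degenerate zero baseline")
    return float(100.0 * (1.0 - resumed.mean() / base_mean))


def per_discharge_probability(f: float, n: int) -> float:
    """p solving (1 - p)^n = 1 - f (independent-discharge model)."""
    if not (0.0 <= f < 1.0):
        raise InputError("cumulative fraction f must be in [0, 1)")
    if n < 1:
        raise InputError("discharge count must be >= 1")
    return float(1.0 - (1.0 - f) ** (1.0 / n))


def subsample_nn_distance(d0: float, p: float) -> float:
    """Mean nearest-neighbour distance after density thinning: d0 * p^(-1/3)."""
    if d0 <= 0:
        raise InputError("d0 must be > 0")
    if not (0.0 < p <= 1.0):
        raise InputError("subsample fraction must be in (0, 1]")
    return float(d0 * p ** (-1.0 / 3.0))


def ecs_increase(vf_astro: float, vf_decrease: float, ecs: float) -> float:
    """Relative extracellular-space increase from a fractional PAP-VF loss.

    A relative decrease ``vf_decrease`` of the astroglial tissue fraction
    ``vf_astro`` releases vf_decrease * vf_astro of tissue volume into the
    extracellular space ``ecs``.
    """
    for name, v in (("vf_astro", vf_astro), ("vf_decrease", vf_decrease)):
        if not (0.0 <= v < 1.0):
            raise InputError(f"{name} must be in [0, 1)")
    if not (0.0 < ecs < 1.0):
        raise InputError("ecs must be in (0, 1)")
    return float(vf_decrease * vf_astro / ecs)


def paired_pulse_ratio(a1: float, a2: float) -> float:
    """Facilitation percent, 100 * (a2 - a1) / a1."""
    if a1 <= 0:
        raise InputError("first amplitude must be > 0")
    return float(100.0 * (a2 - a1) / a1)


def inv_cv_squared(amplitudes) -> float:
    """1/CV^2 = mean^2 / variance (sample variance, ddof=1).

    Under a binomial release model with N sites and release probability p,
    1/CV^2 ~= N p / (1 - p); scale-invariant.
    """
    a = np.asarray(amplitudes, dtype=float)
    if len(a) < 3:
        raise InputError("need at least 3 trials")
    var = a.var(ddof=1)
    if var == 0:
        raise InputError("zero variance: 1/CV^2 undefined")
    return float(a.mean() ** 2 / var)


@dataclass
class MK801Decay:
    k0: float                    # decay constant in trials
    k0_stderr: float
    a0: float
    identifiable: bool
    n_trials: int

    def confidence_interval(self, z: float = 1.96) -> tuple[float, float]:
        return (self.k0 - z * self.k0_stderr, self.k0 + z * self.k0_stderr)


def mk801_block_rate(
    series: EPSCSeries,
    pathway: str = "active",
    phase: str = "mk801",
) -> MK801Decay:
    """Trial-decay constant of NMDAR EPSCs under MK801.

    Fits amplitude_k = A0 * exp(-k / k0) over trial number k; the decay rate
    reflects release probability.  A non-decaying series is flagged
    unidentifiable.
    """
    amps = series.amplitudes(pathway, phase)
    if len(amps) < 5:
        raise InputError("need >= 5 MK801-phase trials")
    k = np.arange(len(amps), dtype=float)
    if amps[-max(2, len(amps) // 4):].mean() >= amps[: max(2, len(amps) // 4)].mean():
        return MK801Decay(
            k0=float("nan"),
            k0_stderr=float("nan"),
            a0=float(amps.mean()),
            identifiable=False,
            n_trials=len(amps),
        )

    def model(k, a0, k0):
        return a0 * np.exp(-k / k0)

    try:
        popt, pcov = optimize.curve_fit(
            model, k, amps, p0=(float(amps[0]), max(len(amps) / 2.0, 1.0)),
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"MK801 decay fit failed: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return MK801Decay(
        k0=float(popt[1]),
        k0_stderr=float(perr[1]),
        a0=float(popt[0]),
        identifiable=True,
        n_trials=len(amps),
    )
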