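"""Seeded synthetic-data generators for every analysis stage.

Each generator is deterministic given (parameters, seed) and returns the
data object together with a ``truth`` dict recording the generating
parameters, so estimator recovery can be tested without any external data.
Noise defaults: additive Gaussian for imaging signals, multiplicative
Gaussian for EPSC amplitudes, optional Poisson shot noise for line scans.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd

from ..errors import InputError
from ..nanoscale.localizations import LocalizationSet
from ..nanoscale.shells import VoxelMask
from ..optical.linescan import LineScan
from ..optical.vf import VFTrace
from ..crosstalk.epsc import EPSCSeries

__all__ = [
    "gen_vf_trace",
    "gen_point_source_linescan",
    "gen_uncaging_linescan",
    "gen_localizations",
    "gen_masks",
    "gen_epsc_series",
    "write_truth_sidecar",
]


def write_truth_sidecar(path, truth: dict) -> None:
    """Serialise a generator's ground truth next to its dataset."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)


def gen_vf_trace(
    vf_ss: float = 0.77,
    tau: float = 14.0,
    noise_sd: float = 0.02,
    n_points: int = 30,
    duration: float = 30.0,
    seed: int = 0,
) -> tuple[VFTrace, dict]:
    """Exponential VF decay to steady state plus i.i.d. Gaussian noise.

    Defaults reproduce the LTP-induction decay (steady state 0.77, time
    constant 14 min).
    """
    if not (0.0 < vf_ss <= 1.0):
        raise InputError("vf_ss must be in (0, 1]")
    if tau <= 0:
        raise InputError("tau must be > 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    model = vf_ss + (1.0 - vf_ss) * np.exp(-t / tau)
    values = model + rng.normal(0.0, noise_sd, n_points)
    truth = {
        "generator": "vf_trace",
        "vf_ss": vf_ss,
        "tau_min": tau,
        "noise_sd": noise_sd,
        "n_points": n_points,
        "duration_min": duration,
        "seed": seed,
    }
    return VFTrace(t, values, condition="synthetic", meta=truth), truth


def gen_point_source_linescan(
    d_coeff: float = 0.4,
    dx: float = 0.25,
    dt: float = 0.5,
    duration: float = 20.0,
    n_pixels: int = 160,
    source_position: float | None = None,
    amplitude: float = 100.0,
    noise_sd: float = 1.0,
    baseline_level: float = 20.0,
    puff_time: float = 2.0,
    shot_noise: bool = False,
    seed: int = 0,
) -> tuple[LineScan, dict]:
    """Line scan of a dye bolus spreading from a point source.

    Per-line profile ~ (4 pi D t)^(-1/2) exp(-(x - x_c)^2 / (4 D t)) with
    w = D*t, so the diffusivity estimator should recover d_coeff (um^2/ms).
    dx um per pixel, dt ms per line.  baseline_level is a constant detector
    offset keeping the noisy signal positive (intensities are clipped at 0).
    """
    if d_coeff <= 0:
        raise InputError("diffusion coefficient must be > 0")
    rng = np.random.default_rng(seed)
    n_lines = int(round(duration / dt))
    x = np.arange(n_pixels) * dx
    xc = source_position if source_position is not None else x[n_pixels // 2]
    img = np.zeros((n_lines, n_pixels))
    times = np.arange(n_lines) * dt
    for i, t in enumerate(times):
        te = t - puff_time
        if te <= 0:
            continue
        w = d_coeff * te
        img[i] = (
            amplitude / math.sqrt(4.0 * math.pi * w)
            * np.exp(-((x - xc) ** 2) / (4.0 * w))
        )
    img = img + baseline_level
    if shot_noise:
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.maximum(img, 0.0)
    truth = {
        "generator": "point_source_linescan",
        "d_coeff_um2_per_ms": d_coeff,
        "dx_um": dx,
        "dt_ms": dt,
        "duration_ms": duration,
        "amplitude": amplitude,
        "noise_sd": noise_sd,
        "puff_time_ms": puff_time,
        "source_position_um": float(xc),
        "shot_noise": shot_noise,
        "seed": seed,
    }
    return LineScan(img, line_period=dt, pixel_pitch=dx, meta=truth), truth


def gen_uncaging_linescan(
    sigma_pre: float = 1.0,
    sigma_post: float = 1.09,
    amplitude: float = 0.8,
    f0_level: float = 50.0,
    noise_sd: float = 2.0,
    dx: float = 0.1,
    dt: float = 2.0,
    n_pixels: int = 128,
    n_pre_lines: int = 20,
    n_post_lines: int = 20,
    seed: int = 0,
) -> tuple[LineScan, LineScan, dict]:
    """Pre/post-LTP pair of uncaging-evoked sensor line scans.

    Each scan holds a baseline segment followed by a Gaussian dF/F0
    transient of spatial width sigma (um) centred at the uncaging spot; the
    FWHM-change ground truth is sigma_post / sigma_pre - 1 (+9% at the
    defaults, the LTP-scenario magnitude).
    """
    rng = np.random.default_rng(seed)
    x = np.arange(n_pixels) * dx
    xc = x[n_pixels // 2]

    def one(sigma):
        profile = amplitude * np.exp(-((x - xc) ** 2) / (2.0 * sigma**2))
        n_lines = n_pre_lines + n_post_lines
        img = np.full((n_lines, n_pixels), f0_level)
        img[n_pre_lines:] = f0_level * (1.0 + profile)
        img = img + rng.normal(0.0, noise_sd, img.shape)
        return LineScan(np.maximum(img, 0.0), line_period=dt, pixel_pitch=dx)

    pre = one(sigma_pre)
    post = one(sigma_post)
    truth = {
        "generator": "uncaging_linescan",
        "sigma_pre_um": sigma_pre,
        "sigma_post_um": sigma_post,
        "fwhm_change": sigma_post / sigma_pre - 1.0,
        "amplitude": amplitude,
        "f0_level": f0_level,
        "noise_sd": noise_sd,
        "uncaging_position_um": float(xc),
        "n_pre_lines": n_pre_lines,
        "seed": seed,
    }
    pre.meta.update(truth)
    post.meta.update(truth)
    return pre, post, truth


def gen_localizations(
    n_synapses: int = 5,
    bassoon_sd: float = 40.0,
    homer_offset: float = 80.0,
    glt1_radial_mean: float = 150.0,
    glt1_radial_sd: float = 30.0,
    points_per_channel: int = 60,
    background_rate: float = 0.0,
    synapse_spacing: float = 1000.0,
    seed: int = 0,
) -> tuple[LocalizationSet, dict]:
    """Perisynaptic three-channel localization clouds (nm).

    Per synapse: a bassoon cluster (isotropic Gaussian, sd bassoon_sd), a
    Homer1 cluster displaced by homer_offset along +z, and GLT1 points on a
    noisy spherical shell at radial distance ~N(glt1_radial_mean,
    glt1_radial_sd) from the bassoon centroid.  background_rate adds
    uniformly scattered points per channel across the field.
    """
    rng = np.random.default_rng(seed)
    pts, chans, syn = [], [], []
    field_hi = n_synapses * synapse_spacing
    for s in range(n_synapses):
        centre = np.array(
            [s * synapse_spacing + synapse_spacing / 2.0, 0.0, 0.0]
        )
        bass = centre + rng.normal(0.0, bassoon_sd, (points_per_channel, 3))
        homer = (
            centre
            + np.array([0.0, 0.0, homer_offset])
            + rng.normal(0.0, bassoon_sd, (points_per_channel, 3))
        )
        radii = rng.normal(glt1_radial_mean, glt1_radial_sd, points_per_channel)
        radii = np.maximum(radii, 1.0)
        dirs = rng.normal(size=(points_per_channel, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        glt = centre + dirs * radii[:, None]
        for arr, name in ((bass, "bassoon"), (homer, "homer1"), (glt, "glt1")):
            pts.append(arr)
            chans.extend([name] * len(arr))
            syn.extend([s] * len(arr))
    n_bg = rng.poisson(background_rate) if background_rate > 0 else 0
    if n_bg:
        for name in ("bassoon", "homer1", "glt1"):
            bg = rng.uniform(
                [-500.0, -500.0, -500.0],
                [field_hi + 500.0, 500.0, 500.0],
                (n_bg, 3),
            )
            pts.append(bg)
            chans.extend([name] * n_bg)
            syn.extend([-1] * n_bg)
    points = np.concatenate(pts)
    truth = {
        "generator": "localizations",
        "n_synapses": n_synapses,
        "bassoon_sd_nm": bassoon_sd,
        "homer_offset_nm": homer_offset,
        "glt1_radial_mean_nm": glt1_radial_mean,
        "glt1_radial_sd_nm": glt1_radial_sd,
        "points_per_channel": points_per_channel,
        "background_rate": background_rate,
        "seed": seed,
    }
    return (
        LocalizationSet(
            points,
            np.array(chans),
            synapse_ids=np.array(syn),
            meta=truth,
        ),
        truth,
    )


def gen_masks(
    shapes: list[dict] | None = None,
    grid_shape: tuple[int, int, int] = (120, 120, 120),
    pitch: float = 10.0,
    seed: int = 0,
) -> tuple[VoxelMask, dict]:
    """Voxelised occupancy mask from spheres/ellipsoids.

    shapes: list of {"center": (x, y, z) nm, "radii": r or (rx, ry, rz) nm}.
    An empty list gives an empty mask.
    """
    shapes = shapes if shapes is not None else []
    occ = np.zeros(grid_shape, dtype=bool)
    coords = [
        (np.arange(n) + 0.5) * pitch for n in grid_shape
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    for spec in shapes:
        c = np.asarray(spec["center"], dtype=float)
        radii = np.asarray(spec["radii"], dtype=float)
        if radii.ndim == 0:
            radii = np.repeat(radii, 3)
        occ |= (
            ((xx - c[0]) / radii[0]) ** 2
            + ((yy - c[1]) / radii[1]) ** 2
            + ((zz - c[2]) / radii[2]) ** 2
        ) <= 1.0
    truth = {
        "generator": "masks",
        "shapes": shapes,
        "grid_shape": list(grid_shape),
        "pitch_nm": pitch,
        "seed": seed,
    }
    return VoxelMask(occ, pitch, meta=truth), truth


def gen_epsc_series(
    n_sites: int = 20,
    p_release: float = 0.35,
    quantal_size: float = 10.0,
    trials_per_phase: int = 20,
    mk801_block_prob: float = 0.2,
    crosstalk: float = 0.0,
    noise_cv: float = 0.2,
    seed: int = 0,
) -> tuple[EPSCSeries, dict]:
    """Two-pathway EPSC series under the binomial release model.

    Amplitudes ~ Binomial(n_sites, p_release) * quantal_size with
    multiplicative Gaussian noise (CV noise_cv).  During the MK801 phase the
    active pathway's NMDAR response declines as receptors open and block
    (per-trial open-and-block probability mk801_block_prob); the silent
    pathway's resumed amplitudes are scaled by (1 - crosstalk).
    """
    if not (0.0 <= p_release <= 1.0) or not (0.0 <= crosstalk < 1.0):
        raise InputError("probabilities must be valid")
    rng = np.random.default_rng(seed)
    rows = []
    trial = 0

    def draw(n):
        q = rng.binomial(n_sites, p_release, n) * quantal_size
        return q * np.maximum(rng.normal(1.0, noise_cv, n), 0.0)

    mean_amp = n_sites * p_release * quantal_size
    for pathway in ("active", "silent"):
        for phase in ("ampar_baseline", "nmdar_baseline"):
            for a in draw(trials_per_phase):
                rows.append((trial, pathway, phase, a))
                trial += 1
    # MK801 phase: only the active pathway is stimulated
    surviving = 1.0
    for a in draw(trials_per_phase):
        rows.append((trial, "active", "mk801", a * surviving))
        surviving *= 1.0 - mk801_block_prob
        trial += 1
    for a in draw(trials_per_phase):
        rows.append((trial, "silent", "resumed", a * (1.0 - crosstalk)))
        trial += 1
    frame = pd.DataFrame(
        rows, columns=["trial", "pathway", "phase", "amplitude_pA"]
    )
    truth = {
        "generator": "epsc_series",
        "n_sites": n_sites,
        "p_release": p_release,
        "quantal_size_pA": quantal_size,
        "trials_per_phase": trials_per_phase,
        "mk801_block_prob": mk801_block_prob,
        "crosstalk": crosstalk,
        "noise_cv": noise_cv,
        "mean_amplitude_pA": mean_amp,
        "inv_cv2_expected": n_sites * p_release / (1.0 - p_release),
        "mk801_k0_expected": (
            -1.0 / math.log(1.0 - mk801_block_prob)
            if 0.0 < mk801_block_prob < 1.0
            else float("nan")
        ),
        "seed": seed,
    }
    return EPSCSeries(frame, meta=truth), truth
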