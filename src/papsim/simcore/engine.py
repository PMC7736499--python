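"""Stochastic simulation of glutamate release, diffusion, capture and
NMDAR activation.

3000 glutamate molecules are released instantaneously at the cleft centre and
perform Brownian steps with per-axis variance 2*D*dt (displacements drawn
from a zero-mean uniform with exactly that variance; over the >=10^3 steps of
any observable interval the propagator is Gaussian by the central limit
theorem).  Solid membranes reflect (step rejection).  The outer domain
boundary absorbs by default: a molecule leaving the ~1 um local environment
is booked as "escaped", standing in for dilution and eventual uptake by the
ubiquitous transporters of the distal neuropil; a reflective (mirror)
option represents a periodic tissue with no distal sink instead.  Molecules
passing within a reaction radius of a free
transporter or a non-saturated NMDAR bind with a per-encounter probability;
bound-state transitions are sampled per time step from exponential
waiting-time approximations.

Internal units: nm and ms.  ``SimConfig.time_step`` is in microseconds, as is
conventional for these step sizes; outputs are in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numba
import numpy as np

from ..errors import ConfigurationError
from .geometry import GeometryModel
from .kinetics import KineticScheme, nmdar_scheme, transporter_scheme
from .placement import SiteLayout

__all__ = ["SimConfig", "SimResult", "simulate_release", "default_schemes"]

_D_UM2_PER_MS_TO_NM2 = 1e6

# molecule states
_FREE, _TBOUND, _RBOUND, _TAKEN, _ESCAPED = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    time_step is in microseconds; if None the largest step satisfying
    sqrt(6*D*dt) <= gap_width/4 is used.  total_time and bin_width are in ms.
    """

    n_molecules: int = 3000
    diffusion_coefficient: float = 0.4  # um^2/ms
    time_step: float | None = None      # us
    total_time: float = 2.0             # ms, covers the extrasynaptic transient
    n_runs: int = 32
    rng_seed: int = 0
    transporter_density: float = 7500.0  # per um^2, within the 5-10e3 range
    bin_width: float = 0.02              # ms, output binning
    probe_radius: float = 200.0          # nm, for dwell-time readout
    store_snapshots: bool = False
    #: outer-boundary handling: "absorbing" books molecules leaving the
    #: local environment as escaped (distal dilution and uptake);
    #: "reflective" mirrors a periodic neuropil with no distal sink
    boundary: str = "absorbing"

    def __post_init__(self) -> None:
        if self.n_molecules < 0 or self.n_runs < 1:
            raise ConfigurationError("need n_molecules >= 0 and n_runs >= 1")
        if self.diffusion_coefficient <= 0 or self.total_time <= 0:
            raise ConfigurationError("D and total_time must be > 0")
        if self.time_step is not None and self.time_step <= 0:
            raise ConfigurationError("time_step must be > 0")
        if self.boundary not in ("reflective", "absorbing"):
            raise ConfigurationError(
                f"boundary must be 'reflective' or 'absorbing', "
                f"got {self.boundary!r}"
            )

    def resolved_time_step_ms(self, gap_width: float | None) -> float:
        d_nm = self.diffusion_coefficient * _D_UM2_PER_MS_TO_NM2
        if self.time_step is not None:
            dt = self.time_step * 1e-3
            if gap_width is not None:
                rms = math.sqrt(6.0 * d_nm * dt)
                if rms > gap_width / 4.0 * (1 + 1e-9):
                    raise ConfigurationError(
                        f"rms step {rms:.2f} nm exceeds gap_width/4 "
                        f"= {gap_width / 4:.2f} nm; reduce time_step"
                    )
            return dt
        if gap_width is None:
            return 1e-3  # 1 us default in open space
        return (gap_width / 4.0) ** 2 / (6.0 * d_nm)


@dataclass
class SimResult:
    """Per-run time series of molecule and receptor states."""

    time: np.ndarray                # bin-end times, ms
    free: np.ndarray
    transporter_bound: np.ndarray
    receptor_bound: np.ndarray
    taken_up: np.ndarray
    escaped: np.ndarray
    open_counts: np.ndarray         # (n_bins, n_sectors) NMDAR open channels
    uptake_cum: np.ndarray          # (n_bins, n_sectors) cumulative uptake
    beyond_probe: np.ndarray        # free molecules beyond probe_radius
    cross_sector_events: tuple[int, int]  # (same-sector, cross-sector) bindings
    rng_seed: int
    n_molecules: int
    bin_width: float
    snapshots: np.ndarray | None = None   # (n_bins, n_molecules, 3) nm

    def conservation_ok(self) -> bool:
        total = (
            self.free
            + self.transporter_bound
            + self.receptor_bound
            + self.taken_up
            + self.escaped
        )
        return bool(np.all(total == self.n_molecules))

    @property
    def removed(self) -> np.ndarray:
        """Molecules permanently removed (taken up or escaped)."""
        return self.taken_up + self.escaped


def default_schemes() -> dict[str, KineticScheme]:
    return {"transporter": transporter_scheme(), "nmdar": nmdar_scheme()}


def _build_site_grid(positions: np.ndarray, cell: float):
    """Uniform-grid CSR index over site positions for O(1) neighbour lookup."""
    if len(positions) == 0:
        return (
            np.zeros(3),
            np.ones(3, dtype=np.int64),
            np.zeros(2, dtype=np.int64),
            np.zeros(0, dtype=np.int64),
        )
    origin = positions.min(axis=0) - cell
    dims = np.floor((positions.max(axis=0) - origin) / cell).astype(np.int64) + 2
    idx = np.floor((positions - origin) / cell).astype(np.int64)
    flat = (idx[:, 0] * dims[1] + idx[:, 1]) * dims[2] + idx[:, 2]
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=int(dims.prod()))
    start = np.zeros(int(dims.prod()) + 1, dtype=np.int64)
    np.cumsum(counts, out=start[1:])
    return origin, dims, start, order.astype(np.int64)


@numba.njit(cache=True, fastmath=True, inline="always")
def _inside_solid(x, y, z, r2, zoff, hh, excl2, period, half_cube, dh):
    rxy2 = x * x + y * y
    dpre2 = rxy2 + (z - zoff) * (z - zoff)
    if z >= hh and dpre2 <= r2:
        return True
    dpost2 = rxy2 + (z + zoff) * (z + zoff)
    if z <= -hh and dpost2 <= r2:
        return True
    if dpre2 > excl2 and dpost2 > excl2:
        ux = x + dh
        ux -= period * math.floor(ux / period) + period * 0.5
        if abs(ux) <= half_cube:
            uy = y + dh
            uy -= period * math.floor(uy / period) + period * 0.5
            if abs(uy) <= half_cube:
                uz = z + dh
                uz -= period * math.floor(uz / period) + period * 0.5
                if abs(uz) <= half_cube:
                    return True
    return False


@numba.njit(cache=True, fastmath=True)
def _run_kernel(
    seed,
    n_mol,
    n_steps,
    bin_every,
    step_amp,
    has_solids,
    r2,
    zoff,
    hh,
    excl2,
    period,
    half_cube,
    domain_half,
    reflective,
    wall_r02,
    n_sectors,
    exit_r2,
    # transporters
    tpos,
    tsec,
    tgrid_origin,
    tgrid_dims,
    tgrid_start,
    tgrid_items,
    tgrid_cell,
    rho_t,
    belt_lo2,
    belt_hi2,
    p_enc_t,
    p_tleave,
    frac_unbind,
    # receptors
    rpos,
    rsec,
    rho_r,
    p_enc_r,
    p_koff,
    p_open,
    p_close,
    rz_lo,
    rz_hi,
    rd_lo2,
    rd_hi2,
    probe_r2,
    store_snap,
    # outputs
    counts,
    open_counts,
    uptake_cum,
    beyond_probe,
    snapshots,
):
    np.random.seed(seed)
    pos = np.zeros((n_mol, 3))
    state = np.zeros(n_mol, dtype=np.int8)
    site = np.full(n_mol, -1, dtype=np.int64)
    exit_sector = np.full(n_mol, -1, dtype=np.int8)
    n_t = tpos.shape[0]
    n_r = rpos.shape[0]
    t_occupied = np.zeros(n_t, dtype=np.int8)
    r_glu = np.zeros(n_r, dtype=np.int8)
    r_open = np.zeros(n_r, dtype=np.int8)
    uptake_counter = np.zeros(n_sectors, dtype=np.int64)
    same_sector = 0
    cross_sector = 0
    rho_t2 = rho_t * rho_t
    rho_r2 = rho_r * rho_r
    two_pi = 2.0 * math.pi
    bin_idx = 0
    for step in range(n_steps):
        for m in range(n_mol):
            s = state[m]
            if s >= _TAKEN:
                continue
            if s == _TBOUND:
                if np.random.random() < p_tleave:
                    t_occupied[site[m]] = 0
                    if np.random.random() < frac_unbind:
                        state[m] = _FREE
                    else:
                        state[m] = _TAKEN
                        uptake_counter[tsec[site[m]]] += 1
                    site[m] = -1
                continue
            if s == _RBOUND:
                k = site[m]
                if r_open[k] == 0 and np.random.random() < p_koff:
                    r_glu[k] -= 1
                    state[m] = _FREE
                    site[m] = -1
                continue
            # free molecule: Brownian step (uniform, variance 2*D*dt per axis)
            x = pos[m, 0] + step_amp * (2.0 * np.random.random() - 1.0)
            y = pos[m, 1] + step_amp * (2.0 * np.random.random() - 1.0)
            z = pos[m, 2] + step_amp * (2.0 * np.random.random() - 1.0)
            if (
                abs(x) > domain_half
                or abs(y) > domain_half
                or abs(z) > domain_half
            ):
                if reflective == 1:
                    continue  # mirror boundary: reject the move
                state[m] = _ESCAPED
                continue
            blocked = False
            if wall_r02 >= 0.0 and (
                x * pos[m, 0] < 0.0 or y * pos[m, 1] < 0.0
            ):
                # crossing a sector partition plane beyond the wall radius
                if x * x + y * y > wall_r02:
                    blocked = True
            if not blocked and has_solids == 1 and _inside_solid(
                x, y, z, r2, zoff, hh, excl2, period, half_cube, domain_half
            ):
                blocked = True
            if blocked:
                x, y, z = pos[m, 0], pos[m, 1], pos[m, 2]  # reflect by rejection
            else:
                pos[m, 0], pos[m, 1], pos[m, 2] = x, y, z
            rad2 = x * x + y * y + z * z
            if exit_sector[m] < 0 and rad2 >= exit_r2:
                phi = math.atan2(y, x) % two_pi
                sec = int(phi / two_pi * n_sectors)
                if sec >= n_sectors:
                    sec = n_sectors - 1
                exit_sector[m] = sec
            # transporter encounter (near the astroglial belt radius)
            if n_t > 0 and belt_lo2 < rad2 < belt_hi2:
                ci = int((x - tgrid_origin[0]) / tgrid_cell)
                cj = int((y - tgrid_origin[1]) / tgrid_cell)
                ck = int((z - tgrid_origin[2]) / tgrid_cell)
                best = -1
                best_d2 = rho_t2
                for di in range(-1, 2):
                    ii = ci + di
                    if ii < 0 or ii >= tgrid_dims[0]:
                        continue
                    for dj in range(-1, 2):
                        jj = cj + dj
                        if jj < 0 or jj >= tgrid_dims[1]:
                            continue
                        for dk in range(-1, 2):
                            kk = ck + dk
                            if kk < 0 or kk >= tgrid_dims[2]:
                                continue
                            cell = (
                                ii * tgrid_dims[1] + jj
                            ) * tgrid_dims[2] + kk
                            for q in range(
                                tgrid_start[cell], tgrid_start[cell + 1]
                            ):
                                t = tgrid_items[q]
                                if t_occupied[t] == 1:
                                    continue
                                dx = x - tpos[t, 0]
                                dy = y - tpos[t, 1]
                                dz = z - tpos[t, 2]
                                d2 = dx * dx + dy * dy + dz * dz
                                if d2 < best_d2:
                                    best_d2 = d2
                                    best = t
                if best >= 0 and np.random.random() < p_enc_t:
                    state[m] = _TBOUND
                    site[m] = best
                    t_occupied[best] = 1
                    if exit_sector[m] == tsec[best]:
                        same_sector += 1
                    else:
                        cross_sector += 1
                    continue
            # receptor encounter (postsynaptic band)
            if n_r > 0 and rz_lo <= z <= rz_hi and rd_lo2 <= rad2 <= rd_hi2:
                for k in range(n_r):
                    if r_glu[k] >= 2:
                        continue
                    dx = x - rpos[k, 0]
                    dy = y - rpos[k, 1]
                    dz = z - rpos[k, 2]
                    if dx * dx + dy * dy + dz * dz < rho_r2:
                        if np.random.random() < p_enc_r:
                            state[m] = _RBOUND
                            site[m] = k
                            r_glu[k] += 1
                            if exit_sector[m] == rsec[k]:
                                same_sector += 1
                            else:
                                cross_sector += 1
                        break
        # receptor gating
        for k in range(n_r):
            if r_open[k] == 1:
                if np.random.random() < p_close:
                    r_open[k] = 0
            elif r_glu[k] == 2:
                if np.random.random() < p_open:
                    r_open[k] = 1
        # output binning
        if (step + 1) % bin_every == 0:
            for m in range(n_mol):
                s = state[m]
                counts[bin_idx, s] += 1
                if s == _FREE:
                    d2 = (
                        pos[m, 0] * pos[m, 0]
                        + pos[m, 1] * pos[m, 1]
                        + pos[m, 2] * pos[m, 2]
                    )
                    if d2 > probe_r2:
                        beyond_probe[bin_idx] += 1
                if store_snap == 1:
                    snapshots[bin_idx, m, 0] = pos[m, 0]
                    snapshots[bin_idx, m, 1] = pos[m, 1]
                    snapshots[bin_idx, m, 2] = pos[m, 2]
            for k in range(n_r):
                if r_open[k] == 1:
                    open_counts[bin_idx, rsec[k]] += 1
            for sct in range(n_sectors):
                uptake_cum[bin_idx, sct] = uptake_counter[sct]
            bin_idx += 1
    return same_sector, cross_sector


def simulate_release(
    model: GeometryModel | None,
    transporters: SiteLayout | None,
    receptors: SiteLayout | None,
    schemes: dict[str, KineticScheme] | None,
    sim: SimConfig,
) -> list[SimResult]:
    """Run an ensemble of stochastic release simulations.

    model=None simulates free diffusion in unobstructed space (no membranes,
    no absorbing boundary within reach) — used for physics validation.
    Returns one SimResult per run; per-run RNG streams are derived
    deterministically from sim.rng_seed.
    """
    schemes = schemes or default_schemes()
    t_scheme = schemes["transporter"]
    r_scheme = schemes["nmdar"]
    gap = model.config.gap_width if model is not None else None
    dt = sim.resolved_time_step_ms(gap)
    d_nm = sim.diffusion_coefficient * _D_UM2_PER_MS_TO_NM2
    step_amp = math.sqrt(3.0 * 2.0 * d_nm * dt)  # uniform with variance 2*D*dt
    n_steps = max(1, int(round(sim.total_time / dt)))
    bin_every = max(1, int(round(sim.bin_width / dt)))
    n_bins = n_steps // bin_every
    if n_bins < 1:
        raise ConfigurationError("total_time shorter than one output bin")

    if model is not None:
        has_solids = 1
        r2 = model.sphere_radius**2
        zoff, hh = model.sphere_offset, model.half_height
        excl2 = model.clearance_radius**2
        period, half_cube = model.lattice_period, model.cube_side / 2.0
        domain_half = model.domain_half
        r_astro = model.astro_radius
        n_sectors = model.config.sector_count
        rz = model.nmdar_band_z()
        rd = model.config.nmdar_cluster_distance
        # partition planes are implemented for the four-quadrant layout only
        wall_r02 = (
            model.sector_wall_radius**2
            if (model.sector_wall_radius > 0 and n_sectors == 4)
            else -1.0
        )
        exit_r2 = wall_r02 if wall_r02 > 0 else r_astro**2
    else:
        has_solids = 0
        r2 = zoff = hh = excl2 = 0.0
        period, half_cube = 1e9, 0.0
        domain_half = 1e12
        r_astro = 1e11
        n_sectors = 1
        rz = (0.0, 0.0)
        rd = (0.0, 0.0)
        wall_r02 = -1.0
        exit_r2 = 1e22

    tpos = (
        transporters.positions.astype(np.float64)
        if transporters is not None
        else np.empty((0, 3))
    )
    tsec = (
        transporters.sectors.astype(np.int64)
        if transporters is not None
        else np.empty(0, dtype=np.int64)
    )
    rpos = (
        receptors.positions.astype(np.float64)
        if receptors is not None
        else np.empty((0, 3))
    )
    rsec = (
        receptors.sectors.astype(np.int64)
        if receptors is not None
        else np.empty(0, dtype=np.int64)
    )

    rho_t = t_scheme.reaction_radius
    grid_origin, grid_dims, grid_start, grid_items = _build_site_grid(
        tpos, 2.0 * rho_t
    )
    if model is not None:
        half_th = model.collar_thickness / 2.0
        belt_lo2 = max(r_astro - half_th - rho_t, 0.0) ** 2
        belt_hi2 = (r_astro + half_th + rho_t) ** 2
    else:
        belt_lo2, belt_hi2 = 1e22, 1e22
    k_unbind = t_scheme.rate("bound", "free")
    k_transport = t_scheme.rate("bound", "translocated")
    k_leave = k_unbind + k_transport
    p_tleave = 1.0 - math.exp(-k_leave * dt)
    frac_unbind = k_unbind / k_leave if k_leave > 0 else 0.0
    rho_r = r_scheme.reaction_radius
    p_koff = 1.0 - math.exp(-r_scheme.rate("C1", "C0") * dt)
    p_open = 1.0 - math.exp(-r_scheme.rate("C2", "O") * dt)
    p_close = 1.0 - math.exp(-r_scheme.rate("O", "C2") * dt)

    seeds = np.random.SeedSequence(sim.rng_seed).generate_state(sim.n_runs)
    seeds = (seeds % np.uint32(2**31)).astype(np.uint32)
    results: list[SimResult] = []
    time_axis = (np.arange(n_bins) + 1) * bin_every * dt
    for run in range(sim.n_runs):
        counts = np.zeros((n_bins, 5), dtype=np.int64)
        open_counts = np.zeros((n_bins, n_sectors), dtype=np.int64)
        uptake_cum = np.zeros((n_bins, n_sectors), dtype=np.int64)
        beyond_probe = np.zeros(n_bins, dtype=np.int64)
        snapshots = (
            np.zeros((n_bins, sim.n_molecules, 3))
            if sim.store_snapshots
            else np.zeros((1, 1, 3))
        )
        same, cross = _run_kernel(
            seeds[run],
            sim.n_molecules,
            n_steps,
            bin_every,
            step_amp,
            has_solids,
            r2,
            zoff,
            hh,
            excl2,
            period,
            half_cube,
            domain_half,
            1 if sim.boundary == "reflective" else 0,
            wall_r02,
            n_sectors,
            exit_r2,
            tpos,
            tsec,
            grid_origin.astype(np.float64),
            grid_dims.astype(np.int64),
            grid_start,
            grid_items,
            2.0 * rho_t,
            rho_t,
            belt_lo2,
            belt_hi2,
            t_scheme.encounter_probability,
            p_tleave,
            frac_unbind,
            rpos,
            rsec,
            rho_r,
            r_scheme.encounter_probability,
            p_koff,
            p_open,
            p_close,
            rz[0] - rho_r,
            rz[1] + rho_r,
            max(rd[0] - rho_r, 0.0) ** 2,
            (rd[1] + rho_r) ** 2,
            sim.probe_radius**2,
            1 if sim.store_snapshots else 0,
            counts,
            open_counts,
            uptake_cum,
            beyond_probe,
            snapshots,
        )
        results.append(
            SimResult(
                time=time_axis,
                free=counts[:, _FREE],
                transporter_bound=counts[:, _TBOUND],
                receptor_bound=counts[:, _RBOUND],
                taken_up=counts[:, _TAKEN],
                escaped=counts[:, _ESCAPED],
                open_counts=open_counts,
                uptake_cum=uptake_cum,
                beyond_probe=beyond_probe,
                cross_sector_events=(int(same), int(cross)),
                rng_seed=int(seeds[run]),
                n_molecules=sim.n_molecules,
                bin_width=bin_every * dt,
                snapshots=snapshots if sim.store_snapshots else None,
            )
        )
    return results
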