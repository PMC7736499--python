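"""Placement of glutamate transporters and extrasynaptic NMDAR clusters.

Transporters live on the astroglial belt — a spherical band of radius
``astro_radius`` around the synaptic centroid, one azimuthal patch per
sector.  NMDAR clusters sit on the postsynaptic membrane surface within the
stated radial band (200-250 nm by default) from the synaptic centroid, one
cluster at each sector's azimuth centre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .geometry import GeometryModel
from .scenarios import ScenarioSpec

__all__ = ["SiteLayout", "place_transporters", "place_nmdars"]


@dataclass
class SiteLayout:
    """Point sites on a membrane: positions (N, 3) nm plus sector ids."""

    positions: np.ndarray
    sectors: np.ndarray
    kind: str = "transporter"

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def concatenate(layouts: list["SiteLayout"]) -> "SiteLayout":
        if not layouts:
            return SiteLayout(np.empty((0, 3)), np.empty(0, dtype=np.int64))
        return SiteLayout(
            np.concatenate([l.positions for l in layouts]),
            np.concatenate([l.sectors for l in layouts]),
            layouts[0].kind,
        )


def _patch_azimuth(
    model: GeometryModel, sector: int, scenario: ScenarioSpec
) -> tuple[float, float]:
    """Azimuth range [lo, hi) of the occupied collar patch for one sector."""
    az_lo, az_hi = model.sector_azimuth_bounds(sector)
    wedge = az_hi - az_lo
    span = math.radians(model.belt_az_span_deg)
    if span > wedge:
        raise ConfigurationError("belt azimuth span exceeds sector wedge")
    center = (az_lo + az_hi) / 2.0
    if scenario.lateral_shift:
        # slide the patch to one flank of the NMDAR cluster (which sits at the
        # wedge centre azimuth), keeping it inside the sector wedge
        center = az_hi - span / 2.0 - 0.02
    return center - span / 2.0, center + span / 2.0


def place_transporters(
    model: GeometryModel,
    scenario: ScenarioSpec,
    surface_density: float,
    seed: int,
    sectors: list[int] | None = None,
) -> SiteLayout:
    """Distribute transporters on the astroglial belt patches.

    surface_density is per um^2 of membrane; the per-sector count is
    round(density * density_multiplier * base_area * area_multiplier), which
    conserves the baseline number for scenarios i and iii and halves it
    (within rounding) for scenario ii.
    """
    if surface_density < 0:
        raise ConfigurationError("surface_density must be >= 0")
    if scenario.lateral_shift and model.config.sector_count < 2:
        # a lateral shift needs a defined NMDAR-cluster flank within the wedge
        raise ConfigurationError(
            "scenario iii needs a sector wedge wider than the occupied patch"
        )
    rng = np.random.default_rng(seed)
    sectors = list(range(model.config.sector_count)) if sectors is None else sectors
    base_area = model.belt_area_per_sector()  # um^2, folded membrane
    r_in = model.astro_radius - model.collar_thickness / 2.0
    r_out = model.astro_radius + model.collar_thickness / 2.0
    out = []
    for sector in sectors:
        a_lo, a_hi = _patch_azimuth(model, sector, scenario)
        n = int(
            round(
                surface_density
                * scenario.density_multiplier
                * base_area
                * scenario.area_multiplier
            )
        )
        if n == 0:
            continue
        # sites spread through the collar shell (the PAP membrane mesh);
        # withdrawal (area_multiplier < 1) retains the presynaptic-side
        # (z > 0) part of the collar, opening the corridor toward the
        # postsynaptic extrasynaptic NMDAR cluster
        u = rng.uniform(r_in, r_out, n)
        z_lim = np.array([model.collar_z_limit(r) for r in u])
        v = rng.uniform(1.0 - scenario.area_multiplier, 1.0, n)
        z = z_lim * (2.0 * v - 1.0)
        phi = rng.uniform(a_lo, a_hi, n)
        rxy = np.sqrt(np.maximum(u * u - z * z, 0.0))
        pos = np.column_stack([rxy * np.cos(phi), rxy * np.sin(phi), z])
        out.append(SiteLayout(pos, np.full(n, sector, dtype=np.int64)))
    if not out:
        return SiteLayout(
            np.empty((0, 3)), np.empty(0, dtype=np.int64), "transporter"
        )
    return SiteLayout.concatenate(out)


def place_nmdars(
    model: GeometryModel,
    cluster_distance: tuple[float, float] | None = None,
    n_receptors: int = 24,
    seed: int = 0,
    sectors: list[int] | None = None,
    azimuth_spread_deg: float = 12.0,
) -> SiteLayout:
    """Place an extrasynaptic NMDAR cluster per sector on the postsynaptic side.

    Receptors sit on the postsynaptic truncated-sphere surface at radial
    distances within ``cluster_distance`` of the synaptic centroid, clustered
    around each sector's azimuth centre.
    """
    band = cluster_distance or model.config.nmdar_cluster_distance
    lo, hi = band
    max_dist = math.hypot(
        model.sphere_radius, model.sphere_offset
    )  # farthest surface point
    if lo < model.face_radius or hi > max_dist:
        raise ConfigurationError(
            f"NMDAR band {band} falls outside the postsynaptic surface"
        )
    rng = np.random.default_rng(seed)
    sectors = list(range(model.config.sector_count)) if sectors is None else sectors
    spread = math.radians(azimuth_spread_deg)
    # one cluster template, rotated into every sector: per-sector readouts then
    # differ only through the coverage scenario and the stochastic run, not
    # through cluster-placement luck
    d_template = rng.uniform(lo, hi, n_receptors)
    dphi_template = rng.uniform(-spread, spread, n_receptors)
    out = []
    for sector in sectors:
        if n_receptors == 0:
            continue
        az_lo, az_hi = model.sector_azimuth_bounds(sector)
        center = (az_lo + az_hi) / 2.0
        d = d_template
        phi = center + dphi_template
        # surface point at distance d from origin on the postsynaptic sphere:
        # z = (R^2 - z_off^2 - d^2) / (2 z_off)  (see GeometryModel.nmdar_band_z)
        z = (model.sphere_radius**2 - model.sphere_offset**2 - d * d) / (
            2.0 * model.sphere_offset
        )
        rxy = np.sqrt(np.maximum(d * d - z * z, 0.0))
        pos = np.column_stack([rxy * np.cos(phi), rxy * np.sin(phi), z])
        out.append(SiteLayout(pos, np.full(n_receptors, sector, dtype=np.int64),
                              "nmdar"))
    if not out:
        return SiteLayout(np.empty((0, 3)), np.empty(0, dtype=np.int64), "nmdar")
    return SiteLayout.concatenate(out)
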