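"""3D single-molecule localization sets and nearest-neighbour statistics.

Channels follow the standard perisynaptic labelling: ``bassoon``
(presynaptic active zone), ``homer1`` (postsynaptic density) and ``glt1``
(astroglial glutamate transporter).  Nearest-neighbour distances between
GLT1 and bassoon report how far released glutamate must travel to reach
astroglial transporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..errors import InputError

__all__ = [
    "CHANNELS",
    "LocalizationSet",
    "nearest_neighbor_distances",
    "nnd_density",
    "group_synapses",
]

CHANNELS = ("bassoon", "homer1", "glt1")


@dataclass
class LocalizationSet:
    """Labelled 3D molecular coordinates (nm)."""

    points: np.ndarray              # (N, 3)
    channels: np.ndarray            # (N,) str from CHANNELS
    synapse_ids: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.channels = np.asarray(self.channels)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InputError("points must be an (N, 3) array")
        if len(self.channels) != len(self.points):
            raise InputError("one channel label per point required")
        if not np.all(np.isfinite(self.points)):
            raise InputError("coordinates must be finite")
        bad = set(np.unique(self.channels)) - set(CHANNELS)
        if bad:
            raise InputError(f"unknown channel labels: {sorted(bad)}")

    def select(self, channel: str) -> np.ndarray:
        if channel not in CHANNELS:
            raise InputError(f"unknown channel {channel!r}")
        return self.points[self.channels == channel]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["x [nm]", "y [nm]", "z [nm]"])
        df["channel"] = self.channels
        if self.synapse_ids is not None:
            df["synapse"] = self.synapse_ids
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LocalizationSet":
        cols = {c.lower().split(" ")[0]: c for c in df.columns}
        try:
            pts = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
            channels = df[cols["channel"]].to_numpy()
        except KeyError as exc:
            raise InputError(f"missing localization column: {exc}") from exc
        syn = df[cols["synapse"]].to_numpy() if "synapse" in cols else None
        return cls(pts, channels, syn)

    @classmethod
    def read_csv(cls, path) -> "LocalizationSet":
        """ThunderSTORM-compatible dialect: x [nm], y [nm], z [nm], channel."""
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def nearest_neighbor_distances(
    source: LocalizationSet | np.ndarray,
    target: LocalizationSet | np.ndarray,
    source_channel: str = "glt1",
    target_channel: str = "bassoon",
) -> np.ndarray:
    """3D Euclidean distance from each source point to its nearest target.

    Accepts either LocalizationSets (with channel selection) or raw (N, 3)
    arrays.
    """
    src = (
        source.select(source_channel)
        if isinstance(source, LocalizationSet)
        else np.asarray(source, dtype=float)
    )
    tgt = (
        target.select(target_channel)
        if isinstance(target, LocalizationSet)
        else np.asarray(target, dtype=float)
    )
    if len(src) == 0 or len(tgt) == 0:
        raise InputError("both channels must be non-empty")
    tree = cKDTree(tgt)
    dist, _ = tree.query(src, k=1)
    return np.asarray(dist, dtype=float)


def nnd_density(
    distances: np.ndarray,
    bin_width: float = 50.0,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned probability density of nearest-neighbour distances with SEM.

    The density integrates to 1 (sum of density * bin_width).  If per-
    distance group labels (e.g. preparation ids) are given, the per-bin SEM
    is computed over group-wise densities, matching a mean +/- SEM display
    with N = number of groups; with a single group the SEM is reported as
    NaN.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        raise InputError("need at least one distance")
    if bin_width <= 0:
        raise InputError("bin width must be > 0")
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, _ = np.histogram(d, bins=edges)
    density = counts / (len(d) * bin_width)
    out = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "density": density,
        }
    )
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != len(d):
            raise InputError("one group label per distance required")
        uniq = np.unique(groups)
        if len(uniq) < 2:
            out["sem"] = np.nan
        else:
            per = np.stack(
                [
                    np.histogram(d[groups == g], bins=edges)[0]
                    / (max((groups == g).sum(), 1) * bin_width)
                    for g in uniq
                ]
            )
            out["sem"] = per.std(axis=0, ddof=1) / np.sqrt(len(uniq))
    return out


def group_synapses(
    locs: LocalizationSet,
    eps: float = 100.0,
    min_samples: int = 5,
) -> LocalizationSet:
    """Cluster bassoon/homer1 points into synapses; assign GLT1 by proximity.

    Density-based clustering (DBSCAN) on the synaptic-marker channels defines
    synapse ids (noise points get -1); each GLT1 point inherits the id of its
    nearest clustered synaptic point.  Returns a new set with synapse_ids.
    """
    from sklearn.cluster import DBSCAN

    synaptic = np.isin(locs.channels, ("bassoon", "homer1"))
    if synaptic.sum() == 0:
        raise InputError("no synaptic-marker points to cluster")
    labels = np.full(len(locs.points), -1, dtype=int)
    core = DBSCAN(eps=eps, min_samples=min_samples).fit(locs.points[synaptic])
    labels[synaptic] = core.labels_
    glt = locs.channels == "glt1"
    clustered = synaptic.copy()
    clustered[synaptic] &= core.labels_ >= 0
    if glt.any() and clustered.any():
        tree = cKDTree(locs.points[clustered])
        _, idx = tree.query(locs.points[glt], k=1)
        labels[glt] = labels[clustered][idx]
    return LocalizationSet(
        locs.points, locs.channels, synapse_ids=labels, meta=dict(locs.meta)
    )
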