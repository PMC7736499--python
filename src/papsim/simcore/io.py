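"""HDF5 trajectory/summary output for simulation ensembles."""

from __future__ import annotations

import h5py
import numpy as np

from .engine import SimResult

__all__ = ["write_ensemble_hdf5", "read_ensemble_hdf5"]

_COUNT_FIELDS = (
    "free",
    "transporter_bound",
    "receptor_bound",
    "taken_up",
    "escaped",
)


def write_ensemble_hdf5(path, results: list[SimResult], summary=None) -> None:
    """Layout: /runs/<k>/counts (+ open_counts, uptake_cum), /summary table."""
    with h5py.File(path, "w") as fh:
        runs = fh.create_group("runs")
        for k, r in enumerate(results):
            g = runs.create_group(str(k))
            counts = np.column_stack([getattr(r, f) for f in _COUNT_FIELDS])
            g.create_dataset("counts", data=counts)
            g.create_dataset("time_ms", data=r.time)
            g.create_dataset("open_counts", data=r.open_counts)
            g.create_dataset("uptake_cum", data=r.uptake_cum)
            g.create_dataset("beyond_probe", data=r.beyond_probe)
            g.attrs["rng_seed"] = r.rng_seed
            g.attrs["n_molecules"] = r.n_molecules
            g.attrs["bin_width_ms"] = r.bin_width
            g.attrs["count_fields"] = ",".join(_COUNT_FIELDS)
            g.attrs["cross_sector_events"] = list(r.cross_sector_events)
        if summary is not None:
            sg = fh.create_group("summary")
            rec = summary.table.to_records(index=False)
            for name in rec.dtype.names:
                col = rec[name]
                if col.dtype.kind in ("U", "O"):
                    col = col.astype("S")
                sg.create_dataset(name, data=col)


def read_ensemble_hdf5(path) -> list[SimResult]:
    out = []
    with h5py.File(path, "r") as fh:
        keys = sorted(fh["runs"], key=int)
        for k in keys:
            g = fh["runs"][k]
            counts = g["counts"][()]
            fields = dict(
                zip(g.attrs["count_fields"].split(","), counts.T)
            )
            out.append(
                SimResult(
                    time=g["time_ms"][()],
                    free=fields["free"].astype(np.int64),
                    transporter_bound=fields["transporter_bound"].astype(
                        np.int64
                    ),
                    receptor_bound=fields["receptor_bound"].astype(np.int64),
                    taken_up=fields["taken_up"].astype(np.int64),
                    escaped=fields["escaped"].astype(np.int64),
                    open_counts=g["open_counts"][()],
                    uptake_cum=g["uptake_cum"][()],
                    beyond_probe=g["beyond_probe"][()],
                    cross_sector_events=tuple(
                        int(v) for v in g.attrs["cross_sector_events"]
                    ),
                    rng_seed=int(g.attrs["rng_seed"]),
                    n_molecules=int(g.attrs["n_molecules"]),
                    bin_width=float(g.attrs["bin_width_ms"]),
                )
            )
    return out
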