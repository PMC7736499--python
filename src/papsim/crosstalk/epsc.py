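"""Two-pathway EPSC series for MK801 cross-talk experiments.

Trials are labelled by pathway (``active`` stimulated throughout, ``silent``
paused while MK801 acts) and by experimental phase: AMPAR baseline, NMDAR
baseline, MK801 application, silent pause, resumed stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import InputError

__all__ = ["PHASES", "PATHWAYS", "EPSCSeries"]

PHASES = ("ampar_baseline", "nmdar_baseline", "mk801", "silent_pause", "resumed")
PATHWAYS = ("active", "silent")


@dataclass
class EPSCSeries:
    """Per-trial evoked response amplitudes (pA, sign-normalised positive)."""

    frame: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"trial", "pathway", "phase", "amplitude_pA"}
        missing = required - set(self.frame.columns)
        if missing:
            raise InputError(f"EPSC series missing columns: {sorted(missing)}")
        # inward currents are rectified to magnitudes at load time
        self.frame = self.frame.copy()
        self.frame["amplitude_pA"] = self.frame["amplitude_pA"].abs()
        bad_phase = set(self.frame["phase"].unique()) - set(PHASES)
        if bad_phase:
            raise InputError(f"unknown phases: {sorted(bad_phase)}")
        bad_path = set(self.frame["pathway"].unique()) - set(PATHWAYS)
        if bad_path:
            raise InputError(f"unknown pathways: {sorted(bad_path)}")
        order = {p: k for k, p in enumerate(PHASES)}
        for pathway, sub in self.frame.groupby("pathway"):
            sub = sub.sort_values("trial")
            ranks = sub["phase"].map(order).to_numpy()
            if np.any(np.diff(ranks) < 0):
                raise InputError(
                    f"phases out of temporal order in pathway {pathway!r}"
                )

    def amplitudes(self, pathway: str, phase: str) -> np.ndarray:
        sel = (self.frame["pathway"] == pathway) & (self.frame["phase"] == phase)
        return self.frame.loc[sel].sort_values("trial")["amplitude_pA"].to_numpy()

    @classmethod
    def read_csv(cls, path) -> "EPSCSeries":
        return cls(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)
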