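"""Line-scan container and TIFF I/O.

A line scan is a time x position fluorescence matrix acquired by repeatedly
scanning one line (typically 300-1000 Hz), with a pixel pitch along the line
and a line period in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from ..errors import InputError

__all__ = ["LineScan", "read_linescan_tiff", "write_linescan_tiff"]


@dataclass
class LineScan:
    """Fluorescence matrix with shape (n_lines, n_pixels).

    line_period: ms between successive lines.
    pixel_pitch: um between adjacent pixels along the scanned line.
    shutter_closed: optional (start_line, end_line) interval during which the
    excitation shutter was closed (used in photobleaching protocols).
    """

    intensity: np.ndarray
    line_period: float
    pixel_pitch: float
    shutter_closed: tuple[int, int] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2 or self.intensity.size == 0:
            raise InputError("line scan must be a non-empty 2D matrix")
        if self.line_period <= 0 or self.pixel_pitch <= 0:
            raise InputError("line_period and pixel_pitch must be > 0")
        if np.any(self.intensity < 0):
            raise InputError("intensity values must be >= 0")

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.intensity.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Line acquisition times, ms, starting at 0."""
        return np.arange(self.n_lines) * self.line_period

    @property
    def positions(self) -> np.ndarray:
        """Pixel positions along the line, um, starting at 0."""
        return np.arange(self.n_pixels) * self.pixel_pitch


def read_linescan_tiff(path, line_period: float, pixel_pitch: float) -> LineScan:
    """Read a single-page TIFF as (time, position); multi-page stacks are
    concatenated along time."""
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data.reshape(-1, data.shape[-1])
    return LineScan(np.asarray(data, dtype=float), line_period, pixel_pitch)


def write_linescan_tiff(path, scan: LineScan) -> None:
    tifffile.imwrite(path, scan.intensity.astype(np.float32))
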