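"""The in-memory container for 4D time-lapse image data.

Axis order is fixed as ``(t, z, y, x)`` throughout the package; indices are
0-based and physical coordinates are ``index * pixel_size_um`` (voxels are
treated as isotropic, i.e. the z-step equals the in-plane pixel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """A single-channel grayscale image stack over time.

    Parameters
    ----------
    data : ndarray, shape (t, z, y, x)
        Intensity values.
    pixel_size_um : float
        Physical size of one pixel (and one z-step) in micrometres.
    frame_interval_s : float
        Time between consecutive frames in seconds.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    name: str = field(default="movie")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"movie data must be 4D (t, z, y, x); got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def frame(self, t: int) -> np.ndarray:
        """Return the (z, y, x) volume of frame ``t``."""
        if not 0 <= t < self.n_frames:
            raise IndexError(f"frame {t} out of range [0, {self.n_frames})")
        return self.data[t]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames, dtype=float) * self.frame_interval_s
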