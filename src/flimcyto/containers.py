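"""Core in-memory containers shared across the pipeline.

A TCSPC acquisition is a per-pixel histogram of photon arrival times
after pulsed excitation; fitting it yields per-pixel lifetime maps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionConfig", "TCSPCImage", "LifetimeMaps"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and timing of a TCSPC FLIM measurement.

    Defaults describe a 50 MHz pulsed excitation (20 ns period), 256
    time bins and a 256 x 256 pixel field of view of 188 x 188 um, with
    the fast (free NAD(P)H) lifetime fixed at 460 ps.
    """

    rep_rate: float = 5.0e7           # laser repetition rate, Hz
    n_time_bins: int = 256            # histogram bins per period
    image_size_px: int = 256          # square image side, pixels
    pixel_size_um: float = 188 / 256  # micrometers per pixel
    t1_ps: float = 460.0              # fixed fast lifetime, ps
    background_rate: float = 0.02     # mean background counts / bin / pixel

    def __post_init__(self) -> None:
        if self.rep_rate <= 0:
            raise ValueError("rep_rate must be positive")
        if self.n_time_bins < 16:
            raise ValueError("n_time_bins must be >= 16")
        if self.image_size_px < 32:
            raise ValueError("image_size_px must be >= 32")
        if self.t1_ps <= 0:
            raise ValueError("t1_ps must be positive")
        if self.period_ps <= self.t1_ps:
            raise ValueError("laser period must exceed t1_ps")

    @property
    def period_ps(self) -> float:
        """Laser period in picoseconds (20,000 ps at 50 MHz)."""
        return 1e12 / self.rep_rate

    @property
    def bin_width_ps(self) -> float:
        return self.period_ps / self.n_time_bins

    @property
    def bin_centers_ps(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width_ps


@dataclass
class TCSPCImage:
    """Raw TCSPC stack: integer photon counts indexed (y, x, time-bin)."""

    counts: np.ndarray
    bin_width_ps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be a 3-D (y, x, t) array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.bin_width_ps <= 0:
            raise ValueError("bin_width_ps must be positive")

    @property
    def n_time_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def period_ps(self) -> float:
        return self.bin_width_ps * self.n_time_bins

    @property
    def bin_centers_ps(self) -> np.ndarray:
        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width_ps

    def intensity(self) -> np.ndarray:
        """Per-pixel photon sum (the conventional intensity image)."""
        return self.counts.sum(axis=2)


@dataclass
class LifetimeMaps:
    """Per-pixel biexponential decay parameters.

    The amplitude-weighted mean lifetime obeys
    ``tm = (1 - a2) * t1 + a2 * t2``; the free fraction a1 is never
    stored because a1 = 1 - a2 by definition.
    """

    tm_ps: np.ndarray
    a2_frac: np.ndarray
    t2_ps: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    t1_ps: float = 460.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.tm_ps, self.a2_frac, self.t2_ps,
                                    self.intensity, self.valid)}
        if len(shapes) != 1:
            raise ValueError("all map layers must share one shape")
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tm_ps.shape

    def check_tm_consistency(self, atol_ps: float = 1e-3) -> bool:
        """True when tm recombines from (a2, t2, t1) on every valid pixel."""
        v = self.valid
        if not v.any():
            return True
        recon = (1.0 - self.a2_frac[v]) * self.t1_ps + self.a2_frac[v] * self.t2_ps[v]
        return bool(np.allclose(recon, self.tm_ps[v], atol=atol_ps, rtol=0))
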