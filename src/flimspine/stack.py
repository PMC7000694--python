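"""In-memory FLIM stack container: per-pixel TCSPC histograms over time.

A :class:`FLIMStack` holds an ordered sequence of frames, each a
(rows, cols, bins) photon-count array with a timestamp in seconds relative
to the uncaging onset (t = 0 at the first uncaging pulse) and a z index.
The on-disk HDF5 layout lives in :mod:`flimspine.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CalibrationConstants, TCSPCHistogram

__all__ = ["FLIMFrame", "FLIMStack"]


@dataclass
class FLIMFrame:
    counts: np.ndarray  # (rows, cols, bins) non-negative integers
    time_s: float
    z_index: int = 0


@dataclass
class FLIMStack:
    frames: list[FLIMFrame]
    bin_edges: np.ndarray
    pixel_size_um: float
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames[0].counts.shape[:2]

    @property
    def times_s(self) -> np.ndarray:
        return np.array([f.time_s for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("FLIMStack needs at least one frame")
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("bin_edges must define at least one bin")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shape = self.frames[0].counts.shape
        for i, f in enumerate(self.frames):
            if f.counts.ndim != 3 or f.counts.shape != shape:
                raise ValueError(f"frame {i} shape {f.counts.shape} != {shape}")
            if f.counts.shape[2] != self.n_bins:
                raise ValueError(f"frame {i} has {f.counts.shape[2]} bins, expected {self.n_bins}")
        by_z: dict[int, list[float]] = {}
        for f in self.frames:
            by_z.setdefault(f.z_index, []).append(f.time_s)
        for z, ts in by_z.items():
            if np.any(np.diff(ts) <= 0):
                raise ValueError(f"timestamps not strictly increasing for z={z}")

    # -- access ------------------------------------------------------------
    def summed_histogram(self, frame_index: int) -> TCSPCHistogram:
        """Whole-image histogram of one frame (all pixels pooled)."""
        counts = self.frames[frame_index].counts.sum(axis=(0, 1))
        return TCSPCHistogram(self.bin_edges, counts)
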