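"""From calibrated frames to reported quantities.

Spine volume change F/F0 from background-subtracted integrated intensity,
per-ROI binding-fraction time courses (absolute and change-from-baseline),
window averages over the standard analysis windows, and the dendritic
spreading profile measured in contiguous 1 um ROIs along the shaft from
the base of the stimulated spine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .model import FitResult, fit_population, roi_binding_fraction
from .simulate import IntensityMovie, ScenePhantom
from .stack import FLIMStack

__all__ = [
    "RoiSet",
    "TimeCourse",
    "WindowSpec",
    "SpreadProfile",
    "BASAL_WINDOW",
    "VOLUME_TRANSIENT_WINDOW",
    "PAD_TRANSIENT_WINDOW",
    "SUSTAINED_WINDOW",
    "DEFAULT_WINDOWS",
    "measure_spine_fluorescence",
    "volume_change_timecourse",
    "fit_frame_offsets",
    "roi_mean_lifetime_series",
    "activation_timecourse",
    "window_average",
    "dendrite_spread_profile",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WindowSpec:
    """A closed analysis window [start, end] in minutes relative to uncaging."""

    name: str
    start_min: float
    end_min: float

    def __post_init__(self) -> None:
        if not self.start_min < self.end_min:
            raise ValueError(f"window '{self.name}' needs start < end")

    def contains(self, times_s) -> np.ndarray:
        m = np.asarray(times_s, dtype=float) / 60.0
        return (m >= self.start_min) & (m <= self.end_min)


BASAL_WINDOW = WindowSpec("basal", -8.0, 0.0)
VOLUME_TRANSIENT_WINDOW = WindowSpec("transient", 1.0, 3.0)
PAD_TRANSIENT_WINDOW = WindowSpec("transient", 1.5, 3.5)
SUSTAINED_WINDOW = WindowSpec("sustained", 10.0, 25.0)
DEFAULT_WINDOWS = {
    "basal": BASAL_WINDOW,
    "volume_transient": VOLUME_TRANSIENT_WINDOW,
    "pad_transient": PAD_TRANSIENT_WINDOW,
    "sustained": SUSTAINED_WINDOW,
}


@dataclass
class TimeCourse:
    """A per-frame measurement series aligned with acquisition timestamps.

    For ``kind="volume"`` the values are F/F0; for
    ``kind="binding_fraction"`` the values are dP_AD (change from the basal
    mean), with the absolute per-frame P_AD kept in ``absolute`` and the
    basal mean in ``baseline_value``.
    """

    times_s: np.ndarray
    values: np.ndarray
    kind: str
    baseline_value: float | None = None
    absolute: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def times_min(self) -> np.ndarray:
        return self.times_s / 60.0


@dataclass
class RoiSet:
    """Manual ROI definitions: labelled spine masks, a background region,
    and the arc-length-parameterized dendrite path."""

    spine_masks: dict[int, np.ndarray]
    background_mask: np.ndarray
    dendrite_path: np.ndarray
    stimulated_spine: int
    spine_base_arclength_um: dict[int, float]
    pixel_size_um: float
    dendrite_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for label, m in self.spine_masks.items():
            if np.asarray(m).shape != np.asarray(self.background_mask).shape:
                raise ValueError(f"spine mask {label} shape mismatch")
            if np.any(np.asarray(m) & np.asarray(self.background_mask)):
                raise ValueError(f"spine mask {label} overlaps the background mask")
        if self.stimulated_spine not in self.spine_masks:
            raise ValueError("stimulated_spine label missing from spine_masks")

    @classmethod
    def from_phantom(cls, phantom: ScenePhantom, background_margin_um: float = 0.5) -> "RoiSet":
        """Ground-truth ROIs from a simulated scene.  The background mask is
        everything farther than ``background_margin_um`` from any structure."""
        from scipy.ndimage import binary_dilation

        any_struct = np.zeros(phantom.shape, dtype=bool)
        for s in phantom.structures:
            any_struct |= s.mask
        it = max(int(np.ceil(background_margin_um / phantom.pixel_size_um)), 1)
        background = ~binary_dilation(any_struct, iterations=it)
        return cls(
            spine_masks={s.label: s.mask for s in phantom.spines},
            background_mask=background,
            dendrite_path=phantom.dendrite_path,
            stimulated_spine=phantom.stimulated_label,
            spine_base_arclength_um={s.label: s.arclength_um for s in phantom.spines},
            pixel_size_um=phantom.pixel_size_um,
            dendrite_mask=phantom.dendrite.mask,
        )


@dataclass
class SpreadProfile:
    """dP_AD versus distance along the dendrite, per analysis window."""

    distances_um: np.ndarray
    window_names: list[str]
    values: np.ndarray  # (windows, distances)
    timecourses: list[TimeCourse] = field(default_factory=list)
    roi_masks: list[np.ndarray] = field(default_factory=list)

    def by_window(self, name: str) -> np.ndarray:
        return self.values[self.window_names.index(name)]


# ---------------------------------------------------------------------------
# Intensity / volume
# ---------------------------------------------------------------------------


def measure_spine_fluorescence(image, spine_mask, background_mask) -> float:
    """Background-subtracted integrated spine intensity F.

    ``image`` is a single plane (rows, cols) or a z-stack (z, rows, cols);
    the per-pixel background level is the mean over ``background_mask``,
    estimated per plane.  F can come out non-positive for pathological
    input; callers treat that as a flag, not an exception here.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[None]
    spine = np.asarray(spine_mask, dtype=bool)
    bg = np.asarray(background_mask, dtype=bool)
    if not spine.any():
        raise ValueError("spine mask is empty")
    if not bg.any():
        raise ValueError("background mask is empty")
    n_spine = int(spine.sum())
    total = 0.0
    for plane in img:
        total += float(plane[spine].sum()) - n_spine * float(plane[bg].mean())
    return total


def volume_change_timecourse(
    movie: IntensityMovie,
    spine_mask,
    background_mask,
    baseline_window: WindowSpec = BASAL_WINDOW,
) -> TimeCourse:
    """Spine volume change F/F0, with F0 the mean F over baseline frames."""
    f = np.array(
        [measure_spine_fluorescence(movie.data[i], spine_mask, background_mask) for i in range(len(movie.times_s))]
    )
    base = baseline_window.contains(movie.times_s) & (movie.times_s < 0)
    if base.sum() < 2:
        raise ValueError("need at least two baseline frames for F0")
    f0 = float(f[base].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline intensity F0={f0:.3g}")
    return TimeCourse(movie.times_s, f / f0, kind="volume", baseline_value=f0)


# ---------------------------------------------------------------------------
# Binding-fraction time courses
# ---------------------------------------------------------------------------


def fit_frame_offsets(stack: FLIMStack, **fit_kwargs) -> list[FitResult]:
    """Whole-image population fit per frame (yields the per-frame t0)."""
    return [fit_population(stack.summed_histogram(i), stack.calibration, **fit_kwargs) for i in range(len(stack))]


def _as_t0_array(stack: FLIMStack, t0, which: str) -> np.ndarray:
    if t0 is None:
        fits = fit_frame_offsets(stack)
        if which == "model":
            return np.array([f.params.t0 for f in fits])
        return np.array([f.t0_effective for f in fits])
    t0 = np.asarray(t0, dtype=float)
    if t0.ndim == 0:
        return np.full(len(stack), float(t0))
    if t0.size != len(stack):
        raise ValueError("t0 must be scalar or one value per frame")
    return t0


def roi_mean_lifetime_series(stack: FLIMStack, roi_mask, t0_effective=None, min_photons: int = 100) -> np.ndarray:
    """Per-frame ROI mean lifetime <tau> = <t> - t0 (ns); NaN where sparse.

    Used for baseline-stability QC; ``t0_effective`` defaults to the
    per-frame whole-image fit's effective offset.
    """
    t0s = _as_t0_array(stack, t0_effective, "effective")
    centers = 0.5 * (stack.bin_edges[:-1] + stack.bin_edges[1:])
    mask = np.asarray(roi_mask, dtype=bool)
    out = np.full(len(stack), np.nan)
    for i, frame in enumerate(stack.frames):
        pooled = frame.counts[mask].sum(axis=0).astype(float)
        tot = pooled.sum()
        if tot >= min_photons:
            out[i] = float(pooled @ centers / tot) - t0s[i]
    return out


def activation_timecourse(
    stack: FLIMStack,
    roi_mask,
    baseline_window: WindowSpec = BASAL_WINDOW,
    *,
    t0=None,
    min_photons: int = 100,
    truncation_correction: bool = True,
) -> TimeCourse:
    """dP_AD(t) of one ROI: per-frame pooled binding fraction minus the
    basal-window mean.

    ``t0`` is the per-frame model offset from the whole-image fits (fitted
    on demand when omitted).  Frames below ``min_photons`` propagate as NaN
    gaps rather than being dropped.  The basal mean (absolute P_AD) is kept
    on the result, since baseline levels are compared across groups.
    """
    t0s = _as_t0_array(stack, t0, "model")
    pad = np.full(len(stack), np.nan)
    for i, frame in enumerate(stack.frames):
        bf = roi_binding_fraction(
            frame.counts,
            roi_mask,
            stack.bin_edges,
            t0s[i],
            stack.calibration,
            min_photons=min_photons,
            truncation_correction=truncation_correction,
        )
        pad[i] = bf.clamped
    times = stack.times_s
    base = baseline_window.contains(times) & (times < 0)
    if not base.any():
        raise ValueError("no baseline frames inside the basal window")
    basal_vals = pad[base]
    if np.all(np.isnan(basal_vals)):
        raise ValueError("all baseline frames are undefined")
    basal = float(np.nanmean(basal_vals))
    return TimeCourse(times, pad - basal, kind="binding_fraction", baseline_value=basal, absolute=pad)


def window_average(tc: TimeCourse, window: WindowSpec) -> float:
    """Mean of the frames inside the closed window [start, end] minutes."""
    sel = window.contains(tc.times_s)
    if not sel.any():
        raise ValueError(f"no frames inside window '{window.name}' [{window.start_min}, {window.end_min}] min")
    vals = tc.values[sel]
    if np.all(np.isnan(vals)):
        raise ValueError(f"all frames in window '{window.name}' are undefined")
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# Dendritic spreading
# ---------------------------------------------------------------------------


def dendrite_spread_profile(
    stack: FLIMStack,
    roiset: RoiSet,
    windows=(PAD_TRANSIENT_WINDOW, SUSTAINED_WINDOW),
    distances_um=(0.0, 1.0, 2.0, 3.0, 4.0),
    *,
    roi_diameter_um: float = 1.0,
    direction: str = "auto",
    t0=None,
    exclude_spines: bool = True,
    clip_to_dendrite: bool = False,
    min_photons: int = 100,
) -> SpreadProfile:
    """dP_AD in contiguous 1 um ROIs along the dendrite from the spine base.

    ROIs are disks of ``roi_diameter_um`` centred on the path at arc-length
    offsets ``distances_um`` from the stimulated spine's attachment point,
    walking toward the longer remaining stretch of path (``direction`` may
    force "forward"/"backward").  Pixels belonging to any spine mask are
    excluded; ``clip_to_dendrite`` additionally intersects with the
    dendrite mask when one is available.
    """
    path = roiset.dendrite_path
    s_base = roiset.spine_base_arclength_um[roiset.stimulated_spine]
    total = geometry.path_length(path)
    reach = max(distances_um) + roi_diameter_um / 2.0
    if direction == "auto":
        sign = 1.0 if (total - s_base) >= s_base else -1.0
    elif direction == "forward":
        sign = 1.0
    elif direction == "backward":
        sign = -1.0
    else:
        raise ValueError(f"unknown direction '{direction}'")
    avail = (total - s_base) if sign > 0 else s_base
    if avail + 1e-9 < reach:
        raise ValueError(
            f"dendrite path too short: need {reach:.2f} um beyond the spine base, have {avail:.2f} um"
        )

    shape = next(iter(roiset.spine_masks.values())).shape
    spine_any = np.zeros(shape, dtype=bool)
    for m in roiset.spine_masks.values():
        spine_any |= np.asarray(m, dtype=bool)

    t0s = _as_t0_array(stack, t0, "model")
    masks, tcs = [], []
    for d in distances_um:
        center = geometry.point_at_arclength(path, s_base + sign * d)
        mask = geometry.disk_mask(shape, roiset.pixel_size_um, center, roi_diameter_um / 2.0)
        if exclude_spines:
            mask &= ~spine_any
        if clip_to_dendrite and roiset.dendrite_mask is not None:
            mask &= np.asarray(roiset.dendrite_mask, dtype=bool)
        masks.append(mask)
        tcs.append(activation_timecourse(stack, mask, t0=t0s, min_photons=min_photons))

    values = np.array([[window_average(tc, w) for tc in tcs] for w in windows])
    return SpreadProfile(
        distances_um=np.asarray(distances_um, dtype=float),
        window_names=[w.name for w in windows],
        values=values,
        timecourses=tcs,
        roi_masks=masks,
    )
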