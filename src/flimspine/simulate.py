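"""Photon-level simulator of single-spine structural-plasticity FLIM runs.

The generator builds a dendrite-plus-spines phantom, drives it with a
transient-plus-sustained activation program triggered at the glutamate
uncaging onset (a 30-pulse, 0.5 Hz train collapsed to a single onset time,
since pulse-resolved dynamics are far below the frame rate), and emits

* a :class:`~flimspine.stack.FLIMStack` of per-pixel TCSPC histograms, with
  photon arrival times drawn from the two-lifetime mixture through a
  Gaussian IRF, and
* intensity z-stacks (the green channel) for spine-volume measurements.

Photons choose the FRET-bound component with probability
``P_AD tau_AD / (P_D tau_D + P_AD tau_AD)``: photon yield is proportional
to lifetime, which makes the photon-weighted mean lifetime of the sample
equal the intensity-weighted mixture mean that the closed-form binding
fraction inverts.  Every random draw descends from a single root seed via
per-frame child streams, so identical (config, seed) pairs give
bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import geometry
from .model import CalibrationConstants, TCSPCHistogram, default_bin_edges
from .stack import FLIMFrame, FLIMStack

__all__ = [
    "SpineSpec",
    "GeometryConfig",
    "Structure",
    "ScenePhantom",
    "PlasticityProgram",
    "AcquisitionConfig",
    "Scenario",
    "IntensityMovie",
    "build_phantom",
    "activation_time_course",
    "bound_photon_probability",
    "sample_decay_histogram",
    "simulate_flim_stack",
    "simulate_intensity_stack",
    "make_fixture",
]


# ---------------------------------------------------------------------------
# Scene geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpineSpec:
    """A spine attached to the dendrite at arc length ``arclength_um``;
    ``side`` (+1/-1) selects which side of the shaft it protrudes from."""

    arclength_um: float
    radius_um: float = 0.35
    side: int = 1


@dataclass
class GeometryConfig:
    """Phantom layout.  Defaults give a 12.8 um field at 0.1 um/px with a
    straight dendritic shaft and three spines, the first one stimulated."""

    shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = 0.1
    dendrite_radius_um: float = 0.25
    dendrite_path_um: list | None = None  # default: horizontal midline
    spines: list[SpineSpec] = field(
        default_factory=lambda: [
            SpineSpec(4.6, 0.35, 1),
            SpineSpec(2.2, 0.30, -1),
            SpineSpec(1.0, 0.30, 1),
        ]
    )
    stimulated_index: int = 0
    neck_length_um: float = 0.3  # gap between shaft edge and spine head
    spine_brightness: float = 1800.0  # expected photons / pixel / frame
    dendrite_brightness: float = 1400.0
    background_rate: float = 2.0
    psf_sigma_um: float = 0.2  # lateral blur of rendered structures
    radius_jitter: float = 0.05  # fractional spine-radius jitter (seeded)


@dataclass
class Structure:
    label: int
    name: str
    kind: str  # "dendrite" | "spine"
    mask: np.ndarray
    brightness_map: np.ndarray
    arclength_um: float | None = None  # spine attachment point on the path
    center_um: tuple[float, float] | None = None
    radius_um: float | None = None


@dataclass
class ScenePhantom:
    """Ground-truth scene: labelled structures with brightness maps."""

    shape: tuple[int, int]
    pixel_size_um: float
    dendrite_path: np.ndarray
    structures: list[Structure]
    background_rate: float
    stimulated_label: int

    @property
    def dendrite(self) -> Structure:
        return next(s for s in self.structures if s.kind == "dendrite")

    @property
    def spines(self) -> list[Structure]:
        return [s for s in self.structures if s.kind == "spine"]

    @property
    def stimulated_spine(self) -> Structure:
        return next(s for s in self.structures if s.label == self.stimulated_label)

    @property
    def label_image(self) -> np.ndarray:
        img = np.zeros(self.shape, dtype=np.int32)
        for s in self.structures:
            img[s.mask] = s.label
        return img

    @property
    def masks(self) -> dict[str, np.ndarray]:
        out = {s.name: s.mask for s in self.structures}
        out["background"] = self.label_image == 0
        return out


def build_phantom(config: GeometryConfig, seed: int = 0) -> ScenePhantom:
    """Render the phantom deterministically from (config, seed).

    Spines are disks attached perpendicular to the shaft at their arc-length
    positions; masks are disjoint (spines take precedence over the shaft).
    Brightness maps are the hard masks blurred by a 2-D Gaussian of
    ``psf_sigma_um`` — a lateral point-spread stand-in adequate for
    integrated-intensity volume measures.  Spines whose centres come closer
    than the sum of their radii are rejected.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E3779B9]))
    shape, px = tuple(config.shape), config.pixel_size_um
    if px <= 0:
        raise ValueError("pixel_size_um must be positive")
    if not config.spines:
        raise ValueError("phantom needs at least one spine")
    if config.dendrite_path_um is None:
        y_mid = (shape[0] - 1) * px / 2.0
        path = np.array([[0.0, y_mid], [(shape[1] - 1) * px, y_mid]])
    else:
        path = np.asarray(config.dendrite_path_um, dtype=float)

    dend_mask = geometry.tube_mask(shape, px, path, config.dendrite_radius_um)
    sigma_px = config.psf_sigma_um / px

    centers, radii = [], []
    for sp in config.spines:
        r = sp.radius_um * (1.0 + config.radius_jitter * (2.0 * rng.random() - 1.0))
        base = geometry.point_at_arclength(path, sp.arclength_um)
        ahead = geometry.point_at_arclength(path, sp.arclength_um + 1e-3)
        tang = ahead - base
        nrm = np.linalg.norm(tang)
        tang = tang / nrm if nrm > 0 else np.array([1.0, 0.0])
        normal = np.array([-tang[1], tang[0]]) * np.sign(sp.side)
        center = base + (config.dendrite_radius_um + config.neck_length_um + r) * normal
        if not (0 <= center[0] <= (shape[1] - 1) * px and 0 <= center[1] <= (shape[0] - 1) * px):
            raise ValueError(f"spine at s={sp.arclength_um} um falls outside the image")
        centers.append(center)
        radii.append(r)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                raise ValueError(f"spines {i} and {j} overlap")

    structures: list[Structure] = []
    spine_any = np.zeros(shape, dtype=bool)
    for i, (sp, center, r) in enumerate(zip(config.spines, centers, radii)):
        mask = geometry.disk_mask(shape, px, center, r)
        bright = gaussian_filter(mask.astype(float), sigma_px) * config.spine_brightness
        structures.append(
            Structure(
                label=2 + i,
                name=f"spine_{i}",
                kind="spine",
                mask=mask,
                brightness_map=bright,
                arclength_um=sp.arclength_um,
                center_um=(float(center[0]), float(center[1])),
                radius_um=float(r),
            )
        )
        spine_any |= mask
    dend_mask &= ~spine_any
    dend_bright = gaussian_filter(dend_mask.astype(float), sigma_px) * config.dendrite_brightness
    structures.insert(
        0,
        Structure(label=1, name="dendrite", kind="dendrite", mask=dend_mask, brightness_map=dend_bright),
    )
    return ScenePhantom(
        shape=shape,
        pixel_size_um=px,
        dendrite_path=path,
        structures=structures,
        background_rate=config.background_rate,
        stimulated_label=2 + config.stimulated_index,
    )


# ---------------------------------------------------------------------------
# Activation program
# ---------------------------------------------------------------------------


@dataclass
class PlasticityProgram:
    """Transient-plus-sustained activation program triggered at uncaging.

    After the onset the spine volume relaxes exponentially from a peak of
    (1 + transient amplitude) to a plateau of (1 + sustained amplitude);
    the binding fraction follows the same single-exponential relaxation on
    top of its baseline.  Dendritic activation decays exponentially with
    distance from the stimulated spine's base (length constant
    ``spread_length_um``) and starts after ``spread_onset_delay_s``.
    """

    uncaging_time_s: float = 0.0
    volume_transient_amplitude: float = 1.5
    volume_sustained_amplitude: float = 0.4
    volume_transient_decay_tau_s: float = 150.0
    pad_baseline: float = 0.12
    pad_transient_amplitude: float = 0.08
    pad_sustained_amplitude: float = 0.04
    pad_transient_decay_tau_s: float = 120.0
    spread_length_um: float = 2.0
    spread_onset_delay_s: float = 120.0

    def __post_init__(self) -> None:
        for name in (
            "volume_transient_amplitude",
            "volume_sustained_amplitude",
            "pad_transient_amplitude",
            "pad_sustained_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.pad_baseline <= 1.0):
            raise ValueError("pad_baseline must lie in [0, 1]")
        peak = self.pad_baseline + max(self.pad_transient_amplitude, self.pad_sustained_amplitude)
        if peak > 1.0:
            raise ValueError(f"programmed P_AD exceeds 1 (peak {peak:.3f})")
        if self.volume_transient_decay_tau_s <= 0 or self.pad_transient_decay_tau_s <= 0:
            raise ValueError("decay time constants must be positive")
        if self.spread_length_um <= 0:
            raise ValueError("spread_length_um must be positive")


def _relax(t, onset, peak, plateau, tau):
    """plateau + (peak - plateau) exp(-(t-onset)/tau) for t >= onset, else 0."""
    t = np.asarray(t, dtype=float)
    dt = t - onset
    active = dt >= 0
    out = np.zeros_like(t)
    out[active] = plateau + (peak - plateau) * np.exp(-dt[active] / tau)
    return out


def activation_time_course(
    program: PlasticityProgram,
    times_s,
    *,
    kind: str = "stimulated",
    distance_um: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (volume_scale(t), P_AD(t)) for one structure.

    ``kind`` is "stimulated" for the uncaged spine (full amplitudes, onset
    at the uncaging time, volume change applies) or "dendrite"/"spine" for
    bystander structures (volume constant, binding-fraction amplitudes
    scaled by exp(-distance/spread_length) and onset delayed by
    ``spread_onset_delay_s``).
    """
    times_s = np.asarray(times_s, dtype=float)
    t_u = program.uncaging_time_s
    if kind == "stimulated":
        vol = 1.0 + _relax(
            times_s,
            t_u,
            program.volume_transient_amplitude,
            program.volume_sustained_amplitude,
            program.volume_transient_decay_tau_s,
        )
        pad = program.pad_baseline + _relax(
            times_s,
            t_u,
            program.pad_transient_amplitude,
            program.pad_sustained_amplitude,
            program.pad_transient_decay_tau_s,
        )
    elif kind in ("dendrite", "spine"):
        scale = float(np.exp(-abs(distance_um) / program.spread_length_um))
        vol = np.ones_like(times_s)
        pad = program.pad_baseline + _relax(
            times_s,
            t_u + program.spread_onset_delay_s,
            scale * program.pad_transient_amplitude,
            scale * program.pad_sustained_amplitude,
            program.pad_transient_decay_tau_s,
        )
    else:
        raise ValueError(f"unknown structure kind '{kind}'")
    return vol, pad


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------


def default_frame_times(
    start_s: float = -480.0,
    stop_s: float = 1500.0,
    step_s: float = 30.0,
    skip: tuple[float, float] | None = (0.0, 59.0),
) -> np.ndarray:
    """Frame timestamps relative to uncaging onset: an 8 min baseline and
    25 min of follow-up at one frame per 30 s.  Frames inside ``skip``
    (by default the 30-pulse, 0.5 Hz uncaging train, 0-58 s) are omitted,
    as acquisition pauses while the stimulus runs."""
    t = np.arange(start_s, stop_s + step_s / 2, step_s)
    if skip is not None:
        t = t[(t < skip[0]) | (t > skip[1])]
    return t


@dataclass
class AcquisitionConfig:
    """Imaging geometry and TCSPC settings."""

    frame_shape: tuple[int, int] = (128, 128)
    z_slices: int = 3
    z_spacing_um: float = 1.0
    frames_averaged: int = 6
    frame_times_s: np.ndarray = field(default_factory=default_frame_times)
    n_bins: int = 64
    tcspc_window_ns: float = 12.5
    tau_G: float = 0.2
    true_t0: float = 1.2
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)

    def __post_init__(self) -> None:
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.ndim != 1 or self.frame_times_s.size < 2:
            raise ValueError("frame_times_s must hold at least two frames")
        if np.any(np.diff(self.frame_times_s) <= 0):
            raise ValueError("frame_times_s must be strictly increasing")
        if not np.any(self.frame_times_s < 0):
            raise ValueError("frame_times_s must include baseline frames (t < 0)")
        if self.tau_G <= 0:
            raise ValueError("tau_G must be positive")

    @property
    def bin_edges(self) -> np.ndarray:
        return default_bin_edges(self.n_bins, self.tcspc_window_ns)

    @property
    def axial_weights(self) -> np.ndarray:
        """How a structure's light distributes across z-slices (unit sum)."""
        off = np.arange(self.z_slices) - (self.z_slices - 1) / 2.0
        w = np.exp(-0.5 * off * off)
        return w / w.sum()


@dataclass
class Scenario:
    name: str
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    program: PlasticityProgram = field(default_factory=PlasticityProgram)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)


# ---------------------------------------------------------------------------
# Photon sampling
# ---------------------------------------------------------------------------


def bound_photon_probability(p_ad, calibration: CalibrationConstants):
    """Probability that an emitted photon comes from the bound component.

    Photon yield is proportional to lifetime, so a molecular bound fraction
    ``p_ad`` emits bound photons with probability
    p_ad tau_AD / ((1-p_ad) tau_D + p_ad tau_AD).
    """
    p_ad = np.asarray(p_ad, dtype=float)
    td, ta = calibration.tau_D, calibration.tau_AD
    out = p_ad * ta / ((1.0 - p_ad) * td + p_ad * ta)
    return float(out) if out.ndim == 0 else out


def _sample_arrivals(n, p_ad, calibration, t0, tau_G, rng):
    q = bound_photon_probability(p_ad, calibration)
    bound = rng.random(n) < q
    taus = np.where(bound, calibration.tau_AD, calibration.tau_D)
    return t0 + rng.exponential(1.0, n) * taus + rng.normal(0.0, tau_G, n)


def sample_decay_histogram(
    n_photons: int,
    p_ad: float,
    bin_edges: np.ndarray,
    *,
    t0: float = 1.2,
    tau_G: float = 0.2,
    calibration: CalibrationConstants | None = None,
    rng: np.random.Generator | None = None,
) -> TCSPCHistogram:
    """Draw one pooled TCSPC histogram from the mixture model.

    Photons falling outside the binning window are dropped, exactly as a
    TCSPC board records nothing outside its measurement window.
    """
    calibration = calibration or CalibrationConstants()
    rng = rng or np.random.default_rng()
    edges = np.asarray(bin_edges, dtype=float)
    t = _sample_arrivals(int(n_photons), p_ad, calibration, t0, tau_G, rng)
    counts, _ = np.histogram(t, bins=edges)
    return TCSPCHistogram(edges, counts)


# ---------------------------------------------------------------------------
# Stack simulation
# ---------------------------------------------------------------------------

_SEGMENT_UM = 0.25  # arc-length discretization of dendritic activation


@dataclass
class _EmitterGroup:
    name: str
    pix: np.ndarray  # flat pixel indices
    rates: np.ndarray  # baseline expected photons / pixel / frame
    vol: np.ndarray  # per-frame volume scale
    pad: np.ndarray  # per-frame molecular binding fraction


def _emitter_groups(phantom: ScenePhantom, program: PlasticityProgram, times: np.ndarray):
    """Split the scene into groups of pixels sharing one P_AD time course."""
    shape = phantom.shape
    n_pix = shape[0] * shape[1]
    s_stim = phantom.stimulated_spine.arclength_um
    groups: list[_EmitterGroup] = []

    for struct in phantom.structures:
        sel = struct.brightness_map.ravel() > 1e-9
        if not sel.any():
            continue
        pix = np.flatnonzero(sel)
        rates = struct.brightness_map.ravel()[pix]
        if struct.kind == "spine":
            if struct.label == phantom.stimulated_label:
                vol, pad = activation_time_course(program, times, kind="stimulated")
                groups.append(_EmitterGroup(struct.name, pix, rates, vol, pad))
            else:
                d = abs(struct.arclength_um - s_stim)
                vol, pad = activation_time_course(program, times, kind="spine", distance_um=d)
                groups.append(_EmitterGroup(struct.name, pix, rates, vol, pad))
        else:
            # Dendrite: activation varies along the shaft, so split pixels
            # into short arc-length segments, each with its own distance.
            pts = geometry.pixel_centers(shape, phantom.pixel_size_um)[pix]
            s, _ = geometry.project_to_polyline(pts, phantom.dendrite_path)
            d = np.abs(s - s_stim)
            seg = np.floor(d / _SEGMENT_UM).astype(int)
            for k in sorted(set(seg.tolist())):
                in_seg = seg == k
                d_rep = float(d[in_seg].mean())
                vol, pad = activation_time_course(program, times, kind="dendrite", distance_um=d_rep)
                groups.append(
                    _EmitterGroup(f"{struct.name}_seg{k}", pix[in_seg], rates[in_seg], vol, pad)
                )

    # Background: dark/autofluorescence photons, modelled as free donor.
    if phantom.background_rate > 0:
        groups.append(
            _EmitterGroup(
                "background",
                np.arange(n_pix),
                np.full(n_pix, phantom.background_rate),
                np.ones_like(times, dtype=float),
                np.zeros_like(times, dtype=float),
            )
        )
    return groups


def simulate_flim_stack(
    phantom: ScenePhantom,
    program: PlasticityProgram,
    acquisition: AcquisitionConfig,
    seed: int,
) -> tuple[FLIMStack, dict]:
    """Simulate the full FLIM time series plus a ground-truth record.

    Per pixel and frame the photon count is Poisson with mean
    brightness x volume_scale; each photon picks its decay component by
    :func:`bound_photon_probability`, draws an arrival time
    Exp(tau) + N(true_t0, tau_G), and is binned into the TCSPC window
    (out-of-window photons dropped).
    """
    if tuple(acquisition.frame_shape) != tuple(phantom.shape):
        raise ValueError("acquisition frame_shape must match the phantom shape")
    cal = acquisition.calibration
    times = acquisition.frame_times_s
    edges = acquisition.bin_edges
    n_bins = edges.size - 1
    e0, width = float(edges[0]), float(edges[1] - edges[0])
    shape = phantom.shape
    n_pix = shape[0] * shape[1]

    groups = _emitter_groups(phantom, program, times)
    children = np.random.SeedSequence(int(seed)).spawn(len(times))

    frames: list[FLIMFrame] = []
    drawn = 0
    binned = 0
    for f, t in enumerate(times):
        rng = np.random.default_rng(children[f])
        flat = np.zeros(n_pix * n_bins, dtype=np.int64)
        for g in groups:
            lam = g.rates * g.vol[f]
            counts = rng.poisson(lam)
            n = int(counts.sum())
            if n == 0:
                continue
            drawn += n
            arr = _sample_arrivals(n, float(g.pad[f]), cal, acquisition.true_t0, acquisition.tau_G, rng)
            bins = np.floor((arr - e0) / width).astype(np.int64)
            keep = (bins >= 0) & (bins < n_bins)
            binned += int(keep.sum())
            pix = np.repeat(g.pix, counts)[keep]
            flat += np.bincount(pix * n_bins + bins[keep], minlength=n_pix * n_bins)
        dtype = np.uint32 if flat.max() > np.iinfo(np.uint16).max else np.uint16
        frames.append(FLIMFrame(flat.reshape(shape[0], shape[1], n_bins).astype(dtype), float(t)))

    stack = FLIMStack(
        frames=frames,
        bin_edges=edges,
        pixel_size_um=phantom.pixel_size_um,
        calibration=cal,
        metadata={
            "seed": int(seed),
            "true_t0_ns": acquisition.true_t0,
            "tau_G_ns": acquisition.tau_G,
        },
    )
    truth = _ground_truth_record(phantom, program, acquisition, seed, drawn, binned)
    return stack, truth


def _ground_truth_record(phantom, program, acquisition, seed, drawn, binned) -> dict:
    times = acquisition.frame_times_s
    s_stim = phantom.stimulated_spine.arclength_um
    structures = {}
    for struct in phantom.structures:
        if struct.kind == "spine":
            stim = struct.label == phantom.stimulated_label
            d = 0.0 if stim else abs(struct.arclength_um - s_stim)
            vol, pad = activation_time_course(
                program, times, kind="stimulated" if stim else "spine", distance_um=d
            )
        else:
            d = 0.0
            vol, pad = activation_time_course(program, times, kind="dendrite", distance_um=0.0)
        structures[struct.name] = {
            "kind": struct.kind,
            "stimulated": struct.label == phantom.stimulated_label,
            "distance_um": d,
            "volume_scale": vol.tolist(),
            "p_ad": pad.tolist(),
        }
    profile = {}
    for d in range(5):
        _, pad = activation_time_course(program, times, kind="dendrite", distance_um=float(d))
        profile[str(d)] = pad.tolist()
    return {
        "seed": int(seed),
        "frame_times_s": times.tolist(),
        "program": dataclasses.asdict(program),
        "calibration": {"tau_D": acquisition.calibration.tau_D, "tau_AD": acquisition.calibration.tau_AD},
        "true_t0_ns": acquisition.true_t0,
        "tau_G_ns": acquisition.tau_G,
        "photons_drawn": int(drawn),
        "photons_binned": int(binned),
        "structures": structures,
        "dendrite_profile_p_ad": profile,
        "stimulated_base_arclength_um": s_stim,
    }


@dataclass
class IntensityMovie:
    """Green-channel intensity time series: (frames, z, rows, cols)."""

    data: np.ndarray
    times_s: np.ndarray
    pixel_size_um: float
    z_spacing_um: float = 1.0


def simulate_intensity_stack(
    phantom: ScenePhantom,
    program: PlasticityProgram,
    acquisition: AcquisitionConfig,
    seed: int,
) -> IntensityMovie:
    """Simulate the intensity z-stacks used for volume quantification.

    Each frame is a z-stack of ``z_slices`` planes; structure brightness is
    distributed across planes by the axial weighting profile and each plane
    is the average of ``frames_averaged`` independent Poisson acquisitions
    (so pixel variance is 1/frames_averaged of a single exposure).
    """
    if tuple(acquisition.frame_shape) != tuple(phantom.shape):
        raise ValueError("acquisition frame_shape must match the phantom shape")
    times = acquisition.frame_times_s
    stim = phantom.stimulated_spine
    static = phantom.background_rate + sum(s.brightness_map for s in phantom.structures)
    vol, _ = activation_time_course(program, times, kind="stimulated")
    w = acquisition.axial_weights
    children = np.random.SeedSequence([int(seed), 1]).spawn(len(times))
    out = np.empty((len(times), acquisition.z_slices) + tuple(phantom.shape), dtype=np.float32)
    for f in range(len(times)):
        rng = np.random.default_rng(children[f])
        rate = static + stim.brightness_map * (vol[f] - 1.0)
        for z in range(acquisition.z_slices):
            lam = rate * w[z]
            reps = rng.poisson(lam, size=(acquisition.frames_averaged,) + lam.shape)
            out[f, z] = reps.mean(axis=0)
    return IntensityMovie(out, times.copy(), phantom.pixel_size_um, acquisition.z_spacing_um)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_fixture(scenario: Scenario, seed: int, out_dir) -> dict:
    """Simulate a scenario and write the standard fixture files.

    Writes the FLIM container (HDF5), the intensity stack (OME-TIFF), the
    labelled structure masks (TIFF), the dendrite path (CSV), the
    ground-truth sidecar (JSON) and the scenario itself (YAML); returns a
    dict of the written paths.
    """
    from . import io as fio  # deferred: io imports nothing from here

    phantom = build_phantom(scenario.geometry, seed=seed)
    stack, truth = simulate_flim_stack(phantom, scenario.program, scenario.acquisition, seed)
    movie = simulate_intensity_stack(phantom, scenario.program, scenario.acquisition, seed)
    return fio.write_fixture(out_dir, scenario, phantom, stack, truth, movie)
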