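"""Shared fixtures: numerical oracles and simulated datasets.

The heavy simulated datasets are session-scoped so that unit tests and the
acceptance suite share one computation.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import curve_fit

import flimspine as fs
from flimspine import roi as froi
from flimspine.scenarios import load_scenario

try:
    from hypothesis import HealthCheck, settings

    settings.register_profile(
        "deterministic",
        derandomize=True,
        max_examples=50,
        deadline=None,
        suppress_health_check=[HealthCheck.too_slow],
    )
    settings.load_profile("deterministic")
except ImportError:  # pragma: no cover
    pass


# ---------------------------------------------------------------------------
# Independent numerical oracles
# ---------------------------------------------------------------------------


def kernel_convolution_oracle(dt: float, tau: float, sigma: float) -> float:
    """Gaussian (x) one-sided-exponential convolution by adaptive quadrature.

    Integrates exp(-(dt-u)/tau) phi(u; 0, sigma) over u <= dt; independent
    of the closed-form kernel it checks.
    """
    lo = min(dt, 0.0) - 12.0 * sigma
    pts = [x for x in (-3 * sigma, 0.0, 3 * sigma) if lo < x < dt]
    val, _ = quad(
        lambda u: math.exp(-(dt - u) / tau - u * u / (2 * sigma * sigma)),
        lo,
        dt,
        points=pts or None,
        epsabs=0.0,
        epsrel=1e-11,
        limit=400,
    )
    return val / (sigma * math.sqrt(2.0 * math.pi))


def fit_exponential_decay_length(distances, values) -> float:
    """Least-squares A exp(-d/L) fit; returns L."""
    popt, _ = curve_fit(
        lambda d, a, L: a * np.exp(-d / L),
        np.asarray(distances, float),
        np.asarray(values, float),
        p0=(max(float(np.max(values)), 1e-3), 2.0),
        maxfev=20000,
    )
    return float(popt[1])


@pytest.fixture(scope="session")
def calibration() -> fs.CalibrationConstants:
    return fs.CalibrationConstants()


# ---------------------------------------------------------------------------
# Simulated datasets
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def smoke_run() -> dict:
    """One seed of the small smoke-test scenario (shared, read-only)."""
    scn = load_scenario("smoke_test")
    phantom = fs.build_phantom(scn.geometry, seed=11)
    stack, truth = fs.simulate_flim_stack(phantom, scn.program, scn.acquisition, seed=11)
    movie = fs.simulate_intensity_stack(phantom, scn.program, scn.acquisition, seed=11)
    return {"scenario": scn, "phantom": phantom, "stack": stack, "truth": truth, "movie": movie}


@pytest.fixture(scope="session")
def quiet_run() -> dict:
    """Small scenario with zero programmed activation and volume change."""
    scn = load_scenario("smoke_test")
    prog = fs.PlasticityProgram(
        volume_transient_amplitude=0.0,
        volume_sustained_amplitude=0.0,
        pad_transient_amplitude=0.0,
        pad_sustained_amplitude=0.0,
    )
    phantom = fs.build_phantom(scn.geometry, seed=11)
    stack, truth = fs.simulate_flim_stack(phantom, prog, scn.acquisition, seed=21)
    movie = fs.simulate_intensity_stack(phantom, prog, scn.acquisition, seed=21)
    return {"scenario": scn, "program": prog, "phantom": phantom, "stack": stack, "truth": truth, "movie": movie}


def run_default_scenario_recovery(seeds) -> dict:
    """End-to-end pipeline recovery of the default scenario over seeds.

    For each seed: simulate FLIM + intensity, fit per-frame offsets, measure
    the stimulated spine's volume and activation time courses and the
    dendritic spreading profile, and window-average both the recovered and
    the programmed (ground-truth) curves at the frame times.
    """
    scn = load_scenario("wt_default")
    phantom = fs.build_phantom(scn.geometry, seed=3)
    roiset = froi.RoiSet.from_phantom(phantom)
    stim = roiset.stimulated_spine
    out = {k: [] for k in (
        "vol_transient", "vol_sustained", "pad_transient", "pad_sustained",
        "true_vol_transient", "true_vol_sustained", "true_pad_transient", "true_pad_sustained",
        "basal_pad", "spread_sustained",
    )}
    for seed in seeds:
        stack, truth = fs.simulate_flim_stack(phantom, scn.program, scn.acquisition, seed=seed)
        movie = fs.simulate_intensity_stack(phantom, scn.program, scn.acquisition, seed=seed)
        fits = froi.fit_frame_offsets(stack)
        t0 = np.array([f.params.t0 for f in fits])
        vol = froi.volume_change_timecourse(movie, roiset.spine_masks[stim], roiset.background_mask)
        act = froi.activation_timecourse(stack, roiset.spine_masks[stim], t0=t0)
        prof = froi.dendrite_spread_profile(stack, roiset, t0=t0)
        times = stack.times_s
        tv = np.array(truth["structures"]["spine_0"]["volume_scale"])
        tp = np.array(truth["structures"]["spine_0"]["p_ad"])
        basal = froi.BASAL_WINDOW.contains(times) & (times < 0)
        tp_delta = tp - tp[basal].mean()

        def true_avg(vals, window):
            return float(np.mean(vals[window.contains(times)]))

        out["vol_transient"].append(froi.window_average(vol, froi.VOLUME_TRANSIENT_WINDOW))
        out["vol_sustained"].append(froi.window_average(vol, froi.SUSTAINED_WINDOW))
        out["pad_transient"].append(froi.window_average(act, froi.PAD_TRANSIENT_WINDOW))
        out["pad_sustained"].append(froi.window_average(act, froi.SUSTAINED_WINDOW))
        out["true_vol_transient"].append(true_avg(tv, froi.VOLUME_TRANSIENT_WINDOW))
        out["true_vol_sustained"].append(true_avg(tv, froi.SUSTAINED_WINDOW))
        out["true_pad_transient"].append(true_avg(tp_delta, froi.PAD_TRANSIENT_WINDOW))
        out["true_pad_sustained"].append(true_avg(tp_delta, froi.SUSTAINED_WINDOW))
        out["basal_pad"].append(act.baseline_value)
        out["spread_sustained"].append(prof.by_window("sustained"))
    result = {k: np.asarray(v) for k, v in out.items()}
    result["spread_distances"] = prof.distances_um
    result["program"] = scn.program
    result["true_basal_pad"] = scn.program.pad_baseline
    result["spread_length_fit"] = fit_exponential_decay_length(
        prof.distances_um, result["spread_sustained"].mean(axis=0)
    )
    return result


@pytest.fixture(scope="session")
def wt_recovery() -> dict:
    """Ten-seed end-to-end recovery of the default scenario."""
    return run_default_scenario_recovery(range(10))
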