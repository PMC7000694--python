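# flimspine

Quantification of two-photon fluorescence-lifetime imaging (2pFLIM) FRET
experiments on single dendritic spines, together with a photon-level
simulator of the underlying experiment so the entire pipeline can be
exercised and validated without microscope data.

## Who this is for

Labs that monitor signaling (e.g. small-GTPase FRET sensors) during
single-spine structural plasticity: a caged-glutamate stimulus is delivered
to one spine, and the readouts are (i) the spine volume change from
green-channel intensity stacks and (ii) the sensor **binding fraction**
from the donor fluorescence lifetime, over a baseline period and tens of
minutes of follow-up, including how activation spreads into the dendrite.

## The model

Time-correlated single photon counting (TCSPC) histograms of donor photons
are described by a two-lifetime mixture convolved with a Gaussian
instrument response of width τ<sub>G</sub>:

```
F(t) = F0 [ P_D · H(t, t0, τ_D, τ_G) + P_AD · H(t, t0, τ_AD, τ_G) ]

H(t, t0, τ, τ_G) = ½ exp(τ_G²/(2τ²) − (t−t0)/τ) · erfc( (τ_G² − τ(t−t0)) / (√2 τ τ_G) )
```

with τ_D = 2.6 ns (free eGFP donor) and τ_AD = 1.1 ns (donor bound to
acceptor) held fixed.  Whole-image histograms are fit by Poisson maximum
likelihood to obtain F0, P_AD, t0 and τ_G.  Small ROIs (a spine, or 1 µm
segments of dendrite) are quantified without fitting: pooled photons give a
mean arrival time ⟨t⟩, the mean lifetime is ⟨τ⟩ = ⟨t⟩ − t0, and the binding
fraction follows in closed form,

```
P_AD = τ_D (τ_D − ⟨τ⟩) / [ (τ_D − τ_AD)(τ_D + τ_AD − ⟨τ⟩) ]
```

which is the exact inverse of the intensity-weighted mixture mean
⟨τ⟩ = (P_D τ_D² + P_AD τ_AD²)/(P_D τ_D + P_AD τ_AD).  Because the TCSPC
window is finite (12.5 ns at an 80 MHz laser), ROI estimates use the exact
finite-window generalization of this inversion by default (see
`docs/methods.md`); it reduces to the formula above as the window grows.

Spine volume is the background-subtracted integrated green intensity F,
reported as F/F0 with F0 the mean over the pre-stimulus baseline.  Quality
control follows the standard rules: recordings whose baseline ROI lifetime
fluctuates by more than 0.15 ns (peak-to-peak) are excluded, spine-volume
cohorts pass through ROUT outlier removal (Q = 1%), groups are summarized
as mean ± SEM, and two-group comparisons use the unpaired two-tailed
Student's t test.

The simulator (`flimspine.simulate`) renders a dendrite-plus-spines
phantom, drives it with a transient-plus-sustained activation program
triggered at the uncaging onset (volume: +150% peak relaxing to +40%;
binding fraction: baseline 0.12, ΔP_AD 0.08 transient / 0.04 sustained;
dendritic spread with a 2 µm length constant), and emits every photon
individually: Poisson pixel counts, lifetime mixture component by
photon-yield weighting, arrival time Exp(τ) + Gaussian IRF, binned into
the TCSPC window.

## Worked example

```
flimspine simulate --scenario smoke_test --seed 7 --out demo/fx
flimspine analyze  --fixture demo/fx --out demo/analysis
cat demo/analysis/window_averages.csv
```

prints

```
roi,quantity,window,value
stimulated_spine,F_over_F0,transient,1.9011619437213747
stimulated_spine,F_over_F0,sustained,1.4020590359415437
stimulated_spine,delta_P_AD,transient,0.03308140483407784
stimulated_spine,delta_P_AD,sustained,0.041586396008797676
stimulated_spine,P_AD,basal,0.12589269261247354
```

The stimulated spine roughly doubled in volume during the transient window
(F/F0 ≈ 1.90, i.e. +90% averaged over minutes 1–3) and settled at +40%
(sustained window, minutes 10–25), matching the programmed +150% peak with
exponential relaxation to +40%.  Sensor activation rose by ΔP_AD ≈ 0.03–0.04
over a basal binding fraction of ≈ 0.126 (programmed: 0.12); this small demo
scenario carries few photons per frame, so individual windows sit within a
couple of standard errors of the programmed values.  `spread_profile.csv`
tabulates ΔP_AD versus distance along the dendrite (0–4 µm), and
`qc_report.csv` shows the baseline-stability check (here 0.063 ns
peak-to-peak, retained at the 0.15 ns threshold).

The same steps at the library level:

```python
import flimspine as fs
from flimspine import roi

scn = fs.load_scenario("wt_default")
phantom = fs.build_phantom(scn.geometry, seed=3)
stack, truth = fs.simulate_flim_stack(phantom, scn.program, scn.acquisition, seed=0)
rois = roi.RoiSet.from_phantom(phantom)
act = roi.activation_timecourse(stack, rois.spine_masks[rois.stimulated_spine])
print(act.baseline_value, roi.window_average(act, roi.SUSTAINED_WINDOW))
```

## Layout

| module | contents |
| --- | --- |
| `flimspine.model` | decay kernel, mixture model, Poisson population fit, lifetime maps, binding-fraction inversion |
| `flimspine.simulate` | phantom, plasticity program, photon-level FLIM and intensity simulation, fixtures |
| `flimspine.roi` | volume change, activation time courses, window averages, dendritic spread profiles |
| `flimspine.qc` | baseline-stability filter, ROUT outlier removal, group summaries, t test |
| `flimspine.stack` / `flimspine.io` | FLIM container (HDF5), TIFF/CSV/YAML/JSON readers and writers, run manifests |
| `flimspine.cli` | `flimspine simulate / fit / map / analyze / report` |
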