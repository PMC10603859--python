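# caroseg

Tools for 3D carotid ultrasound (3DUS) vessel-wall analysis: reproducibility
of repeated boundary segmentation at different inter-slice distances (ISD),
vessel-wall volume (VWV) and vessel-wall-plus-plaque thickness (VWT)
quantification, a two-channel U-Net driven by an adaptive triple Dice loss,
and a comparison of data-partition strategies for serial (baseline /
follow-up) imaging — all exercised on synthetic carotid phantoms with known
ground truth.

## Who this is for

Researchers building or validating 3DUS carotid workflows: the package
provides the full measurement chain (contours → shape-based inter-slice
interpolation → DSC/Hausdorff → VWV/VWT → agreement statistics) plus a
CPU-only segmentation network and reproducible study harnesses, without
requiring any patient data.

## The measurements at its core

Two closed boundaries are delineated per axial slice: the media-adventitia
boundary (MAB) and the lumen-intima boundary (LIB). Repeated segmentations
are compared slice-by-slice after shape-based interpolation to common
slices, using the Dice similarity coefficient

    DSC = 2 |M1 ∩ M2| / (|M1| + |M2|)

and the in-plane Hausdorff distance
HD = max(h(M1, M2), h(M2, M1)), h(A, B) = max_{a∈A} min_{b∈B} d(a, b).

VWV is the volume enclosed by the MAB surface minus that enclosed by the
LIB surface; point-wise VWT is the distance between corresponding MAB/LIB
points, flattened to a 2D L-shaped carotid map. Agreement statistics follow
the standard toolbox: Shapiro–Wilk-gated paired t / Wilcoxon tests, the
two-way mixed absolute-agreement ICC(A,1) with F-based 95% CI, Pearson r,
and Bland–Altman bias / RPC (= 1.96·SD of differences) / CV.

The segmentation network is a two-channel U-Net (sigmoid outputs for MAB
and LIB) trained with the adaptive triple Dice loss

    L = a·L_DSC(y_MAB, ŷ_MAB) + b·L_DSC(y_LIB, ŷ_LIB) + c·L_DSC(y_CVW, ŷ_CVW),

a + b + c = 1, where CVW = MAB − LIB is the vessel wall; the weights start
uniform and then adapt to the smoothed component losses. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from caroseg import phantom, metrics, quantify

# one synthetic patient (baseline + follow-up), rendered 3DUS-like volume
base, followup = phantom.sample_cohort(1, seed=7)[0]

# two virtual-observer segmentation trials at ISD = 2 mm
obs = phantom.ObserverModel(radial_noise_sd=0.15, seed=0)
t1 = phantom.virtual_observer(base, isd=2.0, model=obs, trial_seed=0)
t2 = phantom.virtual_observer(base, isd=2.0, model=obs, trial_seed=1)

comps = metrics.compare_stacks(t1, t2, grid_spacing=0.1)
dsc = np.mean([c.dsc for c in comps if c.boundary_kind == "MAB"])
print(f"bifurcation distance: {metrics.bifurcation_distance(t1, t2):.2f} mm")
print(f"mean MAB DSC between trials: {dsc:.3f}")
print(f"VWV trial 1: {quantify.vwv(t1, grid_spacing=0.1):.1f} mm^3")
print(f"VWV trial 2: {quantify.vwv(t2, grid_spacing=0.1):.1f} mm^3")
```

prints (seeds as above):

```
bifurcation distance: 0.00 mm
mean MAB DSC between trials: 0.948
VWV trial 1: 347.5 mm^3
VWV trial 2: 337.0 mm^3
```

The two trials happen to agree on the bifurcation slice, their MAB
outlines overlap with DSC ≈ 0.95 — in the range typical of repeated manual
tracing — and the tracing noise moves the VWV estimate by about 3%,
illustrating why VWV agreement is summarized with ICC and Bland–Altman
statistics over a cohort rather than single volumes.

A command-line interface mirrors the library:
`caroseg phantom generate`, `caroseg metrics compare`, `caroseg quantify`,
`caroseg stats`, `caroseg segment train/predict`,
`caroseg study isd`, `caroseg study partition` (see `--help`).

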