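# lsdi — local-saturation-and-delay MR flow imaging

Blood viscosity is usually measured by drawing a sample and spinning it in a
rotary rheometer. That number is fragile — it depends on anticoagulants,
storage, and a Couette flow regime unlike anything in a vessel — and it cannot
be tracked longitudinally in the same animal without repeated blood draws.
Local-saturation-and-delay imaging (LSDI) turns an MR scanner into an in-vivo
viscometer: saturate a slab perpendicular to an artery, wait a few
milliseconds, and read out with a T1-weighted FLASH sequence. Fresh blood that
flowed into the slab during the flow-sensitive window τ = T_delay + TE is
bright, so the upstream edge of the dark slab is carved into the shape of the
radial velocity profile v(r).

This package implements that method end to end for synthetic data:

* **`lsdi.two_phase_flow`** — steady two-phase laminar flow in a rigid
  circular vessel. Blood is a viscous RBC-rich core (viscosity μ_c, radius
  λ·r_vessel) surrounded by a cell-free plasma layer (viscosity μ_p). The
  Stokes equation with piecewise viscosity gives a two-segment parabola,

      v_p(r) = (−A/4μ_p)(r_v² − r²)                        λr_v < r ≤ r_v
      v_c(r) = (−A/4)[(λ²r_v² − r²)/μ_c + r_v²(1−λ²)/μ_p]   0 ≤ r ≤ λr_v

  with A = dp/dz < 0. The ratio of the quadratic coefficients of the two
  branches equals μ_c/μ_p — the **whole blood relative viscosity**
  (WBRV, η_r), the same dimensionless quantity a rheometer reports as
  WBV/PV. A finite-volume solver of the same boundary-value problem serves
  as an independent numeric oracle.
* **`lsdi.lsdi_simulator`** — the forward model: protocol arithmetic (pixel
  spacing, scan time, flow-sensitive window), the cardiac-timing-derived
  segmentation threshold P = 1 − (T_dia − τ)/T_C (used at 80 % as a safety
  margin), and a renderer producing saturation/delay images of a pulsatile
  two-phase flow with Gaussian or Rician noise.
* **`lsdi.profile_extraction`** — the inverse pipeline: crop → threshold
  segmentation (suppresses systolic inflow) → bicubic subpixel edge
  localization → vessel axis/tilt correction → constrained two-parabola fit
  with no-slip and interface continuity enforced, breakpoint found by
  exhaustive search → η_r and λ̂.
* **`lsdi.hemorheology`** — rheometer-side WBRV, the Doppler vascular
  resistance index (PSV − EDV)/PSV, an exact (fully enumerated) two-sided
  rank test for five-animal groups, Spearman correlation, and a bundled
  13-rat rheology panel.
* **`lsdi.io_cli`** — YAML config, the seeded fixture battery, reporting,
  and the `lsdi` command line.

## Worked example

Render a noisy image of a vessel with true η_r = 4 and λ = 0.9, then recover
both from the image alone:

```bash
$ lsdi simulate --out scan.tif --eta-r 4 --lambda 0.9 --noise 0.02 --seed 7
INFO lsdi: wrote scan.tif (threshold 0.420)
$ lsdi extract --image scan.tif
{
  "eta_r": 4.068494714715579,
  "lambda_hat": 0.9000000000000004,
  "a_core": -3.0495833338586116,
  "a_plasma": -12.407213675888476,
  ...
}
```

The threshold 0.420 is the cardiac-timing value for τ = 20 ms, a 160 ms
cycle with a 3/5 diastolic fraction and the 80 % safety factor. The
recovered `eta_r` of 4.07 (true value 4) is the ratio of the fitted
plasma-branch to core-branch quadratic coefficients (−12.41 / −3.05); the
breakpoint search put the cell-free-layer boundary at λ̂ = 0.90.

The rheometer side, on the bundled panel:

```bash
$ lsdi rheo --compare NC EPO --shear 200
{... "statistic": 0.0, "p_value": 0.007936507936507936 ...}
```

The erythropoietin-treated group separates completely from controls at a
shear rate of 200 s⁻¹ (U = 0); with five animals per group the exact
two-sided p is 2/252 ≈ 0.0079.

Python API equivalent:

```python
from lsdi import (AcquisitionProtocol, CardiacCycle, phantom_profile,
                  render_lsdi_image, estimate_wbrv_from_image)

protocol = AcquisitionProtocol()          # rat carotid protocol defaults
cycle = CardiacCycle(T_C=160.0)           # 375 bpm, diastolic fraction 0.6
profile = phantom_profile(eta_r=4.0, lambda_core=0.9)
image = render_lsdi_image(profile, protocol, cycle, noise_sigma=0.0, seed=1)
estimate = estimate_wbrv_from_image(image, protocol, cycle)
print(estimate.eta_r, estimate.lambda_hat)   # 3.9658... 0.9000...
```

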