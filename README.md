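# qpiphase

Simulated quantitative-phase microscopy of uniform layered samples, and a
deep-learning phase-retrieval pipeline whose recovered phase can be
*quantified* against the analytically known ground truth.

## The problem

Quantitative phase imaging (QPI) measures the optical phase a sample imprints
on light, but phase maps recovered by neural networks raise an obvious
question: are they *correct*? For uniform layered samples the answer is
computable. A thin film on a glass coverslip — a lossy plasmonic gold layer
(thickness d_m, complex index n_m) or a lossless dielectric waveguide —
has closed-form complex reflection coefficients r_s(θ), r_p(θ) from the
Fresnel equations and the transfer-matrix method. Imaged through a high-NA
oil-immersion objective (NA 1.49, substrate index n₀ = 1.52), every pixel of
the objective's back focal plane (BFP) corresponds to one incidence
direction (k_x, k_y), and for x-polarized illumination the reflected pupil
field is

    E_x = r_p cos²φ + r_s sin²φ
    E_y = (r_p − r_s) sinφ cosφ,     φ = atan2(k_y, k_x)

with the captured BFP image |E_x|² + |E_y|². Defocusing the sample by z
multiplies the pupil field by the double-pass factor e^{2ikz·z}, and the
image-plane (IMP) field is its inverse Fourier transform:

    IMP_x = F⁻¹{E_x e^{2ikz·z}},   IMP = |IMP_x|² + |IMP_y|².

The package generates supervised datasets pairing these *intensity* images
(BFP and/or defocused IMPs, cropped to one mirror-symmetric quadrant) with
the wrapped phase of E_x as the regression label, trains a context
aggregation network (CAN: ten levels of exponentially dilated 3×3
convolutions with adaptive normalization) to recover the phase, and scores
the result with an offset-invariant SSIM — the structural similarity of the
wrapped maps maximized over a global phase constant, which is physically
unobservable. As a functional end-point, confocal V(z) curves computed from
the true and the recovered phase are compared: for plasmonic samples |V(z)|
ripples at negative defocus with period λ/(2 n₀ (1 − cosθ_sp)) set by the
plasmon angle θ_sp.

The network variants differ only in their inputs: CAN1 [BFP], CAN2
[BFP + IMP(0)], CAN3 [IMP(6 µm)], CAN4 [IMP(6), IMP(9)], CAN5
[IMP(6), IMP(7.5), IMP(9)]. Channel switch-off (ablation) experiments ask
which plane actually carries the phase information.

## Worked example

```python
import numpy as np
import qpiphase as q

# pupil sampling of the simulated 1.49-NA objective
grid = q.build_pupil_grid(512, 1.49, 633.0, 1.52)
print(f"per-pixel sin(theta0) increment: {grid.delta_sin_theta0:.4f}")

# 50 nm gold film on BK7, air backing, at the HeNe line
gold = q.LayerStack(1.52, ((q.material_index("gold", 633.0), 50.0),), 1.0, 633.0)
crit = q.critical_angle(1.52, 1.0)
dip, depth = q.find_reflectance_dip(gold, "p", theta_min=crit + 0.005,
                                    theta_max=np.arcsin(1.49 / 1.52))
print(f"glass/air critical angle: {np.degrees(crit):.2f} deg")
print(f"plasmon dip: {np.degrees(dip):.2f} deg, reflectance {depth:.4f}")
print(f"predicted V(z) ripple period: {q.vz_ripple_period(633.0, 1.52, dip):.3f} um")

field = q.compute_bfp_fields(grid, gold)
bfp = q.bfp_intensity(field)
print(f"BFP intensity min inside pupil: {bfp[grid.mask].min():.4f}")
```

prints

```
per-pixel sin(theta0) increment: 0.0038
glass/air critical angle: 41.14 deg
plasmon dip: 43.60 deg, reflectance 0.0059
predicted V(z) ripple period: 0.755 um
BFP intensity min inside pupil: 0.0067
```

The 512-pixel pupil samples sinθ₀ in steps of 0.0038. The p-polarized
reflectance of the gold film collapses to 0.6% at 43.60°, beyond the 41.14°
critical angle — the dark surface-plasmon band in the BFP (the intensity
minimum of the full vectorial pupil image, 0.0067, sits on that band).
A phase recovered from such images is validated functionally by the V(z)
ripple period, 0.755 µm here.

End-to-end pipelines are scripted:

```bash
qpiphase pipeline --preset spr-desk --out runs/spr-can1
qpiphase simulate --preset spr-paper --case 3 --z 0 --z 6 --out sim/case3
qpiphase vz --preset spr-paper --case 3 --out vz_case3.csv
```

`spr-desk` / `waveguide-desk` are CPU-scale presets (64×64 inputs, 8
features, 200 records, 30 epochs); `spr-paper` / `waveguide-paper` carry
the full-scale settings (256×256, 64 features, 1000 records, 100 epochs,
learning rate 1e-4), which want a GPU-class budget.

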