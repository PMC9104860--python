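# Methods

## Optical model

The microscope is a reflection-mode inverted system: a linearly polarized
plane wave (electric field along x) fills the pupil of an oil-immersion
objective (NA 1.49) and is focused through a BK7 coverslip (n₀ = 1.52) onto
a single deposited layer backed by the sample medium. Two sample families
are modeled:

* **Plasmonic (SPR) samples** — a gold film, 30–60 nm, complex index from
  the embedded Johnson & Christy (1972) tabulation (CSV fixture
  `data/gold_johnson_christy.csv`, 496–892 nm, linearly interpolated).
  Lossy: p-polarized reflectance collapses at the plasmon angle beyond the
  critical angle, producing a dark band in the BFP.
* **Dielectric waveguide samples** — a lossless layer (n = 1.20–1.50,
  0.95–1.05 µm, PMMA = 1.489 for the fixed test cases). |r| = 1 beyond the
  critical angle: all mode information lives in the phase.

Reflection coefficients come from the Fresnel equations (bare interface)
and the 2×2 characteristic-matrix method (finite films), with tilted
admittances η_s = n cosθ and η_p = n/cosθ. Conventions, fixed once and
used everywhere:

* Time dependence e^{−iωt}; absorbing media have Im(n) > 0; the matrix
  entries are −i sinδ/η and −iη sinδ, and evanescent transmitted cosines
  take the decaying branch Im(n cosθ) ≥ 0. Flipping the convention
  conjugates r and leaves |r| unchanged (tested).
* r_p is defined so that r_p(0°) = r_s(0°). This is the only choice under
  which E_x = r_p cos²φ + r_s sin²φ is continuous at the pupil centre;
  the Brewster zero and unit-modulus total internal reflection are
  unaffected.
* The phase reference plane is the substrate/film interface (the
  characteristic-matrix formulation references phase there by
  construction), so labels carry no arbitrary per-sample offset.

## Pupil and image formation

The pupil is an N×N grid (N = 512 at full scale) spanning ±2πNA/λ with
k = 0 at pixel (N/2, N/2); the per-pixel increment of sinθ₀ is
2(NA/n₀)/N = 0.0038 at N = 512. The NA mask is the *strict* interior of
the pupil circle, evaluated at pixel centres; strictness guarantees every
in-mask pixel has an exact mirror partner on the grid, which makes
quadrant cropping exactly invertible. Azimuthal factors are computed as
k_x²/k_r², k_y²/k_r², k_x k_y/k_r² rather than through trigonometric
functions of atan2, so the twofold mirror symmetry of the sampled maps is
bitwise. No apodization (√cosθ) factor is applied: the model pupil is a
uniform plane-wave expansion and only the sample's reflection coefficients
shape the field.

Defocus by z (µm, positive away from the objective) multiplies the pupil
field by e^{2ikz·z} — the factor 2 is the reflection double pass — and the
image-plane field is the centred inverse FFT with unitary ("ortho")
normalization, which conserves energy exactly (kz is real inside the mask
because NA < n₀). The image-plane pixel pitch is the FFT-conjugate pitch
λ/(2NA) ≈ 212 nm at 633 nm. The confocal response V(z) = Σ w·E_x·e^{2ikz·z}
uses a unit pupil weight by default (a weight map hook exists); reported
curves are |V| normalized to a maximum of 1. For gold in air the
negative-defocus ripple period λ/(2n₀(1 − cosθ_sp)) evaluates to 0.755 µm
with θ_sp = 43.60° from the reflectance-dip scan, and the simulated curve
reproduces it to the z sampling step.

## Dataset generation

Each record draws d_m, the film index (a ±10% scale on gold, or the
waveguide index directly), the backing index n_s ∈ [1.0, 1.4], and
λ ∈ [600, 700] nm independently and uniformly; the six held-out test cases
(3 thicknesses × {air, water}, λ = 633 nm, nominal film index) have zero
probability of being drawn exactly, and a minimum-distance check asserts
it. Inputs are the upper-right quadrant (k_x ≥ 0, k_y ≥ 0, including the
centre row/column) of the BFP intensity and/or defocused IMP intensities;
IMP channels are z-score normalized per image, while the BFP channel keeps
its natural reflectance scale (a flag z-scores it too). The label is the
cropped wrapped phase of E_x in [−π, π). Defaults for the single-IMP
variants: z = 0 for the BFP+IMP pair (CAN2), z = 6 µm when learning from
image-plane data alone (CAN3–5, whose multi-plane defaults are 6/9 and
6/7.5/9 µm). Records serialize to one HDF5 file per dataset
(/inputs, /labels, /params) with a JSON sidecar holding the generating
config and seed; reload is bit-exact.

Two ambiguities were closed as package defaults with config switches for
the alternative: the ±10% gold perturbation scales n and k jointly
(`independent_gold_scale` draws them separately), and IMP channels carry
intensity |IMP_x|² + |IMP_y|² (`imp_amplitude` switches to its square
root), intensity being what a camera records.

## Network and training

The CAN is fully convolutional: nine 3×3 convolution levels with dilation
1, 2, 4, …, 128, 1 (padding = dilation, stride 1, spatial size preserved),
each followed by adaptive normalization and a leaky ReLU (slope 0.2;
0.01 at the last hidden level), closed by a 1×1 convolution to one
channel and an MSE regression head. After the dilation-128 level the
receptive field is 1 + 2(1+2+…+128) = 511 pixels — it covers the 256×256
input. Adaptive normalization is AN(x) = a·x + m·(γ·IN(x) + β) with
learnable scalars a, m per level and per-channel γ, β; instance statistics
are used since the minibatch size is one (with a single image, batch and
instance statistics coincide). Initialization: fan-in-scaled Gaussian
weights, a = 1, m = 0 (the network starts as a plain convolution stack and
learns the normalized branch in).

No deep-learning framework is used: convolutions are im2col + matmul in
numpy with hand-derived reverse-mode gradients, optimized by Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), minibatch 1. Training is deterministic
given the seed. Checkpoints are a `.npz` weight archive plus a JSON
architecture sidecar.

Two profiles exist as presets:

| profile | pupil | input | M | records | epochs | lr |
|---|---|---|---|---|---|---|
| paper (`spr-paper`, `waveguide-paper`) | 512 | 256×256 | 64 | 1000 | 100 | 1e-4 |
| desk (`spr-desk`, `waveguide-desk`) | 128 | 64×64 | 8 | 200 | 30 | 1e-3 |

The desk profile exists so the complete method — generation, training,
evaluation, ablation — runs in minutes on one CPU. Its learning rate is
1e-3 rather than the full-scale 1e-4 because the scaled model has ~3
orders of magnitude fewer parameters and far fewer update steps. The
memorization check (5 records, 500 epochs) uses a 3e-3 rate: that check
asks whether the architecture and optimizer can drive the training loss
to a small fraction of its initial value on a handful of images, so its
rate is chosen for convergence within the epoch budget (a cosine
annealing schedule is available in ``TrainConfig`` but is not the
default).

## Evaluation

Recovered and theoretical phase maps are compared wrapped to [−π, π)
(wrapping avoids unwrapping artifacts at near-2π transitions). Because a
global phase constant is unobservable, SSIM is maximized over a uniform
grid of 360 offsets in [0, 2π); the reported value is that maximum
together with its offset. SSIM uses the standard windowed form: 11-pixel
Gaussian window (σ = 1.5), K₁ = 0.01, K₂ = 0.03, dynamic range 2π.
Notes on behaviour that follows from wrapping: the maximum over offsets
is taken as the similarity score (an extremum over the nuisance
parameter); an off-grid true offset is recovered to grid resolution, so
a constant-offset-shifted map scores 1 only up to the half-step residual
interacting with the ±π boundary; the metric is symmetric under argument
swap only up to that same boundary effect; and values below 0 are
reported as computed rather than clipped.

The V(z) comparison mirrors the recovered quadrant back to the full pupil,
builds the surrogate field |E_x|·e^{iφ_rec}, and compares max-normalized
|V(z)| curves; a constant phase error cancels exactly, so the functional
check is insensitive to precisely the degree of freedom SSIM is made
invariant to.

## What the tests show — and what they do not

The synthetic generator *is* the study design: noiseless, uniform,
laterally homogeneous samples whose ground truth is computable. Passing
tests demonstrate that the simulator obeys its physics (energy
conservation, TIR, Brewster, plasmon dispersion), that the learning
pipeline extracts phase information from intensity images at CPU scale
(beating predict-the-mean and untrained baselines, and reproducing the
channel-importance ordering: for SPR samples, zeroing the BFP input hurts
far more than zeroing the IMP input), and that the evaluation metric has
the claimed invariances. They do not demonstrate full-scale SSIM levels
(which require ~10⁴× more compute), robustness to detector noise or
aberrations, generalization beyond the training parameter ranges, or
performance on structured (non-uniform) samples.

## Numerical notes

* Pixels at exactly the mask boundary are excluded (strict inequality);
  θ₀ at the mask edge uses the pixel-centre coordinate.
* Degenerate inputs fail loudly: z-scoring a constant image, empty
  datasets, mismatched channel counts or defocus lists, NA ≥ n₀ grids.
* Labels are stored float64 so the wrapped-phase half-open range survives
  storage; network inputs are float32.
* The reflectance-dip search is a dense angular scan refined by one
  parabolic interpolation; V(z) ripple periods are medians of successive
  minima spacings over z ∈ [−10, −3] µm at 0.05 µm steps.
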